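"""Differentially methylated site (DMS) discovery.

Two groups of samples are compared per CpG site with the Wilcoxon
rank-sum test (methylation levels are bimodal, not normal), p values are
adjusted with Benjamini-Hochberg over exactly the tested sites, and
sites are filtered on FDR, optional raw p, absolute delta methylation
(case-minus-control difference of group mean betas over non-missing
entries) and per-group detection frequency.  Sites must be measured in
at least ``min_detect`` of the samples of each compared group before
testing; the BH universe is the post-filter site set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from methdx.calling import detection_frequency, split_site_id
from methdx.simulate import BENIGN, MALIGNANT

DMS_COLUMNS = ["site_id", "n_case", "n_control", "p_value", "fdr",
               "delta", "detect_case", "detect_control"]


@dataclass(frozen=True)
class DMSThresholds:
    """Cutoffs for DMS discovery.

    Defaults are the tissue criteria (FDR < 0.05, |delta| >= 0.15,
    detection >= 0.65).  ``plasma()`` gives the plasma criteria
    (FDR < 0.2, p < 0.001, |delta| >= 0.02).  FDR/p comparisons are
    strict by default; set ``fdr_comparator="le"`` for inclusive.
    """

    max_fdr: float = 0.05
    max_p: float | None = None
    min_abs_delta: float = 0.15
    min_detect: float = 0.65
    fdr_comparator: str = "lt"

    def __post_init__(self) -> None:
        for name in ("max_fdr", "min_abs_delta", "min_detect"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.max_p is not None and not (0.0 <= self.max_p <= 1.0):
            raise ValueError("max_p must be in [0, 1]")
        if self.fdr_comparator not in {"lt", "le"}:
            raise ValueError("fdr_comparator must be 'lt' or 'le'")

    @classmethod
    def tissue(cls) -> "DMSThresholds":
        return cls(max_fdr=0.05, max_p=None, min_abs_delta=0.15, min_detect=0.65)

    @classmethod
    def plasma(cls) -> "DMSThresholds":
        return cls(max_fdr=0.2, max_p=0.001, min_abs_delta=0.02, min_detect=0.65)


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p value.

    Exact enumeration when the pooled sample is small (n <= 12) and
    tie-free; otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 12 and no_ties) else "asymptotic"
    p = stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    return float(min(p, 1.0))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_columns(labels: pd.Series, case: str, control: str) -> tuple[list[str], list[str]]:
    case_ids = list(labels.index[labels == case])
    control_ids = list(labels.index[labels == control])
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise ValueError(f"need >= 2 samples per class; got {len(case_ids)} {case!r}, "
                         f"{len(control_ids)} {control!r}")
    return case_ids, control_ids


def test_all_sites(
    matrix: pd.DataFrame,
    labels: pd.Series,
    *,
    case: str = MALIGNANT,
    control: str = BENIGN,
    min_detect: float = 0.65,
    detect_scope: str = "per_group",
) -> pd.DataFrame:
    """Rank-sum test every site passing the detection filter.

    Returns the full tested table (one row per tested site) with BH FDR
    computed over exactly these sites.  ``detect_scope="per_group"``
    requires the detection fraction in *each* group to reach
    ``min_detect``; ``"overall"`` applies it to the pooled cohort.
    """
    if detect_scope not in {"per_group", "overall"}:
        raise ValueError("detect_scope must be 'per_group' or 'overall'")
    labels = labels.loc[labels.index.intersection(matrix.columns)]
    case_ids, control_ids = _group_columns(labels, case, control)

    det_case = detection_frequency(matrix, case_ids)
    det_control = detection_frequency(matrix, control_ids)
    if detect_scope == "per_group":
        eligible = (det_case >= min_detect) & (det_control >= min_detect)
    else:
        eligible = detection_frequency(matrix, case_ids + control_ids) >= min_detect

    X = matrix.loc[eligible, case_ids].to_numpy(dtype=float)
    Y = matrix.loc[eligible, control_ids].to_numpy(dtype=float)
    sites = matrix.index[eligible]

    rows = []
    for i, site in enumerate(sites):
        x = X[i][~np.isnan(X[i])]
        y = Y[i][~np.isnan(Y[i])]
        if x.size < 2 or y.size < 2:
            continue
        rows.append((site, x.size, y.size, rank_sum_test(x, y),
                     float(x.mean() - y.mean()),
                     float(det_case.loc[site]), float(det_control.loc[site])))
    tested = pd.DataFrame(rows, columns=["site_id", "n_case", "n_control",
                                         "p_value", "delta", "detect_case", "detect_control"])
    tested["fdr"] = bh_adjust(tested["p_value"].to_numpy()) if len(tested) else np.nan
    tested = tested[DMS_COLUMNS]
    tested.attrs["n_eligible"] = int(eligible.sum())
    tested.attrs["n_input_sites"] = int(matrix.shape[0])
    return tested


def _apply_thresholds(tested: pd.DataFrame, thresholds: DMSThresholds) -> pd.DataFrame:
    if len(tested) == 0:
        out = tested.copy()
        out.attrs.update(tested.attrs)
        out.attrs["empty_after_filter"] = True
        return out
    cmp = np.less if thresholds.fdr_comparator == "lt" else np.less_equal
    keep = cmp(tested["fdr"].to_numpy(), thresholds.max_fdr)
    if thresholds.max_p is not None:
        keep &= tested["p_value"].to_numpy() < thresholds.max_p
    keep &= np.abs(tested["delta"].to_numpy()) >= thresholds.min_abs_delta
    out = tested.loc[keep].reset_index(drop=True)
    out.attrs.update(tested.attrs)
    out.attrs["empty_after_filter"] = bool(len(out) == 0)
    return out


def discover_dms(
    matrix: pd.DataFrame,
    labels: pd.Series,
    thresholds: DMSThresholds | None = None,
    *,
    case: str = MALIGNANT,
    control: str = BENIGN,
    detect_scope: str = "per_group",
) -> pd.DataFrame:
    """Discover DMSs: detection filter -> rank-sum -> BH -> thresholds.

    Returns only the passing records; an empty result carries
    ``attrs["empty_after_filter"] = True`` rather than raising.  The
    full tested universe is available via :func:`test_all_sites`.
    """
    thresholds = thresholds or DMSThresholds.tissue()
    tested = test_all_sites(matrix, labels, case=case, control=control,
                            min_detect=thresholds.min_detect, detect_scope=detect_scope)
    return _apply_thresholds(tested, thresholds)


def subgroup_dms(
    matrix: pd.DataFrame,
    factor: pd.Series,
    thresholds: DMSThresholds | None = None,
    *,
    levels: tuple[str, str] | None = None,
    detect_scope: str = "per_group",
) -> pd.DataFrame:
    """DMS machinery applied to any binary sample attribute.

    ``levels=(a, b)`` orders the comparison as a-minus-b; by default the
    two observed levels are taken in sorted order.
    """
    observed = sorted(pd.unique(factor.dropna()))
    if levels is None:
        if len(observed) != 2:
            raise ValueError(f"factor must have exactly 2 levels, found {observed}")
        levels = (observed[0], observed[1])
    return discover_dms(matrix, factor, thresholds, case=levels[0], control=levels[1],
                        detect_scope=detect_scope)


def dichotomize_age(ages: pd.Series, cutoff: float = 55.0) -> pd.Series:
    """Age groups with the boundary in the younger class (55 -> younger)."""
    return pd.Series(np.where(ages > cutoff, "older", "younger"), index=ages.index)


def _site_categories(sites, annotation: pd.DataFrame) -> pd.Series:
    """Map site ids to annotation categories (BED 0-based half-open)."""
    lookup = {}
    for _, row in annotation.iterrows():
        for pos in range(int(row["start"]) + 1, int(row["end"]) + 1):
            lookup[f"{row['chrom']}:{pos}"] = row["category"]
    return pd.Series({s: lookup.get(s) for s in sites})


def annotation_enrichment(
    dms_sites,
    background_sites,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Per-category fold enrichment of DMSs over the background panel.

    fold = (k/m) / (K/M) with k, m the in-category and total DMS counts
    and K, M the background counts.  Categories absent from the
    background (K = 0) get an undefined (NaN) fold.
    """
    dms_sites = list(dms_sites)
    background_sites = list(background_sites)
    missing = set(dms_sites) - set(background_sites)
    if missing:
        raise ValueError(f"{len(missing)} DMS sites absent from background")
    cats = _site_categories(background_sites, annotation)
    m, M = len(dms_sites), len(background_sites)
    rows = []
    for cat in sorted({c for c in cats.dropna().unique()}):
        K = int((cats == cat).sum())
        k = int(sum(cats.get(s) == cat for s in dms_sites))
        fold = (k / m) / (K / M) if K > 0 and m > 0 else np.nan
        rows.append((cat, k, m, K, M, fold))
    return pd.DataFrame(rows, columns=["category", "k", "m", "K", "M", "fold"])
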