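"""Tissue-plasma concordance of delta methylation.

Tissue-discovered DMSs are followed into plasma: per site, the
case-minus-control delta is computed in each matrix and the paired
deltas are compared by Spearman rank correlation plus a sign-based
classification (concordant: same sign; discordant: opposite sign; sites
with a zero delta in either matrix are excluded from both classes).
Two cohort modes mirror the study designs: ``paired`` restricts both
matrices to samples sharing a pair id; ``whole`` uses every labeled
sample of each matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from methdx.simulate import BENIGN, MALIGNANT


@dataclass(frozen=True)
class ConcordanceSummary:
    rho: float
    p_value: float
    n_concordant: int
    n_discordant: int
    n_excluded: int

    @property
    def n_sites(self) -> int:
        return self.n_concordant + self.n_discordant + self.n_excluded


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho (Pearson correlation of midranks) and the two-sided
    p value from the t approximation with n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant vector: rho undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def classify_concordance(deltas: pd.DataFrame) -> tuple[int, int, int]:
    """Counts (concordant, discordant, excluded) over paired deltas.

    ``deltas`` has columns delta_tissue and delta_plasma; a site is
    concordant when the product of its deltas is positive, discordant
    when negative, excluded when either delta is exactly zero.
    """
    if len(deltas) == 0:
        raise ValueError("empty delta list")
    prod = deltas["delta_tissue"].to_numpy() * deltas["delta_plasma"].to_numpy()
    zero = (deltas["delta_tissue"] == 0) | (deltas["delta_plasma"] == 0)
    n_conc = int(((prod > 0) & ~zero).sum())
    n_disc = int(((prod < 0) & ~zero).sum())
    return n_conc, n_disc, int(zero.sum())


def _group_deltas(matrix: pd.DataFrame, labels: pd.Series,
                  case: str, control: str) -> pd.Series:
    case_ids = [s for s in labels.index[labels == case] if s in matrix.columns]
    ctrl_ids = [s for s in labels.index[labels == control] if s in matrix.columns]
    if not case_ids or not ctrl_ids:
        raise ValueError("both classes required in each matrix")
    return matrix[case_ids].mean(axis=1) - matrix[ctrl_ids].mean(axis=1)


def paired_concordance(
    tissue: pd.DataFrame,
    plasma: pd.DataFrame,
    labels: pd.Series,
    dms_sites,
    *,
    mode: str = "whole",
    metadata: pd.DataFrame | None = None,
    case: str = MALIGNANT,
    control: str = BENIGN,
) -> ConcordanceSummary:
    """Concordance summary over a DMS site set.

    ``mode="paired"`` keeps only samples with a non-empty ``pair_id`` in
    ``metadata``; ``mode="whole"`` uses all labeled samples.
    """
    sites = [s for s in dms_sites if s in tissue.index and s in plasma.index]
    if not sites:
        raise ValueError("empty site overlap between matrices and DMS set")
    if mode == "paired":
        if metadata is None:
            raise ValueError("paired mode needs metadata with pair_id")
        paired_ids = metadata.index[metadata["pair_id"].astype(str) != ""]
        labels = labels.loc[labels.index.intersection(paired_ids)]
    elif mode != "whole":
        raise ValueError("mode must be 'paired' or 'whole'")

    dt = _group_deltas(tissue.loc[sites], labels, case, control)
    dp = _group_deltas(plasma.loc[sites], labels, case, control)
    both = pd.DataFrame({"delta_tissue": dt, "delta_plasma": dp}).dropna()
    if len(both) < 3:
        raise ValueError("fewer than 3 sites with deltas in both matrices")
    rho, p = spearman(both["delta_tissue"], both["delta_plasma"])
    n_conc, n_disc, n_excl = classify_concordance(both)
    return ConcordanceSummary(rho=rho, p_value=p, n_concordant=n_conc,
                              n_discordant=n_disc, n_excluded=n_excl)
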