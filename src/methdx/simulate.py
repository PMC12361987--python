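"""Synthetic targeted-bisulfite cohorts with known ground truth.

The generator emulates the data structure of a capture-panel bisulfite
study comparing malignant and benign samples:

* per-site methylation levels with the characteristic **bimodal**
  marginal (most CpGs near 0 or near 1), drawn from a two-component
  Beta mixture with modes near 0.03 and 0.97;
* a set of **planted differentially methylated sites** whose class
  means differ by a fixed delta, half hypermethylated and half
  hypomethylated in cases;
* Poisson read coverage and i.i.d. class-independent **capture
  missingness** (a site-sample pair is observed with probability
  ``detection_rate``);
* binomial read counts through the bisulfite conversion channel
  ``p_obs = beta + (1 - beta) * (1 - e)``;
* **plasma as a dilution**: the case plasma methylation level at each
  site is ``f * tumor_beta + (1 - f) * background_beta`` for a small
  circulating-tumor-DNA fraction ``f`` (a few percent in early-stage
  disease), controls carry the background profile;
* read-level CpG haplotype patterns within blocks, either fully
  coordinated (all covered CpGs share one methylation state) or
  independent per CpG.

Class-level site means are shared by all samples of a class; sample
variability arises from coverage, capture and binomial counting noise
only.  Identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from methdx.calling import COUNT_COLUMNS, site_id

MALIGNANT = "malignant"
BENIGN = "benign"

#: default panel geometry: all sites on one contig, evenly spaced CpGs
_CHROM = "chr1"
_FIRST_POS = 1001
_SPACING = 50


def default_site_ids(n_sites: int) -> list[str]:
    """Evenly spaced 1-based CpG positions on a single contig."""
    return [site_id(_CHROM, _FIRST_POS + _SPACING * i) for i in range(n_sites)]


@dataclass(frozen=True)
class BimodalMix:
    """Two-component Beta mixture with modes near 0 and near 1.

    Defaults place the modes at 0.03 and 0.97 with equal weight, giving
    the bimodal beta marginal typical of CpG panels.
    """

    a_low: float = 2.0
    b_low: float = 33.33
    a_high: float = 33.33
    b_high: float = 2.0
    weight_low: float = 0.5

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        low = rng.random(n) < self.weight_low
        out = np.empty(n)
        out[low] = rng.beta(self.a_low, self.b_low, size=int(low.sum()))
        out[~low] = rng.beta(self.a_high, self.b_high, size=int((~low).sum()))
        return out

    def draw_component(self, rng: np.random.Generator, n: int, *, low: bool,
                       lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
        """Draw from one component truncated to [lo, hi] by rejection."""
        a, b = (self.a_low, self.b_low) if low else (self.a_high, self.b_high)
        out = np.empty(n)
        filled = 0
        for _ in range(1000):
            draw = rng.beta(a, b, size=max(4 * (n - filled), 16))
            ok = draw[(draw >= lo) & (draw <= hi)]
            take = min(len(ok), n - filled)
            out[filled:filled + take] = ok[:take]
            filled += take
            if filled == n:
                return out
        raise ValueError(f"cannot draw betas inside [{lo:.3f}, {hi:.3f}]")


@dataclass(frozen=True)
class CovariateModel:
    """Marginals for age / gender / smoking; independent of class by
    default, with optional class-linked smoking and age shift for
    confounding experiments."""

    age_mean: float = 56.0
    age_sd: float = 11.0
    male_prob: float = 0.5
    smoker_prob: float = 0.4
    smoker_prob_case: float | None = None  # None => same as controls
    age_shift_case: float = 0.0


@dataclass(frozen=True)
class SynthDesign:
    """Full description of a synthetic cohort.

    ``delta_target`` is the case-minus-control mean beta difference at
    planted sites (sign set per site by its planted direction).
    """

    n_cases: int = 56
    n_controls: int = 44
    n_sites: int = 2000
    n_dms: int = 6
    delta_target: float = 0.3
    bimodal_mix: BimodalMix = field(default_factory=BimodalMix)
    mean_coverage: float = 200.0
    detection_rate: float = 0.9
    conversion_efficiency: float = 0.99
    #: inter-individual dispersion: per-sample beta ~ Beta(mu*k, (1-mu)*k)
    #: around the class mean mu; larger k = tighter samples. 0 disables it.
    beta_concentration: float = 30.0
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1 or self.n_sites < 1:
            raise ValueError("cohort dimensions must be positive")
        if self.n_dms < 0 or self.n_dms > self.n_sites:
            raise ValueError(f"n_dms={self.n_dms} must be in [0, n_sites={self.n_sites}]")
        if not (0.0 <= self.delta_target <= 1.0):
            raise ValueError(f"delta_target must be in [0, 1], got {self.delta_target}")
        if self.delta_target >= 1.0 and self.n_dms > 0:
            raise ValueError("delta_target of 1 leaves no room for a base methylation level")
        if not (0.0 <= self.detection_rate <= 1.0):
            raise ValueError("detection_rate must be in [0, 1]")
        if not (0.0 < self.conversion_efficiency <= 1.0):
            raise ValueError("conversion_efficiency must be in (0, 1]")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        if self.beta_concentration < 0:
            raise ValueError("beta_concentration must be >= 0")


@dataclass
class TruthSet:
    """Ground truth of a simulated cohort: which sites were planted, in
    which direction, and the true class-level mean betas."""

    planted_sites: list[str]
    directions: dict[str, str]          # site -> "hyper" | "hypo" (in cases)
    true_means: pd.DataFrame            # planted sites x case_mean/control_mean
    seed: int
    design: SynthDesign | None = None
    full_means: pd.DataFrame | None = None      # all sites, for dilution models
    sample_betas: pd.DataFrame | None = None    # sites x samples true levels

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "planted_sites": self.planted_sites,
            "directions": self.directions,
            "true_means": {
                s: {"case_mean": float(r.case_mean), "control_mean": float(r.control_mean)}
                for s, r in self.true_means.iterrows()
            },
            "seed": self.seed,
            "design": dataclasses.asdict(self.design) if self.design is not None else None,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass(frozen=True)
class PlasmaMixtureSpec:
    """ctDNA dilution: plasma case beta = f * tumor beta + (1-f) * background.

    ``ctdna_fraction`` may be a scalar (shared by all cases) or a mapping
    sample_id -> fraction.  ``background_profile`` is a per-site Series;
    when None, the tissue benign-class true means are used, so the
    expected plasma delta is exactly ``f`` times the tissue delta.
    """

    ctdna_fraction: float | Mapping[str, float] = 0.05
    background_profile: pd.Series | None = None

    def fraction_for(self, sample: str) -> float:
        f = (self.ctdna_fraction[sample]
             if isinstance(self.ctdna_fraction, Mapping) else float(self.ctdna_fraction))
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"ctDNA fraction for {sample} outside [0, 1]: {f}")
        return f


def _sample_ids(design: SynthDesign) -> tuple[list[str], list[str]]:
    width = len(str(max(design.n_cases, design.n_controls)))
    cases = [f"case_{i + 1:0{width}d}" for i in range(design.n_cases)]
    controls = [f"ctrl_{i + 1:0{width}d}" for i in range(design.n_controls)]
    return cases, controls


def _simulate_metadata(design: SynthDesign, rng: np.random.Generator) -> pd.DataFrame:
    cases, controls = _sample_ids(design)
    cov = design.covariate_model
    rows = []
    for sample, label in [(s, MALIGNANT) for s in cases] + [(s, BENIGN) for s in controls]:
        is_case = label == MALIGNANT
        p_smoke = cov.smoker_prob_case if (is_case and cov.smoker_prob_case is not None) else cov.smoker_prob
        age = rng.normal(cov.age_mean + (cov.age_shift_case if is_case else 0.0), cov.age_sd)
        rows.append({
            "sample_id": sample,
            "class": label,
            "age": float(np.clip(round(age), 20, 90)),
            "gender": "M" if rng.random() < cov.male_prob else "F",
            "smoking": "ever" if rng.random() < p_smoke else "never",
            "histology": "adenocarcinoma" if is_case else "inflammation",
            "pair_id": "",
        })
    return pd.DataFrame(rows).set_index("sample_id")


def _true_site_means(design: SynthDesign, rng: np.random.Generator) -> tuple[pd.DataFrame, TruthSet]:
    sites = default_site_ids(design.n_sites)
    base = design.bimodal_mix.draw(rng, design.n_sites)
    case_mean = base.copy()
    control_mean = base.copy()

    planted_idx = np.sort(rng.choice(design.n_sites, size=design.n_dms, replace=False))
    directions: dict[str, str] = {}
    delta = design.delta_target
    n_hyper = (design.n_dms + 1) // 2
    for k, idx in enumerate(planted_idx):
        hyper = k < n_hyper
        # base drawn from the matching mixture component, truncated so the
        # shifted mean stays inside [0, 1] (no clipping of means allowed)
        if hyper:
            b = design.bimodal_mix.draw_component(rng, 1, low=True, hi=1.0 - delta)[0]
            control_mean[idx], case_mean[idx] = b, b + delta
        else:
            b = design.bimodal_mix.draw_component(rng, 1, low=False, lo=delta)[0]
            control_mean[idx], case_mean[idx] = b, b - delta
        directions[sites[idx]] = "hyper" if hyper else "hypo"
    if ((case_mean < 0) | (case_mean > 1) | (control_mean < 0) | (control_mean > 1)).any():
        raise ValueError("delta_target pushes a true site mean outside [0, 1]")

    means = pd.DataFrame({"case_mean": case_mean, "control_mean": control_mean}, index=pd.Index(sites, name="site_id"))
    truth = TruthSet(
        planted_sites=[sites[i] for i in planted_idx],
        directions=directions,
        true_means=means.loc[[sites[i] for i in planted_idx]].copy(),
        seed=design.seed,
        design=design,
    )
    return means, truth


def _disperse(mu: np.ndarray, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Per-sample beta draws around class means (biological variation)."""
    if kappa <= 0:
        return mu.copy()
    mu_c = np.clip(mu, 1e-9, 1.0 - 1e-9)
    return rng.beta(mu_c * kappa, (1.0 - mu_c) * kappa)


def _sample_beta_matrix(
    means: pd.DataFrame,
    case_samples: Sequence[str],
    control_samples: Sequence[str],
    kappa: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    samples = list(case_samples) + list(control_samples)
    cols = {}
    for s in case_samples:
        cols[s] = _disperse(means["case_mean"].to_numpy(), kappa, rng)
    for s in control_samples:
        cols[s] = _disperse(means["control_mean"].to_numpy(), kappa, rng)
    return pd.DataFrame(cols, index=means.index, columns=samples)


def _counts_from_betas(
    betas: pd.DataFrame,
    design: SynthDesign,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Coverage -> capture -> binomial counts through the conversion
    channel, long format."""
    beta = betas.to_numpy()
    e = design.conversion_efficiency
    p_obs = beta + (1.0 - beta) * (1.0 - e)
    shape = beta.shape
    n_total = rng.poisson(design.mean_coverage, size=shape)
    detected = rng.random(shape) < design.detection_rate
    n_meth = rng.binomial(n_total, p_obs)

    rows, cols = np.nonzero(detected)
    return pd.DataFrame({
        "site_id": betas.index.to_numpy()[rows],
        "sample_id": np.asarray(list(betas.columns), dtype=object)[cols],
        "n_meth": n_meth[rows, cols],
        "n_total": n_total[rows, cols],
    }, columns=COUNT_COLUMNS)


def simulate_cohort(design: SynthDesign) -> tuple[pd.DataFrame, pd.DataFrame, TruthSet]:
    """Simulate one cohort: counts (long), metadata, and ground truth."""
    design.validate()
    rng = np.random.default_rng(design.seed)
    metadata = _simulate_metadata(design, rng)
    means, truth = _true_site_means(design, rng)
    cases, controls = _sample_ids(design)
    betas = _sample_beta_matrix(means, cases, controls, design.beta_concentration, rng)
    counts = _counts_from_betas(betas, design, rng)
    truth.full_means = means  # all-site truth, used by simulate_paired
    truth.sample_betas = betas
    return counts, metadata, truth


def simulate_paired(
    design: SynthDesign, mix: PlasmaMixtureSpec
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthSet]:
    """Simulate matched tissue and plasma cohorts for one sample roster.

    Tissue follows :func:`simulate_cohort`.  Plasma case levels are the
    ctDNA dilution of the tissue tumor levels into the background
    profile; plasma controls carry the background profile itself.
    """
    tissue_counts, metadata, truth = simulate_cohort(design)
    means: pd.DataFrame = truth.full_means
    background = (mix.background_profile.reindex(means.index)
                  if mix.background_profile is not None else means["control_mean"])
    if background.isna().any():
        raise ValueError("background profile does not cover all sites")

    cases, controls = _sample_ids(design)
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 0x706C61]))  # plasma stream

    bg = background.to_numpy()
    # per-patient plasma level: the patient's own tissue profile diluted
    # into an individual background draw (cases), or background only
    plasma_cols = {}
    for sample in cases:
        f = mix.fraction_for(sample)
        bg_i = _disperse(bg, design.beta_concentration, rng)
        plasma_cols[sample] = f * truth.sample_betas[sample].to_numpy() + (1.0 - f) * bg_i
    for sample in controls:
        plasma_cols[sample] = _disperse(bg, design.beta_concentration, rng)
    plasma_betas = pd.DataFrame(plasma_cols, index=means.index, columns=cases + controls)
    plasma_counts = _counts_from_betas(plasma_betas, design, rng)

    metadata = metadata.copy()
    metadata["pair_id"] = metadata.index  # same roster: each patient pairs with itself
    return tissue_counts, plasma_counts, metadata, truth


def simulate_read_haplotypes(
    blocks: Sequence,
    block_state: pd.DataFrame,
    reads_per_block: int,
    *,
    read_span: tuple = ("full",),
    coordination: str = "full",
    seed: int = 0,
) -> pd.DataFrame:
    """Emit read-level CpG haplotype patterns for (block, sample) pairs.

    Parameters
    ----------
    blocks
        Sequence of :class:`methdx.mhl.HaplotypeBlock`.
    block_state
        Blocks x samples methylation probability matrix (index block_id).
    reads_per_block
        Reads emitted per (block, sample).
    read_span
        ``("full",)`` — every read covers the whole block; or
        ``("uniform", min_len)`` — read length uniform on
        [min_len, L] with a uniform valid start.
    coordination
        ``"full"`` — all covered CpGs of a read are jointly methylated
        with the block-sample probability; ``"independent"`` — i.i.d.
        Bernoulli per covered CpG.
    """
    if len(blocks) == 0:
        raise ValueError("empty block list")
    if reads_per_block < 0:
        raise ValueError("reads_per_block must be >= 0")
    if coordination not in {"full", "independent"}:
        raise ValueError(f"unknown coordination mode {coordination!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for block in blocks:
        L = len(block.cpg_positions)
        if block.block_id not in block_state.index:
            raise KeyError(f"no state row for block {block.block_id}")
        for sample in block_state.columns:
            p = float(block_state.loc[block.block_id, sample])
            for r in range(reads_per_block):
                if read_span[0] == "full":
                    start, length = 0, L
                elif read_span[0] == "uniform":
                    length = int(rng.integers(read_span[1], L + 1))
                    start = int(rng.integers(0, L - length + 1))
                else:
                    raise ValueError(f"unknown read_span {read_span!r}")
                pattern = ["."] * L
                if coordination == "full":
                    state = "1" if rng.random() < p else "0"
                    pattern[start:start + length] = [state] * length
                else:
                    bits = rng.random(length) < p
                    pattern[start:start + length] = ["1" if b else "0" for b in bits]
                rows.append((block.block_id, sample, f"{block.block_id}:{sample}:r{r}", "".join(pattern)))
    return pd.DataFrame(rows, columns=["block_id", "sample_id", "read_id", "pattern"])


def _largest_remainder(n: int, props: Mapping[str, float]) -> dict[str, int]:
    """Deterministic integer allocation of n items to categories."""
    raw = {k: n * p for k, p in props.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    shortfall = n - sum(counts.values()) - int(np.floor(n * (1.0 - sum(props.values()))))
    # order by descending remainder, ties by category name for determinism
    by_rem = sorted(props, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in by_rem[:max(shortfall, 0)]:
        counts[k] += 1
    return counts


def simulate_annotations(
    n_sites: int,
    category_props: Mapping[str, float],
    n_genes: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Build BED-convention annotation, gene, and haplotype-block tracks
    over the default site layout.

    Category counts follow the largest-remainder rounding of
    ``n_sites * proportion``; which sites get which category is a seeded
    permutation.  Genes are non-overlapping intervals tiling the site
    range.  Blocks partition consecutive CpGs into runs of four.
    """
    total = sum(category_props.values())
    if total > 1.0 + 1e-9:
        raise ValueError(f"category proportions sum to {total} > 1")
    if any(p < 0 for p in category_props.values()):
        raise ValueError("negative category proportion")
    rng = np.random.default_rng(seed)

    positions = np.array([_FIRST_POS + _SPACING * i for i in range(n_sites)])
    counts = _largest_remainder(n_sites, category_props)
    order = rng.permutation(n_sites)
    ann_rows = []
    cursor = 0
    for cat in sorted(category_props):
        for idx in order[cursor:cursor + counts[cat]]:
            pos = positions[idx]
            ann_rows.append((_CHROM, pos - 1, pos, cat))  # BED 0-based half-open
        cursor += counts[cat]
    annotation = (pd.DataFrame(ann_rows, columns=["chrom", "start", "end", "category"])
                  .sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True))

    # non-overlapping genes tiling the panel span
    span_lo, span_hi = int(positions[0] - 500), int(positions[-1] + 500)
    bounds = np.linspace(span_lo, span_hi, n_genes + 1).astype(int)
    gene_rows = []
    for g in range(n_genes):
        lo, hi = bounds[g], bounds[g + 1]
        width = hi - lo
        g_start = lo + int(rng.integers(0, max(width // 4, 1)))
        g_end = hi - int(rng.integers(1, max(width // 4, 2)))
        gene_rows.append((_CHROM, g_start, max(g_end, g_start + 1), f"GENE{g + 1:03d}"))
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "name"])

    block_rows = []
    for b, lo in enumerate(range(0, n_sites, 4)):
        members = positions[lo:lo + 4]
        block_rows.append((_CHROM, members[0] - 1, members[-1],
                           f"BLK{b + 1:04d}", ",".join(str(p) for p in members)))
    blocks = pd.DataFrame(block_rows, columns=["chrom", "start", "end", "block_id", "cpg_positions"])
    return annotation, genes, blocks


def write_metadata(metadata: pd.DataFrame, path: str | os.PathLike) -> None:
    metadata.to_csv(path, sep="\t")


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="sample_id",
                       dtype={"pair_id": str}, keep_default_na=False, na_values=[])
    meta["age"] = pd.to_numeric(meta["age"])
    return meta
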