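"""Beta calling: per-site bisulfite counts -> filtered methylation matrix.

Conventions
-----------
*Site counts* are a long-format :class:`pandas.DataFrame` with columns
``site_id``, ``sample_id``, ``n_meth``, ``n_total``.  ``site_id`` is
``"<chrom>:<pos>"`` with a 1-based CpG cytosine position on the forward
strand (CpG dyads are assumed pre-collapsed to the forward strand).

A *site matrix* is a wide :class:`pandas.DataFrame`, sites (rows) by
samples (columns), holding beta values in [0, 1] with :data:`numpy.nan`
for entries that were not captured or failed the coverage filter.  The
conversion efficiency and coverage floor used are recorded in
``matrix.attrs``.

The observed methylated-read fraction of a site with true methylation
level beta under bisulfite conversion efficiency ``e`` is

    p_obs = beta + (1 - beta) * (1 - e)

because a fraction (1 - e) of unmethylated cytosines escapes conversion
and reads as methylated.  ``call_betas`` inverts this relation and clips
to [0, 1].
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

COUNT_COLUMNS = ["site_id", "sample_id", "n_meth", "n_total"]

#: bismark-style coverage columns: chrom, 1-based start, end,
#: methylation percentage, methylated count, unmethylated count.
COVERAGE_COLUMNS = ["chrom", "start", "end", "meth_pct", "count_m", "count_u"]


def site_id(chrom: str, pos: int) -> str:
    """Canonical site identifier for a 1-based CpG position."""
    return f"{chrom}:{int(pos)}"


def split_site_id(sid: str) -> tuple[str, int]:
    chrom, _, pos = sid.rpartition(":")
    return chrom, int(pos)


def _validate_counts(counts: pd.DataFrame) -> None:
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"counts table lacks columns {missing}")
    if len(counts) == 0:
        return
    if (counts["n_meth"] < 0).any() or (counts["n_total"] < 0).any():
        raise ValueError("negative read counts")
    if (counts["n_meth"] > counts["n_total"]).any():
        raise ValueError("n_meth exceeds n_total")


def call_betas(counts: pd.DataFrame, e: float = 1.0, min_coverage: int = 30) -> pd.DataFrame:
    """Convert site counts into a conversion-corrected beta matrix.

    Parameters
    ----------
    counts
        Long-format counts table (see module docstring).
    e
        Library bisulfite conversion efficiency in (0, 1].
    min_coverage
        Strict coverage floor: only entries with ``n_total > min_coverage``
        are called (the high-confidence ">30x" rule); everything else is
        missing.

    Returns
    -------
    pandas.DataFrame
        Sites x samples beta matrix with ``attrs`` recording ``e`` and
        ``min_coverage``.
    """
    if not (0.0 < e <= 1.0):
        raise ValueError(f"conversion efficiency must be in (0, 1], got {e}")
    _validate_counts(counts)

    kept = counts[counts["n_total"] > min_coverage]
    p_obs = kept["n_meth"] / kept["n_total"]
    beta = np.clip((p_obs - (1.0 - e)) / e, 0.0, 1.0)

    called = kept[["site_id", "sample_id"]].copy()
    called["beta"] = np.asarray(beta, dtype=float)
    matrix = called.pivot_table(index="site_id", columns="sample_id", values="beta", aggfunc="first")

    # keep every site and sample present in the input, even if fully filtered
    all_samples = pd.unique(counts["sample_id"]) if len(counts) else []
    all_sites = pd.unique(counts["site_id"]) if len(counts) else []
    matrix = matrix.reindex(index=list(all_sites), columns=list(all_samples))
    matrix = matrix.sort_index(key=_genomic_sort_key)
    matrix.attrs["conversion_efficiency"] = e
    matrix.attrs["min_coverage"] = min_coverage
    return matrix


def _genomic_sort_key(index: pd.Index) -> pd.Index:
    parsed = [split_site_id(s) for s in index]
    return pd.Index([(c, p) for c, p in parsed])


def detection_frequency(matrix: pd.DataFrame, samples: Sequence[str] | None = None) -> pd.Series:
    """Per-site fraction of non-missing entries over a sample subset."""
    cols = list(matrix.columns) if samples is None else list(samples)
    if len(cols) == 0:
        raise ValueError("empty sample subset")
    sub = matrix[cols]
    return sub.notna().sum(axis=1) / len(cols)


def read_coverage_files(paths: Iterable[str | os.PathLike], sample_ids: Sequence[str]) -> pd.DataFrame:
    """Read per-sample bismark-style coverage TSVs into a counts table.

    Each file holds one sample; ``n_total = count_m + count_u``.  Site-sample
    pairs absent from a file are absent from the result (not zero).  A
    malformed row raises :class:`ValueError` naming the file and line.
    """
    paths = list(paths)
    if len(paths) != len(sample_ids):
        raise ValueError("paths and sample_ids differ in length")
    frames = []
    for path, sample in zip(paths, sample_ids):
        try:
            tab = pd.read_csv(
                path,
                sep="\t",
                header=None,
                names=COVERAGE_COLUMNS,
                dtype={"chrom": str, "start": np.int64, "end": np.int64,
                       "meth_pct": float, "count_m": np.int64, "count_u": np.int64},
            )
        except (ValueError, pd.errors.ParserError) as exc:
            raise ValueError(f"malformed coverage file {path}: {exc}") from exc
        except pd.errors.EmptyDataError:
            continue
        if (tab[["count_m", "count_u"]] < 0).any().any():
            bad = int(np.argmax((tab[["count_m", "count_u"]] < 0).any(axis=1).to_numpy())) + 1
            raise ValueError(f"negative count in {path} line {bad}")
        frames.append(pd.DataFrame({
            "site_id": [site_id(c, p) for c, p in zip(tab["chrom"], tab["start"])],
            "sample_id": sample,
            "n_meth": tab["count_m"].to_numpy(),
            "n_total": (tab["count_m"] + tab["count_u"]).to_numpy(),
        }))
    if not frames:
        return pd.DataFrame(columns=COUNT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def write_coverage_files(counts: pd.DataFrame, outdir: str | os.PathLike) -> dict[str, str]:
    """Write one coverage TSV per sample; returns sample_id -> path."""
    _validate_counts(counts)
    os.makedirs(outdir, exist_ok=True)
    written: dict[str, str] = {}
    for sample, grp in counts.groupby("sample_id", sort=True):
        chrom_pos = [split_site_id(s) for s in grp["site_id"]]
        tab = pd.DataFrame({
            "chrom": [c for c, _ in chrom_pos],
            "start": [p for _, p in chrom_pos],
            "end": [p for _, p in chrom_pos],
            "meth_pct": 100.0 * grp["n_meth"].to_numpy() / np.maximum(grp["n_total"].to_numpy(), 1),
            "count_m": grp["n_meth"].to_numpy(),
            "count_u": (grp["n_total"] - grp["n_meth"]).to_numpy(),
        }).sort_values(["chrom", "start"], kind="mergesort")
        path = os.path.join(outdir, f"{sample}.cov.tsv")
        tab.to_csv(path, sep="\t", header=False, index=False)
        written[str(sample)] = path
    return written
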