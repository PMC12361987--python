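"""Methylation haplotype load (MHL) and haplotype-block DMRs.

A haplotype block is a short genomic region of L co-methylated CpGs.
Reads covering the block are reduced to patterns over {1, 0, .}
(methylated / unmethylated / not covered).  The MHL of a block in a
sample is the length-weighted fraction of fully methylated contiguous
substrings:

    MHL = sum_i w_i * MH_i / sum_i w_i,   w_i = i,  i = 1..L

where MH_i is the fraction of fully observed contiguous i-CpG windows
(across all reads) that are all-methylated.  Window counts pool over
reads within one sample; lengths with no fully observed window drop out
of both sums.  Windows containing a '.' are excluded entirely.

DMR discovery re-uses the DMS machinery (rank-sum + BH) on the
blocks x samples MHL matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from methdx import dms as _dms


@dataclass(frozen=True)
class HaplotypeBlock:
    block_id: str
    chrom: str
    start: int                      # 0-based half-open interval on disk
    end: int
    cpg_positions: tuple[int, ...]  # 1-based, strictly increasing

    def __post_init__(self) -> None:
        pos = self.cpg_positions
        if len(pos) < 1:
            raise ValueError(f"block {self.block_id} has no CpGs")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(f"block {self.block_id} CpG positions not strictly increasing")
        if pos[0] <= self.start or pos[-1] > self.end:
            raise ValueError(f"block {self.block_id} CpGs outside its interval")

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)


def blocks_from_bed(bed: pd.DataFrame) -> list[HaplotypeBlock]:
    """Build blocks from a BED table with block_id and a comma-separated
    cpg_positions column (1-based positions)."""
    blocks = []
    for _, row in bed.iterrows():
        pos = tuple(int(p) for p in str(row["cpg_positions"]).split(","))
        blocks.append(HaplotypeBlock(str(row["block_id"]), str(row["chrom"]),
                                     int(row["start"]), int(row["end"]), pos))
    return blocks


def mhl_score(patterns) -> float:
    """MHL of one block-sample pattern set; NaN when uninformative.

    Each pattern is a string over {1, 0, .}; all patterns must share one
    length L.  Returns NaN for an empty pattern set or when no window of
    any length is fully observed.
    """
    patterns = [str(p) for p in patterns]
    if len(patterns) == 0:
        return float("nan")
    L = len(patterns[0])
    if any(len(p) != L for p in patterns):
        raise ValueError("patterns of unequal length in one block")
    num = 0.0
    den = 0.0
    for i in range(1, L + 1):
        windows = 0
        all_meth = 0
        for p in patterns:
            for off in range(0, L - i + 1):
                w = p[off:off + i]
                if "." in w:
                    continue
                windows += 1
                if "0" not in w:
                    all_meth += 1
        if windows == 0:
            continue  # this length contributes to neither sum
        num += i * (all_meth / windows)
        den += i
    if den == 0:
        return float("nan")
    return num / den


def mhl_matrix(
    reads: pd.DataFrame,
    blocks,
    samples,
    min_reads: int = 1,
) -> pd.DataFrame:
    """Blocks x samples MHL matrix from a read-pattern table.

    ``reads`` has columns block_id, sample_id, read_id, pattern.  An
    entry is missing when the (block, sample) read count is below
    ``min_reads`` or no window is fully observed.
    """
    block_ids = [b.block_id for b in blocks]
    known = set(block_ids)
    unknown = set(reads["block_id"]) - known
    if unknown:
        raise ValueError(f"reads reference unknown blocks: {sorted(unknown)[:5]}")
    samples = list(samples)
    out = pd.DataFrame(np.nan, index=pd.Index(block_ids, name="block_id"), columns=samples)
    grouped = reads.groupby(["block_id", "sample_id"], sort=False)["pattern"]
    for (bid, sid), pats in grouped:
        if sid not in out.columns:
            continue
        if len(pats) < min_reads:
            continue
        out.loc[bid, sid] = mhl_score(list(pats))
    return out


def discover_dmr(
    mhl: pd.DataFrame,
    labels: pd.Series,
    thresholds: _dms.DMSThresholds | None = None,
    *,
    case: str = "malignant",
    control: str = "benign",
    detect_scope: str = "per_group",
) -> pd.DataFrame:
    """DMR discovery: the DMS machinery applied to MHL rows.

    Returned records carry block ids in the ``site_id`` column; delta is
    the case-minus-control difference of mean MHL.
    """
    thresholds = thresholds or _dms.DMSThresholds(max_fdr=0.05, min_abs_delta=0.0, min_detect=0.65)
    return _dms.discover_dms(mhl, labels, thresholds, case=case, control=control,
                             detect_scope=detect_scope)


def assign_nearest_gene(regions: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Assign each region to its nearest gene on the same chromosome.

    Both tables are BED-convention (0-based half-open) with columns
    chrom/start/end; genes also carry ``name``.  Distance is 0 for any
    overlap, otherwise the gap between the closest interval ends.  Ties
    go to the gene with the smaller start.  Regions on chromosomes
    absent from the gene track come back unassigned (gene NaN) with the
    ``unassigned`` flag set.
    """
    if len(genes) == 0:
        raise ValueError("empty gene track")
    by_chrom = {c: g.sort_values(["start", "end"]).reset_index(drop=True)
                for c, g in genes.groupby("chrom")}
    rows = []
    for _, reg in regions.iterrows():
        chrom, r_start, r_end = reg["chrom"], int(reg["start"]), int(reg["end"])
        g = by_chrom.get(chrom)
        if g is None:
            rows.append((chrom, r_start, r_end, None, np.nan, True))
            continue
        gap_left = g["start"].to_numpy() - r_end      # gene right of region
        gap_right = r_start - g["end"].to_numpy()     # gene left of region
        dist = np.maximum(np.maximum(gap_left, gap_right), 0)
        best = np.min(dist)
        cands = g.loc[dist == best]
        winner = cands.loc[cands["start"].idxmin()]
        rows.append((chrom, r_start, r_end, winner["name"], int(best), False))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene", "distance", "unassigned"])


def read_patterns_tsv(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["block_id", "sample_id", "read_id", "pattern"]
    if list(tab.columns) != expected:
        raise ValueError(f"read-pattern file must have columns {expected}, got {list(tab.columns)}")
    return tab


def write_patterns_tsv(reads: pd.DataFrame, path) -> None:
    reads.to_csv(path, sep="\t", index=False)
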