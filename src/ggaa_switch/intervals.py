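"""Minimal genomic interval algebra: sort/merge, slop, intersect, and
Fisher overlap-enrichment testing.

All coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
Interval sets are plain :class:`pandas.DataFrame` objects with at least the
columns ``chrom``, ``start``, ``end``; ``name``, ``score`` and ``strand`` are
carried through when present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass(frozen=True)
class GenomicInterval:
    """A single half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start


def validate_intervals(df: pd.DataFrame, chrom_sizes: Mapping[str, int] | None = None) -> None:
    """Raise ``ValueError`` on malformed intervals (start<0, end<=start, or a
    chromosome absent from ``chrom_sizes`` when one is supplied)."""
    if (df["start"] < 0).any() or (df["end"] <= df["start"]).any():
        bad = df[(df["start"] < 0) | (df["end"] <= df["start"])].index[0]
        raise ValueError(f"malformed interval at index {bad}: require 0 <= start < end")
    if chrom_sizes is not None:
        unknown = set(df["chrom"]) - set(chrom_sizes)
        if unknown:
            raise ValueError(f"chromosomes not in size table: {sorted(unknown)}")
        for chrom, sub in df.groupby("chrom", sort=False):
            if (sub["end"] > chrom_sizes[chrom]).any():
                raise ValueError(f"interval beyond end of {chrom}")


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def sort_merge(df: pd.DataFrame, merge_distance: int = 0) -> pd.DataFrame:
    """Sort and merge intervals closer than ``merge_distance``.

    With ``merge_distance=0`` only genuinely overlapping intervals merge:
    half-open abutting intervals ([10,20) and [20,30)) stay separate,
    matching ``bedtools merge`` semantics. Each output interval spans the
    min start to max end of its cluster.
    """
    if merge_distance < 0:
        raise ValueError("merge_distance must be >= 0")
    validate_intervals(df)
    if len(df) == 0:
        return df.loc[:, ["chrom", "start", "end"]].copy()
    df = sort_intervals(df)
    out = []
    cur_chrom, cur_start, cur_end = None, None, None
    for chrom, start, end in zip(df["chrom"], df["start"], df["end"]):
        if chrom == cur_chrom and start < cur_end + merge_distance:
            cur_end = max(cur_end, end)
        else:
            if cur_chrom is not None:
                out.append((cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = chrom, start, end
    out.append((cur_chrom, cur_start, cur_end))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def slop(df: pd.DataFrame, flank: int, chrom_sizes: Mapping[str, int]) -> pd.DataFrame:
    """Widen every interval by ``flank`` bp on both sides, clipped to
    ``[0, chromosome size)`` (the bedtools slop operation)."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    validate_intervals(df, chrom_sizes)
    out = df.copy()
    sizes = out["chrom"].map(chrom_sizes)
    out["start"] = np.maximum(0, out["start"] - flank)
    out["end"] = np.minimum(sizes, out["end"] + flank).astype(int)
    return out


def intersect(
    a: pd.DataFrame, b: pd.DataFrame, min_overlap: int = 1
) -> tuple[pd.DataFrame, np.ndarray]:
    """All pairs of intervals from ``a`` and ``b`` overlapping by at least
    ``min_overlap`` bp.

    Returns a pair table (``a_index``, ``b_index``, ``overlap``; positional
    row indices into the inputs) and a per-``a`` boolean hit vector marking
    rows with at least one partner.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    validate_intervals(a)
    validate_intervals(b)
    hits = np.zeros(len(a), dtype=bool)
    pairs: list[tuple[int, int, int]] = []
    a_chrom = a["chrom"].to_numpy()
    a_start_all = a["start"].to_numpy()
    a_end_all = a["end"].to_numpy()
    b_chrom = b["chrom"].to_numpy()
    b_start_all = b["start"].to_numpy()
    b_end_all = b["end"].to_numpy()
    for chrom in pd.unique(a_chrom):
        a_pos = np.flatnonzero(a_chrom == chrom)
        b_pos = np.flatnonzero(b_chrom == chrom)
        if len(b_pos) == 0:
            continue
        order = np.argsort(b_start_all[b_pos], kind="mergesort")
        b_pos = b_pos[order]
        b_start = b_start_all[b_pos]
        b_end = b_end_all[b_pos]
        for ai in a_pos:
            a_start = int(a_start_all[ai])
            a_end = int(a_end_all[ai])
            # candidate b rows start early enough to reach min_overlap
            hi = int(np.searchsorted(b_start, a_end - min_overlap, side="right"))
            if hi == 0:
                continue
            ov = np.minimum(a_end, b_end[:hi]) - np.maximum(a_start, b_start[:hi])
            sel = np.flatnonzero(ov >= min_overlap)
            for j in sel:
                pairs.append((int(ai), int(b_pos[j]), int(ov[j])))
            if sel.size:
                hits[ai] = True
    pair_df = pd.DataFrame(pairs, columns=["a_index", "b_index", "overlap"])
    return pair_df, hits


def fisher_exact_2x2(
    table: np.ndarray | list, odds_ratio_method: str = "conditional"
) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    The p-value sums hypergeometric probabilities of tables (with the
    observed margins) at most as probable as the observed one, with the
    customary relative tolerance for ties. The odds ratio is the conditional
    MLE (``odds_ratio_method="conditional"``) or the sample odds ratio
    ``ad/bc`` (``"sample"``, much faster).

    Returns ``(odds_ratio, p)``. A zero margin gives ``p=1`` and a NaN odds
    ratio with a warning.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be a non-negative 2x2 array")
    n = int(t.sum())
    if n == 0:
        raise ValueError("empty table (universe size 0)")
    a, b_, c, d = int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1])
    r1, c1 = a + b_, a + c
    if min(r1, c1, n - r1, n - c1) == 0:
        warnings.warn("a margin of the 2x2 table is zero: p=1, odds ratio undefined")
        return float("nan"), 1.0
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    p = min(1.0, p)
    if odds_ratio_method == "sample":
        if b_ * c == 0:
            oddsr = float("inf") if a * d > 0 else float("nan")
        else:
            oddsr = (a * d) / (b_ * c)
    elif odds_ratio_method == "conditional":
        oddsr = float(stats.contingency.odds_ratio(t, kind="conditional").statistic)
    else:
        raise ValueError(f"unknown odds_ratio_method {odds_ratio_method!r}")
    return oddsr, p


def overlap_fisher(
    set_a_hits: np.ndarray, set_b_hits: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Fisher exact test for co-occurrence of two boolean annotations over a
    shared universe of regions.

    Returns ``(odds_ratio, p, table)`` where ``table`` is the 2x2 count
    matrix [[a&b, a&!b], [!a&b, !a&!b]].
    """
    a = np.asarray(set_a_hits, dtype=bool)
    b = np.asarray(set_b_hits, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("hit vectors must share the same universe")
    if a.size == 0:
        raise ValueError("empty universe")
    table = np.array(
        [
            [int((a & b).sum()), int((a & ~b).sum())],
            [int((~a & b).sum()), int((~a & ~b).sum())],
        ]
    )
    oddsr, p = fisher_exact_2x2(table)
    return oddsr, p, table


def read_bed(path) -> pd.DataFrame:
    """Read a BED3-6(+) file into an interval frame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = min(df.shape[1], 6)
    df = df.iloc[:, : max(3, ncol)]
    df.columns = BED_COLUMNS[: df.shape[1]]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    validate_intervals(df)
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df.loc[:, cols].to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))
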