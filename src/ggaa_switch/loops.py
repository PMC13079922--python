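"""Chromatin-loop ingestion, replicate consensus, and enhancer->gene mapping.

Loop calls arrive as bedPE-like TSV (chrom1, start1, end1, chrom2, start2,
end2, score; 0-based half-open). Only loops supported by both replicates
(within a matching tolerance) are retained; consensus loop anchors are then
annotated with overlapping peaks and with genes whose promoter (the 1.5 kb
region immediately upstream of the TSS) overlaps the anchor, yielding
enhancer-to-gene assignments for any peak predicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import intervals

logger = logging.getLogger(__name__)

LOOP_COLUMNS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "score"]

DEFAULT_PROMOTER_FLANK = 1500  # bp upstream of the TSS
DEFAULT_TOLERANCE = 10_000  # bp; replicate anchor-matching tolerance


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its TSS and derived promoter interval."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def promoter(self, flank: int = DEFAULT_PROMOTER_FLANK, downstream: int = 0) -> tuple[int, int]:
        """Half-open promoter interval, strictly upstream of the TSS by
        default; ``downstream`` extends past the TSS."""
        if self.strand == "+":
            return max(0, self.tss - flank), self.tss + downstream
        return self.tss + 1 - downstream, self.tss + 1 + flank


def promoter_table(
    genes: pd.DataFrame, flank: int = DEFAULT_PROMOTER_FLANK, downstream: int = 0
) -> pd.DataFrame:
    """Promoter interval frame (chrom, start, end, name=gene_id) from a gene
    table with columns gene_id, chrom, strand, tss."""
    rows = []
    for g in genes.itertuples(index=False):
        gm = GeneModel(str(g.gene_id), g.chrom, g.strand, int(g.tss))
        s, e = gm.promoter(flank, downstream)
        if e > s >= 0:
            rows.append((gm.chrom, s, e, gm.gene_id))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def _order_anchors(df: pd.DataFrame) -> pd.DataFrame:
    swap = df["start1"] > df["start2"]
    if swap.any():
        for c1, c2 in (("chrom1", "chrom2"), ("start1", "start2"), ("end1", "end2")):
            tmp = df.loc[swap, c1].copy()
            df.loc[swap, c1] = df.loc[swap, c2]
            df.loc[swap, c2] = tmp
    return df


def validate_loops(df: pd.DataFrame) -> pd.DataFrame:
    """Normalize and validate a loop frame: order anchors by start, drop
    trans-chromosomal rows (counted in the log), reject overlapping
    anchors."""
    df = df.copy()
    trans = df["chrom1"] != df["chrom2"]
    if trans.any():
        logger.warning("excluded %d trans-chromosomal loop rows", int(trans.sum()))
        df = df[~trans].copy()
    df = _order_anchors(df)
    bad = (df["start1"] < 0) | (df["end1"] <= df["start1"]) | (df["end2"] <= df["start2"])
    if bad.any():
        raise ValueError(f"malformed anchor coordinates at row {df.index[bad][0]}")
    overlapping = df["start2"] < df["end1"]
    if overlapping.any():
        raise ValueError(f"self-overlapping anchors at row {df.index[overlapping][0]}")
    return df.reset_index(drop=True)


def read_loops(path) -> pd.DataFrame:
    """Read a bedPE-like loop file (6+1 columns, TSV)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except Exception as exc:  # pragma: no cover - pandas reports details
        raise ValueError(f"cannot parse loop file {path}: {exc}") from exc
    if df.shape[1] < 6:
        raise ValueError(f"loop file {path} has {df.shape[1]} columns; need >= 6")
    if df.shape[1] == 6:
        df[6] = 0.0
    df = df.iloc[:, :7]
    df.columns = LOOP_COLUMNS
    for i, col in enumerate(["start1", "end1", "start2", "end2"]):
        try:
            df[col] = df[col].astype(int)
        except (TypeError, ValueError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise ValueError(f"malformed {col} at line {bad + 1} of {path}") from exc
    return validate_loops(df)


def write_loops(df: pd.DataFrame, path) -> None:
    cols = LOOP_COLUMNS + [c for c in df.columns if c not in LOOP_COLUMNS]
    df.loc[:, cols].to_csv(path, sep="\t", header=False, index=False)


def _anchors_match(a_start, a_end, b_start, b_end, half_tol: float) -> np.ndarray:
    """Vectorized: does each b anchor, widened by half_tol (as is the single
    a anchor), overlap the a anchor?"""
    return (b_start - half_tol < a_end + half_tol) & (b_end + half_tol > a_start - half_tol)


def consensus_loops(rep1: pd.DataFrame, rep2: pd.DataFrame, tolerance: float = DEFAULT_TOLERANCE) -> pd.DataFrame:
    """Replicate-supported consensus loops.

    A replicate-1 loop is consensus iff some replicate-2 loop's anchors each
    overlap the corresponding replicate-1 anchor once both are widened by
    tolerance/2. Matching is greedy 1-to-1 in descending replicate-1 score
    order (ties by coordinate), so each replicate-2 loop supports at most
    one consensus loop. The merged anchor is the coordinate average of the
    matched anchors, which makes the consensus count symmetric in replicate
    order.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    half = tolerance / 2.0
    r1 = validate_loops(rep1).sort_values(
        ["score", "chrom1", "start1", "start2"], ascending=[False, True, True, True]
    )
    r2 = validate_loops(rep2)
    used = np.zeros(len(r2), dtype=bool)
    out = []
    by_chrom = {c: np.flatnonzero((r2["chrom1"] == c).to_numpy()) for c in r2["chrom1"].unique()}
    s1 = r2["start1"].to_numpy()
    e1 = r2["end1"].to_numpy()
    s2 = r2["start2"].to_numpy()
    e2 = r2["end2"].to_numpy()
    scores2 = r2["score"].to_numpy()
    for row in r1.itertuples(index=False):
        cand = by_chrom.get(row.chrom1)
        if cand is None:
            continue
        ok = (
            ~used[cand]
            & _anchors_match(row.start1, row.end1, s1[cand], e1[cand], half)
            & _anchors_match(row.start2, row.end2, s2[cand], e2[cand], half)
        )
        idx = cand[ok]
        if idx.size == 0:
            continue
        j = idx[np.argmax(scores2[idx])]  # best-scoring available partner
        used[j] = True
        out.append(
            (
                row.chrom1,
                (row.start1 + int(s1[j])) // 2,
                (row.end1 + int(e1[j])) // 2,
                row.chrom2,
                (row.start2 + int(s2[j])) // 2,
                (row.end2 + int(e2[j])) // 2,
                (row.score + float(scores2[j])) / 2.0,
                "rep1,rep2",
            )
        )
    cons = pd.DataFrame(out, columns=LOOP_COLUMNS + ["support"])
    if len(cons):
        cons = _order_anchors(cons)
        cons = cons.sort_values(["chrom1", "start1", "start2"], kind="mergesort").reset_index(drop=True)
    return cons


def annotate_anchors(
    consensus: pd.DataFrame, peaks: pd.DataFrame, promoters: pd.DataFrame
) -> pd.DataFrame:
    """Attach, per loop and per anchor, the ids of overlapping peaks and of
    genes whose promoter overlaps the anchor.

    ``peaks`` and ``promoters`` are interval frames whose ``name`` column
    carries peak ids / gene ids. Loops hitting nothing are retained with
    empty annotations.
    """
    ann = consensus.copy().reset_index(drop=True)
    for side in ("1", "2"):
        anchor = ann[[f"chrom{side}", f"start{side}", f"end{side}"]].rename(
            columns={f"chrom{side}": "chrom", f"start{side}": "start", f"end{side}": "end"}
        )
        for what, source in (("peaks", peaks), ("genes", promoters)):
            hits: list[list[str]] = [[] for _ in range(len(ann))]
            pair_df, _ = intervals.intersect(anchor, source, 1)
            names = source["name"].to_numpy()
            for ai, bi in zip(pair_df["a_index"], pair_df["b_index"]):
                hits[ai].append(str(names[bi]))
            ann[f"{what}{side}"] = [sorted(set(h)) for h in hits]
    return ann


def enhancer_gene_map(annotated: pd.DataFrame, qualifying_peaks) -> pd.DataFrame:
    """Genes on the opposite anchor of any loop whose peak-bearing anchor
    holds a qualifying peak.

    ``qualifying_peaks`` is a set of peak ids or a predicate on a peak id.
    Both orientations of each loop are considered. Returns one row per gene
    with the supporting loop count and its supporting peak ids. Loops whose
    qualifying anchor faces an anchor with no promoter contribute nothing
    (no nearest-gene fallback).
    """
    if callable(qualifying_peaks):
        pred = qualifying_peaks
    else:
        qual = set(qualifying_peaks)
        pred = qual.__contains__
    support: dict[str, list] = {}
    for i, row in annotated.iterrows():
        for peak_side, gene_side in (("peaks1", "genes2"), ("peaks2", "genes1")):
            good = [p for p in row[peak_side] if pred(p)]
            if not good:
                continue
            for gene in row[gene_side]:
                entry = support.setdefault(gene, [0, set()])
                entry[0] += 1
                entry[1].update(good)
    rows = [
        (gene, n, ",".join(sorted(pk))) for gene, (n, pk) in sorted(support.items())
    ]
    return pd.DataFrame(rows, columns=["gene", "n_loops", "peaks"])
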