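"""GGAA microsatellite scanning and repeat-length classification.

EWS-FLI1 binds GGAA-containing elements, and the number of consecutive GGAA
units within an enhancer ("n x GGAA") determines its class: monomeric (1x)
versus multimeric (>=5x or >=10x) microsatellite enhancers. This module finds
every maximal tandem run of the GGAA unit in a sequence or FASTA genome,
summarizes the repeat content of genomic intervals (peaks), and assigns
repeat-length class labels.

A *block* is a maximal run: it cannot be extended by one more GGAA unit on
either side on its strand. Adjacent blocks separated by even a single base
remain distinct ("disconnected") blocks; no merge distance is applied.
Only exact unit tandem runs match — degenerate repeats do not count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

UNIT = "GGAA"
UNIT_RC = "TTCC"
UNIT_LEN = 4

# IUPAC nucleotide one-letter codes (case-insensitive); none besides the
# literal unit characters ever match.
_IUPAC = set("ACGTUNRYSWKMBDHV")

#: default repeat-number bins: 0x, 1-4x, 5-9x, >=10x
DEFAULT_BINS: list[tuple[int, float, str]] = [
    (0, 0, "0x"),
    (1, 4, "1–4x"),
    (5, 9, "5–9x"),
    (10, float("inf"), "≥10x"),
]

#: the two-class scheme for monomeric (1x) vs long multimeric (10x) sites
TWO_CLASS_BINS: list[tuple[int, float, str]] = [
    (1, 1, "1x"),
    (10, float("inf"), "10x"),
]


@dataclass(frozen=True)
class RepeatBlock:
    """A maximal tandem run of GGAA units (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    strand: str
    unit_count: int

    def __post_init__(self):
        if self.unit_count < 1:
            raise ValueError("unit_count must be >= 1")
        if self.end - self.start != UNIT_LEN * self.unit_count:
            raise ValueError("end - start must equal 4 * unit_count")


@dataclass
class PeakRepeatProfile:
    """Repeat-content summary of one genomic interval.

    ``n_blocks_ge`` maps a unit-count threshold k to the number of
    disconnected blocks with at least k units overlapping the evaluation
    window; a partially overlapping block contributes its full unit count.
    """

    peak_id: str
    max_run: int = 0
    n_blocks_total: int = 0
    total_units: int = 0
    n_blocks_ge: dict[int, int] = field(default_factory=dict)
    repeat_class: str | None = None


def _scan_one_unit(seq: str, unit: str) -> list[tuple[int, int]]:
    """(start, unit_count) of every maximal tandem run of ``unit`` in ``seq``.

    Left-to-right scan with greedy extension: any run found is automatically
    left-maximal (a unit immediately to its left would have been found and
    extended first), and extension makes it right-maximal.
    """
    runs = []
    i = seq.find(unit)
    while i != -1:
        j = i + UNIT_LEN
        while seq.startswith(unit, j):
            j += UNIT_LEN
        runs.append((i, (j - i) // UNIT_LEN))
        i = seq.find(unit, j)
    return runs


def scan_sequence(seq: str, strands: str = "plus_only", chrom: str = ".") -> list[RepeatBlock]:
    """Find all maximal GGAA tandem runs in a nucleotide sequence.

    With ``strands="both"``, maximal TTCC runs are additionally reported as
    minus-strand GGAA blocks (coordinates on the plus reference). Runs on
    opposite strands may overlap and are reported independently. Matching is
    case-insensitive; N (or any other ambiguity code) never matches.
    """
    if strands not in ("plus_only", "both"):
        raise ValueError("strands must be 'plus_only' or 'both'")
    s = seq.upper()
    bad = set(s) - _IUPAC
    if bad:
        ch = next(c for c in bad)
        raise ValueError(
            f"character {ch!r} outside the IUPAC alphabet at position {s.index(ch)}"
        )
    blocks = [
        RepeatBlock(chrom, start, start + UNIT_LEN * n, "+", n)
        for start, n in _scan_one_unit(s, UNIT)
    ]
    if strands == "both":
        blocks += [
            RepeatBlock(chrom, start, start + UNIT_LEN * n, "-", n)
            for start, n in _scan_one_unit(s, UNIT_RC)
        ]
    blocks.sort(key=lambda blk: (blk.start, blk.strand))
    return blocks


def blocks_to_frame(blocks: Iterable[RepeatBlock]) -> pd.DataFrame:
    """RepeatBlock table as a BED6-like frame (score = unit_count)."""
    rows = [(b.chrom, b.start, b.end, f"{b.unit_count}xGGAA", b.unit_count, b.strand) for b in blocks]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def scan_fasta(
    path, strands: str = "plus_only", chrom_subset: Sequence[str] | None = None
) -> pd.DataFrame:
    """Scan a FASTA genome chromosome by chromosome (streaming; one
    chromosome resident at a time). Returns the concatenated block table."""
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True, rebuild=True)
    names = list(fa.keys())
    if chrom_subset is not None:
        missing = set(chrom_subset) - set(names)
        if missing:
            raise ValueError(f"chromosomes missing from FASTA: {sorted(missing)}")
        names = [n for n in names if n in set(chrom_subset)]
    frames = []
    for name in names:
        seq = str(fa[name][:]) if len(fa[name]) else ""
        frames.append(blocks_to_frame(scan_sequence(seq, strands=strands, chrom=name)))
    fa.close()
    if not frames:
        return blocks_to_frame([])
    return pd.concat(frames, ignore_index=True)


class BlockIndex:
    """Per-chromosome sorted index over repeat blocks for interval queries."""

    def __init__(self, blocks: pd.DataFrame):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in blocks.groupby("chrom", sort=False):
            sub = sub.sort_values("start", kind="mergesort")
            self._by_chrom[chrom] = (
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
                sub["score"].to_numpy(dtype=int),
            )

    def overlapping_unit_counts(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Unit counts of all blocks whose span intersects [start, end)."""
        if chrom not in self._by_chrom:
            return np.array([], dtype=int)
        starts, ends, counts = self._by_chrom[chrom]
        hi = np.searchsorted(starts, end, side="left")
        mask = ends[:hi] > start
        return counts[:hi][mask]


def profile_interval(
    peak_id: str,
    chrom: str,
    start: int,
    end: int,
    index: BlockIndex,
    window_mode: str = "full_interval",
    center_halfwidth: int | None = None,
    ge_thresholds: Sequence[int] = (1, 5, 10),
    bins: list[tuple[int, float, str]] | None = None,
) -> PeakRepeatProfile:
    """Summarize repeat content of one interval.

    The evaluation window is the full interval, or (``window_mode=
    "center_window"``) a window of ``+/- center_halfwidth`` bp around the
    interval midpoint. A block partially overlapping the window contributes
    its full unit count (unit counts are atomic, never pro-rated).
    """
    if window_mode == "center_window":
        if center_halfwidth is None or center_halfwidth <= 0:
            raise ValueError("center_window mode requires a positive half-width")
        mid = (start + end) // 2
        w_start, w_end = max(0, mid - center_halfwidth), mid + center_halfwidth
    elif window_mode == "full_interval":
        w_start, w_end = start, end
    else:
        raise ValueError(f"unknown window_mode {window_mode!r}")
    counts = index.overlapping_unit_counts(chrom, w_start, w_end)
    prof = PeakRepeatProfile(
        peak_id=peak_id,
        max_run=int(counts.max()) if counts.size else 0,
        n_blocks_total=int(counts.size),
        total_units=int(counts.sum()),
        n_blocks_ge={int(k): int((counts >= k).sum()) for k in ge_thresholds},
    )
    prof.repeat_class = classify_repeat_class(prof, bins)
    return prof


def profile_peaks(
    peaks: pd.DataFrame,
    blocks: pd.DataFrame,
    window_mode: str = "full_interval",
    center_halfwidth: int | None = None,
    bins: list[tuple[int, float, str]] | None = None,
) -> pd.DataFrame:
    """Profile every peak in an interval frame; returns one row per peak
    (peak_id, max_run, n_blocks_total, total_units, n_ge5, n_ge10,
    repeat_class)."""
    index = BlockIndex(blocks)
    rows = []
    names = peaks["name"] if "name" in peaks.columns else peaks.index.astype(str)
    for name, chrom, start, end in zip(names, peaks["chrom"], peaks["start"], peaks["end"]):
        p = profile_interval(
            str(name), chrom, int(start), int(end), index,
            window_mode=window_mode, center_halfwidth=center_halfwidth, bins=bins,
        )
        rows.append(
            (p.peak_id, p.max_run, p.n_blocks_total, p.total_units,
             p.n_blocks_ge[5], p.n_blocks_ge[10], p.repeat_class)
        )
    return pd.DataFrame(
        rows,
        columns=["peak_id", "max_run", "n_blocks_total", "total_units",
                 "n_ge5", "n_ge10", "repeat_class"],
    )


def classify_repeat_class(
    profile_or_max_run, bins: list[tuple[int, float, str]] | None = None
) -> str | None:
    """Label an interval by its largest repeat run.

    ``bins`` is a list of (lo, hi, label) with inclusive bounds on max_run;
    default: 0x, 1-4x, 5-9x, >=10x. Returns None when max_run falls in no
    bin (possible under custom schemes such as the 1x-vs-10x two-class one).
    """
    max_run = (
        profile_or_max_run.max_run
        if isinstance(profile_or_max_run, PeakRepeatProfile)
        else int(profile_or_max_run)
    )
    if bins is None:
        bins = DEFAULT_BINS
    los = [b[0] for b in bins]
    if any(l2 <= l1 for l1, l2 in zip(los, los[1:])):
        raise ValueError("bin edges must be strictly increasing")
    for lo, hi, label in bins:
        if lo <= max_run <= hi:
            return label
    return None
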