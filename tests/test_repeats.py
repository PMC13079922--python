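"""Repeat scanner: maximal GGAA runs, interval profiling, classification."""

import re

import numpy as np
import pytest

from ggaa_switch import repeats
from ggaa_switch.repeats import (
    BlockIndex,
    blocks_to_frame,
    classify_repeat_class,
    profile_interval,
    scan_fasta,
    scan_sequence,
)


def regex_blocks(seq: str, unit: str) -> list[tuple[int, int]]:
    """Independent maximal-run oracle: greedy leftmost regex matching."""
    return [(m.start(), (m.end() - m.start()) // 4) for m in re.finditer(f"(?:{unit})+", seq.upper())]


def revcomp(seq: str) -> str:
    return seq.upper().translate(str.maketrans("ACGT", "TGCA"))[::-1]


@pytest.mark.parametrize(
    "seq,strands,expected",
    [
        ("GGAAGGAAGGAA", "plus_only", [(0, 12, "+", 3)]),
        ("TTCCTTCC", "plus_only", []),
        ("TTCCTTCC", "both", [(0, 8, "-", 2)]),
        ("GGAAGGAACGGAAGGAAGGAAGGAAGGAA", "plus_only", [(0, 8, "+", 2), (9, 29, "+", 5)]),
        ("ACGT", "plus_only", []),
        ("ggaaggaa", "plus_only", [(0, 8, "+", 2)]),  # soft-masked input
        ("GGAANGGAA", "plus_only", [(0, 4, "+", 1), (5, 9, "+", 1)]),  # N never matches
    ],
)
def test_scan_sequence_examples(seq, strands, expected):
    blocks = scan_sequence(seq, strands=strands)
    assert [(b.start, b.end, b.strand, b.unit_count) for b in blocks] == expected


def test_scan_rejects_non_iupac_characters():
    with pytest.raises(ValueError, match="position"):
        scan_sequence("ACGT7ACGT")


def test_scan_matches_regex_oracle_on_random_sequences():
    rng = np.random.default_rng(42)
    for _ in range(50):
        n = int(rng.integers(1, 3000))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        # enrich with GGAA content so runs actually occur
        seq = seq.replace("CCC", "GGAA").replace("TTT", "GGAAGGAA")
        got = [(b.start, b.unit_count) for b in scan_sequence(seq)]
        assert got == regex_blocks(seq, "GGAA")
        both = scan_sequence(seq, strands="both")
        minus = [(b.start, b.unit_count) for b in both if b.strand == "-"]
        assert minus == regex_blocks(seq, "TTCC")


def test_reverse_complement_symmetry():
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list("ACGT"), size=2000)).replace("CAC", "GGAA")
    n = len(seq)
    both = scan_sequence(seq, strands="both")
    minus = {(n - b.end, n - b.start, b.unit_count) for b in both if b.strand == "-"}
    plus_of_rc = {
        (b.start, b.end, b.unit_count) for b in scan_sequence(revcomp(seq))
    }
    assert minus == plus_of_rc


def test_blocks_are_maximal():
    rng = np.random.default_rng(11)
    seq = "".join(rng.choice(list("ACGT"), size=5000)).replace("TAG", "GGAA")
    for b in scan_sequence(seq):
        assert seq[b.start - 4 : b.start] != "GGAA"
        assert seq[b.end : b.end + 4] != "GGAA"


def test_scan_fasta_roundtrip(tmp_path):
    path = tmp_path / "toy.fa"
    path.write_text(">chrA\nGGAAGGAA\n>chrB\nacgtggaacgta\n")
    df = scan_fasta(path)
    assert list(df["chrom"]) == ["chrA", "chrB"]
    assert list(df["score"]) == [2, 1]
    with pytest.raises(ValueError, match="missing"):
        scan_fasta(path, chrom_subset=["chrC"])


def test_profile_interval_counts_disconnected_blocks():
    # two multimeric blocks (13x and 9x) under one peak, as at a locus with
    # multiple disconnected repeat blocks
    blocks = blocks_to_frame(
        [
            repeats.RepeatBlock("chr1", 100, 152, "+", 13),
            repeats.RepeatBlock("chr1", 200, 236, "+", 9),
        ]
    )
    prof = profile_interval("pk1", "chr1", 50, 300, BlockIndex(blocks))
    assert prof.max_run == 13
    assert prof.n_blocks_ge[5] == 2
    assert prof.total_units == 22
    assert prof.repeat_class == "≥10x"
    # partial overlap still contributes the full unit count
    prof2 = profile_interval("pk2", "chr1", 230, 300, BlockIndex(blocks))
    assert prof2.max_run == 9 and prof2.total_units == 9


def test_profile_interval_empty_and_center_window():
    blocks = blocks_to_frame([repeats.RepeatBlock("chr1", 100, 104, "+", 1)])
    idx = BlockIndex(blocks)
    prof = profile_interval("pk", "chr1", 500, 600, idx)
    assert prof.max_run == 0 and prof.repeat_class == "0x"
    centered = profile_interval("pk", "chr1", 0, 1000, idx, "center_window", center_halfwidth=50)
    assert centered.max_run == 0  # block outside the +/-50 bp center window
    with pytest.raises(ValueError):
        profile_interval("pk", "chr1", 0, 1000, idx, "center_window", center_halfwidth=0)


@pytest.mark.parametrize(
    "max_run,label",
    [(0, "0x"), (1, "1–4x"), (4, "1–4x"), (5, "5–9x"), (9, "5–9x"), (10, "≥10x"), (37, "≥10x")],
)
def test_default_repeat_classes(max_run, label):
    assert classify_repeat_class(max_run) == label


def test_two_class_and_custom_bins():
    assert classify_repeat_class(1, repeats.TWO_CLASS_BINS) == "1x"
    assert classify_repeat_class(12, repeats.TWO_CLASS_BINS) == "10x"
    assert classify_repeat_class(5, repeats.TWO_CLASS_BINS) is None
    custom = [(1, 1, "mono"), (2, float("inf"), "multi")]
    assert classify_repeat_class(1, custom) == "mono"
    with pytest.raises(ValueError, match="increasing"):
        classify_repeat_class(1, [(5, 9, "a"), (1, 4, "b")])


def test_profiles_match_per_peak_rescan(study):
    """Peak profiles over the synthetic genome equal a brute-force regex
    rescan of the underlying sequence."""
    from pyfaidx import Fasta

    blocks = scan_fasta(study.genome_path)
    profiles = repeats.profile_peaks(study.peaks, blocks).set_index("peak_id")
    fa = Fasta(str(study.genome_path), as_raw=True, sequence_always_upper=True)
    rng = np.random.default_rng(0)
    sample = study.peaks.sample(40, random_state=1)
    for row in sample.itertuples(index=False):
        seq = str(fa[row.chrom][:])
        runs = [
            (m.start(), m.end(), (m.end() - m.start()) // 4)
            for m in re.finditer("(?:GGAA)+", seq)
        ]
        over = [u for s, e, u in runs if s < row.end and e > row.start]
        assert profiles.loc[row.name, "max_run"] == (max(over) if over else 0)
        assert profiles.loc[row.name, "total_units"] == sum(over)
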