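"""Synthetic-data generator: determinism, planted-truth consistency, and the
statistical structure the downstream stages rely on."""

import numpy as np
import pandas as pd
import pytest

from ggaa_switch import peaks as pk, repeats, synthetic
from ggaa_switch.synthetic import (
    TruthManifest,
    generate_expression_and_survival,
    generate_genome,
    generate_loops,
    generate_peak_experiment,
    make_genome_manifest,
    plan_study,
)


def test_manifest_rejects_overlapping_repeats():
    with pytest.raises(ValueError, match="overlapping"):
        make_genome_manifest({"c": 1000}, [("c", 100, 3, "+"), ("c", 105, 2, "+")], 1)
    with pytest.raises(ValueError, match="bounds"):
        make_genome_manifest({"c": 100}, [("c", 90, 5, "+")], 1)
    with pytest.raises(ValueError, match="unit_count"):
        make_genome_manifest({"c": 1000}, [("c", 90, 0, "+")], 1)


def test_genome_is_deterministic_and_plants_exact_blocks(tmp_path):
    plan = [("c1", 1000, 1, "+"), ("c1", 2000, 4, "+"), ("c1", 3000, 5, "-"),
            ("c1", 4000, 10, "+"), ("c1", 5000, 15, "+")]
    m = make_genome_manifest({"c1": 10_000}, plan, seed=5)
    p1 = generate_genome(m, tmp_path / "a.fa")
    p2 = generate_genome(m, tmp_path / "b.fa")
    assert p1.read_bytes() == p2.read_bytes()
    blocks = repeats.scan_fasta(p1, strands="both")
    found = {(s, u) for s, u in zip(blocks["start"], blocks["score"])}
    for chrom, start, units, strand in plan:
        assert (start, units) in found


def test_different_seed_changes_background_not_planted_blocks(tmp_path):
    plan = [("c1", 500, 7, "+")]
    m1 = make_genome_manifest({"c1": 2000}, plan, seed=1)
    m2 = make_genome_manifest({"c1": 2000}, plan, seed=2)
    f1 = generate_genome(m1, tmp_path / "s1.fa")
    f2 = generate_genome(m2, tmp_path / "s2.fa")
    assert f1.read_bytes() != f2.read_bytes()
    for f in (f1, f2):
        b = repeats.scan_fasta(f)
        assert (500, 7) in set(zip(b["start"], b["score"]))


def test_clean_windows_suppress_accidental_multimer_runs(tmp_path):
    """No accidental run >= 2 units near any planted repeat, and planted runs
    are never extendable."""
    plan = [("c1", i * 1000 + 500, u, "+") for i, u in enumerate([1, 2, 5, 10] * 5)]
    m = make_genome_manifest({"c1": 21_000}, plan, seed=9)
    path = generate_genome(m, tmp_path / "g.fa", clean_radius=50)
    blocks = repeats.scan_fasta(path)
    planted = {(r["start"], r["unit_count"]) for r in m.planted_repeats}
    by_start = dict(zip(blocks["start"], blocks["score"]))
    for start, units in planted:
        assert by_start[start] == units  # exact, hence maximal
    for r in m.planted_repeats:
        lo, hi = r["start"] - 50, r["start"] + 4 * r["unit_count"] + 50
        near = blocks[(blocks["end"] > lo) & (blocks["start"] < hi)]
        accidental = near[~near["start"].isin([p[0] for p in planted])]
        assert (accidental["score"] <= 1).all()


def test_peak_experiment_depth_normalization_cancels_depth():
    m = make_genome_manifest({"c1": 400_000}, [], seed=3)
    _, table = generate_peak_experiment(
        m, n_background_peaks=400, dispersion=0.1, depth_a=16e6, depth_b=32e6, seed=4
    )
    norm = pk.normalize_signal(table)
    lfc = pk.peak_log2fc(norm, table.samples_in("control"), table.samples_in("stag2_kd"))
    assert abs(lfc.mean()) < 0.05


def test_peak_experiment_noiseless_limit_recovers_planted_fold_changes():
    plan = [("c1", i * 2000 + 1000, u, "+") for i, u in enumerate([1, 3, 7, 12] * 25)]
    m = make_genome_manifest({"c1": 210_000}, plan, seed=6)
    _, table = generate_peak_experiment(
        m, n_background_peaks=0, dispersion=0.0, seed=7, base_mean=50_000
    )
    norm = pk.normalize_signal(table)
    lfc = pk.peak_log2fc(norm, table.samples_in("control"), table.samples_in("stag2_kd"))
    planted = pd.Series({p: v["log2fc"] for p, v in m.planted_peaks.items()})
    assert (lfc - planted.loc[lfc.index]).abs().max() < 0.05


def test_peak_experiment_validates_inputs():
    m = make_genome_manifest({"c1": 10_000}, [], seed=1)
    with pytest.raises(ValueError, match="dispersion"):
        generate_peak_experiment(m, dispersion=-1)
    with pytest.raises(ValueError, match="depth"):
        generate_peak_experiment(m, depth_a=0)


def test_loops_noiseless_consensus_recovers_planted_set(study):
    from ggaa_switch.loops import consensus_loops

    rep1, rep2, truth = generate_loops(
        study.manifest, study.peaks, study.manifest.genes_frame(),
        anchor_jitter_sd=0, drop_rate=0, seed=99, n_decoys=0,
    )
    cons = consensus_loops(rep1, rep2, tolerance=0)
    assert len(cons) == len(truth)


def test_loops_jitter_validation():
    m = plan_study(1)
    with pytest.raises(ValueError, match="anchor width"):
        generate_loops(m, m.peaks_frame(), m.genes_frame(), anchor_jitter_sd=1000,
                       anchor_width=1000)
    with pytest.raises(ValueError, match="drop_rate"):
        generate_loops(m, m.peaks_frame(), m.genes_frame(), drop_rate=1.5)


def test_expression_validates_sample_count():
    m = plan_study(1)
    with pytest.raises(ValueError, match="n_samples"):
        generate_expression_and_survival(m, n_samples=4)


def test_null_effect_expression_gives_centered_scores():
    """With effect_log2 = 0 the ssGSEA score difference between latent-high
    and latent-low samples is centered at zero."""
    from ggaa_switch.scoring import log_transform_counts, ssgsea_score

    m = plan_study(2)
    bundle = generate_expression_and_survival(
        m, n_samples=60, effect_log2=0.0, hazard_beta=0.0, seed=8
    )
    log_expr = log_transform_counts(bundle.cohort_counts)
    scores = ssgsea_score(log_expr, m.signature_genes("10x_promoter"))
    hi = scores[bundle.latent >= 0.5]
    lo = scores[bundle.latent < 0.5]
    pooled = scores.std() * np.sqrt(1 / len(hi) + 1 / len(lo))
    assert abs(hi.mean() - lo.mean()) < 4 * pooled


def test_truth_manifest_roundtrip_and_consistency(study, tmp_path):
    m = study.manifest
    m.validate()
    path = tmp_path / "manifest.json"
    m.to_json(path)
    back = TruthManifest.from_json(path)
    assert back.planted_signature_genes == m.planted_signature_genes
    assert back.genome_spec == m.genome_spec
    # every planted identifier resolves in the generated frames
    peak_ids = set(study.peaks["name"])
    assert set(m.planted_peaks) <= peak_ids
    gene_ids = set(study.manifest.genes_frame()["gene_id"])
    for loop in m.planted_loops:
        assert loop["peak_id"] in peak_ids and loop["gene_id"] in gene_ids
    assert set(m.survival_hazard) == set(study.expression.survival["sample"])


def test_study_files_written(study_dir):
    for fname in (
        "genome.fa", "peaks.bed", "peak_counts.tsv", "peak_samples.tsv",
        "loops_rep1.tsv", "loops_rep2.tsv", "tss.tsv", "expression_cohort.tsv",
        "survival.tsv", "de_siFLI1.tsv", "manifest.json",
    ):
        assert (study_dir / fname).exists(), fname
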