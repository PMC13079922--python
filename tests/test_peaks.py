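"""Differential peak-signal analysis and the surrogate DE test."""

import numpy as np
import pandas as pd
import pytest

from ggaa_switch import peaks
from ggaa_switch.peaks import (
    PeakSignalTable,
    call_status,
    fc_correlation,
    normalize_signal,
    peak_log2fc,
    signal_profile_matrix,
    stratify_by_class,
    surrogate_de,
    venn_partition,
)


def make_table(counts, conditions=("control", "control", "stag2_kd", "stag2_kd"), depths=None):
    samples = [f"s{i}" for i in range(len(conditions))]
    df = pd.DataFrame(counts, columns=samples)
    depths = depths or [16e6] * len(samples)
    return PeakSignalTable(df, dict(zip(samples, conditions)), dict(zip(samples, map(float, depths))))


def test_normalize_scales_to_target_depth():
    t = make_table([[100, 100, 100, 100]], depths=[8e6, 16e6, 16e6, 32e6])
    norm = normalize_signal(t, 16e6)
    assert norm.iloc[0].tolist() == [200.0, 100.0, 100.0, 50.0]


def test_normalize_identity_at_target():
    t = make_table([[7, 8, 9, 10]])
    assert normalize_signal(t).iloc[0].tolist() == [7, 8, 9, 10]


def test_peak_log2fc_examples():
    norm = pd.DataFrame({"c1": [7.0], "t1": [31.0]})
    assert peak_log2fc(norm, ["c1"], ["t1"]).iloc[0] == pytest.approx(2.0)
    same = pd.DataFrame({"c1": [5.0], "t1": [5.0]})
    assert peak_log2fc(same, ["c1"], ["t1"]).iloc[0] == 0.0
    with pytest.raises(ValueError):
        peak_log2fc(norm, [], ["t1"])


def test_status_partition_is_exhaustive_and_exclusive():
    lfc = pd.Series([-3.0, -1.5, 0.0, 1.0, 2.0])
    status = call_status(lfc, preset="figure")
    assert status.tolist() == ["lost", "retained", "retained", "retained", "gained"]
    status_m = call_status(lfc, preset="methods")
    assert status_m.tolist() == ["lost", "lost", "retained", "gained", "gained"]
    with pytest.raises(ValueError, match="preset"):
        call_status(lfc, preset="nope")


def test_venn_partition_trivial_cases():
    a = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [10]})
    b = pd.DataFrame({"chrom": ["c"], "start": [100], "end": [110]})
    disjoint = venn_partition(a, b)
    assert disjoint["shared_a"] == 0 and disjoint["fraction_a_lost"] == 1.0
    same = venn_partition(a, a.copy())
    assert same["a_only"] == same["b_only"] == 0


def test_stratify_by_class_single_class_and_permutation_null():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        {
            "peak_id": [f"p{i}" for i in range(200)],
            "log2fc": rng.normal(0, 1, 200),
            "status": "retained",
            "repeat_class": ["1–4x"] * 200,
        }
    )
    res = stratify_by_class(df, test_classes=("1–4x", "≥10x"))
    assert res["test"] is None  # one class empty: no between-class test
    # permuted labels: between-class difference centered at 0
    df["repeat_class"] = rng.permutation(["1–4x"] * 100 + ["≥10x"] * 100)
    res2 = stratify_by_class(df, test_classes=("1–4x", "≥10x"))
    assert abs(res2["test"]["t"]) < 4


def test_signal_profile_matrix_constant_and_empty_track():
    anchors = pd.DataFrame({"chrom": ["c"], "start": [4_000], "end": [4_200]})
    track = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [10_000], "value": [3.5]})
    mat, means = signal_profile_matrix(track, anchors, half_width=500, bin_size=100)
    assert np.allclose(mat, 3.5) and np.allclose(means, 3.5)
    empty = pd.DataFrame(columns=["chrom", "start", "end", "value"])
    mat2, _ = signal_profile_matrix(empty, anchors, half_width=500, bin_size=100)
    assert np.isnan(mat2).all()
    # anchor too near the chromosome start: padded with missing values
    edge = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [100]})
    mat3, _ = signal_profile_matrix(track, edge, half_width=500, bin_size=100)
    assert np.isnan(mat3).all()


def test_fc_correlation_trivial_and_errors():
    x = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
    assert fc_correlation(x, x)[0] == pytest.approx(1.0)
    assert fc_correlation(x, -x)[0] == pytest.approx(-1.0)
    with pytest.raises(ValueError, match="variance"):
        fc_correlation(x, pd.Series([1.0, 1, 1, 1], index=list("abcd")))
    with pytest.raises(ValueError, match="3"):
        fc_correlation(x[:2], x[:2])


def test_surrogate_de_identical_groups_gives_zero_fold_change():
    expr = pd.DataFrame(
        np.tile([[10.0, 20, 30, 40]], (5, 1)), columns=["a1", "a2", "b1", "b2"],
        index=[f"g{i}" for i in range(5)],
    )
    groups = {"a1": "c", "a2": "c", "b1": "t", "b2": "t"}
    expr[["b1", "b2"]] = expr[["a1", "a2"]].to_numpy()
    de = surrogate_de(expr, groups, "c", "t")
    assert (de["log2FC"] == 0).all()
    with pytest.raises(ValueError, match=">= 2"):
        surrogate_de(expr[["a1", "b1", "b2"]], groups, "c", "t")


def test_surrogate_de_power_and_calibration():
    """Planted 2-fold genes at n=10/group are nearly all detected; nulls keep
    the BH false-positive proportion near nominal."""
    rng = np.random.default_rng(12)
    n_true, n_null, n_rep = 100, 400, 10
    base = rng.lognormal(6, 0.3, size=n_true + n_null)
    mu = np.tile(base[:, None], (1, 2 * n_rep))
    mu[:n_true, n_rep:] *= 2.0  # planted 2-fold up
    counts = rng.poisson(rng.gamma(10.0, mu / 10.0))  # NB dispersion 0.1
    samples = [f"c{i}" for i in range(n_rep)] + [f"t{i}" for i in range(n_rep)]
    expr = pd.DataFrame(counts, columns=samples, index=[f"g{i}" for i in range(n_true + n_null)])
    groups = {s: ("c" if s.startswith("c") else "t") for s in samples}
    de = surrogate_de(expr, groups, "c", "t")
    hit = de["adj_p"] < 0.05
    assert hit[:n_true].mean() >= 0.9
    fdp = hit[n_true:].sum() / max(1, hit.sum())
    assert fdp <= 0.10
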