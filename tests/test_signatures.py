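"""Signature builders, the univariate Cox screen, and prognostic refinement."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as ll_logrank

from ggaa_switch import loops as lp, peaks as pk, repeats, signatures as sg


@pytest.fixture(scope="module")
def derived(study):
    """Differential peaks + profiles for the session study."""
    blocks = repeats.scan_fasta(study.genome_path)
    profiles = repeats.profile_peaks(study.peaks, blocks)
    diff = pk.differential_peaks(
        study.signal, "control", "stag2_kd", preset="methods", profiles=profiles
    )
    return diff


def test_10x_promoter_recovers_planted_genes(study, derived):
    genes = study.manifest.genes_frame()
    sig = sg.build_10x_promoter(derived, study.peaks, genes)
    planted = study.manifest.signature_genes("10x_promoter")
    inter = set(sig.genes) & planted
    union = set(sig.genes) | planted
    assert len(inter) / len(union) >= 0.9
    empty = sg.build_10x_promoter(derived, study.peaks, genes, fc_gt=np.inf)
    assert empty.genes == ()


def test_fc_threshold_monotonicity(study, derived):
    genes = study.manifest.genes_frame()
    loose = set(sg.build_10x_promoter(derived, study.peaks, genes, fc_gt=0.2).genes)
    strict = set(sg.build_10x_promoter(derived, study.peaks, genes, fc_gt=0.5).genes)
    assert strict <= loose


def test_peak_overlapping_two_promoters_includes_both_genes():
    diff = pd.DataFrame(
        {"peak_id": ["p1"], "log2fc": [2.0], "max_run": [12], "status": ["gained"]}
    )
    peaks = pd.DataFrame({"chrom": ["c"], "start": [900], "end": [1_300], "name": ["p1"]})
    genes = pd.DataFrame(
        {"gene_id": ["gA", "gB"], "chrom": ["c", "c"], "strand": ["+", "-"], "tss": [2_000, 500]}
    )
    sig = sg.build_10x_promoter(diff, peaks, genes)
    assert set(sig.genes) == {"gA", "gB"}


def test_1x_promoter_requires_fli1_dependence():
    diff = pd.DataFrame(
        {"peak_id": ["p1", "p2"], "log2fc": [-2.0, -2.0], "max_run": [1, 1],
         "status": ["lost", "lost"]}
    )
    peaks = pd.DataFrame(
        {"chrom": ["c", "c"], "start": [600, 10_600], "end": [1_000, 11_000],
         "name": ["p1", "p2"]}
    )
    genes = pd.DataFrame(
        {"gene_id": ["gDep", "gInd"], "chrom": ["c", "c"], "strand": ["+", "+"],
         "tss": [1_500, 11_500]}
    )
    de = pd.DataFrame(
        {"log2FC": [-2.0, 1.0], "adj_p": [0.001, 0.001]}, index=["gDep", "gInd"]
    )
    sig = sg.build_1x_promoter(diff, peaks, genes, de)
    assert set(sig.genes) == {"gDep"}  # up-regulated upon siFLI1: excluded
    none = sg.build_1x_promoter(diff, peaks, genes, de.assign(adj_p=0.9))
    assert none.genes == ()
    with pytest.raises(ValueError, match="column"):
        sg.build_1x_promoter(diff, peaks, genes, de.drop(columns=["adj_p"]))


def test_enhancer_signature_optional_de_filter():
    gm = pd.DataFrame({"gene": ["g1", "g2"], "n_loops": [2, 1], "peaks": ["a", "b"]})
    plain = sg.build_enhancer_signature(gm, "10x_enhancer", "up")
    assert set(plain.genes) == {"g1", "g2"}
    de = pd.DataFrame({"log2FC": [-1.0, 2.0], "adj_p": [0.01, 0.01]}, index=["g1", "g2"])
    filtered = sg.build_enhancer_signature(gm, "1x_enhancer", "down", de_table=de)
    assert set(filtered.genes) == {"g1"}


def test_signature_rederivation_is_deterministic(study, derived):
    genes = study.manifest.genes_frame()
    a = sg.build_10x_promoter(derived, study.peaks, genes)
    b = sg.build_10x_promoter(derived, study.peaks, genes)
    assert a.digest() == b.digest()
    with pytest.raises(ValueError, match="unique"):
        sg.GeneSignature("x", ("g1", "g1"), "up")


# ---------------------------------------------------------------------------
# Cox screen


def simulate_survival(rng, x, beta, n, censor_scale=None):
    lam = 0.05 * np.exp(beta * x)
    t = rng.exponential(1 / lam)
    c = rng.exponential(censor_scale, size=n) if censor_scale else np.full(n, np.inf)
    return np.minimum(t, c), (t <= c).astype(int)


def test_cox_univariate_matches_lifelines():
    rng = np.random.default_rng(21)
    n = 150
    x = rng.normal(size=n)
    time, event = simulate_survival(rng, x, 0.8, n, censor_scale=40)
    fit = sg.cox_univariate(x, time, event)
    cph = CoxPHFitter()
    cph.fit(pd.DataFrame({"x": x, "T": time, "E": event}), "T", "E")
    assert fit["coef"] == pytest.approx(cph.params_["x"], abs=1e-4)
    assert fit["se"] == pytest.approx(cph.standard_errors_["x"], abs=1e-4)
    assert fit["converged"]


def test_cox_score_test_equals_logrank_on_two_groups():
    rng = np.random.default_rng(22)
    n = 120
    x = (rng.uniform(size=n) < 0.5).astype(float)
    time, event = simulate_survival(rng, x, 0.7, n, censor_scale=50)
    fit = sg.cox_univariate(x, time, event)
    res = ll_logrank(time[x == 1], time[x == 0], event[x == 1], event[x == 0])
    assert fit["score_stat"] == pytest.approx(res.test_statistic, abs=1e-6)


def test_cox_screen_recovers_planted_hazard_direction():
    rng = np.random.default_rng(23)
    n = 200
    risk = rng.normal(size=n)
    time, event = simulate_survival(rng, risk, 1.0, n, censor_scale=60)
    expr = pd.DataFrame(
        {f"S{i}": [risk[i] + rng.normal(0, 0.3), rng.normal()] for i in range(n)},
        index=["g_risk", "g_null"],
    )
    surv = pd.DataFrame({"sample": [f"S{i}" for i in range(n)], "time": time, "event": event})
    res = sg.cox_screen(expr, surv)
    assert res.loc["g_risk", "coef"] > 0.5
    assert res.loc["g_risk", "p"] < 1e-6
    assert abs(res.loc["g_null", "coef"]) < 0.5


def test_cox_screen_errors_and_constant_genes():
    surv = pd.DataFrame({"sample": [f"S{i}" for i in range(12)],
                         "time": np.arange(1.0, 13.0), "event": [1] * 12})
    expr = pd.DataFrame(
        {f"S{i}": [1.0, float(i)] for i in range(12)}, index=["flat", "ok"]
    )
    with pytest.warns(UserWarning, match="constant"):
        res = sg.cox_screen(expr, surv)
    assert list(res.index) == ["ok"]
    with pytest.raises(ValueError, match="event"):
        sg.cox_screen(expr, surv.assign(event=0))


def test_refine_prognostic_rules():
    sig = sg.GeneSignature("10x_union", ("g1", "g2", "g3"), "up")
    cox = pd.DataFrame({"coef": [1.0, -1.0], "se": [0.1, 0.1], "p": [0.001, 0.001],
                        "converged": [True, True]}, index=["g1", "g2"])
    with pytest.warns(UserWarning, match="missing"):
        refined = sg.refine_prognostic(sig, cox)
    assert refined.genes == ("g1",)
    all_neg = cox.assign(coef=[-1.0, -2.0])
    with pytest.warns(UserWarning, match="missing"):
        assert sg.refine_prognostic(sig, all_neg).genes == ()


def test_activity_signature_concordance(study):
    de = study.expression.de_tables
    sig = sg.build_activity_signature(
        {"a673": de["shSTAG2_A673"], "tc71": de["shSTAG2_TC71"]}
    )
    planted = study.manifest.signature_genes("stag2_inactivation")
    derived = set(sig.genes)
    jacc = len(derived & planted) / len(derived | planted)
    assert jacc >= 0.9
    with pytest.raises(ValueError, match=">= 2"):
        sg.build_activity_signature({"one": de["shSTAG2_A673"]})


def test_activity_signature_discordant_gene_excluded():
    t1 = pd.DataFrame({"log2FC": [1.0, 1.0], "adj_p": [0.01, 0.01]}, index=["g1", "g2"])
    t2 = pd.DataFrame({"log2FC": [1.0, -1.0], "adj_p": [0.01, 0.01]}, index=["g1", "g2"])
    sig = sg.build_activity_signature({"a": t1, "b": t2})
    assert sig.genes == ("g1",)
    empty = sg.build_activity_signature({"a": t1, "b": t2.assign(adj_p=0.9)})
    assert empty.genes == ()


def test_gmt_roundtrip(tmp_path):
    sigs = [sg.GeneSignature("s1", ("gB", "gA"), "up"), sg.GeneSignature("s2", ("gC",), "down")]
    path = tmp_path / "sig.gmt"
    sg.write_gmt(sigs, path)
    back = sg.read_gmt(path)
    assert back == {"s1": ["gA", "gB"], "s2": ["gC"]}
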