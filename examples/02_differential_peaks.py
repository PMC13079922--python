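"""Two-condition peak signal stratified by GGAA repeat class.

Simulates EWS-FLI1 binding signal in control vs STAG2-knockdown conditions
with the planted class structure (short-repeat peaks lose signal, long-repeat
peaks gain), then recovers the per-class fold-change pattern.
"""

from ggaa_switch import peaks as pk, repeats, synthetic

data = synthetic.simulate_study(seed=3)

blocks = repeats.scan_fasta(data.genome_path)
profiles = repeats.profile_peaks(data.peaks, blocks)
diff = pk.differential_peaks(
    data.signal, "control", "stag2_kd", preset="methods", profiles=profiles
)

strat = pk.stratify_by_class(diff, test_classes=("1–4x", "≥10x"))
print("mean log2 fold-change (STAG2 loss vs control) by repeat class:")
print(strat["log2fc_summary"].to_string(index=False))
print("\nlost / retained / gained peaks by repeat class:")
print(strat["contingency"])
t = strat["test"]
print(f"\n1–4x vs ≥10x fold-change difference: t = {t['t']:.1f}, p = {t['p']:.2e}")
# Short-repeat (1-4x) peaks show a net loss of binding while multimeric
# (>=5x, >=10x) peaks gain - the enhancer-class switch in miniature.
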