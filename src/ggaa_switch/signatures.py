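"""Repeat-length-specific gene signature derivation and prognostic refinement.

Four signatures partition the fusion transcription factor's output by the
GGAA repeat length of its control element and by regulatory mode:

* ``10x_promoter``: genes whose promoter overlaps a multimeric (max_run >=
  10) peak gaining signal (log2fc > 0.5) after STAG2 loss;
* ``1x_promoter``: genes whose promoter overlaps a monomeric (max_run == 1)
  peak losing signal (log2fc < -1), intersected with genes significantly
  down-regulated upon FLI1 knockdown (logFC < 0, adjusted p < 0.05);
* ``10x_enhancer`` / ``1x_enhancer``: the same peak rules applied to distal
  peaks, with genes assigned through replicate-supported chromatin loops
  (one anchor holds the qualifying peak, the other the gene promoter); the
  1x rule again requires FLI1-dependence.

The prognostic refinement keeps 10x-signature genes whose univariate Cox
coefficient for overall survival is positive; the activity signature takes
genes concordantly significant across >= 2 model-system DE contrasts.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import intervals, loops as loops_mod


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set with direction and re-derivable provenance."""

    name: str
    genes: tuple[str, ...]
    direction: str  # "up" or "down" relative to the defining contrast
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")
        object.__setattr__(self, "genes", tuple(sorted(self.genes)))

    def digest(self) -> str:
        payload = json.dumps(
            {"name": self.name, "genes": self.genes, "direction": self.direction,
             "provenance": self.provenance},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    def as_set(self) -> frozenset[str]:
        return frozenset(self.genes)


def _digest_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(df.reset_index(drop=True), index=False).to_numpy().tobytes()
    ).hexdigest()


def _promoter_genes_of_peaks(
    qualifying: pd.DataFrame, genes: pd.DataFrame, promoter_flank: int
) -> set[str]:
    promoters = loops_mod.promoter_table(genes, flank=promoter_flank)
    if len(qualifying) == 0 or len(promoters) == 0:
        return set()
    pair_df, _ = intervals.intersect(
        qualifying[["chrom", "start", "end"]], promoters, 1
    )
    names = promoters["name"].to_numpy()
    return {str(names[bi]) for bi in pair_df["b_index"]}


def build_10x_promoter(
    diff_peaks: pd.DataFrame,
    peak_intervals: pd.DataFrame,
    genes: pd.DataFrame,
    min_run: int = 10,
    fc_gt: float = 0.5,
    promoter_flank: int = loops_mod.DEFAULT_PROMOTER_FLANK,
) -> GeneSignature:
    """Genes with a multimeric up-regulated peak (max_run >= min_run,
    log2fc > fc_gt) overlapping their promoter."""
    qual_ids = set(
        diff_peaks.loc[(diff_peaks["max_run"] >= min_run) & (diff_peaks["log2fc"] > fc_gt), "peak_id"]
    )
    qual = peak_intervals[peak_intervals["name"].isin(qual_ids)]
    found = _promoter_genes_of_peaks(qual, genes, promoter_flank)
    return GeneSignature(
        "10x_promoter", tuple(found), "up",
        {"rule": f"max_run>={min_run} & log2fc>{fc_gt} & promoter overlap",
         "n_qualifying_peaks": len(qual_ids), "inputs": _digest_frame(diff_peaks)},
    )


def build_1x_promoter(
    diff_peaks: pd.DataFrame,
    peak_intervals: pd.DataFrame,
    genes: pd.DataFrame,
    de_sifli1: pd.DataFrame,
    run_eq: int = 1,
    fc_lt: float = -1.0,
    de_logfc_lt: float = 0.0,
    de_adj_p: float = 0.05,
    promoter_flank: int = loops_mod.DEFAULT_PROMOTER_FLANK,
) -> GeneSignature:
    """Genes with a monomeric lost peak at their promoter that are also
    significantly down-regulated upon FLI1 knockdown."""
    for col in ("log2FC", "adj_p"):
        if col not in de_sifli1.columns:
            raise ValueError(f"DE table lacks required column {col!r}")
    qual_ids = set(
        diff_peaks.loc[(diff_peaks["max_run"] == run_eq) & (diff_peaks["log2fc"] < fc_lt), "peak_id"]
    )
    qual = peak_intervals[peak_intervals["name"].isin(qual_ids)]
    by_peak = _promoter_genes_of_peaks(qual, genes, promoter_flank)
    dependent = set(
        de_sifli1.index[(de_sifli1["log2FC"] < de_logfc_lt) & (de_sifli1["adj_p"] < de_adj_p)].astype(str)
    )
    found = by_peak & dependent
    return GeneSignature(
        "1x_promoter", tuple(found), "down",
        {"rule": f"max_run=={run_eq} & log2fc<{fc_lt} & promoter overlap & "
                 f"siFLI1 logFC<{de_logfc_lt}, adj.p<{de_adj_p}",
         "n_qualifying_peaks": len(qual_ids), "inputs": _digest_frame(diff_peaks)},
    )


def build_enhancer_signature(
    gene_map: pd.DataFrame,
    name: str,
    direction: str,
    de_table: pd.DataFrame | None = None,
    de_logfc_lt: float = 0.0,
    de_adj_p: float = 0.05,
) -> GeneSignature:
    """Signature from a loop-derived enhancer->gene map
    (:func:`ggaa_switch.loops.enhancer_gene_map` output), optionally
    filtered to FLI1-dependent genes (the monomeric rule)."""
    found = set(gene_map["gene"].astype(str))
    rule = "loop-mapped genes of qualifying enhancer peaks"
    if de_table is not None:
        dependent = set(
            de_table.index[(de_table["log2FC"] < de_logfc_lt) & (de_table["adj_p"] < de_adj_p)].astype(str)
        )
        found &= dependent
        rule += f" & siFLI1 logFC<{de_logfc_lt}, adj.p<{de_adj_p}"
    return GeneSignature(name, tuple(found), direction,
                         {"rule": rule, "n_loop_genes": len(gene_map)})


# --------------------------------------------------------------------------
# Univariate Cox proportional-hazards screen


def cox_univariate(x: np.ndarray, time: np.ndarray, event: np.ndarray,
                   max_iter: int = 50, tol: float = 1e-9) -> dict:
    """Univariate Cox PH fit by Newton-Raphson on the Efron partial
    likelihood.

    Returns coef, se, Wald p, the score test statistic at beta=0 (which on
    two-group data equals the log-rank chi-square), and a convergence flag.
    """
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.lexsort((1 - event, time))  # by time; deaths before censorings at ties
    x, time, event = x[order], time[order], event[order]
    n = len(x)

    event_times = np.unique(time[event == 1])

    # per-event-time bookkeeping (times sorted ascending)
    first_at_risk = np.searchsorted(time, event_times, side="left")
    death_masks = [(time == t) & (event == 1) for t in event_times]

    def score_info(beta: float) -> tuple[float, float, float]:
        theta = np.exp(beta * x)
        # suffix sums: S_k(t) over the risk set {time >= t} in O(n)
        suf0 = np.concatenate([np.cumsum(theta[::-1])[::-1], [0.0]])
        suf1 = np.concatenate([np.cumsum((x * theta)[::-1])[::-1], [0.0]])
        suf2 = np.concatenate([np.cumsum((x * x * theta)[::-1])[::-1], [0.0]])
        loglik = 0.0
        u = 0.0
        info = 0.0
        for k, t in enumerate(event_times):
            dead = death_masks[k]
            d = int(dead.sum())
            i0 = first_at_risk[k]
            s0, s1, s2 = suf0[i0], suf1[i0], suf2[i0]
            s0d = theta[dead].sum()
            s1d = (x[dead] * theta[dead]).sum()
            s2d = (x[dead] ** 2 * theta[dead]).sum()
            xsum_d = x[dead].sum()
            loglik += beta * xsum_d
            ell = np.arange(d) / d
            phi0 = s0 - ell * s0d
            phi1 = s1 - ell * s1d
            phi2 = s2 - ell * s2d
            loglik -= np.log(phi0).sum()
            u += xsum_d - (phi1 / phi0).sum()
            info += (phi2 / phi0 - (phi1 / phi0) ** 2).sum()
        return loglik, u, info

    _, u0, i0 = score_info(0.0)
    score_stat = u0 * u0 / i0 if i0 > 0 else float("nan")

    beta = 0.0
    converged = False
    for _ in range(max_iter):
        _, u, info = score_info(beta)
        if info <= 0 or not np.isfinite(u):
            break
        step = u / info
        beta += step
        if abs(step) < tol:
            converged = True
            break
    _, _, info = score_info(beta)
    se = 1.0 / np.sqrt(info) if info > 0 else float("nan")
    z = beta / se if se and np.isfinite(se) else float("nan")
    p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else float("nan")
    return {
        "coef": float(beta),
        "se": float(se),
        "p": float(p),
        "score_stat": float(score_stat),
        "converged": bool(converged),
    }


def cox_screen(expression: pd.DataFrame, survival: pd.DataFrame, zscore: bool = True) -> pd.DataFrame:
    """Per-gene univariate Cox screen of a genes x samples expression matrix
    against (sample, time, event) survival records.

    Expression is z-scored per gene by default; constant genes are excluded
    with a warning. Requires >= 10 samples with >= 1 event.
    """
    surv = survival.set_index("sample") if "sample" in survival.columns else survival
    shared = [s for s in expression.columns if s in surv.index]
    if len(shared) < 10:
        raise ValueError("need >= 10 samples shared between expression and survival")
    time = surv.loc[shared, "time"].to_numpy(dtype=float)
    event = surv.loc[shared, "event"].to_numpy(dtype=int)
    if (time <= 0).any():
        raise ValueError("survival times must be positive")
    if event.sum() == 0:
        raise ValueError("no events in the survival table")
    rows = []
    skipped = []
    for gene, values in expression[shared].iterrows():
        xv = values.to_numpy(dtype=float)
        sd = xv.std()
        if sd == 0 or not np.isfinite(sd):
            skipped.append(gene)
            continue
        if zscore:
            xv = (xv - xv.mean()) / sd
        fit = cox_univariate(xv, time, event)
        rows.append((gene, fit["coef"], fit["se"], fit["p"], fit["converged"]))
    if skipped:
        warnings.warn(f"excluded {len(skipped)} constant genes from the Cox screen")
    return pd.DataFrame(rows, columns=["gene", "coef", "se", "p", "converged"]).set_index("gene")


def refine_prognostic(
    signature: GeneSignature,
    cox_results: pd.DataFrame,
    coef_gt: float = 0.0,
    p_lt: float | None = None,
    name: str = "prognostic_10x",
) -> GeneSignature:
    """Subset a signature to genes with a positive (``> coef_gt``) Cox
    coefficient; an optional Wald p threshold is off by default. Signature
    genes missing from the Cox results are dropped with a warning."""
    present = [g for g in signature.genes if g in cox_results.index]
    missing = set(signature.genes) - set(present)
    if missing:
        warnings.warn(f"{len(missing)} signature genes missing from Cox results; dropped")
    sub = cox_results.loc[present]
    keep = sub["coef"] > coef_gt
    if p_lt is not None:
        keep &= sub["p"] < p_lt
    return GeneSignature(
        name, tuple(sub.index[keep].astype(str)), "up",
        {"rule": f"coef>{coef_gt}" + (f" & p<{p_lt}" if p_lt is not None else ""),
         "parent": signature.name, "parent_digest": signature.digest()},
    )


def build_activity_signature(
    de_tables: dict[str, pd.DataFrame],
    adj_p: float = 0.05,
    name: str = "stag2_inactivation",
) -> GeneSignature:
    """Genes significant (adjusted p < threshold) with concordant log2FC
    sign in every supplied model-system DE contrast."""
    if len(de_tables) < 2:
        raise ValueError("need >= 2 DE tables")
    shared: set[str] | None = None
    for df in de_tables.values():
        sig = df[(df["adj_p"] < adj_p) & (df["log2FC"] != 0)]
        genes = set(sig.index.astype(str))
        shared = genes if shared is None else shared & genes
    concordant = []
    directions = {}
    for gene in sorted(shared or ()):
        signs = {np.sign(df.loc[gene, "log2FC"]) for df in de_tables.values()}
        if len(signs) == 1:
            concordant.append(gene)
            directions[gene] = "up" if signs.pop() > 0 else "down"
    up = [g for g in concordant if directions[g] == "up"]
    return GeneSignature(
        name, tuple(concordant), "up" if len(up) >= len(concordant) / 2 else "down",
        {"rule": f"adj_p<{adj_p} & concordant sign in {len(de_tables)} contrasts",
         "per_gene_direction": directions},
    )


def write_gmt(signatures: list[GeneSignature], path) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, sig.provenance.get("rule", "."), *sig.genes]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2:
                out[parts[0]] = [g for g in parts[2:] if g]
    return out
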