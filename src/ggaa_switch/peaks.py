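"""Differential peak-signal analysis stratified by GGAA repeat class.

Quantifies how a perturbation (e.g. STAG2 knockdown) redistributes a
transcription factor's binding signal across peak classes: depth
normalization of per-peak counts, condition log2 fold-changes, partition of
the cistrome into lost/retained/gained sets, cross-tabulation by repeat
class, anchored signal profiles, and a surrogate differential-expression
test used to derive DE tables from synthetic counts.

"Fold" is always log2 in this package. Two named threshold presets are
provided and never mixed implicitly:

* ``figure``: lost < -2, gained > 1.25 (broad cistrome partition)
* ``methods``: lost < -1, gained > 0.5 (signature-definition rules)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import intervals

#: named (lost, gained) log2 fold-change threshold presets
THRESHOLD_PRESETS: dict[str, tuple[float, float]] = {
    "figure": (-2.0, 1.25),
    "methods": (-1.0, 0.5),
}

DEFAULT_TARGET_DEPTH = 16e6  # reads; "normalized to 16 M reads" convention


@dataclass
class PeakSignalTable:
    """Raw per-peak counts with sample->condition and sample->library size maps."""

    counts: pd.DataFrame  # peaks x samples
    condition: Mapping[str, str]
    library_size: Mapping[str, float]

    def __post_init__(self):
        missing = set(self.counts.columns) - set(self.condition)
        if missing:
            raise ValueError(f"samples without a condition label: {sorted(missing)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        for s in self.counts.columns:
            if self.library_size[s] <= 0:
                raise ValueError(f"non-positive library size for sample {s}")

    def samples_in(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.condition[s] == condition]


def normalize_signal(
    table: PeakSignalTable, target_depth: float = DEFAULT_TARGET_DEPTH
) -> pd.DataFrame:
    """Scale each sample's counts to a common sequencing depth:
    count * (target_depth / library_size)."""
    factors = pd.Series(
        {s: target_depth / table.library_size[s] for s in table.counts.columns}
    )
    return table.counts * factors


def peak_log2fc(
    normalized: pd.DataFrame,
    control_ids: Sequence[str],
    treatment_ids: Sequence[str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """log2((mean_treatment + c) / (mean_control + c)) per peak, on the
    depth-normalized scale."""
    if len(control_ids) == 0 or len(treatment_ids) == 0:
        raise ValueError("both groups must be non-empty")
    mean_c = normalized.loc[:, list(control_ids)].mean(axis=1)
    mean_t = normalized.loc[:, list(treatment_ids)].mean(axis=1)
    return np.log2((mean_t + pseudocount) / (mean_c + pseudocount)).rename("log2fc")


def call_status(log2fc: pd.Series, preset: str = "figure",
                lost_lt: float | None = None, gained_gt: float | None = None) -> pd.Series:
    """Partition peaks into lost/retained/gained by log2 fold-change.

    Thresholds come from a named preset unless given explicitly. The
    partition is exhaustive and exclusive.
    """
    if lost_lt is None or gained_gt is None:
        try:
            p_lost, p_gained = THRESHOLD_PRESETS[preset]
        except KeyError:
            raise ValueError(f"unknown threshold preset {preset!r}") from None
        lost_lt = p_lost if lost_lt is None else lost_lt
        gained_gt = p_gained if gained_gt is None else gained_gt
    status = pd.Series("retained", index=log2fc.index, name="status")
    status[log2fc < lost_lt] = "lost"
    status[log2fc > gained_gt] = "gained"
    return status


def differential_peaks(
    table: PeakSignalTable,
    control: str,
    treatment: str,
    target_depth: float = DEFAULT_TARGET_DEPTH,
    pseudocount: float = 1.0,
    preset: str = "figure",
    profiles: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """End-to-end differential peak table: normalized condition means, log2fc,
    lost/retained/gained status, and (when ``profiles`` is given) the joined
    repeat class and max_run."""
    norm = normalize_signal(table, target_depth)
    ctrl, trt = table.samples_in(control), table.samples_in(treatment)
    lfc = peak_log2fc(norm, ctrl, trt, pseudocount)
    out = pd.DataFrame(
        {
            "peak_id": norm.index,
            "mean_control": norm[ctrl].mean(axis=1).to_numpy(),
            "mean_treatment": norm[trt].mean(axis=1).to_numpy(),
            "log2fc": lfc.to_numpy(),
        }
    )
    out["status"] = call_status(out["log2fc"], preset=preset).to_numpy()
    if profiles is not None:
        out = out.merge(
            profiles[["peak_id", "max_run", "repeat_class"]], on="peak_id", how="left"
        )
    return out


def venn_partition(
    peaks_a: pd.DataFrame, peaks_b: pd.DataFrame, min_overlap: int = 1
) -> dict:
    """Presence/absence overlap of two called peak sets (Venn mode).

    Returns counts of shared / a_only / b_only peaks and the fraction of
    ``a`` lost (a_only / |a|). "Shared" counts peaks (of a, resp. b) with a
    >= min_overlap bp partner in the other set.
    """
    _, a_hits = intervals.intersect(peaks_a, peaks_b, min_overlap)
    _, b_hits = intervals.intersect(peaks_b, peaks_a, min_overlap)
    n_a, n_b = len(peaks_a), len(peaks_b)
    return {
        "shared_a": int(a_hits.sum()),
        "shared_b": int(b_hits.sum()),
        "a_only": int(n_a - a_hits.sum()),
        "b_only": int(n_b - b_hits.sum()),
        "fraction_a_lost": float(n_a - a_hits.sum()) / n_a if n_a else float("nan"),
        "a_hits": a_hits,
        "b_hits": b_hits,
    }


def stratify_by_class(diff_peaks: pd.DataFrame, test_classes: tuple[str, str] | None = None) -> dict:
    """Cross-tabulate lost/retained/gained status against repeat class and
    summarize the per-class log2fc distributions.

    ``test_classes`` optionally names two classes to compare with a
    two-sided Welch t test on log2fc. Empty classes are reported with count
    0 and no test.
    """
    if "repeat_class" not in diff_peaks.columns:
        raise ValueError("diff_peaks must carry a repeat_class column")
    df = diff_peaks.copy()
    contingency = pd.crosstab(df["status"], df["repeat_class"])
    summary = (
        df.groupby("repeat_class")["log2fc"]
        .agg(["count", "mean", "median", "std"])
        .reset_index()
    )
    result = {"contingency": contingency, "log2fc_summary": summary}
    if test_classes is not None:
        x = df.loc[df["repeat_class"] == test_classes[0], "log2fc"].dropna()
        y = df.loc[df["repeat_class"] == test_classes[1], "log2fc"].dropna()
        if len(x) >= 2 and len(y) >= 2:
            t, p = stats.ttest_ind(x, y, equal_var=False)
            result["test"] = {"classes": test_classes, "t": float(t), "p": float(p)}
        else:
            result["test"] = None
    return result


def signal_profile_matrix(
    track: pd.DataFrame,
    anchors: pd.DataFrame,
    half_width: int = 1000,
    bin_size: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-signal matrix around anchor midpoints (the aggregate profile
    plot primitive).

    ``track`` is a bedGraph-like frame (chrom, start, end, value),
    non-overlapping within a sample; ``anchors`` an interval frame whose
    midpoints center the windows. Returns (anchor x bin matrix, column
    means); bins with no track coverage, and windows running off the
    chromosome start, are NaN.
    """
    if half_width <= 0 or bin_size <= 0 or (2 * half_width) % bin_size:
        raise ValueError("half_width and bin_size must be positive with 2*half_width divisible by bin_size")
    n_bins = (2 * half_width) // bin_size
    mat = np.full((len(anchors), n_bins), np.nan)
    track_by_chrom = {
        c: s.sort_values("start", kind="mergesort") for c, s in track.groupby("chrom", sort=False)
    }
    for row, (chrom, a_start, a_end) in enumerate(
        zip(anchors["chrom"], anchors["start"], anchors["end"])
    ):
        mid = (int(a_start) + int(a_end)) // 2
        w_start = mid - half_width
        if w_start < 0:  # too near the chromosome edge: padded row
            continue
        sub = track_by_chrom.get(chrom)
        if sub is None:
            continue
        ts = sub["start"].to_numpy()
        te = sub["end"].to_numpy()
        tv = sub["value"].to_numpy(dtype=float)
        for k in range(n_bins):
            b0 = w_start + k * bin_size
            b1 = b0 + bin_size
            hi = np.searchsorted(ts, b1, side="left")
            ov = np.minimum(b1, te[:hi]) - np.maximum(b0, ts[:hi])
            keep = ov > 0
            if keep.any():
                # coverage-weighted mean over covered bases
                mat[row, k] = float((tv[:hi][keep] * ov[keep]).sum() / ov[keep].sum())
    if len(anchors) and not np.isnan(mat).all(axis=0).any():
        col_means = np.nanmean(mat, axis=0)
    elif len(anchors):
        col_means = np.array(
            [np.nan if np.isnan(col).all() else np.nanmean(col) for col in mat.T]
        )
    else:
        col_means = np.full(n_bins, np.nan)
    return mat, col_means


def fc_correlation(log2fc_x: pd.Series, log2fc_y: pd.Series) -> tuple[float, float]:
    """Pearson correlation between two fold-change vectors on shared peaks."""
    joined = pd.concat([log2fc_x, log2fc_y], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need >= 3 shared peaks")
    x, y = joined.iloc[:, 0], joined.iloc[:, 1]
    if np.std(x.to_numpy()) == 0 or np.std(y.to_numpy()) == 0:
        raise ValueError("zero variance in a fold-change vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def surrogate_de(
    normalized_expression: pd.DataFrame,
    groups: Mapping[str, str],
    control: str,
    treatment: str,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Simple per-gene differential expression on log2(normalized + c):
    Welch t test with Benjamini-Hochberg correction.

    Produces the DE-table inputs (gene, log2FC, statistic, adjusted p) the
    signature rules consume; it stands in for a full count-model DE fit when
    deriving tables from synthetic counts.
    """
    ctrl = [s for s in normalized_expression.columns if groups[s] == control]
    trt = [s for s in normalized_expression.columns if groups[s] == treatment]
    if len(ctrl) < 2 or len(trt) < 2:
        raise ValueError("need >= 2 samples per group")
    log_expr = np.log2(normalized_expression + pseudocount)
    xc = log_expr[ctrl].to_numpy()
    xt = log_expr[trt].to_numpy()
    log2fc = xt.mean(axis=1) - xc.mean(axis=1)
    t, p = stats.ttest_ind(xt, xc, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance genes: no evidence
    adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": normalized_expression.index,
            "log2FC": log2fc,
            "statistic": np.where(np.isnan(t), 0.0, t),
            "adj_p": adj,
        }
    ).set_index("gene")
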