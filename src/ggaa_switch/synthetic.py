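"""Synthetic study generator with planted ground truth.

Produces every input the enhancer-class-switch pipeline consumes — a genome
with planted GGAA tandem runs of controlled length, two-condition peak
counts with repeat-class-dependent fold-change structure (short-repeat
peaks lose signal, long-repeat peaks gain), replicate chromatin-loop calls
with anchor jitter and dropout, negative-binomial expression with planted
signature effects, and survival times whose hazard tracks the planted
signature burden — together with a :class:`TruthManifest` recording what
was planted, so every downstream stage can be tested for recovery without
any external download.

Study conditions (class effects, dispersion, replicate counts, the ~25%
prevalence of the latent STAG2-loss state) are fixed as defaults here and
treated as the simulated experiment's design, not as tuning knobs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import peaks as peaks_mod

UNIT = "GGAA"
UNIT_RC = "TTCC"

#: planted log2 fold-change (STAG2-loss vs control) per repeat class
DEFAULT_CLASS_EFFECTS: dict[str, float] = {
    "1x": -1.5,
    "2-4x": -0.5,
    "5-9x": 0.5,
    "ge10x": 1.0,
    "background": 0.0,
}

#: unit-count sampling range per planted class
CLASS_UNIT_RANGES: dict[str, tuple[int, int]] = {
    "1x": (1, 1),
    "2-4x": (2, 4),
    "5-9x": (5, 9),
    "ge10x": (10, 15),
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class TruthManifest:
    """Planted ground truth for one synthetic study."""

    genome_spec: dict[str, int] = field(default_factory=dict)
    planted_repeats: list[dict] = field(default_factory=list)
    planted_peaks: dict[str, dict] = field(default_factory=dict)
    planted_loops: list[dict] = field(default_factory=list)
    planted_signature_genes: dict[str, dict] = field(default_factory=dict)
    survival_hazard: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    genes: list[dict] = field(default_factory=list)
    fli1_dependent: list[str] = field(default_factory=list)

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        reps = sorted(self.planted_repeats, key=lambda r: (r["chrom"], r["start"]))
        prev = None
        for r in reps:
            if r["unit_count"] < 1:
                raise ValueError(f"unit_count < 1 at {r}")
            end = r["start"] + 4 * r["unit_count"]
            if r["start"] < 0 or end > self.genome_spec.get(r["chrom"], 0):
                raise ValueError(f"planted repeat outside chromosome bounds: {r}")
            if prev is not None and prev["chrom"] == r["chrom"]:
                prev_end = prev["start"] + 4 * prev["unit_count"]
                if r["start"] < prev_end:
                    raise ValueError(f"overlapping repeat plan entries: {prev} and {r}")
            prev = r
        peak_ids = set(self.planted_peaks)
        gene_ids = {g["gene_id"] for g in self.genes}
        for loop in self.planted_loops:
            if loop["peak_id"] not in peak_ids:
                raise ValueError(f"loop references unknown peak {loop['peak_id']}")
            if loop["gene_id"] not in gene_ids:
                raise ValueError(f"loop references unknown gene {loop['gene_id']}")

    # -- views --------------------------------------------------------------
    def peaks_frame(self) -> pd.DataFrame:
        rows = [
            (v["chrom"], v["start"], v["end"], pid, 0, ".")
            for pid, v in self.planted_peaks.items()
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])

    def genes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.genes, columns=["gene_id", "chrom", "strand", "tss"])

    def signature_genes(self, name: str) -> set[str]:
        return set(self.planted_signature_genes[name]["genes"])

    # -- (de)serialization ---------------------------------------------------
    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# genome


def _unit_for_strand(strand: str) -> str:
    return UNIT if strand == "+" else UNIT_RC


def make_genome_manifest(
    chrom_lengths: dict[str, int], repeat_plan: list[tuple], seed: int
) -> TruthManifest:
    """Minimal manifest from (chrom, start, unit_count, strand) plan entries."""
    reps = [
        {"chrom": c, "start": int(s), "unit_count": int(u), "strand": st}
        for c, s, u, st in repeat_plan
    ]
    m = TruthManifest(genome_spec=dict(chrom_lengths), planted_repeats=reps, seed=seed)
    m.validate()
    return m


def _clean_windows(arr: np.ndarray, planted: list[tuple[int, int, str]], radius: int, rng) -> None:
    """Regenerate background so no planted run is extendable and no
    accidental run of >= 2 units lies within ``radius`` bp of a planted run.

    ``planted`` holds (start, end, strand) on one chromosome. Positions
    inside planted blocks are never touched.
    """
    n = len(arr)
    mask = np.zeros(n, dtype=bool)
    for s, e, _ in planted:
        mask[s:e] = True

    def regen(lo: int, hi: int) -> None:
        span = np.arange(max(0, lo), min(n, hi))
        span = span[~mask[span]]
        arr[span] = _BASES[rng.integers(0, 4, size=len(span))]

    doubles = [UNIT.encode() * 2, UNIT_RC.encode() * 2]
    for s, e, strand in planted:
        unit = _unit_for_strand(strand).encode()
        for _ in range(200):
            dirty = False
            if s >= 4 and bytes(arr[s - 4 : s]) == unit and not mask[s - 4]:
                regen(s - 4, s)
                dirty = True
            if e + 4 <= n and bytes(arr[e : e + 4]) == unit and not mask[e]:
                regen(e, e + 4)
                dirty = True
            lo, hi = max(0, s - radius - 8), min(n, e + radius + 8)
            window = bytes(arr[lo:hi])
            for pat in doubles:
                start = 0
                while True:
                    i = window.find(pat, start)
                    if i == -1:
                        break
                    g_lo, g_hi = lo + i, lo + i + 8
                    if not mask[g_lo:g_hi].any():  # planted neighbours are allowed
                        regen(g_lo, g_hi)
                        dirty = True
                    start = i + 1
            if not dirty:
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not clean window around planted repeat")


def generate_genome(manifest: TruthManifest, path, clean_radius: int = 50) -> Path:
    """Write the synthetic genome FASTA for a manifest's repeat plan.

    Background is i.i.d. uniform over A/C/G/T; planted runs are exact GGAA
    (or TTCC for minus-strand) tandem repeats. Windows of ``clean_radius``
    bp around each planted run are regenerated until they contain no
    accidental run of >= 2 units and cannot extend the planted run, so
    planted blocks are maximal with their exact unit counts. Deterministic:
    the same manifest (and seed) yields a byte-identical file.
    """
    manifest.validate()
    rng = np.random.default_rng(manifest.seed)
    path = Path(path)
    by_chrom: dict[str, list] = {c: [] for c in manifest.genome_spec}
    for r in manifest.planted_repeats:
        s = r["start"]
        by_chrom[r["chrom"]].append((s, s + 4 * r["unit_count"], r["strand"]))
    with open(path, "w") as fh:
        for chrom, length in manifest.genome_spec.items():
            arr = _BASES[rng.integers(0, 4, size=length)]
            for s, e, strand in by_chrom[chrom]:
                unit = _unit_for_strand(strand).encode()
                arr[s:e] = np.frombuffer(unit * ((e - s) // 4), dtype=np.uint8)
            _clean_windows(arr, sorted(by_chrom[chrom]), clean_radius, rng)
            fh.write(f">{chrom}\n")
            seq = bytes(arr).decode()
            for i in range(0, length, 60):
                fh.write(seq[i : i + 60] + "\n")
    return path


# ---------------------------------------------------------------------------
# peak experiment


def _nb_counts(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = mu + dispersion * mu^2 (Poisson in
    the dispersion -> 0 limit)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion < 1e-12:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _default_peaks_from_repeats(manifest: TruthManifest, peak_width: int,
                                effects: dict[str, float]) -> None:
    """Populate manifest.planted_peaks with one fixed-width peak centered on
    each planted repeat (used when no study plan pre-assigned peaks)."""
    for i, r in enumerate(manifest.planted_repeats):
        u = r["unit_count"]
        cls = next(
            (c for c, (lo, hi) in CLASS_UNIT_RANGES.items() if lo <= u <= hi), "ge10x" if u > 15 else "1x"
        )
        mid = r["start"] + 2 * r["unit_count"]
        start = max(0, mid - peak_width // 2)
        manifest.planted_peaks[f"pk{i:05d}"] = {
            "chrom": r["chrom"],
            "start": start,
            "end": start + peak_width,
            "repeat_class": cls,
            "log2fc": effects[cls],
        }


def generate_peak_experiment(
    manifest: TruthManifest,
    n_background_peaks: int = 200,
    dispersion: float = 0.1,
    depth_a: float = 16e6,
    depth_b: float = 16e6,
    n_reps: int = 2,
    seed: int | None = None,
    peak_width: int = 400,
    class_effects: dict[str, float] | None = None,
    base_mean: float = 200.0,
) -> tuple[pd.DataFrame, peaks_mod.PeakSignalTable]:
    """Two-condition per-peak counts with planted repeat-class effects.

    Peaks are fixed-width intervals centered on planted repeats (plus random
    background positions with zero planted effect). Counts are negative
    binomial with means respecting the planted log2 fold-changes and the
    library depths (reference depth 16M). Returns the peak interval frame
    and a :class:`~ggaa_switch.peaks.PeakSignalTable`; the truth log2fc is
    recorded in the manifest.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0 (nonpositive means no overdispersion)")
    if depth_a <= 0 or depth_b <= 0:
        raise ValueError("library depths must be positive")
    effects = dict(DEFAULT_CLASS_EFFECTS)
    if class_effects:
        effects.update(class_effects)
    rng = np.random.default_rng(manifest.seed + 1 if seed is None else seed)
    if not manifest.planted_peaks:
        _default_peaks_from_repeats(manifest, peak_width, effects)

    # background peaks at random positions avoiding existing peaks
    occupied: dict[str, list[tuple[int, int]]] = {}
    for v in manifest.planted_peaks.values():
        occupied.setdefault(v["chrom"], []).append((v["start"], v["end"]))
    chroms = list(manifest.genome_spec)
    n_bg = 0
    attempts = 0
    while n_bg < n_background_peaks and attempts < 100 * n_background_peaks:
        attempts += 1
        chrom = chroms[rng.integers(len(chroms))]
        length = manifest.genome_spec[chrom]
        if length <= peak_width:
            continue
        start = int(rng.integers(0, length - peak_width))
        end = start + peak_width
        if any(start < e and s < end for s, e in occupied.get(chrom, [])):
            continue
        occupied.setdefault(chrom, []).append((start, end))
        manifest.planted_peaks[f"bg{n_bg:05d}"] = {
            "chrom": chrom, "start": start, "end": end,
            "repeat_class": "background", "log2fc": effects["background"],
        }
        n_bg += 1

    peak_ids = list(manifest.planted_peaks)
    lfc = np.array([manifest.planted_peaks[p]["log2fc"] for p in peak_ids])
    base = base_mean * rng.lognormal(0.0, 0.5, size=len(peak_ids))
    samples, condition, libsize = [], {}, {}
    counts = {}
    for cond, depth, tag in (("control", depth_a, "ctrl"), ("stag2_kd", depth_b, "kd")):
        for rep in range(1, n_reps + 1):
            name = f"{tag}_{rep}"
            samples.append(name)
            condition[name] = cond
            libsize[name] = depth
            mu = base * (2.0 ** (lfc if cond == "stag2_kd" else 0.0)) * (depth / 16e6)
            counts[name] = _nb_counts(rng, mu, dispersion)
    count_df = pd.DataFrame(counts, index=peak_ids)[samples]
    table = peaks_mod.PeakSignalTable(count_df, condition, libsize)
    return manifest.peaks_frame(), table


# ---------------------------------------------------------------------------
# loops


def _promoter_mid(gene: dict, flank: int = 1500) -> int:
    if gene["strand"] == "+":
        return int(gene["tss"]) - flank // 2
    return int(gene["tss"]) + flank // 2


def generate_loops(
    manifest: TruthManifest,
    peaks: pd.DataFrame,
    tss_table: pd.DataFrame,
    anchor_jitter_sd: float = 0.0,
    drop_rate: float = 0.0,
    seed: int | None = None,
    anchor_width: int = 1000,
    n_decoys: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Two replicate loop files plus the truth map.

    Each planted loop connects an anchor centered on its enhancer peak to an
    anchor centered on the target gene's promoter. In each replicate, every
    planted loop is independently dropped with probability ``drop_rate`` and
    its anchors are shifted by rounded Gaussian jitter (sd in bp); decoy
    loops unique to each replicate are appended.
    """
    if not 0 <= drop_rate < 1:
        raise ValueError("drop_rate must be in [0, 1)")
    if anchor_jitter_sd >= anchor_width:
        raise ValueError("anchor jitter sd must be smaller than the anchor width (consensus undefined)")
    rng = np.random.default_rng(manifest.seed + 2 if seed is None else seed)
    peak_lookup = {
        str(n): (c, int(s), int(e))
        for n, c, s, e in zip(peaks["name"], peaks["chrom"], peaks["start"], peaks["end"])
    }
    gene_lookup = {str(g["gene_id"]): g for g in tss_table.to_dict("records")}
    half = anchor_width // 2
    truth_rows = []
    for i, loop in enumerate(manifest.planted_loops):
        chrom, ps, pe = peak_lookup[loop["peak_id"]]
        gene = gene_lookup[loop["gene_id"]]
        pmid = (ps + pe) // 2
        gmid = _promoter_mid(gene)
        a1, a2 = sorted((pmid, gmid))
        truth_rows.append(
            (f"loop{i:05d}", loop["peak_id"], loop["gene_id"], chrom,
             a1 - half, a1 + half, a2 - half, a2 + half, float(rng.uniform(1, 10)))
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["loop_id", "peak_id", "gene_id", "chrom",
                 "start1", "end1", "start2", "end2", "score"],
    )

    def one_replicate() -> pd.DataFrame:
        keep = rng.uniform(size=len(truth)) >= drop_rate
        sub = truth[keep]
        rows = []
        for row in sub.itertuples(index=False):
            j1 = int(np.rint(rng.normal(0, anchor_jitter_sd))) if anchor_jitter_sd else 0
            j2 = int(np.rint(rng.normal(0, anchor_jitter_sd))) if anchor_jitter_sd else 0
            rows.append(
                (row.chrom, max(0, row.start1 + j1), row.end1 + j1,
                 row.chrom, max(0, row.start2 + j2), row.end2 + j2,
                 row.score + float(rng.normal(0, 0.1)))
            )
        # decoys: random intra-chromosomal loops unique to this replicate
        chroms = list(manifest.genome_spec) or list(truth["chrom"].unique())
        sizes = manifest.genome_spec or {c: int(truth["end2"].max() + 10 * anchor_width) for c in chroms}
        for _ in range(n_decoys):
            chrom = chroms[rng.integers(len(chroms))]
            hi = sizes[chrom] - 20 * anchor_width
            if hi <= 0:
                continue
            s1 = int(rng.integers(0, hi))
            gap = int(rng.integers(2 * anchor_width, 10 * anchor_width))
            rows.append((chrom, s1, s1 + anchor_width,
                         chrom, s1 + gap, s1 + gap + anchor_width, float(rng.uniform(1, 10))))
        df = pd.DataFrame(rows, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "score"])
        return df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)

    return one_replicate(), one_replicate(), truth


# ---------------------------------------------------------------------------
# expression and survival


@dataclass
class ExpressionBundle:
    """Synthetic cohort + model-system expression with survival."""

    cohort_counts: pd.DataFrame  # genes x samples, raw counts
    latent: pd.Series  # per-sample STAG2-loss factor in [0, 1]
    survival: pd.DataFrame  # sample, time, event
    model_counts: dict[str, pd.DataFrame]  # contrast -> genes x samples counts
    model_groups: dict[str, dict[str, str]]  # contrast -> sample -> group
    de_tables: dict[str, pd.DataFrame]  # contrast -> surrogate DE table


def _gene_effect_matrix(manifest: TruthManifest, genes: list[str]) -> pd.Series:
    """Per-gene direction (+1 up / -1 down upon STAG2 loss; 0 otherwise).

    The repeat-length signatures set the direction; genes planted only in
    the broader STAG2-inactivation program default to up.
    """
    direction = pd.Series(0.0, index=genes)
    assigned: set[str] = set()
    for name, d in (("10x_promoter", 1.0), ("10x_enhancer", 1.0),
                    ("1x_promoter", -1.0), ("1x_enhancer", -1.0)):
        for g in manifest.planted_signature_genes.get(name, {}).get("genes", ()):
            if g in direction.index:
                direction[g] = d
                assigned.add(g)
    for g in manifest.planted_signature_genes.get("stag2_inactivation", {}).get("genes", ()):
        if g in direction.index and g not in assigned:
            direction[g] = 1.0
    return direction


def generate_expression_and_survival(
    manifest: TruthManifest,
    n_samples: int = 200,
    nb_dispersion: float = 0.1,
    effect_log2: float = 2.0,
    hazard_beta: float = 1.0,
    censor_rate: float = 0.2,
    seed: int | None = None,
    n_filler_genes: int = 600,
    n_model_reps: int = 8,
    baseline_median_months: float = 36.0,
    high_fraction: float = 0.25,
) -> ExpressionBundle:
    """Cohort counts, model-system contrasts, surrogate DE tables, and
    survival records, all tied to a latent per-sample STAG2-loss factor.

    The latent factor is bimodal in [0, 1] (a ``high_fraction`` subpopulation
    near 1, the rest near 0, mirroring the expected prevalence of the
    alteration). Planted signature genes shift by ``effect_log2 x factor``
    in their planted direction; the *STAG2* transcript itself moves
    oppositely. Survival is exponential with log-hazard
    ``hazard_beta x z(burden)`` where burden is the latent factor z-scored
    across the cohort; censoring is independent exponential tuned to
    ``censor_rate``.
    """
    if n_samples < 8:
        raise ValueError("n_samples must be >= 8 (quartile stratification degenerate)")
    rng = np.random.default_rng(manifest.seed + 3 if seed is None else seed)
    planted_genes = [g["gene_id"] for g in manifest.genes]
    genes = planted_genes + [f"F{i:04d}" for i in range(n_filler_genes)]
    if "STAG2" not in genes:
        genes = ["STAG2"] + genes
    direction = _gene_effect_matrix(manifest, genes)
    direction["STAG2"] = -1.0  # transcript tracks the intact allele

    base = pd.Series(300.0 * rng.lognormal(0.0, 1.0, size=len(genes)), index=genes)

    samples = [f"S{i:03d}" for i in range(n_samples)]
    is_high = rng.uniform(size=n_samples) < high_fraction
    latent = np.where(is_high, rng.uniform(0.75, 1.0, n_samples), rng.uniform(0.0, 0.25, n_samples))
    latent = pd.Series(latent, index=samples, name="latent")

    mu = base.to_numpy()[:, None] * 2.0 ** (
        effect_log2 * direction.to_numpy()[:, None] * latent.to_numpy()[None, :]
    )
    cohort = pd.DataFrame(_nb_counts(rng, mu, nb_dispersion), index=genes, columns=samples)

    # survival: exponential PH on the z-scored latent burden
    burden = (latent - latent.mean()) / (latent.std(ddof=0) or 1.0)
    lam0 = np.log(2) / baseline_median_months
    lam = lam0 * np.exp(hazard_beta * burden.to_numpy())
    t_event = rng.exponential(1.0 / lam)
    if censor_rate > 0:
        mu_c = lam0 * censor_rate / (1 - censor_rate)
        t_cens = rng.exponential(1.0 / mu_c, size=n_samples)
    else:
        t_cens = np.full(n_samples, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    survival = pd.DataFrame({"sample": samples, "time": np.maximum(time, 1e-3), "event": event})
    manifest.survival_hazard = {s: float(v) for s, v in zip(samples, hazard_beta * burden)}

    # model systems: two STAG2-knockdown contrasts and one FLI1 knockdown
    fli1_dep = set(manifest.fli1_dependent)
    model_counts, model_groups, de_tables = {}, {}, {}
    contrasts = {
        "shSTAG2_A673": direction,
        "shSTAG2_TC71": direction,
        "siFLI1": pd.Series([-1.0 if g in fli1_dep else 0.0 for g in genes], index=genes),
    }
    for name, dir_vec in contrasts.items():
        cols, groups = [], {}
        mats = []
        for group, f in (("control", 0.0), ("treated", 1.0)):
            for rep in range(1, n_model_reps + 1):
                sample = f"{name}_{group}_{rep}"
                cols.append(sample)
                groups[sample] = group
                mu_m = base.to_numpy() * 2.0 ** (effect_log2 * dir_vec.to_numpy() * f)
                mats.append(_nb_counts(rng, mu_m, nb_dispersion))
        mat = pd.DataFrame(np.column_stack(mats), index=genes, columns=cols)
        model_counts[name] = mat
        model_groups[name] = groups
        de_tables[name] = peaks_mod.surrogate_de(mat, groups, "control", "treated")
    return ExpressionBundle(cohort, latent, survival, model_counts, model_groups, de_tables)


# ---------------------------------------------------------------------------
# full study plan


@dataclass
class StudySizes:
    """Design of the planted study (gene counts per signature, decoys,
    peak-only classes, supporting peaks/loops per gene)."""

    n_10x_promoter: int = 25
    n_1x_promoter: int = 25
    n_10x_enhancer: int = 30
    n_1x_enhancer: int = 25
    n_stag2_activity: int = 40
    n_plain_decoys: int = 60
    n_1x_promoter_nondep: int = 6  # qualify by peak, not FLI1-dependent
    n_1x_enhancer_nondep: int = 6
    n_mid_enhancer_decoys: int = 8  # 5-9x loops: excluded from the 10x rule
    peaks_per_gene: int = 3
    extra_peaks: dict = field(
        default_factory=lambda: {"1x": 100, "2-4x": 70, "5-9x": 70, "ge10x": 50}
    )
    peak_width: int = 400
    gene_slot: int = 12_000
    peak_slot: int = 2_000
    anchor_width: int = 1_000
    n_chroms: int = 3


def _sample_units(rng, cls: str) -> int:
    lo, hi = CLASS_UNIT_RANGES[cls]
    return int(rng.integers(lo, hi + 1))


def plan_study(seed: int, sizes: StudySizes | None = None) -> TruthManifest:
    """Lay out genes, planted repeats, peaks and loops on a synthetic genome
    plan (coordinates only; no sequence is generated here).

    Signature genes receive ``peaks_per_gene`` qualifying peaks each
    (promoter classes: repeats planted inside the promoter; enhancer
    classes: distal repeats connected to the promoter by planted loops).
    Decoy genes exercise every exclusion rule of the signature builders.
    """
    sz = sizes or StudySizes()
    rng = np.random.default_rng(seed)
    m = TruthManifest(seed=seed)
    gene_counter = peak_counter = 0
    cursors: dict[str, int] = {}
    chrom_names = [f"chr{i+1}" for i in range(sz.n_chroms)]
    for c in chrom_names:
        cursors[c] = 10_000
    rr = iter(range(10**9))

    def next_chrom() -> str:
        return chrom_names[next(rr) % len(chrom_names)]

    def add_repeat(chrom: str, start: int, units: int) -> None:
        m.planted_repeats.append(
            {"chrom": chrom, "start": int(start), "unit_count": int(units), "strand": "+"}
        )

    def add_peak(chrom: str, center: int, cls: str) -> str:
        nonlocal peak_counter
        units = _sample_units(rng, cls)
        rep_start = center - 2 * units
        add_repeat(chrom, rep_start, units)
        pid = f"pk{peak_counter:05d}"
        peak_counter += 1
        start = center - sz.peak_width // 2
        m.planted_peaks[pid] = {
            "chrom": chrom, "start": int(start), "end": int(start + sz.peak_width),
            "repeat_class": cls, "log2fc": DEFAULT_CLASS_EFFECTS[cls],
        }
        return pid

    def add_gene(kind: str, cls: str | None) -> str:
        """One gene slot; ``kind`` in {promoter, enhancer, plain}."""
        nonlocal gene_counter
        chrom = next_chrom()
        o = cursors[chrom]
        cursors[chrom] = o + sz.gene_slot
        tss = o + 3_000
        gid = f"G{gene_counter:04d}"
        gene_counter += 1
        m.genes.append({"gene_id": gid, "chrom": chrom, "strand": "+", "tss": int(tss)})
        if kind == "promoter":
            for center in (tss - 1_250, tss - 750, tss - 250)[: sz.peaks_per_gene]:
                add_peak(chrom, center, cls)
        elif kind == "enhancer":
            # distal peaks spaced > loop-matching tolerance apart so the
            # loops of one gene can never cross-match between replicates
            for center in (tss + 2_500, tss + 5_000, tss + 7_500)[: sz.peaks_per_gene]:
                pid = add_peak(chrom, center, cls)
                m.planted_loops.append({"peak_id": pid, "gene_id": gid})
        return gid

    sig: dict[str, list[str]] = {k: [] for k in
                                 ("10x_promoter", "1x_promoter", "10x_enhancer", "1x_enhancer")}
    for _ in range(sz.n_10x_promoter):
        sig["10x_promoter"].append(add_gene("promoter", "ge10x"))
    for _ in range(sz.n_1x_promoter):
        sig["1x_promoter"].append(add_gene("promoter", "1x"))
    for _ in range(sz.n_10x_enhancer):
        sig["10x_enhancer"].append(add_gene("enhancer", "ge10x"))
    for _ in range(sz.n_1x_enhancer):
        sig["1x_enhancer"].append(add_gene("enhancer", "1x"))

    nondep: list[str] = []
    for _ in range(sz.n_1x_promoter_nondep):
        nondep.append(add_gene("promoter", "1x"))
    for _ in range(sz.n_1x_enhancer_nondep):
        nondep.append(add_gene("enhancer", "1x"))
    for _ in range(sz.n_mid_enhancer_decoys):
        add_gene("enhancer", "5-9x")
    plain = [add_gene("plain", None) for _ in range(sz.n_plain_decoys)]

    # STAG2-inactivation activity program: expression-only planted genes
    activity = plain[: sz.n_stag2_activity]
    if len(activity) < sz.n_stag2_activity:
        activity = activity + [add_gene("plain", None) for _ in range(sz.n_stag2_activity - len(activity))]

    # standalone peaks per class (no gene association)
    for cls, n in sz.extra_peaks.items():
        for _ in range(n):
            chrom = next_chrom()
            o = cursors[chrom]
            cursors[chrom] = o + sz.peak_slot
            add_peak(chrom, o + sz.peak_slot // 2, cls)

    m.genome_spec = {c: int(cursors[c] + 10_000) for c in chrom_names}
    # the STAG2-inactivation program covers every STAG2-responsive planted
    # gene: the dedicated activity genes plus all repeat-length signatures
    activity_all = sorted(set(activity) | set(sum((sig[k] for k in sig), [])))
    m.planted_signature_genes = {
        "10x_promoter": {"genes": sig["10x_promoter"], "direction": 1},
        "1x_promoter": {"genes": sig["1x_promoter"], "direction": -1},
        "10x_enhancer": {"genes": sig["10x_enhancer"], "direction": 1},
        "1x_enhancer": {"genes": sig["1x_enhancer"], "direction": -1},
        "stag2_inactivation": {"genes": activity_all, "direction": 0},
    }
    # every signature gene is FLI1-dependent; the nondep decoys are not
    m.fli1_dependent = sorted(set(sum((sig[k] for k in sig), [])))
    m.validate()
    return m


# ---------------------------------------------------------------------------
# one-call study


@dataclass
class StudyData:
    """Everything one synthetic study produced, in memory."""

    manifest: TruthManifest
    peaks: pd.DataFrame
    signal: peaks_mod.PeakSignalTable
    loops_rep1: pd.DataFrame
    loops_rep2: pd.DataFrame
    loop_truth: pd.DataFrame
    expression: ExpressionBundle
    genome_path: Path | None = None


def simulate_study(
    seed: int,
    outdir=None,
    sizes: StudySizes | None = None,
    with_genome: bool = True,
    n_background_peaks: int = 150,
    dispersion: float = 0.1,
    n_reps: int = 2,
    anchor_jitter_sd: float = 0.0,
    drop_rate: float = 0.0,
    n_decoy_loops: int = 40,
    n_samples: int = 200,
    hazard_beta: float = 1.0,
    effect_log2: float = 2.0,
    censor_rate: float = 0.2,
    clean_radius: int = 250,
) -> StudyData:
    """Generate a complete synthetic study; optionally write every pipeline
    input file under ``outdir``."""
    manifest = plan_study(seed, sizes)
    outdir = Path(outdir) if outdir is not None else None
    genome_path = None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    if with_genome:
        genome_path = (outdir / "genome.fa") if outdir is not None else Path("genome.fa")
        if outdir is None:
            import tempfile

            genome_path = Path(tempfile.mkdtemp()) / "genome.fa"
        generate_genome(manifest, genome_path, clean_radius=clean_radius)
    peaks_df, signal = generate_peak_experiment(
        manifest, n_background_peaks=n_background_peaks, dispersion=dispersion,
        n_reps=n_reps, seed=seed + 11,
    )
    peaks_df = manifest.peaks_frame()  # includes background peaks
    rep1, rep2, truth = generate_loops(
        manifest, peaks_df, manifest.genes_frame(), anchor_jitter_sd=anchor_jitter_sd,
        drop_rate=drop_rate, seed=seed + 12, n_decoys=n_decoy_loops,
    )
    expr = generate_expression_and_survival(
        manifest, n_samples=n_samples, nb_dispersion=dispersion, effect_log2=effect_log2,
        hazard_beta=hazard_beta, censor_rate=censor_rate, seed=seed + 13,
    )
    data = StudyData(manifest, peaks_df, signal, rep1, rep2, truth, expr, genome_path)
    if outdir is not None:
        _write_study(data, outdir)
    return data


def _write_study(data: StudyData, outdir: Path) -> None:
    from . import intervals

    intervals.write_bed(data.peaks, outdir / "peaks.bed")
    data.signal.counts.rename_axis("peak_id").to_csv(outdir / "peak_counts.tsv", sep="\t")
    pd.DataFrame(
        {
            "sample": list(data.signal.counts.columns),
            "condition": [data.signal.condition[s] for s in data.signal.counts.columns],
            "library_size": [data.signal.library_size[s] for s in data.signal.counts.columns],
        }
    ).to_csv(outdir / "peak_samples.tsv", sep="\t", index=False)
    data.loops_rep1.to_csv(outdir / "loops_rep1.tsv", sep="\t", header=False, index=False)
    data.loops_rep2.to_csv(outdir / "loops_rep2.tsv", sep="\t", header=False, index=False)
    data.manifest.genes_frame().to_csv(outdir / "tss.tsv", sep="\t", index=False)
    data.expression.cohort_counts.rename_axis("gene").to_csv(outdir / "expression_cohort.tsv", sep="\t")
    data.expression.survival.to_csv(outdir / "survival.tsv", sep="\t", index=False)
    for name, df in data.expression.de_tables.items():
        df.to_csv(outdir / f"de_{name}.tsv", sep="\t")
    data.manifest.to_json(outdir / "manifest.json")
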