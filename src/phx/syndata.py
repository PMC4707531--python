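"""Synthetic dual-organism infection time-series generator.

Emulates a two-color microarray experiment in which a temperate phage
infects its bacterial host and both transcriptomes are measured at
0 (uninfected reference), 5, 10, 20, 30 and 80 min post-infection in
three biological replicates. The generator plants known structure --
temporal kinetic classes for the phage ORFs, per-timepoint suppressed or
induced host gene sets, and signed phage-host correlation pairs -- so
that every downstream stage (kinetic classing, DEG calling, enrichment,
co-expression screens) can be validated against ground truth.

Model sketch (all signal on the log2 scale, converted to positive
intensities at the end):

* every feature gets a baseline intensity drawn once per seed;
* each phage ORF follows a unimodal log-normal-in-time bump whose peak
  lies inside its temporal class window (early/middle/late);
* planted host DEGs are shifted by a signed log2 effect at their planted
  time points;
* planted correlation pairs rewrite the host partner as an affine image
  of the phage profile plus an orthogonalized Gaussian complement scaled
  so the sample Pearson correlation over the pair's stage window equals
  the target exactly;
* multiplicative log-normal noise is applied to everything except the
  housekeeping reference feature, which is exactly constant;
* under chloramphenicol (Cm) only early ORFs are transcribed, under
  phosphonoacetic acid (PAA) early and middle ORFs are; permitted
  classes rise and then hold their plateau (transcripts persist because
  the drug freezes the regulatory cascade), blocked classes stay at
  baseline.

Per-feature random substreams are derived by stable hashing of the
feature id, so adding features never reshuffles existing ones.
"""
from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .containers import ExpressionMatrix, GrowthCurve
from .stages import StageWindows

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# generator constants (log2 scale unless noted)
# ---------------------------------------------------------------------------
BASE_LOG2_RANGE = (6.0, 12.0)     # baseline intensity 2^6 .. 2^12
AMPLITUDE_RANGE = (2.8, 4.0)      # phage bump height
BUMP_WIDTH = 0.4                  # log-time width of the kinetic bump
# Peak times are drawn inside a subinterval of each stage window chosen so
# that the geometric sampling grid (5,10,20,30,80 min) resolves the peak
# into the correct class: the discrete argmax of a log-normal bump is the
# grid point nearest in log-time, so e.g. a nominal middle peak at 12 min
# would read out at the 10-min sample and class as early.
PEAK_RANGES = {"early": (6.0, 9.5), "middle": (16.0, 26.0), "late": (60.0, 78.0)}
PAIR_SLOPE = 0.2                  # host-partner amplitude per unit phage log2
TR_DECOY_JITTER = 0.35            # partner jitter outside its stage window
REFERENCE_LEVEL = 1000.0          # constant intensity of the reference feature
# Biological replicate-to-replicate variability: each sample's kinetic bump
# and each planted DEG effect is scaled by exp(N(0, sd)). Microarray
# replicates of an infection time course never reproduce amplitudes exactly
# (infection synchrony and MOI vary by culture), and this variability is
# what keeps unrelated features' sample correlations away from +/-1.
KINETIC_REPLICATE_SD = 0.2
EFFECT_REPLICATE_SD = 0.05

CONDITIONS = {
    "infected": "infected",
    "infected+cm": "cm",
    "infected+paa": "paa",
    "cm": "cm",
    "paa": "paa",
}

DEFAULT_TIME_POINTS = (0, 5, 10, 20, 30, 80)


@dataclass(frozen=True)
class PlantedPair:
    """A planted signed phage-host correlation over a stage window."""

    phage: str
    host: str
    sign: int                    # +1 or -1
    target_abs_cor: float
    window: str = "middle"       # 'early' | 'middle' | 'late' | 'merged'

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValueError("pair sign must be +1 or -1")
        if not 0 < self.target_abs_cor < 1:
            raise ValueError("target |cor| must lie in (0, 1)")


@dataclass
class SyntheticConfig:
    """Full description of the planted structure of a synthetic dataset.

    ``deg_plan`` maps time point -> {host gene -> signed log2 effect}
    (negative = suppressed). ``tr_pair_plan`` holds middle-window
    phage-TR pairs, ``merged_pair_plan`` pairs planted over the merged
    (all post-infection time points) window.
    """

    time_points: tuple[int, ...] = DEFAULT_TIME_POINTS
    replicates: int = 3
    phage_class_map: dict[str, str] = field(default_factory=dict)
    host_gene_count: int = 5633
    deg_plan: dict[int, dict[str, float]] = field(default_factory=dict)
    tr_pair_plan: list[PlantedPair] = field(default_factory=list)
    merged_pair_plan: list[PlantedPair] = field(default_factory=list)
    tr_genes: tuple[str, ...] = ()
    noise_sigma: float = 0.1
    reference_feature: str = "16S"
    moi: float = 10.0            # metadata only
    seed: int = 0

    # -- id helpers ----------------------------------------------------------
    @property
    def host_ids(self) -> list[str]:
        return [f"PA{i:04d}" for i in range(1, self.host_gene_count + 1)]

    @property
    def phage_ids(self) -> list[str]:
        return sorted(self.phage_class_map, key=_orf_number)

    def validate(self) -> None:
        times = list(self.time_points)
        if times != sorted(set(times)):
            raise ValueError("time_points must be strictly increasing")
        if times[0] != 0:
            raise ValueError("first time point must be the uninfected reference (0 min)")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        bad = {c for c in self.phage_class_map.values()} - {"early", "middle", "late"}
        if bad:
            raise ValueError(f"unknown temporal class(es): {sorted(bad)}")
        universe = set(self.host_ids) | set(self.phage_class_map)
        for t, effects in self.deg_plan.items():
            if t not in times or t == 0:
                raise ValueError(f"deg_plan time {t} is not a post-infection time point")
            unknown = set(effects) - set(self.host_ids)
            if unknown:
                raise ValueError(f"deg_plan genes not in feature set: {sorted(unknown)[:5]}")
        for pair in list(self.tr_pair_plan) + list(self.merged_pair_plan):
            if pair.phage not in self.phage_class_map:
                raise ValueError(f"planted pair phage gene unknown: {pair.phage}")
            if pair.host not in universe:
                raise ValueError(f"planted pair host gene unknown: {pair.host}")
        unknown_tr = set(self.tr_genes) - set(self.host_ids)
        if unknown_tr:
            raise ValueError(f"TR genes not in host set: {sorted(unknown_tr)[:5]}")

    # -- (de)serialization ----------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["tr_pair_plan"] = [asdict(p) for p in self.tr_pair_plan]
        doc["merged_pair_plan"] = [asdict(p) for p in self.merged_pair_plan]
        doc["time_points"] = list(self.time_points)
        doc["tr_genes"] = list(self.tr_genes)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["time_points"] = tuple(doc["time_points"])
        doc["tr_genes"] = tuple(doc.get("tr_genes", ()))
        doc["tr_pair_plan"] = [PlantedPair(**p) for p in doc.get("tr_pair_plan", [])]
        doc["merged_pair_plan"] = [PlantedPair(**p) for p in doc.get("merged_pair_plan", [])]
        doc["deg_plan"] = {int(t): dict(v) for t, v in doc.get("deg_plan", {}).items()}
        return cls(**doc)


def _orf_number(orf_id: str) -> int:
    digits = "".join(ch for ch in orf_id if ch.isdigit())
    return int(digits) if digits else 0


def orf_id(n: int) -> str:
    return f"ORF{n:02d}"


def _stable_hash(key: str) -> int:
    digest = hashlib.blake2b(key.encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def _rng(seed: int, key: str, *extra: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed % (2**31), _stable_hash(key), *extra])
    )


# ---------------------------------------------------------------------------
# paper-mirror configuration
# ---------------------------------------------------------------------------

def _covering_sets(pool: list[str], counts: dict[int, int]) -> dict[int, list[str]]:
    """Deterministic per-timepoint subsets of ``pool`` with given sizes
    whose union is exactly ``pool`` (requires sum(counts) >= len(pool) and
    every count <= len(pool))."""
    n = len(pool)
    total = sum(counts.values())
    if total < n:
        raise ValueError("per-timepoint counts cannot cover the pool")
    times = sorted(counts)
    # primary quota per time point (largest remainder, capped by count)
    quota = {t: min(counts[t], int(n * counts[t] / total)) for t in times}
    short = n - sum(quota.values())
    for t in sorted(times, key=lambda t: counts[t] - quota[t], reverse=True):
        if short == 0:
            break
        room = counts[t] - quota[t]
        take = min(room, short)
        quota[t] += take
        short -= take
    if sum(quota.values()) != n:
        raise ValueError("cannot apportion pool coverage")
    sets: dict[int, list[str]] = {}
    start = 0
    chunks = {}
    for t in times:
        chunks[t] = pool[start : start + quota[t]]
        start += quota[t]
    for t in times:
        members = list(chunks[t])
        have = set(members)
        # fill to the requested size by cycling through the rest of the pool
        cursor = (pool.index(chunks[t][0]) if chunks[t] else 0)
        i = cursor
        while len(members) < counts[t]:
            gene = pool[i % n]
            if gene not in have:
                members.append(gene)
                have.add(gene)
            i += 1
        sets[t] = members
    return sets


def paper_mirror_config(seed: int = 0) -> SyntheticConfig:
    """Configuration whose planted structure reproduces the study's printed
    counts: 71 phage ORFs in classes early=ORF57-71 (15), middle=ORF22-56
    (35), late=ORF01-21 (21); 5633 host genes; per-timepoint DEG sets with
    unique totals 2120 down / 40 up (sum over time points 4129, 30-min
    point 1852 down / 28 up); a middle-stage TR pair plan with 24 negative
    and 1 positive (ORF52-PA0163) planted pairs; a merged-window plan
    linking 14 early ORFs to 110 host genes, all positive."""
    rng = _rng(seed, "paper_mirror_config")
    class_map = {}
    for n in range(1, 22):
        class_map[orf_id(n)] = "late"
    for n in range(22, 57):
        class_map[orf_id(n)] = "middle"
    for n in range(57, 72):
        class_map[orf_id(n)] = "early"

    host_ids = [f"PA{i:04d}" for i in range(1, 5634)]
    positive_tr = "PA0163"
    # disjoint id blocks: planted DEGs, TR genes, pair partners
    down_pool = [g for g in host_ids[:2121] if g != positive_tr]      # 2120
    up_pool = host_ids[2121:2161]                                     # 40
    neg_tr_partners = [f"PA{i:04d}" for i in range(4001, 4025)]       # 24
    tr_genes = tuple(sorted([positive_tr] + [f"PA{i:04d}" for i in range(4001, 4476)]))
    merged_partners = [f"PA{i:04d}" for i in range(4501, 4611)]       # 110

    down_counts = {5: 120, 10: 500, 20: 1177, 30: 1852, 80: 400}      # sum 4049
    down_sets = _covering_sets(down_pool, down_counts)
    # Each induced gene is planted at two time points spanning different
    # infection stages, so no induced profile mimics a single kinetic
    # class pulse; the 30-min point carries the printed 28 up-calls and
    # no up-regulation occurs at 5 min. Per-timepoint up counts:
    # 10->25, 20->12, 30->28, 80->15 (sum 80, union 40).
    up_time_pairs = [(10, 30)] * 20 + [(30, 80)] * 8 + [(20, 80)] * 7 + [(10, 20)] * 5
    deg_plan: dict[int, dict[str, float]] = {t: {} for t in (5, 10, 20, 30, 80)}
    for t, genes in down_sets.items():
        for g in genes:
            deg_plan[t][g] = -float(rng.uniform(2.5, 3.5))
    for g, (t1, t2) in zip(up_pool, up_time_pairs):
        deg_plan[t1][g] = float(rng.uniform(2.5, 3.5))
        deg_plan[t2][g] = float(rng.uniform(2.5, 3.5))

    target = 0.9975
    tr_pairs = [
        PlantedPair(orf_id(22 + (i % 18)), neg_tr_partners[i], -1, target, "middle")
        for i in range(24)
    ]
    tr_pairs.append(PlantedPair(orf_id(52), positive_tr, +1, target, "middle"))

    early_orfs = [orf_id(n) for n in range(57, 71)]  # 14 of the 15 early ORFs
    merged_pairs = [
        PlantedPair(early_orfs[j % len(early_orfs)], merged_partners[j], +1, target, "merged")
        for j in range(110)
    ]

    cfg = SyntheticConfig(
        phage_class_map=class_map,
        deg_plan=deg_plan,
        tr_pair_plan=tr_pairs,
        merged_pair_plan=merged_pairs,
        tr_genes=tr_genes,
        seed=seed,
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# expression generation
# ---------------------------------------------------------------------------

def _bump(t: np.ndarray, peak: float, amplitude: float, hold: bool) -> np.ndarray:
    """Unimodal log-normal-in-time kinetic bump (log2 units); zero at t=0.

    With ``hold`` the profile saturates at its plateau after the peak
    instead of declining (drug-frozen regulatory cascade)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tt = np.minimum(t[pos], peak) if hold else t[pos]
    out[pos] = amplitude * np.exp(-np.log(tt / peak) ** 2 / (2 * BUMP_WIDTH**2))
    return out


def _kinetic_params(cfg: SyntheticConfig, orf: str) -> tuple[float, float, float]:
    """(baseline log2, peak time, amplitude) for a phage ORF; per-seed."""
    rng = _rng(cfg.seed, f"feature::{orf}", 0)
    base = rng.uniform(*BASE_LOG2_RANGE)
    lo, hi = PEAK_RANGES[cfg.phage_class_map[orf]]
    peak = rng.uniform(lo, hi)
    amplitude = rng.uniform(*AMPLITUDE_RANGE)
    return base, peak, amplitude


def _host_baseline(cfg: SyntheticConfig, gene: str) -> float:
    rng = _rng(cfg.seed, f"feature::{gene}", 0)
    return float(rng.uniform(*BASE_LOG2_RANGE))


def generate_expression(
    config: SyntheticConfig, condition: str = "infected"
) -> ExpressionMatrix:
    """Generate a positive-intensity matrix for all phage + host features
    across every (time, replicate) sample of one experimental condition.

    Planted DEG effects and correlation pairs are applied in the plain
    infected condition; under Cm/PAA the host stays at baseline and only
    the drug-permitted phage classes are transcribed.
    """
    config.validate()
    key = condition.lower()
    if key not in CONDITIONS:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of "
            "'infected', 'infected+Cm', 'infected+PAA'"
        )
    cond = CONDITIONS[key]
    cond_code = {"infected": 0, "cm": 1, "paa": 2}[cond]
    windows = StageWindows()

    times = list(config.time_points)
    reps = list(range(1, config.replicates + 1))
    sample_ids = [f"{cond}_t{t:03d}_r{r}" for t in times for r in reps]
    sample_time = np.array([t for t in times for _ in reps], dtype=float)
    samples = pd.DataFrame(
        {
            "time_min": [t for t in times for _ in reps],
            "replicate": [r for _ in times for r in reps],
            "condition": cond,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    phage_ids = config.phage_ids
    host_ids = config.host_ids
    ref = config.reference_feature
    n_samples = len(sample_ids)
    log2_noise_sd = config.noise_sigma * np.log2(np.e)

    rows: dict[str, np.ndarray] = {}
    baselines: dict[str, float] = {}

    allowed = {
        "infected": {"early", "middle", "late"},
        "cm": {"early"},
        "paa": {"early", "middle"},
    }[cond]
    hold = cond != "infected"

    for orf in phage_ids:
        base, peak, amplitude = _kinetic_params(config, orf)
        baselines[orf] = base
        cls = config.phage_class_map[orf]
        nrng = _rng(config.seed, f"feature::{orf}", 1, cond_code)
        signal = np.full(n_samples, base)
        if cls in allowed:
            rep_scale = 1.0
            if config.noise_sigma > 0:  # noise-free mode is fully deterministic
                rep_scale = np.exp(nrng.normal(0.0, KINETIC_REPLICATE_SD, n_samples))
            signal = signal + _bump(sample_time, peak, amplitude, hold) * rep_scale
        noise = nrng.normal(0.0, log2_noise_sd, n_samples)
        rows[orf] = signal + noise

    effect_at: dict[str, dict[int, float]] = {}
    if cond == "infected":
        for t, effects in config.deg_plan.items():
            for g, e in effects.items():
                effect_at.setdefault(g, {})[t] = e

    for gene in host_ids:
        base = _host_baseline(config, gene)
        baselines[gene] = base
        nrng = _rng(config.seed, f"feature::{gene}", 1, cond_code)
        signal = np.full(n_samples, base)
        effects = effect_at.get(gene)
        if effects:
            rep_scale = 1.0
            if config.noise_sigma > 0:
                rep_scale = np.exp(nrng.normal(0.0, EFFECT_REPLICATE_SD, n_samples))
            for t, e in effects.items():
                signal = signal + np.where(sample_time == t, e, 0.0) * rep_scale
        noise = nrng.normal(0.0, log2_noise_sd, n_samples)
        rows[gene] = signal + noise

    rows[ref] = np.full(n_samples, np.log2(REFERENCE_LEVEL))
    baselines[ref] = np.log2(REFERENCE_LEVEL)

    if cond == "infected":
        _plant_pairs(config, rows, baselines, samples, windows)

    values = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
    values = np.power(2.0, values)
    values = values.loc[phage_ids + host_ids + [ref]]
    values.index.name = "feature_id"

    feats = pd.DataFrame(index=pd.Index(values.index, name="feature_id"))
    feats["organism"] = ["phage"] * len(phage_ids) + ["host"] * (len(host_ids) + 1)
    feats["orf_id"] = [o for o in phage_ids] + [""] * (len(host_ids) + 1)
    tr_set = set(config.tr_genes)
    feats["is_tr"] = [False] * len(phage_ids) + [g in tr_set for g in host_ids] + [False]
    feats["is_reference"] = [fid == ref for fid in feats.index]
    feats["class_truth"] = [config.phage_class_map[o] for o in phage_ids] + [""] * (
        len(host_ids) + 1
    )
    return ExpressionMatrix(values, samples, feats)


def _plant_pairs(config, rows, baselines, samples, windows) -> None:
    """Rewrite host-partner rows so each planted pair attains its target
    sample correlation exactly over its stage window."""
    times = list(config.time_points)
    time_arr = samples["time_min"].to_numpy()
    post = [t for t in times if t > 0]
    for pair in list(config.tr_pair_plan) + list(config.merged_pair_plan):
        win_times = set(windows.sample_times(pair.window, post))
        in_win = np.isin(time_arr, list(win_times))
        n = int(in_win.sum())
        if n < 3:
            raise ValueError(f"pair window {pair.window!r} selects fewer than 3 samples")
        if pair.target_abs_cor > 0.99999:
            warnings.warn(
                f"target |cor|={pair.target_abs_cor} for pair "
                f"({pair.phage}, {pair.host}) is numerically extreme",
                stacklevel=2,
            )
        x = rows[pair.phage][in_win]
        xc = x - x.mean()
        norm = np.linalg.norm(xc)
        if norm == 0:
            warnings.warn(
                f"phage profile constant over window; pair ({pair.phage}, "
                f"{pair.host}) not planted",
                stacklevel=2,
            )
            continue
        prng = _rng(config.seed, f"pair::{pair.phage}::{pair.host}", 2)
        g = prng.normal(size=n)
        # orthogonalize against the constant vector and xc
        g = g - g.mean()
        g = g - (g @ xc) / norm**2 * xc
        gnorm = np.linalg.norm(g)
        if gnorm == 0:  # pragma: no cover - measure-zero draw
            g = np.zeros(n)
            gnorm = 1.0
        rho = pair.target_abs_cor
        dev = rho * xc + np.sqrt(1.0 - rho**2) * norm * g / gnorm
        c = baselines[pair.host]
        y = rows[pair.host].copy()
        y[in_win] = c + pair.sign * PAIR_SLOPE * dev
        # outside the pair's stage window (but after infection) the partner
        # follows its own regulation: independent jitter that breaks any
        # pooled-window correlation with the phage profile
        if pair.window != "merged":
            out_win = (time_arr > 0) & ~in_win
            y[out_win] = c + prng.normal(0.0, TR_DECOY_JITTER, int(out_win.sum()))
        rows[pair.host] = y


# ---------------------------------------------------------------------------
# annotations and growth curves
# ---------------------------------------------------------------------------

def generate_annotations(
    config: SyntheticConfig,
    terms_per_gene: int = 1,
    n_terms: int = 27,
    vocabulary: str = "function",
    spike: dict[str, set[str]] | None = None,
):
    """Random gene->term map over the host genes, reproducible from the
    config seed. ``spike`` maps term id -> gene set to force into that
    term (used to plant true enrichment signal). Returns an
    :class:`phx.enrich.AnnotationMap`."""
    from .enrich import AnnotationMap, TermInfo

    if n_terms < 1:
        raise ValueError("need at least one term")
    prefix = "PW" if vocabulary == "pathway" else "F"
    term_ids = [f"{prefix}{i:03d}" for i in range(1, n_terms + 1)]
    rng = _rng(config.seed, f"annotations::{vocabulary}", 3)
    gene_terms: dict[str, set[str]] = {g: set() for g in config.host_ids}
    if terms_per_gene > 0:
        for g in config.host_ids:
            picks = rng.choice(n_terms, size=min(terms_per_gene, n_terms), replace=False)
            gene_terms[g].update(term_ids[int(i)] for i in picks)
    if spike:
        for term, genes in spike.items():
            for g in genes:
                gene_terms.setdefault(g, set()).add(term)
    terms = {t: TermInfo(name=t, vocabulary=vocabulary) for t in term_ids}
    if spike:
        for t in spike:
            terms.setdefault(t, TermInfo(name=t, vocabulary=vocabulary))
    return AnnotationMap(
        gene_terms={g: frozenset(ts) for g, ts in gene_terms.items() if ts},
        terms=terms,
    )


def generate_growth_curve(
    burst_size: float,
    latent_min: float,
    rise_min: float,
    infected_cells: float,
    step_min: float = 5.0,
    tail_min: float = 20.0,
) -> GrowthCurve:
    """One-step growth curve: titer flat at ``infected_cells`` through the
    latent period, smooth sigmoidal rise to ``infected_cells * (1 +
    burst_size)`` by ``rise_min``, flat afterwards (so the plateau rise
    divided by the infected-cell count recovers the burst size)."""
    if burst_size < 0:
        raise ValueError("burst size must be non-negative")
    if rise_min <= latent_min:
        raise ValueError("rise_min must exceed latent_min")
    times = np.arange(0.0, rise_min + tail_min + 0.5 * step_min, step_min)
    u = np.clip((times - latent_min) / (rise_min - latent_min), 0.0, 1.0)
    smooth = u * u * (3.0 - 2.0 * u)  # exact plateaus at both ends
    titers = infected_cells * (1.0 + burst_size * smooth)
    return GrowthCurve(times=times, titers=titers, infected_cells=infected_cells)


# ---------------------------------------------------------------------------
# dataset export
# ---------------------------------------------------------------------------

def write_dataset(matrix: ExpressionMatrix, outdir) -> dict[str, str]:
    """Write matrix + sample sheet + feature sheet as TSV; returns paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "matrix": os.path.join(outdir, "expression.tsv"),
        "samples": os.path.join(outdir, "samples.tsv"),
        "features": os.path.join(outdir, "features.tsv"),
    }
    matrix.values.to_csv(paths["matrix"], sep="\t")
    matrix.samples.to_csv(paths["samples"], sep="\t")
    matrix.features.to_csv(paths["features"], sep="\t")
    return paths
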