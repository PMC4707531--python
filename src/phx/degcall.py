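"""Host differential-expression calling and aggregation.

Per post-infection time point, each host gene is tested by one-way
ANOVA on normalized replicate intensities (infected at t vs the
uninfected 0-min reference; with two groups this reduces to the
equal-variance t-test), p-values are Benjamini-Hochberg adjusted across
all host genes at that time point, and a gene is called a DEG iff its
fold change exceeds the threshold in either direction AND q < 0.05.
Per-timepoint calls are then aggregated into unique up/down sets,
intersection structure over time points, and per-gene infection-stage
labels.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .stages import StageWindows

logger = logging.getLogger(__name__)

DEG_COLUMNS = ("gene", "time_min", "log2fc", "p", "q", "direction")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Sort ascending, q_(i) = min_{j>=i}( p_(j) * m / j ), capped at 1,
    returned in the input order. Empty input yields empty output.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = q_sorted
    return out


def _anova_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise one-way ANOVA p for two replicate groups.

    Rows with zero within-group variance get p = 1 when the group means
    are equal and p = 0 otherwise.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.f_oneway(a, b, axis=1)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        p = p.copy()
        equal = np.isclose(mean_a, mean_b)
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
    return p


def call_degs_at_timepoint(
    m: ExpressionMatrix,
    t: int,
    fc_threshold: float = 2.0,
    q_threshold: float = 0.05,
    use_raw_p: bool = False,
    reference_time: int = 0,
) -> pd.DataFrame:
    """DEG records for host genes at one post-infection time point.

    ``m`` should be reference-normalized. The BH family is all host
    genes at this time point (the housekeeping reference feature is
    excluded). Fold-change and significance thresholds are both strict.
    """
    genes = [g for g in m.host_ids if g not in set(m.reference_ids)]
    cols_t = m.sample_ids(times=t)
    cols_0 = m.sample_ids(times=reference_time)
    if len(cols_t) < 2 or len(cols_0) < 2:
        raise ValueError("need at least two replicates at t and at the reference")
    a = m.values.loc[genes, cols_t].to_numpy(dtype=float)
    b = m.values.loc[genes, cols_0].to_numpy(dtype=float)
    p = _anova_p(a, b)
    q = bh_adjust(p)
    log2fc = np.log2(a.mean(axis=1) / b.mean(axis=1))
    crit = p if use_raw_p else q
    called = (np.abs(log2fc) > np.log2(fc_threshold)) & (crit < q_threshold)
    df = pd.DataFrame(
        {
            "gene": np.asarray(genes)[called],
            "time_min": t,
            "log2fc": log2fc[called],
            "p": p[called],
            "q": q[called],
        }
    )
    df["direction"] = np.where(df["log2fc"] > 0, "up", "down")
    return df.sort_values(["q", "gene"], kind="mergesort").reset_index(drop=True)


def call_degs(
    m: ExpressionMatrix,
    times=None,
    fc_threshold: float = 2.0,
    q_threshold: float = 0.05,
    use_raw_p: bool = False,
) -> pd.DataFrame:
    """DEG records over all post-infection time points (long format)."""
    if times is None:
        times = [t for t in m.times if t > 0]
    frames = [
        call_degs_at_timepoint(m, t, fc_threshold, q_threshold, use_raw_p)
        for t in times
    ]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=list(DEG_COLUMNS)
    )


@dataclass
class DEGSummary:
    """Aggregated view of DEG calls across the infection time course."""

    per_time: dict[int, dict[str, frozenset]]           # t -> {'up': set, 'down': set}
    unique_up: frozenset
    unique_down: frozenset
    unique_all: frozenset
    intersection_counts: dict[tuple[int, ...], int]     # exact time-membership pattern
    stage_labels: dict[str, str]                        # gene -> stage of earliest call
    conflicted: frozenset                               # genes both up and down

    @property
    def per_time_counts(self) -> pd.DataFrame:
        rows = {
            t: {"down": len(d["down"]), "up": len(d["up"])}
            for t, d in sorted(self.per_time.items())
        }
        return pd.DataFrame.from_dict(rows, orient="index")

    @property
    def per_time_total(self) -> int:
        """Sum of per-timepoint counts (genes counted once per affected time)."""
        return int(self.per_time_counts.to_numpy().sum())

    def to_dict(self) -> dict:
        return {
            "unique_total": len(self.unique_all),
            "unique_down": len(self.unique_down),
            "unique_up": len(self.unique_up),
            "per_time_total": self.per_time_total,
            "per_time": {
                str(t): {k: len(v) for k, v in d.items()}
                for t, d in sorted(self.per_time.items())
            },
            "intersections": {
                "+".join(str(t) for t in key): n
                for key, n in sorted(self.intersection_counts.items())
            },
            "conflicted": sorted(self.conflicted),
        }


def aggregate_degs(
    records: pd.DataFrame, windows: StageWindows = StageWindows()
) -> DEGSummary:
    """Aggregate long-format DEG records into a :class:`DEGSummary`.

    Unique unions never double-count a gene affected at several time
    points, so the per-timepoint counts sum to at least the union size.
    A gene called up at one time and down at another stays in both
    direction sets but is flagged (the underlying biology makes this
    rare; the study observed none).
    """
    if len(records) == 0:
        return DEGSummary({}, frozenset(), frozenset(), frozenset(), {}, {}, frozenset())
    per_time: dict[int, dict[str, set]] = {}
    for t, sub in records.groupby("time_min"):
        up = set(sub.loc[sub["direction"] == "up", "gene"])
        down = set(sub.loc[sub["direction"] == "down", "gene"])
        overlap = up & down
        if overlap:
            raise ValueError(
                f"gene(s) both up and down at {t} min: {sorted(overlap)[:5]}"
            )
        per_time[int(t)] = {"up": up, "down": down}
    unique_up = frozenset().union(*(d["up"] for d in per_time.values()))
    unique_down = frozenset().union(*(d["down"] for d in per_time.values()))
    conflicted = frozenset(unique_up & unique_down)
    if conflicted:
        logger.warning(
            "%d gene(s) up-regulated at one time point and down-regulated "
            "at another: %s",
            len(conflicted),
            sorted(conflicted)[:5],
        )
    membership: dict[str, list[int]] = {}
    for t in sorted(per_time):
        for g in per_time[t]["up"] | per_time[t]["down"]:
            membership.setdefault(g, []).append(t)
    intersection_counts: dict[tuple[int, ...], int] = {}
    for g, ts in membership.items():
        key = tuple(ts)
        intersection_counts[key] = intersection_counts.get(key, 0) + 1
    stage_labels = {
        g: windows.class_of_time(ts[0]) for g, ts in membership.items()
    }
    return DEGSummary(
        per_time={t: {k: frozenset(v) for k, v in d.items()} for t, d in per_time.items()},
        unique_up=unique_up,
        unique_down=unique_down,
        unique_all=frozenset(unique_up | unique_down),
        intersection_counts=intersection_counts,
        stage_labels=stage_labels,
        conflicted=conflicted,
    )
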