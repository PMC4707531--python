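"""Reading, validation and preprocessing of expression tables.

Covers the standard preprocessing chain of a dual-organism microarray
time course: read the TSV exchange format, floor non-positive
intensities, normalize every sample against the housekeeping reference
feature (16S rRNA), summarize phage probes to ORFs by the per-sample
median, and compute log2 fold changes of each post-infection time point
against the uninfected 0-min reference. Also computes the burst size
from a one-step growth curve.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, FoldChangeMatrix, GrowthCurve, SAMPLE_COLUMNS

logger = logging.getLogger(__name__)


def read_expression(
    matrix_path,
    sample_sheet_path,
    feature_sheet_path,
    floor_epsilon: float | None = None,
) -> ExpressionMatrix:
    """Read and validate the TSV exchange format.

    Non-positive intensities are floored to ``floor_epsilon`` (default:
    the smallest positive value in the matrix), with the number of
    floored cells logged.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    samples = pd.read_csv(sample_sheet_path, sep="\t", index_col=0)
    features = pd.read_csv(feature_sheet_path, sep="\t", index_col=0)
    missing = set(SAMPLE_COLUMNS) - set(samples.columns)
    if missing:
        raise ValueError(f"sample sheet missing required column(s): {sorted(missing)}")
    for col in ("is_tr", "is_reference"):
        if col in features.columns:
            features[col] = features[col].astype(bool)
    if "orf_id" in features.columns:
        features["orf_id"] = features["orf_id"].fillna("")
    if "class_truth" in features.columns:
        features["class_truth"] = features["class_truth"].fillna("")

    arr = values.to_numpy(dtype=float)
    nonpos = arr <= 0
    if nonpos.any():
        if floor_epsilon is None:
            positive = arr[arr > 0]
            if positive.size == 0:
                raise ValueError("matrix has no positive intensities")
            floor_epsilon = float(positive.min())
        logger.warning(
            "floored %d non-positive intensity cell(s) to %g",
            int(nonpos.sum()),
            floor_epsilon,
        )
        arr = np.where(nonpos, floor_epsilon, arr)
        values = pd.DataFrame(arr, index=values.index, columns=values.columns)
    return ExpressionMatrix(values, samples, features)


def normalize_to_reference(
    m: ExpressionMatrix, reference_feature: str
) -> ExpressionMatrix:
    """Divide each sample by its intensity of the housekeeping reference.

    After normalization the reference row is exactly 1 in every sample.
    Phage and host features share the single per-sample divisor.
    """
    if reference_feature not in m.values.index:
        raise ValueError(f"reference feature {reference_feature!r} absent from matrix")
    ref = m.values.loc[reference_feature]
    if (ref <= 0).any():
        bad = list(ref.index[ref <= 0])
        raise ValueError(
            f"reference feature non-positive in sample(s): {bad[:5]}"
        )
    values = m.values.div(ref, axis=1)
    return ExpressionMatrix(values, m.samples.copy(), m.features.copy())


def summarize_probes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse phage probes to one row per ORF (per-sample median).

    Host rows pass through unchanged. Phage features must carry a
    non-empty ``orf_id`` probe->ORF link.
    """
    if "orf_id" not in m.features.columns:
        raise ValueError("feature sheet lacks the probe->ORF link column 'orf_id'")
    phage = m.features["organism"] == "phage"
    links = m.features.loc[phage, "orf_id"].astype(str)
    if (links == "").any():
        missing = list(links.index[links == ""])
        raise ValueError(f"phage probe(s) without ORF link: {missing[:5]}")

    med = m.values.loc[phage.index[phage]].groupby(links).median()
    orf_order = list(dict.fromkeys(links))  # first-appearance genome order
    med = med.loc[orf_order]
    host_rows = m.values.loc[~phage]
    values = pd.concat([med, host_rows])
    values.index.name = m.values.index.name

    phage_feats = pd.DataFrame(
        {
            "organism": "phage",
            "orf_id": orf_order,
        },
        index=pd.Index(orf_order, name=m.features.index.name),
    )
    for col in ("is_tr", "is_reference"):
        if col in m.features.columns:
            phage_feats[col] = False
    if "class_truth" in m.features.columns:
        truth = m.features.loc[phage].groupby(links)["class_truth"].first()
        phage_feats["class_truth"] = truth.loc[orf_order].values
    host_feats = m.features.loc[~phage]
    features = pd.concat([phage_feats, host_feats])
    features = features.loc[values.index]
    return ExpressionMatrix(values, m.samples.copy(), features)


def log_fold_change(
    m: ExpressionMatrix, reference_time: int = 0
) -> FoldChangeMatrix:
    """log2 of per-timepoint replicate means against the reference time.

    The matrix must hold a single condition; replicate intensities are
    averaged arithmetically before the ratio is taken.
    """
    conditions = m.samples["condition"].unique()
    if len(conditions) > 1:
        raise ValueError("fold change requires a single-condition matrix")
    times = m.times
    if reference_time not in times:
        raise ValueError(f"reference time {reference_time} not present")
    means = {}
    for t in times:
        cols = m.sample_ids(times=t)
        if len(cols) == 0:
            raise ValueError(f"no replicates at time {t}")
        means[t] = m.values[cols].mean(axis=1)
    ref = means[reference_time]
    if (ref <= 0).any():
        raise ValueError("non-positive reference means; floor intensities first")
    fc = pd.DataFrame(
        {t: np.log2(means[t] / ref) for t in times if t != reference_time}
    )
    fc.columns = fc.columns.astype(int)
    return FoldChangeMatrix(fc, m.features.copy(), reference_time=reference_time)


def _plateau_len(titers: np.ndarray, tol: float = 0.10) -> int:
    """Length of the maximal prefix whose titers vary <= tol from their mean."""
    best = 1
    for k in range(1, len(titers) + 1):
        seg = titers[:k]
        mean = seg.mean()
        if mean == 0:
            ok = np.all(seg == 0)
        else:
            ok = np.max(np.abs(seg - mean)) <= tol * abs(mean)
        if ok:
            best = k
    return best


def compute_burst_size(g: GrowthCurve, tol: float = 0.10) -> float:
    """Burst size from a one-step growth curve.

    (mean titer over the terminal plateau - mean titer over the initial
    latent plateau) / infected cells, with each plateau detected as the
    maximal prefix/suffix whose titers vary at most ``tol`` (fractional)
    from their mean. A curve whose single plateau spans all points has
    burst size 0 (warned).
    """
    if len(g.times) < 2:
        raise ValueError("growth curve needs at least two time points")
    if g.infected_cells <= 0:
        raise ValueError("infected cell count must be positive")
    titers = np.asarray(g.titers, dtype=float)
    head = _plateau_len(titers, tol)
    tail = _plateau_len(titers[::-1], tol)
    if head >= len(titers) or tail >= len(titers):
        warnings.warn("degenerate growth curve: no rise detected; burst size 0")
        return 0.0
    latent_mean = titers[:head].mean()
    final_mean = titers[-tail:].mean()
    return float((final_mean - latent_mean) / g.infected_cells)
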