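"""Core in-memory containers shared by every analysis stage.

The universal input is an :class:`ExpressionMatrix`: a features x samples
table of positive microarray-style intensities carrying two companion
sheets, one describing samples (time post-infection in minutes, biological
replicate, drug condition) and one describing features (organism tag,
probe->ORF link for phage probes, transcriptional-regulator flag for host
genes).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ORGANISMS = ("phage", "host")
SAMPLE_COLUMNS = ("time_min", "replicate", "condition")


@dataclass
class ExpressionMatrix:
    """Features x samples intensity matrix with sample and feature metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample id;
        entries are positive intensities.
    samples
        DataFrame indexed by sample id with columns ``time_min`` (int),
        ``replicate`` (int) and ``condition`` (str).
    features
        DataFrame indexed by feature id with at least an ``organism``
        column (``phage`` or ``host``). Optional columns: ``orf_id``
        (probe->ORF link for phage probes), ``is_tr`` (host
        transcriptional regulator flag), ``is_reference`` (housekeeping
        reference feature), ``class_truth`` (planted temporal class in
        synthetic data).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    features: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = set(SAMPLE_COLUMNS) - set(self.samples.columns)
        if missing:
            raise ValueError(
                f"sample sheet missing required column(s): {sorted(missing)}"
            )
        if self.samples[list(SAMPLE_COLUMNS)].isna().any().any():
            bad = [
                c for c in SAMPLE_COLUMNS if self.samples[c].isna().any()
            ]
            raise ValueError(f"sample sheet has missing metadata in: {bad}")
        if "organism" not in self.features.columns:
            raise ValueError("feature sheet missing required column: organism")
        unknown = set(self.features["organism"].unique()) - set(ORGANISMS)
        if unknown:
            raise ValueError(f"unknown organism tag(s): {sorted(unknown)}")
        if not self.values.index.is_unique:
            raise ValueError("duplicate feature ids in matrix")
        if not self.values.columns.is_unique:
            raise ValueError("duplicate sample ids in matrix")
        if set(self.values.columns) != set(self.samples.index):
            raise ValueError("matrix columns do not match the sample sheet")
        if set(self.values.index) != set(self.features.index):
            raise ValueError("matrix rows do not match the feature sheet")
        # align metadata to matrix order
        self.samples = self.samples.loc[self.values.columns]
        self.features = self.features.loc[self.values.index]

    # -- convenience accessors -------------------------------------------------
    @property
    def times(self) -> list[int]:
        return sorted(int(t) for t in self.samples["time_min"].unique())

    @property
    def phage_ids(self) -> list[str]:
        return list(self.features.index[self.features["organism"] == "phage"])

    @property
    def host_ids(self) -> list[str]:
        return list(self.features.index[self.features["organism"] == "host"])

    @property
    def reference_ids(self) -> list[str]:
        if "is_reference" not in self.features.columns:
            return []
        flag = self.features["is_reference"].fillna(False).astype(bool)
        return list(self.features.index[flag])

    @property
    def tr_ids(self) -> list[str]:
        if "is_tr" not in self.features.columns:
            return []
        flag = self.features["is_tr"].fillna(False).astype(bool)
        return list(self.features.index[flag & (self.features["organism"] == "host")])

    def sample_ids(self, times=None, condition: str | None = None) -> list[str]:
        """Sample ids at the given time point(s), in sheet order."""
        mask = pd.Series(True, index=self.samples.index)
        if times is not None:
            if np.isscalar(times):
                times = [times]
            mask &= self.samples["time_min"].isin(list(times))
        if condition is not None:
            mask &= self.samples["condition"] == condition
        return list(self.samples.index[mask])

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), self.samples.copy(), self.features.copy()
        )


@dataclass
class FoldChangeMatrix:
    """Per-feature log2 ratios of each post-infection time point to 0 min.

    ``values`` is indexed by feature id with one integer column per
    post-infection time point; the reference time never appears as a
    column. Entries are log2(mean over replicates at t / mean at 0 min).
    """

    values: pd.DataFrame
    features: pd.DataFrame
    reference_time: int = 0

    def __post_init__(self) -> None:
        if self.reference_time in set(self.values.columns):
            raise ValueError("reference time must not appear as a column")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("fold-change matrix contains non-finite values")

    @property
    def times(self) -> list[int]:
        return sorted(int(t) for t in self.values.columns)

    def row(self, feature_id: str) -> pd.Series:
        return self.values.loc[feature_id]


@dataclass
class GrowthCurve:
    """One-step growth curve: phage titer (PFU/ml) over time after infection."""

    times: np.ndarray
    titers: np.ndarray
    infected_cells: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.titers = np.asarray(self.titers, dtype=float)
        if self.times.shape != self.titers.shape:
            raise ValueError("times and titers must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.titers < 0):
            raise ValueError("titers must be non-negative")
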