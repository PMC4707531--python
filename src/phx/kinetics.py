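"""Temporal kinetic classing of phage ORFs.

A phage transcript is classed early/middle/late by the stage window that
contains its expression peak over the infection time course; profiles
are also clustered hierarchically (correlation distance, average
linkage) and the classing is cross-validated against the drug decision
table: chloramphenicol (Cm) blocks protein synthesis so only early genes
are transcribed, phosphonoacetic acid (PAA) blocks the phage DNA
polymerase so late genes are not.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix, FoldChangeMatrix
from .stages import StageWindows

logger = logging.getLogger(__name__)

UNCLASSIFIABLE = "unclassifiable"


@dataclass
class TemporalClassMap:
    """Per-ORF temporal class, peak time and z-scored profile."""

    table: pd.DataFrame          # index orf_id; columns: peak_time, class
    profiles: pd.DataFrame       # z-scored (per ORF) log2 fold changes

    @property
    def classes(self) -> pd.Series:
        return self.table["class"]

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in ("early", "middle", "late", UNCLASSIFIABLE)}
        out.update(self.classes.value_counts().to_dict())
        return out


def assign_peak_class(
    profile: pd.Series, windows: StageWindows = StageWindows()
) -> tuple[str, int | None]:
    """Class of the stage window containing the profile's peak time.

    ``profile`` is indexed by post-infection time (minutes). Ties are
    broken toward the earlier time point; an all-equal profile is
    unclassifiable. Invariant to any strictly increasing transform of
    the values.
    """
    times = sorted(int(t) for t in profile.index)
    vals = profile.loc[times].to_numpy(dtype=float)
    if np.all(vals == vals[0]):
        return UNCLASSIFIABLE, None
    peak_time = times[int(np.argmax(vals))]  # argmax takes the first maximum
    return windows.class_of_time(peak_time), peak_time


def classify_profiles(
    fc: FoldChangeMatrix, windows: StageWindows = StageWindows()
) -> TemporalClassMap:
    """Peak-class every phage ORF in a fold-change matrix."""
    phage = fc.features["organism"] == "phage"
    sub = fc.values.loc[phage.index[phage]]
    records = {}
    for orf, row in sub.iterrows():
        cls, peak = assign_peak_class(row, windows)
        records[orf] = {"peak_time": peak, "class": cls}
    table = pd.DataFrame.from_dict(records, orient="index")
    table.index.name = "orf_id"
    profiles = _zscore_rows(sub)
    return TemporalClassMap(table=table, profiles=profiles)


def _zscore_rows(df: pd.DataFrame) -> pd.DataFrame:
    arr = df.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return pd.DataFrame((arr - mean) / sd, index=df.index, columns=df.columns)


@dataclass
class ClusterResult:
    labels: pd.Series            # cluster id per ORF
    class_labels: pd.Series      # majority peak class of each ORF's cluster
    leaf_order: list[str]        # dendrogram order
    linkage: np.ndarray


def cluster_profiles(
    fc: FoldChangeMatrix,
    k: int = 3,
    windows: StageWindows = StageWindows(),
) -> ClusterResult:
    """Agglomerative clustering of z-scored phage profiles.

    Correlation distance (1 - Pearson), average linkage, cut at ``k``
    clusters; each cluster is labeled by the majority peak class of its
    members.
    """
    cmap = classify_profiles(fc, windows)
    Z = cmap.profiles
    n = len(Z)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    corr = np.corrcoef(Z.to_numpy(dtype=float))
    corr = np.nan_to_num(corr, nan=0.0)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    labels = pd.Series(
        hierarchy.fcluster(link, t=k, criterion="maxclust"), index=Z.index
    )
    leaf_order = [Z.index[i] for i in hierarchy.leaves_list(link)]
    class_labels = pd.Series(index=Z.index, dtype=object)
    for cid in labels.unique():
        members = labels.index[labels == cid]
        majority = cmap.classes.loc[members].mode()
        class_labels.loc[members] = majority.iloc[0] if len(majority) else UNCLASSIFIABLE
    return ClusterResult(labels, class_labels, leaf_order, link)


def _expression_ratio(m: ExpressionMatrix, t: int, baseline_time: int = 0) -> pd.Series:
    """Per-phage-ORF ratio of mean intensity at t to the 0-min mean."""
    phage = m.phage_ids
    at_t = m.values.loc[phage, m.sample_ids(times=t)].mean(axis=1)
    at_0 = m.values.loc[phage, m.sample_ids(times=baseline_time)].mean(axis=1)
    return at_t / at_0


def classify_by_drug_response(
    control: ExpressionMatrix,
    cm: ExpressionMatrix,
    paa: ExpressionMatrix,
    fc_threshold: float = 2.0,
    cm_time: int = 30,
    paa_time: int = 80,
) -> pd.Series:
    """Temporal class from the Cm/PAA decision table.

    An ORF counts as expressed under a condition when its mean intensity
    at the assay time is at least ``fc_threshold`` times its own 0-min
    baseline in that condition. Expressed under Cm -> early; silent
    under Cm but expressed under PAA -> middle; silent under both ->
    late. ORFs silent under both drugs *and* in the untreated control
    are flagged unclassifiable.
    """
    orfs = set(control.phage_ids)
    if orfs != set(cm.phage_ids) or orfs != set(paa.phage_ids):
        raise ValueError("the three matrices must share the same phage ORFs")
    r_cm = _expression_ratio(cm, cm_time)
    r_paa = _expression_ratio(paa, paa_time)
    post = [t for t in control.times if t > 0]
    r_ctrl = pd.concat(
        [_expression_ratio(control, t) for t in post], axis=1
    ).max(axis=1)
    out = {}
    for orf in control.phage_ids:
        if r_cm[orf] >= fc_threshold:
            out[orf] = "early"
        elif r_paa[orf] >= fc_threshold:
            out[orf] = "middle"
        elif r_ctrl[orf] >= fc_threshold:
            out[orf] = "late"
        else:
            out[orf] = UNCLASSIFIABLE
            logger.warning("ORF %s expressed under neither drug nor control", orf)
    return pd.Series(out, name="drug_class")


@dataclass
class ReconcileReport:
    table: pd.DataFrame          # orf_id, peak class, drug class, agree
    concordance: float

    @property
    def disagreements(self) -> pd.DataFrame:
        return self.table[~self.table["agree"]]


def reconcile(classes_peak: TemporalClassMap, classes_drug: pd.Series) -> ReconcileReport:
    """Per-ORF agreement between peak-based and drug-based classing.

    The peak-based class is retained as primary; the overall concordance
    is the fraction of ORFs on which the two paths agree.
    """
    peak = classes_peak.classes
    if set(peak.index) != set(classes_drug.index):
        raise ValueError("class maps cover different ORF universes")
    drug = classes_drug.loc[peak.index]
    table = pd.DataFrame(
        {
            "peak_class": peak,
            "drug_class": drug,
            "agree": peak == drug,
        }
    )
    table.index.name = "orf_id"
    concordance = float(table["agree"].mean()) if len(table) else float("nan")
    return ReconcileReport(table=table, concordance=concordance)
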