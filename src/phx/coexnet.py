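"""Cross-genome co-expression screening and network construction.

Every phage x host gene pair is scored by the Pearson correlation of
log2 normalized intensities over the replicate-level samples of a stage
window; an edge survives only under the hard double threshold p < 0.01
and |cor| > 0.99 (raw p from the t-transform with n-2 degrees of
freedom). Surviving positive edges form bipartite stage networks in
which each node's K-score is its degree (link count); a merged network
screens over all five post-infection time points jointly. A dedicated
screen restricts the host side to transcriptional regulators (TRs) and
reports negative and positive pair lists separately.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .stages import StageWindows

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ("phage", "host", "cor", "p", "sign", "stage", "n")

DEFAULT_COR_MIN = 0.99
DEFAULT_ALPHA = 0.01


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r with the two-sided t-transform p-value.

    t = r * sqrt(n-2) / sqrt(1-r^2) with n-2 degrees of freedom;
    |r| = 1 gives p = 0. Constant vectors are undefined (ValueError).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
    if 1.0 - abs(r) < 1e-12:  # numerically collinear: p = 0 by contract
        return float(np.sign(r)), 0.0
    p = _t_transform_p(np.array([r]), n)[0]
    return r, float(p)


def _t_transform_p(r: np.ndarray, n: int) -> np.ndarray:
    """Vectorized two-sided p for Pearson r at sample size n."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return np.minimum(p, 1.0)


def _window_columns(
    m: ExpressionMatrix, times, level: str
) -> tuple[pd.DataFrame, int]:
    """Log2 values over the window's samples (replicate-level or
    per-timepoint means)."""
    times = sorted(set(int(t) for t in times))
    cols = m.sample_ids(times=times)
    if level == "replicate":
        X = np.log2(m.values[cols])
    elif level == "mean":
        X = pd.concat(
            {t: np.log2(m.values[m.sample_ids(times=t)]).mean(axis=1) for t in times},
            axis=1,
        )
    else:
        raise ValueError(f"unknown sample level: {level!r}")
    return X, X.shape[1]


def screen_pairs(
    m: ExpressionMatrix,
    times,
    phage_ids=None,
    host_ids=None,
    cor_min: float = DEFAULT_COR_MIN,
    alpha: float = DEFAULT_ALPHA,
    level: str = "replicate",
    stage: str = "merged",
) -> pd.DataFrame:
    """All phage x host Pearson correlations over a sample window,
    hard-thresholded to p < alpha AND |cor| > cor_min, signed.

    ``level`` selects the correlation sample unit: 'replicate' uses
    every replicate-level sample in the window (default), 'mean' uses
    per-timepoint replicate means.
    """
    if phage_ids is None:
        phage_ids = m.phage_ids
    if host_ids is None:
        host_ids = [h for h in m.host_ids if h not in set(m.reference_ids)]
    X, n = _window_columns(m, times, level)
    if n < 3:
        raise ValueError(
            f"correlation window selects {n} sample(s); at least 3 required"
        )
    P = X.loc[phage_ids].to_numpy(dtype=float)
    H = X.loc[host_ids].to_numpy(dtype=float)

    def _standardize(A, ids):
        mean = A.mean(axis=1, keepdims=True)
        sd = A.std(axis=1, keepdims=True)
        constant = (sd == 0).ravel()
        if constant.any():
            dropped = [ids[i] for i in np.flatnonzero(constant)]
            logger.info(
                "skipped %d constant feature(s) in correlation screen: %s",
                len(dropped), dropped[:5],
            )
        keep = ~constant
        Z = (A[keep] - mean[keep]) / sd[keep]
        return Z, [ids[i] for i in np.flatnonzero(keep)]

    Zp, kept_p = _standardize(P, list(phage_ids))
    Zh, kept_h = _standardize(H, list(host_ids))
    if not kept_p or not kept_h:
        return pd.DataFrame(columns=list(EDGE_COLUMNS))
    R = np.clip(Zp @ Zh.T / n, -1.0, 1.0)
    pmat = _t_transform_p(R, n)
    mask = (pmat < alpha) & (np.abs(R) > cor_min)
    pi, hi = np.nonzero(mask)
    df = pd.DataFrame(
        {
            "phage": [kept_p[i] for i in pi],
            "host": [kept_h[j] for j in hi],
            "cor": R[pi, hi],
            "p": pmat[pi, hi],
        }
    )
    df["sign"] = np.where(df["cor"] > 0, "+", "-")
    df["stage"] = stage
    df["n"] = n
    return df.sort_values(["phage", "host"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def build_network(
    edges: pd.DataFrame,
    positive_only: bool = True,
    class_map: dict[str, str] | None = None,
) -> nx.Graph:
    """Bipartite phage-host graph from a screened edge table.

    Only positive-sign edges enter by default (negative correlations
    indicate inhibition, not shared function); isolated nodes are
    excluded; every node carries ``organism``, ``k_score`` (= degree)
    and, when a class map is given, ``temporal_class``.
    """
    G = nx.Graph()
    sub = edges[edges["sign"] == "+"] if positive_only else edges
    for row in sub.itertuples(index=False):
        G.add_node(row.phage, organism="phage")
        G.add_node(row.host, organism="host")
        G.add_edge(row.phage, row.host, cor=float(row.cor), p=float(row.p))
    for node in G.nodes:
        G.nodes[node]["k_score"] = G.degree[node]
        if class_map and node in class_map:
            G.nodes[node]["temporal_class"] = class_map[node]
    return G


def k_scores(G: nx.Graph) -> dict[str, int]:
    return {node: int(G.degree[node]) for node in G.nodes}


def stage_network(
    edges: pd.DataFrame,
    stage: str,
    class_map: dict[str, str] | None = None,
) -> nx.Graph:
    """Positive-edge network for one infection stage."""
    sub = edges[edges["stage"] == stage]
    return build_network(sub, positive_only=True, class_map=class_map)


@dataclass
class TRScreenResult:
    """Signed phage-TR pair lists from the middle-stage screen."""

    negative: pd.DataFrame
    positive: pd.DataFrame

    @property
    def n_negative(self) -> int:
        return len(self.negative)

    @property
    def n_positive(self) -> int:
        return len(self.positive)


def tr_screen(
    m: ExpressionMatrix,
    tr_genes=None,
    times=None,
    cor_min: float = DEFAULT_COR_MIN,
    alpha: float = DEFAULT_ALPHA,
    level: str = "replicate",
    windows: StageWindows = StageWindows(),
) -> TRScreenResult:
    """Phage x transcriptional-regulator screen over the middle stage.

    ``tr_genes`` defaults to the feature sheet's ``is_tr`` flags; the
    window defaults to the middle-stage sample times (10-30 min).
    """
    if tr_genes is None:
        tr_genes = m.tr_ids
    tr_genes = [g for g in tr_genes]
    if not tr_genes:
        raise ValueError("empty transcriptional-regulator list")
    if times is None:
        times = windows.sample_times("middle", m.times)
    edges = screen_pairs(
        m, times, host_ids=tr_genes, cor_min=cor_min, alpha=alpha,
        level=level, stage="middle",
    )
    return TRScreenResult(
        negative=edges[edges["sign"] == "-"].reset_index(drop=True),
        positive=edges[edges["sign"] == "+"].reset_index(drop=True),
    )


@dataclass
class MergedNetworkResult:
    network: nx.Graph
    edges: pd.DataFrame
    function_targets: pd.DataFrame       # ORF x term target-gene counts
    phage_classes: list[str]             # temporal classes present among phage nodes

    @property
    def host_nodes(self) -> list[str]:
        return sorted(
            n for n, d in self.network.nodes(data=True) if d["organism"] == "host"
        )

    @property
    def phage_nodes(self) -> list[str]:
        return sorted(
            n for n, d in self.network.nodes(data=True) if d["organism"] == "phage"
        )


def merged_network(
    m: ExpressionMatrix,
    annotation_map=None,
    class_map: dict[str, str] | None = None,
    expected_times=(5, 10, 20, 30, 80),
    cor_min: float = DEFAULT_COR_MIN,
    alpha: float = DEFAULT_ALPHA,
    level: str = "replicate",
) -> MergedNetworkResult:
    """Single screen over the replicate-level samples of all five
    post-infection time points; positive edges only.

    Also tabulates, per phage ORF, the number of its host targets in
    each annotation term (the ribbon-plot input) and reports which
    temporal classes appear among the phage nodes.
    """
    present = set(m.times)
    missing = [t for t in expected_times if t not in present]
    if missing:
        raise ValueError(f"missing required time point(s): {missing}")
    edges = screen_pairs(
        m, list(expected_times), cor_min=cor_min, alpha=alpha, level=level,
        stage="merged",
    )
    if class_map is None and "class_truth" in m.features.columns:
        phage = m.features["organism"] == "phage"
        class_map = {
            fid: c
            for fid, c in m.features.loc[phage, "class_truth"].items()
            if c
        }
    net = build_network(edges, positive_only=True, class_map=class_map)
    classes = sorted(
        {
            d.get("temporal_class")
            for n, d in net.nodes(data=True)
            if d["organism"] == "phage" and d.get("temporal_class")
        }
    )
    rows = {}
    if annotation_map is not None:
        for node, d in net.nodes(data=True):
            if d["organism"] != "phage":
                continue
            counts: dict[str, int] = {}
            for host in net.neighbors(node):
                for term in annotation_map.gene_terms.get(host, ()):
                    counts[term] = counts.get(term, 0) + 1
            rows[node] = counts
    function_targets = (
        pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
        if rows
        else pd.DataFrame()
    )
    function_targets = function_targets.sort_index()
    return MergedNetworkResult(net, edges, function_targets, classes)


# ---------------------------------------------------------------------------
# genome-adjacency report
# ---------------------------------------------------------------------------

def _orf_number(orf: str) -> int:
    digits = "".join(ch for ch in orf if ch.isdigit())
    if not digits:
        raise ValueError(f"ORF id carries no genome order: {orf!r}")
    return int(digits)


@dataclass
class AdjacencyReport:
    table: pd.DataFrame          # one row per connected component
    contiguity_fraction: float


def adjacency_cluster_report(
    G: nx.Graph, orf_number=_orf_number
) -> AdjacencyReport:
    """Whether the phage genes of each connected sub-network are
    contiguous along the genome.

    A component's phage members are contiguous when their genome-order
    numbers form a consecutive run; single-ORF components are contiguous
    by convention. The overall contiguity fraction is over components
    containing at least one phage gene.
    """
    rows = []
    for comp in nx.connected_components(G):
        orfs = sorted(
            (n for n in comp if G.nodes[n].get("organism") == "phage"),
            key=orf_number,
        )
        if not orfs:
            continue
        numbers = [orf_number(o) for o in orfs]
        contiguous = numbers == list(range(numbers[0], numbers[0] + len(numbers)))
        rows.append(
            {
                "orfs": ",".join(orfs),
                "n_phage": len(orfs),
                "n_host": len(comp) - len(orfs),
                "contiguous": contiguous,
            }
        )
    table = pd.DataFrame(rows, columns=["orfs", "n_phage", "n_host", "contiguous"])
    frac = float(table["contiguous"].mean()) if len(table) else float("nan")
    return AdjacencyReport(table=table, contiguity_fraction=frac)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_edge_list(edges: pd.DataFrame, path) -> None:
    """Cytoscape-style interaction table."""
    edges.to_csv(path, sep="\t", index=False)


def write_node_attributes(G: nx.Graph, path) -> None:
    rows = [
        {
            "id": n,
            "organism": d.get("organism", ""),
            "temporal_class": d.get("temporal_class", ""),
            "k_score": d.get("k_score", G.degree[n]),
        }
        for n, d in sorted(G.nodes(data=True))
    ]
    pd.DataFrame(rows, columns=["id", "organism", "temporal_class", "k_score"]).to_csv(
        path, sep="\t", index=False
    )
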