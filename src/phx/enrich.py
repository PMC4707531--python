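"""Stage-resolved functional analysis of host DEGs.

Per time point, each annotation term (KEGG-style pathway or
PseudoCAP-style functional class) is tested for over-representation
among the DEGs by the one-sided Fisher exact test (hypergeometric upper
tail); term significance profiles over the time course are clustered
hierarchically into infection-stage clusters; and per-term
percentage-of-DEGs tables are computed with the >40% repression flag.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .degcall import DEGSummary

logger = logging.getLogger(__name__)

NEGLOG10_CAP = 16.0  # smallest p handled distinctly ~ 1e-16


@dataclass(frozen=True)
class TermInfo:
    name: str
    vocabulary: str = "pathway"  # 'pathway' | 'function'


@dataclass
class AnnotationMap:
    """gene id -> set of term ids, with per-term display metadata."""

    gene_terms: dict[str, frozenset]
    terms: dict[str, TermInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(self.terms)
        used = set().union(*self.gene_terms.values()) if self.gene_terms else set()
        for t in used - known:
            self.terms[t] = TermInfo(name=t)

    @property
    def term_ids(self) -> list[str]:
        return sorted(self.terms)

    def members(self, term: str) -> set[str]:
        return {g for g, ts in self.gene_terms.items() if term in ts}

    def restricted_to(self, universe) -> "AnnotationMap":
        universe = set(universe)
        return AnnotationMap(
            gene_terms={g: ts for g, ts in self.gene_terms.items() if g in universe},
            terms=dict(self.terms),
        )

    # -- IO -------------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path, vocabulary: str = "pathway") -> "AnnotationMap":
        """Two-column TSV (gene_id, term), optional header."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.iloc[0, 0] in ("gene_id", "gene"):
            df = df.iloc[1:]
        gene_terms: dict[str, set] = {}
        for g, t in zip(df.iloc[:, 0], df.iloc[:, 1]):
            gene_terms.setdefault(g, set()).add(t)
        terms = {t: TermInfo(name=t, vocabulary=vocabulary) for t in set(df.iloc[:, 1])}
        return cls({g: frozenset(ts) for g, ts in gene_terms.items()}, terms)

    @classmethod
    def from_gmt(cls, path, vocabulary: str = "pathway") -> "AnnotationMap":
        """GMT: term <tab> description <tab> gene1 <tab> gene2 ..."""
        gene_terms: dict[str, set] = {}
        terms: dict[str, TermInfo] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                term, desc, genes = parts[0], parts[1], parts[2:]
                terms[term] = TermInfo(name=desc or term, vocabulary=vocabulary)
                for g in genes:
                    if g:
                        gene_terms.setdefault(g, set()).add(term)
        return cls({g: frozenset(ts) for g, ts in gene_terms.items()}, terms)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tterm\n")
            for g in sorted(self.gene_terms):
                for t in sorted(self.gene_terms[g]):
                    fh.write(f"{g}\t{t}\n")


def fisher_enrichment(
    deg_set,
    background,
    amap: AnnotationMap,
    time_min: int | None = None,
    alpha: float = 0.01,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Per-term Fisher exact over-representation of DEGs.

    The 2x2 table per term is (a, b, c, d) = (DEG-in-term, DEG-not-in-
    term, nonDEG-in-term, nonDEG-not-in-term) over the probed
    background; the one-sided p is the hypergeometric upper tail
    P(X >= a). Rows are sorted by p. Terms with no members in the
    background are skipped (logged).
    """
    deg_set = set(deg_set)
    background = set(background)
    if not deg_set <= background:
        raise ValueError("DEG set must be a subset of the background")
    M, n = len(background), len(deg_set)
    rows = []
    for term in amap.term_ids:
        members = amap.members(term) & background
        K = len(members)
        if K == 0:
            logger.info("term %s has no members in the background; skipped", term)
            continue
        a = len(deg_set & members)
        b, c = n - a, K - a
        d = M - K - b
        if alternative == "greater":
            p = float(stats.hypergeom.sf(a - 1, M, K, n))
        elif alternative == "two-sided":
            p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
        else:
            raise ValueError(f"unknown alternative: {alternative!r}")
        p = min(p, 1.0)
        rows.append(
            {
                "term": term,
                "name": amap.terms[term].name,
                "time_min": time_min,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "p": p,
                "significant": p < alpha,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["term", "name", "time_min", "a", "b", "c", "d", "p", "significant"],
    )
    return df.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)


def enrichment_over_time(
    summary: DEGSummary,
    background,
    amap: AnnotationMap,
    alpha: float = 0.01,
    direction: str | None = None,
) -> pd.DataFrame:
    """Fisher enrichment at every time point (long format).

    ``direction`` restricts the DEG set to 'up' or 'down'; default uses
    both directions together.
    """
    frames = []
    for t in sorted(summary.per_time):
        sets = summary.per_time[t]
        if direction is None:
            degs = set(sets["up"]) | set(sets["down"])
        else:
            degs = set(sets[direction])
        frames.append(fisher_enrichment(degs, background, amap, time_min=t, alpha=alpha))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


@dataclass
class PathwayClusters:
    labels: pd.Series            # term -> cluster id
    leaf_order: list[str]
    profile: pd.DataFrame        # term x time, -log10(p) capped
    linkage: np.ndarray


def cluster_pathway_profiles(
    rows: pd.DataFrame, k: int = 4, cap: float = NEGLOG10_CAP
) -> PathwayClusters:
    """Cluster per-term significance profiles over the time course.

    ``rows`` is long-format enrichment output with columns term,
    time_min, p. Profiles are -log10(p) (missing time points count as
    p = 1, i.e. 0), capped at ``cap``; Euclidean distance, average
    linkage, cut at ``k`` clusters.
    """
    pivot = rows.pivot_table(index="term", columns="time_min", values="p", fill_value=1.0)
    if len(pivot) < k:
        raise ValueError(f"fewer terms ({len(pivot)}) than clusters requested ({k})")
    X = np.minimum(-np.log10(np.maximum(pivot.to_numpy(dtype=float), 1e-300)), cap)
    link = hierarchy.linkage(pdist(X, metric="euclidean"), method="average")
    labels = pd.Series(
        hierarchy.fcluster(link, t=k, criterion="maxclust"), index=pivot.index
    )
    leaf_order = [pivot.index[i] for i in hierarchy.leaves_list(link)]
    profile = pd.DataFrame(X, index=pivot.index, columns=pivot.columns)
    return PathwayClusters(labels, leaf_order, profile, link)


def function_ratio_table(
    summary: DEGSummary,
    amap: AnnotationMap,
    background,
    flag_threshold: float = 40.0,
) -> pd.DataFrame:
    """Percentage of each functional class affected per time point and
    direction: 100 * |DEGs of that direction at that time in the term| /
    |term members in the probed background|. Terms exceeding
    ``flag_threshold`` percent are flagged as obviously repressed or
    induced. Empty terms are skipped.
    """
    background = set(background)
    rows = []
    for term in amap.term_ids:
        members = amap.members(term) & background
        size = len(members)
        if size == 0:
            continue
        for t in sorted(summary.per_time):
            for direction in ("down", "up"):
                hits = len(set(summary.per_time[t][direction]) & members)
                pct = 100.0 * hits / size
                rows.append(
                    {
                        "term": term,
                        "name": amap.terms[term].name,
                        "time_min": t,
                        "direction": direction,
                        "n_deg": hits,
                        "term_size": size,
                        "percent": pct,
                        "flagged": pct > flag_threshold,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "term", "name", "time_min", "direction",
            "n_deg", "term_size", "percent", "flagged",
        ],
    )
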