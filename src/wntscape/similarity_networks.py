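"""Jaccard-threshold co-expression networks and combination queries.

A similarity network has one node per gene and an edge wherever the
pairwise Jaccard index meets a threshold.  The published comparison
retained, at each stage, the threshold showing the 15 genes most similar
to other family members; we operationalise "most similar" as each gene's
maximum pairwise JI, and pick the k-th largest of those per-gene scores —
the largest threshold at which at least k genes keep an edge.  Ties keep
all tied genes, so the retained count may exceed k.

Also here: per-edge intersection domains, per-voxel gene-combination
counts (the input to parallel-coordinate views), and region-restricted
expression profiles (which genes are expressed inside a query mask, e.g.
a digitally segmented anatomical territory).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .domains import BinaryDomain, DomainCatalog
from .errors import EmptySelectionError, ParameterError, UndefinedStatisticError
from .volumetrics import PairwiseTable


@dataclass
class SimilarityNetwork:
    """A thresholded JI graph; isolated nodes are retained with degree 0."""

    graph: nx.Graph
    threshold: float
    k_retained: int  # nodes with at least one edge at this threshold

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges}


def build_network(table: PairwiseTable, threshold: float) -> SimilarityNetwork:
    """Graph with an edge for every off-diagonal pair with JI >= threshold."""
    if table.mode != "jaccard":
        raise ParameterError(f"build_network needs a jaccard-mode table, got {table.mode!r}")
    if not 0.0 <= threshold <= 1.0:
        raise ParameterError(f"threshold must be in [0, 1], got {threshold}")
    g = nx.Graph(threshold=float(threshold))
    for lab, vol in zip(table.labels, table.volumes):
        g.add_node(
            lab,
            volume_voxels=int(vol),
            family=table.family or "",
            stage=table.stage or "",
        )
    n = table.n
    for i in range(n):
        for j in range(i + 1, n):
            ji = float(table.values[i, j])
            if ji >= threshold:
                g.add_edge(table.labels[i], table.labels[j], ji=ji)
    k_retained = sum(1 for node in g if g.degree(node) > 0)
    return SimilarityNetwork(graph=g, threshold=float(threshold), k_retained=k_retained)


def select_topk_threshold(table: PairwiseTable, k: int) -> float:
    """Largest threshold at which >= k genes retain at least one edge.

    Each gene's score is its maximum off-diagonal JI; the k-th largest
    score is returned.  A gene is non-isolated at threshold t iff its
    score >= t, so this is exactly the requested threshold; ties mean
    more than k genes may survive.
    """
    if table.mode != "jaccard":
        raise ParameterError(f"needs a jaccard-mode table, got {table.mode!r}")
    n = table.n
    if not 1 <= k <= n:
        raise ParameterError(f"k must be in 1..{n}, got {k}")
    off = table.values.copy()
    np.fill_diagonal(off, -np.inf)
    scores = off.max(axis=1)
    return float(np.sort(scores)[::-1][k - 1])


def edge_intersection_domain(a: BinaryDomain, b: BinaryDomain) -> BinaryDomain:
    """The overlap territory behind one network edge: a ∩ b as a mask."""
    a.grid.require_compatible(b.grid)
    return BinaryDomain(
        grid=a.grid,
        mask=np.logical_and(a.mask, b.mask),
        label=f"{a.label}&{b.label}",
        family=a.family,
        stage=a.stage,
    )


MAX_COMBINATION_GENES = 24


def combination_counts(
    catalog: DomainCatalog,
    family: str | None = None,
    stage: str | None = None,
) -> pd.DataFrame:
    """Voxel counts per gene presence/absence pattern inside the embryo mask.

    One column per gene (0/1) plus ``voxels``, sorted by decreasing
    count; the all-absent pattern is always included.  This is the
    re-formatted data behind parallel-coordinate co-expression views.
    """
    if catalog.embryo_mask is None:
        raise ParameterError("combination counts require an embryo mask")
    domains = catalog.select(family=family, stage=stage)
    if not domains:
        raise EmptySelectionError(f"no domains match family={family!r}, stage={stage!r}")
    if len(domains) > MAX_COMBINATION_GENES:
        raise ParameterError(
            f"{len(domains)} genes exceed the {MAX_COMBINATION_GENES}-gene bit-pattern "
            "guard; filter to a subset"
        )
    emb = catalog.embryo_mask.mask
    labels = [d.label for d in domains]
    bits = np.stack([d.mask[emb] for d in domains]).astype(np.int64)
    codes = (bits.T * (1 << np.arange(len(domains), dtype=np.int64))).sum(axis=1)
    counts = np.bincount(codes, minlength=1)  # index 0 = all-absent

    rows = []
    for code in np.flatnonzero(counts):
        pattern = [(int(code) >> g) & 1 for g in range(len(domains))]
        rows.append((*pattern, int(counts[code])))
    if counts[0] == 0:
        rows.append((*([0] * len(domains)), 0))
    df = pd.DataFrame(rows, columns=[*labels, "voxels"])
    return df.sort_values("voxels", ascending=False, kind="stable").reset_index(drop=True)


def query_region_profile(
    query: BinaryDomain,
    catalog: DomainCatalog,
    family: str | None = None,
    stage: str | None = None,
) -> pd.DataFrame:
    """Per-gene overlap statistics restricted to a query mask.

    Genes with zero overlap are included with zeros, so "no family
    member detected in this region" is a reportable outcome.
    """
    catalog.grid.require_compatible(query.grid)
    qvox = query.volume_voxels
    if qvox == 0:
        raise UndefinedStatisticError("query mask is empty; region profile undefined")
    domains = catalog.select(family=family, stage=stage)
    if not domains:
        raise EmptySelectionError(f"no domains match family={family!r}, stage={stage!r}")
    rows = []
    for dom in domains:
        inter = int(np.logical_and(dom.mask, query.mask).sum())
        rows.append(
            {
                "label": dom.label,
                "family": dom.family,
                "voxels_in_query": inter,
                "frac_of_query": inter / qvox,
                "frac_of_gene_domain": (inter / dom.volume_voxels) if dom.volume_voxels else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("label")
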