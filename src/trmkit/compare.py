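"""Edge-based comparison of reconstructed modules.

Two modules are compared on their unordered edge (interaction) sets
rather than their node sets: shared nodes wired differently are not the
same regulatory structure. Pairwise similarity is the Jaccard index of
the edge sets; groups of structurally similar modules are found by
hierarchical clustering of the Jaccard-matrix rows with Pearson distance
(d = 1 - r) and complete linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from trmkit._util import warn
from trmkit.finder import TRModule

EdgeKeySet = frozenset  # of frozenset gene pairs


@dataclass
class SimilarityMatrix:
    labels: list[str]
    J: np.ndarray  # symmetric, diagonal 1 (for nonempty modules), entries in [0,1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.J, index=self.labels, columns=self.labels)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="module")


@dataclass
class ClusteringResult:
    """Agglomeration trace: merges as (cluster_a, cluster_b, height)."""

    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]
    leaf_order: list[str]
    distance_def: str = "pearson (d = 1 - r)"
    linkage: str = "complete"
    newick: str = ""

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]


def edge_key_set(module: TRModule | nx.Graph) -> EdgeKeySet:
    """Unordered edge keys of a module; self-loops are excluded."""
    graph = module.graph if isinstance(module, TRModule) else module
    return frozenset(frozenset((a, b)) for a, b in graph.edges if a != b)


def jaccard_edges(a: EdgeKeySet, b: EdgeKeySet) -> float:
    """Intersection-over-union of two edge sets.

    Two empty sets compare as 0 (with a warning) so that empty modules
    cannot poison a similarity matrix with NaN.
    """
    a, b = frozenset(a), frozenset(b)
    union = a | b
    if not union:
        warn("Jaccard of two empty edge sets defined as 0")
        return 0.0
    return len(a & b) / len(union)


def common_edge_counts(a: EdgeKeySet, b: EdgeKeySet) -> tuple[int, int, int]:
    """(edges only in a, shared edges, edges only in b)."""
    a, b = frozenset(a), frozenset(b)
    shared = len(a & b)
    return (len(a) - shared, shared, len(b) - shared)


def similarity_matrix(
    modules: Mapping[str, TRModule | nx.Graph] | Sequence[tuple[str, TRModule | nx.Graph]],
) -> SimilarityMatrix:
    """All-against-all edge-Jaccard matrix over named modules."""
    items = list(modules.items()) if isinstance(modules, Mapping) else list(modules)
    if len(items) < 2:
        raise ValueError("need at least 2 modules to compare")
    labels = [name for name, _ in items]
    keys = [edge_key_set(m) for _, m in items]
    n = len(items)
    J = np.zeros((n, n))
    for i in range(n):
        J[i, i] = 1.0 if keys[i] else 0.0
        for j in range(i + 1, n):
            J[i, j] = J[j, i] = jaccard_edges(keys[i], keys[j])
    return SimilarityMatrix(labels=labels, J=J)


def _pearson_distance_matrix(sim: SimilarityMatrix, include_diagonal: bool) -> np.ndarray:
    rows = sim.J.copy()
    n = len(sim.labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if include_diagonal:
                x, y = rows[i], rows[j]
            else:
                mask = np.ones(n, dtype=bool)
                mask[[i, j]] = False
                x, y = rows[i][mask], rows[j][mask]
            for row, lab in ((x, sim.labels[i]), (y, sim.labels[j])):
                if np.std(row) == 0:
                    raise ValueError(
                        f"module {lab!r} has a constant similarity profile; "
                        "Pearson distance is undefined"
                    )
            r = float(np.corrcoef(x, y)[0, 1])
            D[i, j] = D[j, i] = 1.0 - r
    return D


def cluster_modules(
    sim: SimilarityMatrix, include_diagonal: bool = True
) -> ClusteringResult:
    """Complete-linkage agglomeration on Pearson distances of matrix rows.

    Distances are d = 1 - r between rows of the Jaccard matrix (the
    diagonal is part of the profile by default; ``include_diagonal=False``
    drops the two self-similarities from each comparison). Ties are
    broken lexicographically by the smallest member label so the result
    is invariant to input order.
    """
    if len(sim.labels) < 2:
        raise ValueError("need at least 2 modules to cluster")
    D = _pearson_distance_matrix(sim, include_diagonal)

    # clusters as sorted label tuples; pairwise complete-linkage distances
    clusters: dict[tuple[str, ...], dict] = {
        (lab,): {"order": [lab]} for lab in sim.labels
    }
    idx = {lab: i for i, lab in enumerate(sim.labels)}
    dist: dict[frozenset, float] = {}
    labs = sorted(sim.labels)
    for i, a in enumerate(labs):
        for b in labs[i + 1:]:
            dist[frozenset(((a,), (b,)))] = D[idx[a], idx[b]]

    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []
    while len(clusters) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], tuple(sorted(min(c) for c in kv[0]))),
        )
        pair, h = best
        a, b = sorted(pair, key=min)
        new = tuple(sorted(a + b))
        merges.append((a, b, h))
        order = clusters[a]["order"] + clusters[b]["order"]
        del clusters[a], clusters[b]
        # complete linkage: distance to the merged cluster is the max
        for c in list(clusters):
            dist[frozenset((new, c))] = max(
                dist.pop(frozenset((a, c))), dist.pop(frozenset((b, c)))
            )
        dist.pop(pair, None)
        clusters[new] = {"order": order}

    leaf_order = next(iter(clusters.values()))["order"]
    return ClusteringResult(
        merges=merges, leaf_order=leaf_order, newick=_merges_to_newick(merges)
    )


def _merges_to_newick(
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]
) -> str:
    if not merges:
        return ";"
    rep: dict[tuple[str, ...], str] = {}

    def node_str(cluster: tuple[str, ...]) -> str:
        if len(cluster) == 1:
            return cluster[0]
        return rep[cluster]

    for a, b, h in merges:
        rep[tuple(sorted(a + b))] = f"({node_str(a)},{node_str(b)}):{h:.6g}"
    root = tuple(sorted(merges[-1][0] + merges[-1][1]))
    return rep[root].rsplit(":", 1)[0] + ";"


def write_clustering(result: ClusteringResult, path: str | Path) -> None:
    lines = [f"# linkage: {result.linkage}; distance: {result.distance_def}"]
    for a, b, h in result.merges:
        lines.append(f"merge\t{','.join(a)}\t{','.join(b)}\t{h:.10g}")
    lines.append("leaf_order\t" + "\t".join(result.leaf_order))
    lines.append("newick\t" + result.newick)
    Path(path).write_text("\n".join(lines) + "\n")


def plot_similarity_heatmap(sim: SimilarityMatrix, path: str | Path) -> None:
    """Optional heatmap of the Jaccard matrix (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1 + 0.5 * len(sim.labels),) * 2)
    im = ax.imshow(sim.J, vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(sim.labels)), sim.labels, rotation=90, fontsize=7)
    ax.set_yticks(range(len(sim.labels)), sim.labels, fontsize=7)
    fig.colorbar(im, ax=ax, label="edge Jaccard index")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
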