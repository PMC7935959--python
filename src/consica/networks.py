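"""Co-functionality matrices and networks, and hierarchical clustering of
regulatory barcodes and of prediction-score profiles.

Two genes' co-functionality is the absolute Pearson correlation between their
prediction-score vectors. Barcode clustering uses 1 - distance correlation as
the dissimilarity with Ward agglomeration (the squared-update "ward.D2"
convention); score-profile clustering uses 1 - Pearson correlation. Cluster
diagnostics report a transcriptional similarity score (median pairwise
distance correlation of member barcodes) and a predictability score (median
over members of each member's maximum prediction score across all sets).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._dcor import dcor_matrix
from .decomposition import MixingMatrix
from .io import PredictionScoreTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CoFunctionalityMatrix",
    "ClusterReport",
    "cofunctionality",
    "cluster_barcodes",
    "cluster_score_profiles",
    "cluster_diagnostics",
    "export_network",
    "read_network",
]

MAX_NETWORK_GENES = 300


@dataclass
class CoFunctionalityMatrix:
    """Symmetric genes x genes matrix of |Pearson r| between score profiles."""

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.gene_ids)
        if self.values.shape != (n, n):
            raise ValidationError("co-functionality matrix must be square over genes")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("co-functionality matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.gene_ids)


@dataclass
class ClusterReport:
    """Flat clustering of genes plus optional per-cluster diagnostics."""

    gene_ids: list[str]
    labels: np.ndarray
    cut_height: float
    distance: str  # "1-dcor" | "1-pearson"
    linkage_matrix: np.ndarray | None = None
    per_cluster: pd.DataFrame | None = None
    similarity_predictability_r: float | None = None
    size_bounds: tuple[int, int] = (10, 500)
    extras: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def members(self, label: int) -> list[str]:
        return [g for g, l in zip(self.gene_ids, self.labels) if l == label]

    def sizes(self) -> pd.Series:
        return pd.Series(self.labels).value_counts().sort_index()


def cofunctionality(
    scores: PredictionScoreTable, genes: list[str] | None = None,
    max_genes: int = MAX_NETWORK_GENES,
) -> CoFunctionalityMatrix:
    """Pairwise absolute Pearson correlation of prediction-score vectors.

    Intended for a user-supplied gene list (capped at 300 by default, the
    portal's limit); constant profiles get 0 off-diagonal and 1 on the
    diagonal by convention.
    """
    df = scores.to_frame()
    if genes is not None:
        missing = [g for g in genes if g not in df.index]
        if missing:
            raise ValidationError(f"genes not in score table: {missing[:5]}")
        if len(genes) > max_genes:
            raise ValidationError(
                f"{len(genes)} genes exceeds the cap of {max_genes}"
            )
        df = df.loc[list(genes)]
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValidationError("need >= 2 genes and >= 2 sets")
    V = df.to_numpy()
    sd = V.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.abs(np.corrcoef(V))
    C = np.nan_to_num(C, nan=0.0)
    C[sd == 0, :] = 0.0
    C[:, sd == 0] = 0.0
    np.fill_diagonal(C, 1.0)
    C = (C + C.T) / 2  # exact symmetry against float round-off
    return CoFunctionalityMatrix(list(df.index), C)


def _ward_cut(
    D: np.ndarray, cut_height: float, gene_ids: list[str], distance_tag: str,
    size_bounds: tuple[int, int],
) -> ClusterReport:
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2, 0.0, None)
    Z = linkage(squareform(D, checks=False), method="ward")
    if not np.all(np.diff(Z[:, 2]) >= -1e-10):
        logger.warning("non-monotone dendrogram heights under Ward update")
    labels = fcluster(Z, t=cut_height, criterion="distance")
    sizes = pd.Series(labels).value_counts()
    lo, hi = size_bounds
    flagged = sorted(int(l) for l, s in sizes.items() if not lo <= s <= hi)
    if flagged:
        logger.info("%d clusters outside size bounds %s (flagged, kept)",
                    len(flagged), size_bounds)
    return ClusterReport(
        gene_ids=list(gene_ids),
        labels=labels,
        cut_height=cut_height,
        distance=distance_tag,
        linkage_matrix=Z,
        size_bounds=size_bounds,
        extras={"flagged_clusters": flagged},
    )


def cluster_barcodes(
    MM: MixingMatrix, cut_height: float = 2.5, size_bounds: tuple[int, int] = (10, 500),
) -> ClusterReport:
    """Ward ("ward.D2") clustering of gene barcodes at 1 - distance correlation.

    The dendrogram is cut at ``cut_height`` (default 2.5); clusters whose size
    falls outside ``size_bounds`` are flagged in the report, not dropped.
    """
    if len(MM.gene_ids) < size_bounds[0]:
        raise ValidationError("fewer genes than the minimum cluster size")
    R = dcor_matrix(MM.weights)
    if np.allclose(R, 1.0, atol=1e-12):
        logger.warning("all barcodes identical; single cluster")
    return _ward_cut(1.0 - R, cut_height, MM.gene_ids, "1-dcor", size_bounds)


def cluster_score_profiles(
    scores: PredictionScoreTable, genes: list[str] | None = None,
    cut_height: float = 0.8, size_bounds: tuple[int, int] = (10, 500),
) -> ClusterReport:
    """Ward clustering of prediction-score profiles at 1 - Pearson correlation.

    Default cut height 0.8; constant profiles are treated as uncorrelated
    (distance 1) with everything.
    """
    df = scores.to_frame()
    if genes is not None:
        df = df.loc[list(genes)]
    V = df.to_numpy()
    sd = V.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(V)
    C = np.nan_to_num(C, nan=0.0)
    C[sd == 0, :] = 0.0
    C[:, sd == 0] = 0.0
    np.fill_diagonal(C, 1.0)
    return _ward_cut(1.0 - C, cut_height, list(df.index), "1-pearson", size_bounds)


def cluster_diagnostics(
    clusters: ClusterReport,
    MM: MixingMatrix,
    scores: PredictionScoreTable,
    multifun=None,
) -> ClusterReport:
    """Per-cluster transcriptional similarity and predictability scores.

    Similarity: median pairwise distance correlation of member barcodes
    (missing for singleton clusters). Predictability: median over members of
    each member's maximum prediction score across all sets. Also reports the
    across-cluster Pearson correlation between the two scores.
    """
    gene_index = {g: i for i, g in enumerate(MM.gene_ids)}
    df = scores.to_frame()
    max_score = df.max(axis=1)
    rows = []
    for label in np.unique(clusters.labels):
        members = clusters.members(int(label))
        idx = [gene_index[g] for g in members if g in gene_index]
        if len(idx) >= 2:
            R = dcor_matrix(MM.weights[idx])
            iu = np.triu_indices(len(idx), k=1)
            similarity = float(np.median(R[iu]))
        else:
            similarity = np.nan
        in_scores = [g for g in members if g in max_score.index]
        predictability = float(max_score.loc[in_scores].median()) if in_scores else np.nan
        row = {
            "cluster": int(label),
            "size": len(members),
            "similarity": similarity,
            "predictability": predictability,
        }
        if multifun is not None:
            mf = multifun.to_series()
            in_mf = [g for g in members if g in mf.index]
            row["mean_multifunctionality"] = (
                float(mf.loc[in_mf].mean()) if in_mf else np.nan
            )
        rows.append(row)
    per_cluster = pd.DataFrame(rows).set_index("cluster")
    ok = per_cluster[["similarity", "predictability"]].dropna()
    r = np.nan
    if len(ok) >= 2 and ok["similarity"].std() > 0 and ok["predictability"].std() > 0:
        r = float(np.corrcoef(ok["similarity"], ok["predictability"])[0, 1])
    clusters.per_cluster = per_cluster
    clusters.similarity_predictability_r = r
    return clusters


def export_network(
    M: CoFunctionalityMatrix, threshold: float, path: str | Path,
    format: str = "auto",
) -> nx.Graph:
    """Write the thresholded co-functionality graph (GraphML or TSV edge list).

    Nodes are genes with at least one supra-threshold edge; edge weights are
    the co-functionality values. Node and edge order are deterministic
    (sorted by gene id).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError("threshold must be in [0, 1]")
    path = Path(path)
    if format == "auto":
        format = "graphml" if path.suffix == ".graphml" else "tsv"
    G = nx.Graph()
    order = sorted(range(len(M.gene_ids)), key=lambda i: M.gene_ids[i])
    for a_pos, i in enumerate(order):
        for j in order[a_pos + 1:]:
            w = M.values[i, j]
            if w > threshold:
                G.add_edge(M.gene_ids[i], M.gene_ids[j], weight=float(w))
    if G.number_of_edges() == 0:
        logger.warning("no edge above threshold %.3g; empty graph", threshold)
    if format == "graphml":
        nx.write_graphml(G, path)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("gene_a\tgene_b\tweight\n")
            for u, v, d in sorted(G.edges(data=True)):
                fh.write(f"{u}\t{v}\t{d['weight']:.17g}\n")
    return G


def read_network(path: str | Path) -> nx.Graph:
    """Read a graph written by :func:`export_network`."""
    path = Path(path)
    if path.suffix == ".graphml":
        return nx.read_graphml(path)
    G = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("gene_a"):
            raise ValidationError(f"not an edge-list file: {path}")
        for line in fh:
            u, v, w = line.rstrip("\n").split("\t")
            G.add_edge(u, v, weight=float(w))
    return G
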