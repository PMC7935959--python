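"""PCA whitening of the gene covariance and consensus independent component
analysis with credibility filtering.

The observed variables are the genes. Whitening eigendecomposes the gene-gene
covariance of the (per-gene centered) expression matrix and keeps the smallest
number of leading axes whose cumulative explained-variance fraction reaches a
threshold (0.90 by default); the retained axes are rescaled to unit-variance,
decorrelated variables. Consensus ICA then runs the FastICA fixed-point
algorithm repeatedly (25 runs by default) on those whitened variables, matches
components across runs at high absolute Pearson correlation (> 0.98), and
retains a consensus component only when its cluster of mutually matching
components spans enough runs (>= 13 of 25, i.e. credibility index > 0.5).
Each retained consensus component is the sign-aligned mean of its cluster,
renormalized to unit variance; the gene-space mixing matrix is then
recomputed by least-squares projection of the centered expression matrix onto
the consensus sources. A gene's row of that mixing matrix is its
transcriptional regulatory barcode.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .io import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "WhitenedBasis",
    "MixingMatrix",
    "ConsensusReport",
    "whiten",
    "run_consensus_ica",
    "consensus_match",
    "recompute_mixing",
]


@dataclass
class WhitenedBasis:
    """Gene-space principal axes and the whitened variables fed to ICA."""

    gene_ids: list[str]
    loadings: np.ndarray          # genes x n_pc, orthonormal columns
    explained_variance: np.ndarray  # eigenvalues of the gene covariance
    explained_fraction: np.ndarray  # per-axis fraction of total variance
    whitened: np.ndarray          # n_pc x samples, zero-mean unit-variance rows
    var_threshold: float
    sample_ids: list[str] = field(default_factory=list)
    gene_means: np.ndarray | None = None

    @property
    def n_pc(self) -> int:
        return self.loadings.shape[1]


@dataclass
class MixingMatrix:
    """Weights of each component on each observed variable.

    Rows are genes (or whitened variables for the pre-projection mixing),
    columns are consensus transcriptional components; each row of a gene-space
    mixing matrix is that gene's transcriptional regulatory barcode.
    """

    gene_ids: list[str]
    component_ids: list[str]
    weights: np.ndarray
    credibility: np.ndarray
    n_runs: int = 1
    match_r: float = 0.98
    min_match_runs: int = 1

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.credibility = np.asarray(self.credibility, dtype=float)
        if self.weights.shape != (len(self.gene_ids), len(self.component_ids)):
            raise ValidationError("mixing matrix shape does not match id lists")
        if not np.isfinite(self.weights).all():
            raise ValidationError("mixing weights must be finite")

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def barcode(self, gene_id: str) -> np.ndarray:
        return self.weights[self.gene_ids.index(gene_id)]


@dataclass
class ConsensusReport:
    """Bookkeeping of the multi-run matching behind a consensus decomposition."""

    n_runs: int
    per_run_components: list[int]
    converged_runs: list[bool]
    cluster_runs: list[int]          # runs covered by each retained cluster
    credibility: list[float]
    dropped_components: int

    def to_dict(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "per_run_components": self.per_run_components,
            "converged_runs": self.converged_runs,
            "cluster_runs": self.cluster_runs,
            "credibility": self.credibility,
            "dropped_components": self.dropped_components,
        }


def whiten(X: ExpressionMatrix, var_threshold: float = 0.90) -> WhitenedBasis:
    """Whiten the expression matrix by PCA on the gene-gene covariance.

    Genes are centered across samples, the covariance between genes is
    eigendecomposed (via SVD of the centered matrix), and the smallest number
    of leading axes whose cumulative variance fraction reaches
    ``var_threshold`` is retained. Whitened variables are the retained PC
    scores over samples, scaled to unit variance (ddof=1).
    """
    if not 0.0 < var_threshold <= 1.0:
        raise ValidationError(f"var_threshold must be in (0, 1], got {var_threshold}")
    means = X.values.mean(axis=1)
    Xc = X.values - means[:, None]
    U, s, _Vt = np.linalg.svd(Xc, full_matrices=False)
    n = X.n_samples
    eigvals = s**2 / (n - 1)  # eigenvalues of the gene covariance (ddof=1)
    tol = s.max() * max(Xc.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    if rank == 0:
        raise ValidationError("expression matrix has rank 0 after centering")
    total = eigvals[:rank].sum()
    frac = eigvals[:rank] / total
    cum = np.cumsum(frac)
    n_pc = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    n_pc = min(n_pc, rank)

    U = U[:, :n_pc].copy()
    # sign convention: largest-|loading| gene positive, so the basis is
    # invariant to gene-row permutation
    flip = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(n_pc)])
    flip[flip == 0] = 1.0
    U *= flip

    scores = U.T @ Xc  # n_pc x samples, zero-mean rows
    sd = scores.std(axis=1, ddof=1)
    whitened = scores / sd[:, None]
    return WhitenedBasis(
        gene_ids=list(X.gene_ids),
        loadings=U,
        explained_variance=eigvals[:n_pc],
        explained_fraction=frac[:n_pc],
        whitened=whitened,
        var_threshold=var_threshold,
        sample_ids=list(X.sample_ids),
        gene_means=means,
    )


def _fastica_once(
    data: np.ndarray, n_components: int, seed: int, algorithm: str, max_iter: int
) -> tuple[np.ndarray | None, bool]:
    """One FastICA run on whitened data; returns (sources, converged)."""
    # with whiten=False FastICA uses every feature, so callers restrict the
    # data to the leading n_components whitened variables beforehand
    assert data.shape[0] == n_components
    ica = FastICA(
        whiten=False,
        fun="logcosh",
        algorithm=algorithm,
        max_iter=max_iter,
        random_state=seed,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        try:
            sources = ica.fit_transform(data.T).T  # n_components x samples
        except Exception as exc:  # pragma: no cover - FastICA rarely raises
            logger.warning("FastICA run failed: %s", exc)
            return None, False
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    return sources, converged


def run_consensus_ica(
    W: WhitenedBasis,
    n_components: int | None = None,
    n_runs: int = 25,
    match_r: float = 0.98,
    min_match_runs: int = 13,
    seed: int = 0,
    algorithm: str = "parallel",
    max_iter: int = 1000,
) -> tuple[MixingMatrix, np.ndarray, ConsensusReport]:
    """Multi-restart FastICA with cross-run component matching.

    Returns the mixing matrix over the whitened variables, the consensus
    sources (components x samples) and a :class:`ConsensusReport`. The number
    of extracted components per run defaults to the number of whitened
    variables. Run seeds are derived deterministically from ``seed``; a
    non-convergent run is retried once with a fresh derived seed and, if still
    non-convergent, excluded from matching while still counting in the
    credibility denominator.
    """
    n_pc = W.n_pc
    if n_components is None:
        n_components = n_pc
    if n_components > n_pc:
        raise ValidationError(f"n_components={n_components} exceeds n_pc={n_pc}")
    if n_runs < 1 or not 1 <= min_match_runs <= n_runs:
        raise ValidationError("need n_runs >= 1 and 1 <= min_match_runs <= n_runs")

    ss = np.random.SeedSequence(seed)
    run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * n_runs)]

    data = W.whitened[:n_components]  # leading whitened variables
    runs: list[np.ndarray | None] = []
    converged_flags: list[bool] = []
    for r in range(n_runs):
        sources, ok = _fastica_once(
            data, n_components, run_seeds[r], algorithm, max_iter
        )
        if sources is not None and not ok:
            retry, ok = _fastica_once(
                data, n_components, run_seeds[n_runs + r], algorithm, max_iter
            )
            if retry is not None and ok:
                sources = retry
        if sources is None or not ok:
            logger.warning("FastICA run %d did not converge; excluded from matching", r)
            converged_flags.append(False)
            runs.append(sources if ok else None)
        else:
            converged_flags.append(True)
            runs.append(sources)

    if not any(s is not None for s in runs):
        raise ValidationError("all FastICA runs failed to converge")

    consensus, credibility, report = consensus_match(
        runs, n_runs=n_runs, match_r=match_r, min_match_runs=min_match_runs,
        converged=converged_flags,
    )
    if consensus.shape[0] == 0:
        raise ValidationError(
            f"no component reached min_match_runs={min_match_runs}; "
            f"report: {report.to_dict()}"
        )

    # mixing over the whitened variables
    weights = _lstsq_mixing(W.whitened, consensus)
    # canonical component order and sign, so the decomposition is invariant
    # to gene-row permutation of the input: order by descending explained
    # variance (column norm over the whitened variables), sign so the
    # largest-|weight| whitened variable loads positively
    credibility = np.asarray(credibility, dtype=float)
    col_norm = (weights**2).sum(axis=0)
    order = np.argsort(-col_norm, kind="stable")
    weights = weights[:, order]
    consensus = consensus[order]
    credibility = credibility[order]
    flip = np.sign(weights[np.argmax(np.abs(weights), axis=0),
                           np.arange(weights.shape[1])])
    flip[flip == 0] = 1.0
    weights *= flip
    consensus *= flip[:, None]
    component_ids = [f"TC{i + 1}" for i in range(consensus.shape[0])]
    mm = MixingMatrix(
        gene_ids=[f"PC{i + 1}" for i in range(n_pc)],
        component_ids=component_ids,
        weights=weights,
        credibility=credibility,
        n_runs=n_runs,
        match_r=match_r,
        min_match_runs=min_match_runs,
    )
    return mm, consensus, report


def consensus_match(
    runs: list[np.ndarray | None],
    n_runs: int,
    match_r: float = 0.98,
    min_match_runs: int = 13,
    converged: list[bool] | None = None,
) -> tuple[np.ndarray, list[float], ConsensusReport]:
    """Match components across runs and form credibility-filtered consensus.

    ``runs`` holds per-run source matrices (components x samples); ``None``
    marks an excluded run, which still counts in the credibility denominator.
    The first usable run is the reference; its components, ordered by
    descending variance of the (unit-norm ambiguity aside) source signal and
    then by index, seed the clusters. Each other run contributes at most one
    component per cluster, greedily, at absolute Pearson correlation >
    ``match_r``; matched components are sign-aligned to the reference before
    averaging. Clusters spanning fewer than ``min_match_runs`` runs are
    dropped. Consensus components are renormalized to unit variance.
    """
    if converged is None:
        converged = [r is not None for r in runs]
    usable = [i for i, r in enumerate(runs) if r is not None]
    if not usable:
        raise ValidationError("no usable runs to match")
    ref_idx = usable[0]
    ref = runs[ref_idx]

    # order reference components by descending signal variance, ties by index
    ref_var = ref.var(axis=1, ddof=1)
    order = sorted(range(ref.shape[0]), key=lambda i: (-ref_var[i], i))

    clusters: list[dict] = [
        {"members": [np.asarray(ref[i], dtype=float)], "runs": {ref_idx}}
        for i in order
    ]

    for run_i in usable[1:]:
        S = runs[run_i]
        # correlation of each cluster's reference member with each run component
        ref_mat = np.vstack([c["members"][0] for c in clusters])
        R = _rowwise_corr(ref_mat, S)
        absR = np.abs(R)
        taken: set[int] = set()
        for ci in range(len(clusters)):
            cand = np.argsort(-absR[ci])
            for j in cand:
                if absR[ci, j] <= match_r:
                    break
                if j in taken:
                    continue
                sign = 1.0 if R[ci, j] >= 0 else -1.0
                clusters[ci]["members"].append(sign * S[j])
                clusters[ci]["runs"].add(run_i)
                taken.add(int(j))
                break

    kept_sources = []
    credibility = []
    cluster_runs = []
    dropped = 0
    for c in clusters:
        n_cov = len(c["runs"])
        if n_cov >= min_match_runs:
            m = np.mean(c["members"], axis=0)
            sd = m.std(ddof=1)
            if sd > 0:
                m = m / sd
            kept_sources.append(m)
            credibility.append(n_cov / n_runs)
            cluster_runs.append(n_cov)
        else:
            dropped += 1

    consensus = (
        np.vstack(kept_sources) if kept_sources else np.empty((0, ref.shape[1]))
    )
    report = ConsensusReport(
        n_runs=n_runs,
        per_run_components=[0 if r is None else r.shape[0] for r in runs],
        converged_runs=list(converged),
        cluster_runs=cluster_runs,
        credibility=credibility,
        dropped_components=dropped,
    )
    return consensus, credibility, report


def _rowwise_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation between every row of A and every row of B."""
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    An = np.linalg.norm(Ac, axis=1)
    Bn = np.linalg.norm(Bc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Ac @ Bc.T) / np.outer(An, Bn)
    return np.nan_to_num(R, nan=0.0)


def _lstsq_mixing(X: np.ndarray, sources: np.ndarray) -> np.ndarray:
    """Least-squares weights A minimizing ||X - A S||_F (rows of S = sources)."""
    gram = sources @ sources.T
    rank = np.linalg.matrix_rank(gram)
    if rank < sources.shape[0]:
        logger.warning("rank-deficient sources (rank %d < %d); using pseudo-inverse",
                       rank, sources.shape[0])
        return X @ np.linalg.pinv(sources)
    A, *_ = np.linalg.lstsq(sources.T, X.T, rcond=None)
    return A.T


def recompute_mixing(X: ExpressionMatrix, sources: np.ndarray,
                     mm: MixingMatrix | None = None) -> MixingMatrix:
    """Project the centered expression matrix onto consensus sources.

    Returns the genes x components weight matrix minimizing reconstruction
    error; each row is one gene's transcriptional regulatory barcode. When
    ``mm`` (the whitened-space mixing) is given, its component metadata
    (ids, credibility, run parameters) is carried over.
    """
    sources = np.asarray(sources, dtype=float)
    if sources.ndim != 2 or sources.shape[1] != X.n_samples:
        raise ValidationError(
            f"sources must be components x {X.n_samples} samples, got {sources.shape}"
        )
    Xc = X.values - X.values.mean(axis=1, keepdims=True)
    weights = _lstsq_mixing(Xc, sources)
    k = sources.shape[0]
    if mm is not None:
        component_ids = list(mm.component_ids)
        credibility = np.asarray(mm.credibility)
        n_runs, match_r, min_match = mm.n_runs, mm.match_r, mm.min_match_runs
    else:
        component_ids = [f"TC{i + 1}" for i in range(k)]
        credibility = np.ones(k)
        n_runs, match_r, min_match = 1, 0.98, 1
    return MixingMatrix(
        gene_ids=list(X.gene_ids),
        component_ids=component_ids,
        weights=weights,
        credibility=credibility,
        n_runs=n_runs,
        match_r=match_r,
        min_match_runs=min_match,
    )
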