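"""Guilt-by-association prediction scores from transcriptional regulatory
barcodes.

A gene's barcode is its row of the mixing matrix. A gene set's barcode is the
component-wise mean of member rows (ICA path) or the per-component Welch-T
profile of member versus nonmember loadings (PCA comparator, the convention
used by eigenvector-based predictors). The observed similarity between a gene
barcode and a set barcode — distance correlation on the ICA path, Pearson
correlation on the PCA path — is calibrated against a permutation null built
from random same-size gene sets, smoothed with a Gaussian kernel density
estimator, and reported as a Z-score: the prediction score.

Because the null depends only on the querying gene and the set's size, nulls
are cached per (gene, set size); the permutation stream for each pair is
derived deterministically from the global seed, so cached and uncached
scoring agree exactly.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from ._dcor import distance_correlation, distance_correlation_batch
from .decomposition import MixingMatrix, WhitenedBasis
from .io import GeneSetCollection, PredictionScoreTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Barcode",
    "NullDistribution",
    "gene_barcode",
    "set_barcode",
    "distance_correlation",
    "build_null",
    "prediction_score",
    "score_all",
]

MIN_BANDWIDTH = 1e-3  # floor for degenerate (near-constant) null samples


@dataclass
class Barcode:
    """A vector over consensus components for a gene or a gene set."""

    component_ids: list[str]
    values: np.ndarray
    origin: str  # gene | set-mean | set-welch-t

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != len(self.component_ids):
            raise ValidationError("barcode length does not match component ids")
        if not np.isfinite(self.values).all():
            raise ValidationError("barcode values must be finite")


@dataclass
class NullDistribution:
    """Permutation null of a similarity statistic, smoothed with a Gaussian KDE."""

    samples: np.ndarray
    kde_bandwidth: float
    n_perm: int
    set_size: int
    seed: int
    statistic: str = "dcor"  # dcor | pearson

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.kde_bandwidth <= 0:
            raise ValidationError("KDE bandwidth must be positive")


def silverman_bandwidth(samples: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 min(sd, IQR/1.34) n^(-1/5).

    Near-constant samples would give bandwidth 0; floored at a small positive
    value so the smoothed tail stays defined.
    """
    samples = np.asarray(samples, dtype=float)
    n = samples.size
    sd = samples.std(ddof=1) if n > 1 else 0.0
    q75, q25 = np.percentile(samples, [75, 25])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    h = 0.9 * spread * n ** (-1 / 5)
    return max(h, MIN_BANDWIDTH)


def gene_barcode(MM: MixingMatrix, gene_id: str) -> Barcode:
    """A gene's transcriptional regulatory barcode: its mixing-matrix row."""
    if gene_id not in MM.gene_ids:
        raise ValidationError(f"unknown gene id {gene_id!r}")
    return Barcode(list(MM.component_ids), MM.barcode(gene_id), origin="gene")


def welch_t_profile(
    member_rows: np.ndarray, nonmember_rows: np.ndarray
) -> np.ndarray:
    """Per-column Welch T statistic, members vs nonmembers.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2); a column where both groups have
    zero variance gets 0.
    """
    n1, n2 = member_rows.shape[0], nonmember_rows.shape[0]
    m1 = member_rows.mean(axis=0)
    m2 = nonmember_rows.mean(axis=0)
    v1 = member_rows.var(axis=0, ddof=1)
    v2 = nonmember_rows.var(axis=0, ddof=1)
    denom = np.sqrt(v1 / n1 + v2 / n2)
    t = np.zeros_like(m1)
    ok = denom > 0
    t[ok] = (m1 - m2)[ok] / denom[ok]
    if not ok.all():
        logger.warning("%d zero-variance components in Welch T; statistic set to 0",
                       int((~ok).sum()))
    return t


def set_barcode(
    MM: MixingMatrix,
    members,
    method: str = "ica_mean",
    basis: WhitenedBasis | None = None,
) -> Barcode:
    """Barcode of a gene set.

    ``ica_mean``: component-wise mean of the member rows of the mixing matrix.
    ``pca_welch_t``: per-principal-axis Welch T statistic comparing member
    genes' loadings against all nonmember genes' loadings (requires ``basis``).
    """
    members = list(members)
    gene_index = {g: i for i, g in enumerate(MM.gene_ids)}
    unknown = [m for m in members if m not in gene_index]
    if unknown:
        raise ValidationError(f"unknown gene ids in set: {unknown[:5]}")
    idx = np.array([gene_index[m] for m in members], dtype=int)
    if method == "ica_mean":
        if idx.size < 1:
            raise ValidationError("ica_mean needs at least one member")
        return Barcode(
            list(MM.component_ids), MM.weights[idx].mean(axis=0), origin="set-mean"
        )
    if method == "pca_welch_t":
        if basis is None:
            raise ValidationError("pca_welch_t requires the whitened basis")
        b_index = {g: i for i, g in enumerate(basis.gene_ids)}
        m_idx = np.array([b_index[m] for m in members], dtype=int)
        mask = np.ones(len(basis.gene_ids), dtype=bool)
        mask[m_idx] = False
        if m_idx.size < 2 or mask.sum() < 2:
            raise ValidationError("pca_welch_t needs >= 2 members and >= 2 nonmembers")
        t = welch_t_profile(basis.loadings[m_idx], basis.loadings[mask])
        ids = [f"PC{i + 1}" for i in range(basis.n_pc)]
        return Barcode(ids, t, origin="set-welch-t")
    raise ValidationError(f"unknown set-barcode method {method!r}")


# ---------------------------------------------------------------------------
# permutation null and scoring


def _pair_seed(seed: int, gene_id: str, set_size: int) -> np.random.Generator:
    """Deterministic per-(gene, set size) random stream.

    Keyed on the gene *identifier* (stable CRC32), not its row position, so
    reordering the mixing-matrix rows leaves every score bit-identical.
    """
    key = zlib.crc32(str(gene_id).encode())
    ss = np.random.SeedSequence(seed, spawn_key=(key, set_size))
    return np.random.default_rng(ss)


def _random_member_indices(
    n_genes: int, set_size: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """n_perm uniform random gene subsets of size set_size (without replacement).

    Random-key trick: argsort of i.i.d. uniforms is a uniform permutation.
    """
    keys = rng.random((n_perm, n_genes))
    return np.argsort(keys, axis=1)[:, :set_size]


def _random_set_mean_barcodes(
    weights: np.ndarray, set_size: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Mean barcodes of n_perm random same-size gene sets (n_perm x k)."""
    idx = _random_member_indices(weights.shape[0], set_size, n_perm, rng)
    return weights[idx].mean(axis=1)


def build_null(
    gene_barcode: Barcode,
    MM: MixingMatrix,
    set_size: int,
    n_perm: int = 1000,
    seed: int = 0,
    gene_id: str | None = None,
) -> NullDistribution:
    """Permutation null of distance correlation for one gene and one set size.

    Draws ``n_perm`` random gene sets of ``set_size`` uniformly without
    replacement from the mixing-matrix gene universe, computes each random
    set's mean barcode and its distance correlation with the gene's barcode,
    then fits a Gaussian KDE with Silverman's bandwidth.
    """
    if n_perm < 100:
        raise ValidationError("n_perm < 100 makes the null tail too unstable")
    if not 1 <= set_size <= len(MM.gene_ids):
        raise ValidationError(f"set_size must be in [1, {len(MM.gene_ids)}]")
    rng = _pair_seed(seed, gene_id or "", set_size)
    # draw from a canonically sorted gene order so the null is invariant to
    # the row order of the mixing matrix
    order = np.argsort(np.asarray(MM.gene_ids))
    perm_barcodes = _random_set_mean_barcodes(MM.weights[order], set_size, n_perm, rng)
    samples = distance_correlation_batch(gene_barcode.values, perm_barcodes)
    return NullDistribution(
        samples=samples,
        kde_bandwidth=silverman_bandwidth(samples),
        n_perm=n_perm,
        set_size=set_size,
        seed=seed,
        statistic="dcor",
    )


def _kde_tail_log_p(observed: float, samples: np.ndarray, h: float) -> float:
    """log of the Gaussian-mixture survival probability above ``observed``."""
    z = (observed - samples) / h
    return float(special.logsumexp(stats.norm.logsf(z)) - np.log(samples.size))


def _kde_z(observed: float, samples: np.ndarray, h: float) -> float:
    """Z = Phi^-1(1 - p_upper) via whichever mixture tail is numerically small.

    Far below the null, the upper-tail probability rounds to 1 and loses all
    precision; the lower tail (mixture CDF) is then the well-conditioned side
    and Phi^-1(p_lower) equals the same Z.
    """
    z = (observed - samples) / h
    n = samples.size
    log_p_upper = special.logsumexp(stats.norm.logsf(z)) - np.log(n)
    if log_p_upper < np.log(0.5):
        return float(-special.ndtri_exp(log_p_upper))
    log_p_lower = special.logsumexp(stats.norm.logcdf(z)) - np.log(n)
    return float(special.ndtri_exp(log_p_lower))


def prediction_score(observed: float, null: NullDistribution) -> float:
    """Z-score of an observed similarity under a smoothed permutation null.

    p is the analytic survival probability of the fitted Gaussian mixture
    above ``observed`` (never exactly 0 or 1 thanks to the unbounded kernel
    tails), and Z = Phi^-1(1 - p). Strictly increasing in ``observed``.
    """
    return _kde_z(float(observed), null.samples, null.kde_bandwidth)


def _parametric_pearson_z(r: float, n: int) -> float:
    """Z from the one-sided correlation t-test, in the direction of r."""
    r = float(np.clip(r, -1.0, 1.0))
    if n < 3 or abs(r) == 1.0:
        # |r| = 1 has p -> 0; cap via the t-distribution limit at huge t
        t = np.sign(r) * 1e8 if abs(r) == 1.0 else 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    df = max(n - 2, 1)
    if t >= 0:
        return float(-special.ndtri_exp(stats.t.logsf(t, df=df)))
    return float(special.ndtri_exp(stats.t.logcdf(t, df=df)))


def _pearson_batch(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    xc = x - x.mean()
    xn = np.linalg.norm(xc)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    Yn = np.linalg.norm(Yc, axis=1)
    out = np.zeros(Y.shape[0])
    ok = (Yn > 0) & (xn > 0)
    out[ok] = (Yc[ok] @ xc) / (Yn[ok] * xn)
    return out


def _random_welch_barcodes(
    loadings: np.ndarray, set_size: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Welch-T barcodes of n_perm random same-size sets (vectorized via sums)."""
    n_genes, k = loadings.shape
    tot_sum = loadings.sum(axis=0)
    tot_sq = (loadings**2).sum(axis=0)
    n1, n2 = set_size, n_genes - set_size
    idx = _random_member_indices(n_genes, set_size, n_perm, rng)
    s1 = loadings[idx].sum(axis=1)          # n_perm x k
    q1 = (loadings[idx] ** 2).sum(axis=1)
    m1 = s1 / n1
    m2 = (tot_sum - s1) / n2
    v1 = (q1 - n1 * m1**2) / max(n1 - 1, 1)
    v2 = ((tot_sq - q1) - n2 * m2**2) / max(n2 - 1, 1)
    denom = np.sqrt(np.clip(v1, 0, None) / n1 + np.clip(v2, 0, None) / n2)
    t = np.zeros((n_perm, k))
    ok = denom > 0
    t[ok] = (m1 - m2)[ok] / denom[ok]
    return t


def score_all(
    MM: MixingMatrix,
    collection: GeneSetCollection,
    method: str = "ica",
    basis: WhitenedBasis | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    p_mode: str = "permutation",
    leave_one_out: bool = False,
) -> PredictionScoreTable:
    """Score every (gene, gene set) pair of a collection.

    ICA path: distance correlation between the gene barcode and the set's
    mean barcode, calibrated by permutation. PCA path: Pearson correlation
    between the gene's loading row and the set's Welch-T barcode, calibrated
    by permutation (default, for cross-method comparability) or by the
    parametric one-sided correlation test (``p_mode="parametric"``).

    ``leave_one_out`` recomputes a member gene's set barcode without that
    gene (sensitivity analysis; off by default — a member contributes to its
    own set's barcode).
    """
    if not collection.sets:
        raise ValidationError("empty gene set collection")
    if method not in ("ica", "pca"):
        raise ValidationError("method must be 'ica' or 'pca'")
    if method == "pca" and basis is None:
        raise ValidationError("PCA path requires the whitened basis")
    if p_mode not in ("permutation", "parametric"):
        raise ValidationError("p_mode must be 'permutation' or 'parametric'")
    if p_mode == "parametric" and method != "pca":
        raise ValidationError("parametric p-values are only defined for the PCA path")

    gene_ids = list(MM.gene_ids)
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    set_names = collection.set_names
    n_genes, n_sets = len(gene_ids), len(set_names)

    member_idx = {
        name: np.array([gene_index[m] for m in members if m in gene_index], dtype=int)
        for name, members in collection.sets.items()
    }
    for name, idx in member_idx.items():
        if idx.size == 0:
            raise ValidationError(f"set {name!r} has no members in the mixing matrix")

    # permutation sets are drawn from a canonically sorted gene order so the
    # null stream is invariant to the row order of the inputs
    canonical = np.argsort(np.asarray(gene_ids))
    if method == "ica":
        query = MM.weights                      # gene barcodes
        perm_source = MM.weights[canonical]     # random sets drawn from MM rows
        set_mat = np.vstack(
            [MM.weights[member_idx[name]].mean(axis=0) for name in set_names]
        )
    else:
        b_index = {g: i for i, g in enumerate(basis.gene_ids)}
        if set(gene_ids) - set(b_index):
            raise ValidationError("mixing matrix genes missing from the basis")
        order = np.array([b_index[g] for g in gene_ids], dtype=int)
        loadings = basis.loadings[order]
        query = loadings                        # eigenvector scalar rows
        perm_source = loadings[canonical]
        set_mat = np.empty((n_sets, loadings.shape[1]))
        mask = np.ones(n_genes, dtype=bool)
        for j, name in enumerate(set_names):
            idx = member_idx[name]
            mask[:] = True
            mask[idx] = False
            set_mat[j] = welch_t_profile(loadings[idx], loadings[mask])

    sizes = {name: member_idx[name].size for name in set_names}
    scores = np.empty((n_genes, n_sets))

    if method == "pca" and p_mode == "parametric":
        k = query.shape[1]
        for j in range(n_sets):
            r = _pearson_batch(set_mat[j], query)
            scores[:, j] = [_parametric_pearson_z(ri, k) for ri in r]
    else:
        size_groups: dict[int, list[int]] = {}
        for j, name in enumerate(set_names):
            size_groups.setdefault(sizes[name], []).append(j)
        for gi in range(n_genes):
            g_vec = query[gi]
            if method == "ica":
                obs_all = distance_correlation_batch(g_vec, set_mat)
            else:
                obs_all = _pearson_batch(g_vec, set_mat)
            for s, set_js in size_groups.items():
                rng = _pair_seed(seed, gene_ids[gi], s)
                if method == "ica":
                    perm = _random_set_mean_barcodes(perm_source, s, n_perm, rng)
                    null_samples = distance_correlation_batch(g_vec, perm)
                else:
                    perm = _random_welch_barcodes(perm_source, s, n_perm, rng)
                    null_samples = _pearson_batch(g_vec, perm)
                h = silverman_bandwidth(null_samples)
                for j in set_js:
                    obs = obs_all[j]
                    if leave_one_out and gi in member_idx[set_names[j]]:
                        idx = member_idx[set_names[j]]
                        rest = idx[idx != gi]
                        if rest.size:
                            if method == "ica":
                                bc = MM.weights[rest].mean(axis=0)
                                obs = distance_correlation(g_vec, bc)
                            else:
                                mask = np.ones(n_genes, dtype=bool)
                                mask[rest] = False
                                bc = welch_t_profile(query[rest], query[mask])
                                obs = _pearson_batch(bc, g_vec[None, :])[0]
                    scores[gi, j] = _kde_z(float(obs), null_samples, h)

    return PredictionScoreTable(
        gene_ids=gene_ids,
        set_names=set_names,
        scores=scores,
        method_tag=method,
        collection_name=collection.name,
        provenance={
            "n_perm": n_perm,
            "seed": seed,
            "p_mode": p_mode,
            "bandwidth_rule": "silverman",
            "leave_one_out": leave_one_out,
        },
    )
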