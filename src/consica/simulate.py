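"""Synthetic expression data with known latent structure.

The generator emulates the latent model the decomposition assumes: a small
number of mutually independent, super-Gaussian source signals (transcriptional
programs over samples) mixed into genes through a block-structured mixing
matrix, plus i.i.d. Gaussian measurement noise:

    X = A S + eps

Each block of the mixing matrix is a planted gene set: its member genes share
an elevated loading on one designated source, on top of small dense
background loadings that give every gene some weight on every program (and
let multifunctional genes be emulated via membership in several blocks).
Laplace sources are the default (positive excess kurtosis, as FastICA's
log-cosh contrast requires); a Gaussian-source mode serves as a negative
control in which independent components are not identifiable and consensus
filtering should prune unstable components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, GeneSetCollection, ValidationError

__all__ = [
    "PlantedGroundTruth",
    "generate_expression",
    "generate_random_collection",
]


@dataclass
class PlantedGroundTruth:
    """What the generator planted: mixing, sources, sets, noise level."""

    true_mixing: np.ndarray        # genes x k
    true_sources: np.ndarray       # k x samples
    planted_sets: dict[str, dict]  # name -> {"members": [...], "column": int}
    noise_sd: float
    seed: int

    def set_members(self, name: str) -> list[str]:
        return list(self.planted_sets[name]["members"])


def _draw_sources(
    k: int, n_samples: int, source_dist: str, rng: np.random.Generator
) -> np.ndarray:
    if source_dist == "laplace":
        # scale 1/sqrt(2) -> unit variance; excess kurtosis 3
        return rng.laplace(0.0, 1.0 / np.sqrt(2.0), size=(k, n_samples))
    if source_dist == "mixture":
        # two-component scale mixture of Gaussians, unit variance, super-Gaussian
        comp = rng.random((k, n_samples)) < 0.8
        sd_small, sd_big = 0.5, 2.0
        var = 0.8 * sd_small**2 + 0.2 * sd_big**2
        raw = np.where(
            comp,
            rng.normal(0.0, sd_small, size=(k, n_samples)),
            rng.normal(0.0, sd_big, size=(k, n_samples)),
        )
        return raw / np.sqrt(var)
    if source_dist == "gaussian":
        return rng.normal(0.0, 1.0, size=(k, n_samples))
    raise ValidationError(f"unknown source_dist {source_dist!r}")


def generate_expression(
    n_genes: int = 300,
    n_samples: int = 600,
    k: int = 6,
    source_dist: str = "laplace",
    loading_block: float = 1.0,
    background_sd: float = 0.05,
    noise_sd: float = 0.1,
    seed: int = 0,
    set_size: int = 20,
) -> tuple[ExpressionMatrix, PlantedGroundTruth]:
    """Expression matrix X = A S + eps with planted gene sets.

    The first ``k * set_size`` genes are partitioned into ``k`` planted sets;
    set ``b`` loads ``loading_block`` on source ``b`` in addition to dense
    N(0, background_sd^2) background loadings shared by all genes. Sources
    are i.i.d. unit-variance rows of the chosen distribution; noise is
    N(0, noise_sd^2). Everything is deterministic under ``seed``.
    """
    if k < 1 or n_genes < 2 or n_samples < 3:
        raise ValidationError("invalid sizes")
    if k > min(n_genes, n_samples) / 10:
        raise ValidationError(
            f"k={k} too large for {n_genes} genes x {n_samples} samples "
            "(need k <= min/10 for identifiable structure)"
        )
    if k * set_size > n_genes:
        raise ValidationError(f"{k} planted sets of size {set_size} exceed n_genes")
    if loading_block <= background_sd:
        raise ValidationError("loading_block must exceed background_sd")

    rng = np.random.default_rng(seed)
    S = _draw_sources(k, n_samples, source_dist, rng)
    A = rng.normal(0.0, background_sd, size=(n_genes, k))
    gene_ids = [f"G{i + 1}" for i in range(n_genes)]
    planted_sets: dict[str, dict] = {}
    for b in range(k):
        rows = slice(b * set_size, (b + 1) * set_size)
        A[rows, b] += loading_block
        planted_sets[f"SET{b + 1}"] = {
            "members": gene_ids[rows],
            "column": b,
        }
    noise = rng.normal(0.0, noise_sd, size=(n_genes, n_samples)) if noise_sd > 0 else 0.0
    X = A @ S + noise
    sample_ids = [f"S{j + 1}" for j in range(n_samples)]
    expr = ExpressionMatrix(gene_ids, sample_ids, X)
    truth = PlantedGroundTruth(
        true_mixing=A,
        true_sources=S,
        planted_sets=planted_sets,
        noise_sd=noise_sd,
        seed=seed,
    )
    return expr, truth


def planted_collection(
    truth: PlantedGroundTruth, universe, name: str = "planted"
) -> GeneSetCollection:
    """The planted sets as a :class:`GeneSetCollection` over ``universe``."""
    sets = {n: tuple(d["members"]) for n, d in truth.planted_sets.items()}
    sizes = [len(m) for m in sets.values()]
    return GeneSetCollection(
        name=name, universe=frozenset(universe), sets=sets,
        size_bounds=(min(sizes), max(sizes)),
    )


def generate_random_collection(
    universe,
    n_sets: int,
    size_range: tuple[int, int] = (10, 50),
    seed: int = 0,
    name: str = "random",
) -> GeneSetCollection:
    """Structure-free random gene sets: uniform memberships, fixed seed.

    Used for permutation-null calibration checks; set sizes are drawn
    uniformly from ``size_range``.
    """
    universe = sorted(str(g).strip() for g in universe)
    lo, hi = size_range
    if not 1 <= lo <= hi <= len(universe):
        raise ValidationError(f"size_range {size_range} invalid for |universe|={len(universe)}")
    rng = np.random.default_rng(seed)
    sets = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        sets[f"RAND{i + 1}"] = tuple(universe[j] for j in sorted(members))
    return GeneSetCollection(
        name=name, universe=frozenset(universe), sets=sets, size_bounds=(lo, hi)
    )
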