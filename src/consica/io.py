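"""Readers, writers and filters for expression matrices, gene set collections
and prediction-score tables.

Expression matrices are genes x samples on a normalized/log scale; the genes
are the observed variables of the decomposition. Gene set collections follow
the Broad GMT dialect (set name TAB description TAB member ids). Both a
tab-separated text format and an HDF5 container are supported for matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "PredictionScoreTable",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "qc_filter_samples",
    "read_score_table",
    "write_score_table",
]


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with identifier axes.

    Values are assumed already normalized and on a log-like continuous
    scale; no missing values are allowed.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g).strip() for g in self.gene_ids]
        self.sample_ids = [str(s).strip() for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        n_genes, n_samples = self.values.shape
        if n_genes != len(self.gene_ids) or n_samples != len(self.sample_ids):
            raise ValidationError(
                f"shape {self.values.shape} does not match id lists "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        if n_genes < 2 or n_samples < 3:
            raise ValidationError("need at least 2 genes and 3 samples")
        if len(set(self.gene_ids)) != n_genes:
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if len(set(self.sample_ids)) != n_samples:
            raise ValidationError("duplicate sample ids")
        if not np.isfinite(self.values).all():
            raise ValidationError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, keep: list[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in keep]
        return ExpressionMatrix(self.gene_ids, keep, self.values[:, idx])


@dataclass
class GeneSetCollection:
    """Named gene sets over a declared gene universe.

    ``sets`` maps set name to an ordered tuple of member ids; every member is
    guaranteed to be in ``universe``. ``size_bounds`` records the filter that
    was applied.
    """

    name: str
    universe: frozenset[str]
    sets: dict[str, tuple[str, ...]]
    size_bounds: tuple[int, int] = (10, 500)

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe)
        lo, hi = self.size_bounds
        for set_name, members in self.sets.items():
            members = tuple(dict.fromkeys(members))  # dedupe, keep order
            stray = [m for m in members if m not in self.universe]
            if stray:
                raise ValidationError(
                    f"set {set_name!r} has members outside the universe: {stray[:5]}"
                )
            if not lo <= len(members) <= hi:
                raise ValidationError(
                    f"set {set_name!r} has {len(members)} members, "
                    f"outside bounds [{lo}, {hi}]"
                )
            self.sets[set_name] = members

    @property
    def set_names(self) -> list[str]:
        return list(self.sets)

    def member_mask(self, gene_order: list[str]) -> pd.DataFrame:
        """Boolean genes x sets membership table in the given gene order."""
        gene_index = {g: i for i, g in enumerate(gene_order)}
        mask = np.zeros((len(gene_order), len(self.sets)), dtype=bool)
        for j, members in enumerate(self.sets.values()):
            for m in members:
                if m in gene_index:
                    mask[gene_index[m], j] = True
        return pd.DataFrame(mask, index=gene_order, columns=self.set_names)

    def nonmember_genes(self, gene_order: list[str]) -> list[str]:
        """Genes of ``gene_order`` that belong to no set in the collection."""
        assigned = set()
        for members in self.sets.values():
            assigned.update(members)
        return [g for g in gene_order if g not in assigned]


@dataclass
class PredictionScoreTable:
    """Genes x gene-sets Z-score table for one collection and one method."""

    gene_ids: list[str]
    set_names: list[str]
    scores: np.ndarray
    method_tag: str = "ica"
    collection_name: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.gene_ids), len(self.set_names)):
            raise ValidationError("score matrix shape does not match id lists")
        if not np.isfinite(self.scores).all():
            raise ValidationError("scores must be finite")
        if self.method_tag not in ("ica", "pca"):
            raise ValidationError("method_tag must be 'ica' or 'pca'")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.gene_ids, columns=self.set_names)


# ---------------------------------------------------------------------------
# expression matrix I/O


def read_expression(path: str | Path, format: str = "auto") -> ExpressionMatrix:
    """Read a genes x samples matrix from TSV or the HDF5 container.

    The delimited dialect is tab-separated UTF-8 with a header row of sample
    ids and gene ids in the first column. ``format`` is one of ``"delimited"``,
    ``"binary"`` or ``"auto"`` (sniff by extension).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "binary" if path.suffix in (".h5", ".hdf5") else "delimited"
    if format == "binary":
        with h5py.File(path, "r") as f:
            genes = [g.decode() for g in f["gene_ids"][:]]
            samples = [s.decode() for s in f["sample_ids"][:]]
            values = f["values"][:]
        return ExpressionMatrix(genes, samples, values)
    if format != "delimited":
        raise ValueError(f"unknown format {format!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValidationError(f"malformed expression file {path}: {exc}") from exc
    if df.isna().to_numpy().any():
        bad = int(np.argwhere(df.isna().to_numpy())[0, 0]) + 2  # +header +1-based
        raise ValidationError(f"malformed row near line {bad} of {path}")
    return ExpressionMatrix(list(df.index), list(df.columns), df.to_numpy(dtype=float))


def write_expression(X: ExpressionMatrix, path: str | Path, format: str = "auto") -> None:
    path = Path(path)
    if format == "auto":
        format = "binary" if path.suffix in (".h5", ".hdf5") else "delimited"
    if format == "binary":
        with h5py.File(path, "w") as f:
            f.create_dataset("gene_ids", data=np.array(X.gene_ids, dtype="S"))
            f.create_dataset("sample_ids", data=np.array(X.sample_ids, dtype="S"))
            f.create_dataset("values", data=X.values)
        return
    df = pd.DataFrame(X.values, index=X.gene_ids, columns=X.sample_ids)
    df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


# ---------------------------------------------------------------------------
# GMT


def read_gmt(
    path: str | Path,
    universe,
    min_size: int = 10,
    max_size: int = 500,
    name: str | None = None,
) -> GeneSetCollection:
    """Read a GMT collection, harmonize to ``universe`` and size-filter.

    Members are intersected with the universe *before* the size filter, so a
    set is judged on its usable members. Sets with fewer than ``min_size`` or
    more than ``max_size`` surviving members are dropped (the standard 10-500
    range by default). Sets that lose all members are dropped silently, with
    a log record.
    """
    path = Path(path)
    universe = frozenset(str(g).strip() for g in universe)
    sets: dict[str, tuple[str, ...]] = {}
    n_lines = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs name, description, members"
                )
            set_name = fields[0].strip()
            members = tuple(
                dict.fromkeys(m.strip() for m in fields[2:] if m.strip() in universe)
            )
            if not members:
                logger.info("GMT set %r: no members in universe, dropped", set_name)
                continue
            if not min_size <= len(members) <= max_size:
                logger.info(
                    "GMT set %r: %d usable members outside [%d, %d], dropped",
                    set_name, len(members), min_size, max_size,
                )
                continue
            if set_name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {set_name!r}")
            sets[set_name] = members
    if n_lines == 0:
        raise ValidationError(f"empty GMT file: {path}")
    return GeneSetCollection(
        name=name or path.stem,
        universe=universe,
        sets=sets,
        size_bounds=(min_size, max_size),
    )


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_name, members in collection.sets.items():
            fh.write("\t".join([set_name, "na", *members]) + "\n")


def filter_collection(
    collection: GeneSetCollection,
    universe,
    min_size: int = 10,
    max_size: int = 500,
) -> GeneSetCollection:
    """Re-harmonize an in-memory collection to a universe and size-filter.

    Idempotent: filtering an already-filtered collection is a no-op.
    """
    universe = frozenset(str(g).strip() for g in universe)
    sets = {}
    for set_name, members in collection.sets.items():
        kept = tuple(m for m in members if m in universe)
        if min_size <= len(kept) <= max_size:
            sets[set_name] = kept
    return GeneSetCollection(collection.name, universe, sets, (min_size, max_size))


# ---------------------------------------------------------------------------
# sample QC


def qc_filter_samples(
    X: ExpressionMatrix, r_min: float = 0.8
) -> tuple[ExpressionMatrix, list[str]]:
    """Discard samples that do not track the dominant correlation structure.

    The first principal component of the sample-sample Pearson correlation
    matrix nearly always captures a platform-wide signature; samples whose
    expression profile correlates with that component below ``r_min`` are
    discarded. The component's sign is chosen so that the majority of sample
    correlations are positive, making the filter deterministic.
    """
    C = np.corrcoef(X.values, rowvar=False)  # samples x samples
    eigvals, eigvecs = np.linalg.eigh(C)
    v = eigvecs[:, -1]  # leading eigenvector over samples
    # gene-space image of the component: PC1-weighted combination of the raw
    # sample profiles (centering the genes first would annihilate the shared
    # signature the component captures)
    g = X.values @ v
    g_c = g - g.mean()
    g_norm = np.linalg.norm(g_c)
    if g_norm == 0:
        raise ValidationError("degenerate expression matrix: component has no variance")
    prof = X.values - X.values.mean(axis=0, keepdims=True)
    denom = np.linalg.norm(prof, axis=0) * g_norm
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (prof.T @ g_c) / denom
    r = np.nan_to_num(r, nan=0.0)
    if np.sum(r > 0) < np.sum(r < 0):
        r = -r
    keep = r >= r_min
    discarded = [s for s, k in zip(X.sample_ids, keep) if not k]
    if not keep.any() or keep.sum() < 3:
        raise ValidationError(
            f"sample QC at r_min={r_min} leaves {int(keep.sum())} samples (<3)"
        )
    kept_ids = [s for s, k in zip(X.sample_ids, keep) if k]
    return ExpressionMatrix(X.gene_ids, kept_ids, X.values[:, keep]), discarded


# ---------------------------------------------------------------------------
# score tables


def write_score_table(table: PredictionScoreTable, path: str | Path) -> None:
    """Write a score table as TSV (genes as rows) with a JSON sidecar."""
    import json

    path = Path(path)
    table.to_frame().to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")
    sidecar = dict(table.provenance)
    sidecar.update(
        method=table.method_tag,
        collection=table.collection_name,
        n_genes=len(table.gene_ids),
        n_sets=len(table.set_names),
    )
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_score_table(
    path: str | Path, method_tag: str = "ica", collection_name: str = ""
) -> PredictionScoreTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return PredictionScoreTable(
        list(df.index), list(df.columns), df.to_numpy(dtype=float),
        method_tag=method_tag, collection_name=collection_name,
    )
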