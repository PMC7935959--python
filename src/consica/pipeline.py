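"""One-command orchestration of the full analysis flow.

Stages, in order: sample QC -> whitening -> consensus ICA -> mixing-matrix
recomputation -> prediction scoring -> evaluation. A flat key-value config
file drives the run; every artifact carries the config hash so a rerun with
the same config is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import decomposition, evaluation, gba
from .io import (
    ExpressionMatrix,
    ValidationError,
    qc_filter_samples,
    read_expression,
    read_gmt,
    write_score_table,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

_DEFAULTS = {
    "qc_r_min": 0.8,
    "qc_enabled": True,
    "var_threshold": 0.90,
    "n_runs": 25,
    "match_r": 0.98,
    "min_match_runs": 13,
    "method": "ica",
    "n_perm": 1000,
    "p_mode": "permutation",
    "min_set_size": 10,
    "max_set_size": 500,
    "evaluate": True,
}


@dataclass
class RunConfig:
    """Validated pipeline configuration; ``seed`` is mandatory."""

    expression: Path
    gmt: list[Path]
    out_dir: Path
    seed: int
    params: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a flat ``key = value`` config file ('#' comments allowed)."""
        path = Path(path)
        raw: dict[str, str] = {}
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            raw[key] = value
        for required in ("expression", "gmt", "out_dir", "seed"):
            if required not in raw:
                raise ValidationError(f"config is missing required key {required!r}")
        params = dict(_DEFAULTS)
        for key, value in raw.items():
            if key in ("expression", "gmt", "out_dir", "seed"):
                continue
            if key not in params:
                raise ValidationError(f"unknown config key {key!r}")
            default = params[key]
            if isinstance(default, bool):
                params[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                params[key] = int(value)
            elif isinstance(default, float):
                params[key] = float(value)
            else:
                params[key] = value
        cfg = cls(
            expression=Path(raw["expression"]),
            gmt=[Path(p.strip()) for p in raw["gmt"].split(",") if p.strip()],
            out_dir=Path(raw["out_dir"]),
            seed=int(raw["seed"]),
            params=params,
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.expression.exists():
            raise ValidationError(f"expression file not found: {self.expression}")
        for g in self.gmt:
            if not g.exists():
                raise ValidationError(f"GMT file not found: {g}")
        p = self.params
        if not 0.0 < p["var_threshold"] <= 1.0:
            raise ValidationError(f"var_threshold {p['var_threshold']} outside (0, 1]")
        if p["method"] not in ("ica", "pca"):
            raise ValidationError("method must be 'ica' or 'pca'")
        if not 1 <= p["min_match_runs"] <= p["n_runs"]:
            raise ValidationError("need 1 <= min_match_runs <= n_runs")

    def config_hash(self) -> str:
        payload = {
            "expression": str(self.expression),
            "gmt": [str(g) for g in self.gmt],
            "seed": self.seed,
            **{k: self.params[k] for k in sorted(self.params)},
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage_seeds(seed: int) -> dict[str, int]:
    """Fan one global seed out to per-stage deterministic seeds."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(3)
    names = ("ica", "score", "aux")
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the output directory.

    Any stage failure aborts with the stage name; artifacts written by earlier
    stages are preserved. Reruns with an identical config reproduce identical
    outputs.
    """
    config.validate()
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    seeds = _stage_seeds(config.seed)
    p = config.params
    log_path = out / "pipeline.log"
    timings: list[str] = []

    def _log(stage: str, t0: float) -> None:
        msg = f"{stage}\t{time.perf_counter() - t0:.2f}s"
        timings.append(msg)
        logger.info("stage %s", msg)

    stage = "load"
    try:
        t0 = time.perf_counter()
        X = read_expression(config.expression)
        _log(stage, t0)

        stage = "qc"
        t0 = time.perf_counter()
        discarded: list[str] = []
        if p["qc_enabled"]:
            X, discarded = qc_filter_samples(X, r_min=p["qc_r_min"])
        _log(stage, t0)

        stage = "whiten"
        t0 = time.perf_counter()
        basis = decomposition.whiten(X, var_threshold=p["var_threshold"])
        _log(stage, t0)

        stage = "consensus-ica"
        t0 = time.perf_counter()
        mm_w, sources, report = decomposition.run_consensus_ica(
            basis,
            n_runs=p["n_runs"],
            match_r=p["match_r"],
            min_match_runs=p["min_match_runs"],
            seed=seeds["ica"],
        )
        _log(stage, t0)

        stage = "recompute-mixing"
        t0 = time.perf_counter()
        MM = decomposition.recompute_mixing(X, sources, mm_w)
        _log(stage, t0)

        mixing_df = pd.DataFrame(MM.weights, index=MM.gene_ids, columns=MM.component_ids)
        mixing_df.to_csv(out / "mixing_matrix.tsv", sep="\t",
                         index_label="gene_id", float_format="%.17g")
        (out / "consensus_report.json").write_text(json.dumps({
            "config_hash": chash,
            "discarded_samples": discarded,
            "n_pc": basis.n_pc,
            "explained_fraction_sum": float(basis.explained_fraction.sum()),
            "credibility": [float(c) for c in MM.credibility],
            **report.to_dict(),
        }, indent=2))

        stage = "score"
        results = {}
        for gmt_path in config.gmt:
            t0 = time.perf_counter()
            collection = read_gmt(
                gmt_path, universe=X.gene_ids,
                min_size=p["min_set_size"], max_size=p["max_set_size"],
            )
            table = gba.score_all(
                MM, collection,
                method=p["method"],
                basis=basis if p["method"] == "pca" else None,
                n_perm=p["n_perm"],
                seed=seeds["score"],
                p_mode=p["p_mode"],
            )
            table.provenance["config_hash"] = chash
            score_path = out / f"scores_{collection.name}_{p['method']}.tsv"
            write_score_table(table, score_path)
            results[collection.name] = (table, collection)
            _log(f"score:{collection.name}", t0)

        if p["evaluate"]:
            stage = "evaluate"
            t0 = time.perf_counter()
            for name, (table, collection) in results.items():
                summary = evaluation.evaluate_collection(table, collection)
                summary.per_set.to_csv(out / f"evaluation_{name}.tsv", sep="\t")
                mf = evaluation.multifunctionality(collection)
                mf.to_series().to_csv(out / f"multifunctionality_{name}.tsv", sep="\t")
                (out / f"evaluation_{name}.json").write_text(json.dumps({
                    "config_hash": chash,
                    "auc_member_vs_nonmember_medians": summary.auc,
                    "auc_p": summary.auc_p,
                }, indent=2))
            _log(stage, t0)
    except Exception as exc:
        log_path.write_text("\n".join(timings + [f"FAILED at stage {stage}: {exc}"]))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    log_path.write_text("\n".join(timings) + "\n")
    (out / "run_config.json").write_text(json.dumps({
        "config_hash": chash,
        "expression": str(config.expression),
        "gmt": [str(g) for g in config.gmt],
        "seed": config.seed,
        **config.params,
    }, indent=2))
    return out
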