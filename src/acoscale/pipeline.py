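"""End-to-end orchestration of the two studies.

``run_structure_study`` fits the nine competing factor configurations to
one dataset and emits a fit-index table (one row per model) plus a
reliability table (ordinal alpha and hierarchical omega per scale and
model).  ``run_shortform_study`` runs the ant colony, evaluates the winning
20-item form (fit, reliabilities, group separation, ROC/cutoff statistics),
and benchmarks it against random quota-respecting item subsets.

Both take a :class:`RunConfig` that either points at response/scale-map CSV
files or carries a synthetic-generation block; a single top-level seed fans
out deterministically to the generation, colony and baseline stages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cfa as _cfa
from .aco import AcoConfig, CandidateEvaluator, run_aco
from .baseline import combination_count, random_subsets, summarize_baseline
from .polychoric import polychoric_matrix
from .reliability import reliability_report
from .simulate import (
    DOMAINS,
    ItemResponseTable,
    ScaleMap,
    make_default_true_model,
    simulate_responses,
)

logger = logging.getLogger("acoscale")

__all__ = ["RunConfig", "load_data", "run_structure_study", "run_shortform_study", "run_all"]

ALL_MODELS = ("1", "2", "3", "4", "5", "6a", "6b", "7a", "7b")


@dataclass
class SyntheticBlock:
    """Parameters of the built-in data generator."""

    structure: str = "hierarchical"
    n_items_per_domain: tuple = (25, 24, 24, 24)
    n_control: int = 337
    n_patient: int = 96
    group_shift: float = 2.1
    missing_rate: float = 0.0


@dataclass
class RunConfig:
    responses_csv: str | None = None
    scale_map_csv: str | None = None
    synthetic: SyntheticBlock | None = None
    models: tuple = ALL_MODELS
    aco: AcoConfig = field(default_factory=AcoConfig)
    n_baseline_draws: int = 1000
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        from_files = self.responses_csv is not None
        if from_files == (self.synthetic is not None):
            raise ValueError(
                "exactly one of responses_csv / synthetic block must be given"
            )
        if from_files and self.scale_map_csv is None:
            raise ValueError("responses_csv requires scale_map_csv")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticBlock(**raw["synthetic"])
        if "aco" in raw and raw["aco"] is not None:
            raw["aco"] = AcoConfig(**raw["aco"])
        if "models" in raw:
            raw["models"] = tuple(str(m) for m in raw["models"])
        return cls(**raw)


def _stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (< 2**31) from the top-level seed."""
    import zlib

    ss = np.random.SeedSequence([seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def load_data(config: RunConfig) -> tuple[ItemResponseTable, ScaleMap]:
    if config.responses_csv is not None:
        table = ItemResponseTable.from_csv(config.responses_csv)
        scale_map = ScaleMap.from_csv(config.scale_map_csv)
        missing = set(table.item_ids) - set(scale_map.item_ids)
        if missing:
            raise ValueError(f"items not in scale map: {sorted(missing)[:5]} ...")
        return table, scale_map
    blk = config.synthetic
    model = make_default_true_model(
        n_items_per_domain=blk.n_items_per_domain,
        structure=blk.structure,
        seed=_stage_seed(config.seed, "truth"),
        group_shift=blk.group_shift,
    )
    table = simulate_responses(
        model,
        blk.n_control,
        blk.n_patient,
        seed=_stage_seed(config.seed, "responses"),
        missing_rate=blk.missing_rate,
    )
    return table, model.scale_map


def run_structure_study(
    config: RunConfig, *, data=None
) -> dict:
    """Fit the requested configurations; return fit and reliability tables."""
    table, scale_map = data if data is not None else load_data(config)
    n = table.n_respondents
    logger.info("estimating polychoric matrix for %d items, n=%d", table.n_items, n)
    matrix = polychoric_matrix(table)
    if matrix.smoothed:
        logger.warning("polychoric matrix smoothed to PSD")

    fit_rows = []
    rel_frames = {}
    fits = {}
    for mid in config.models:
        spec = _cfa.build_model(mid, scale_map, item_ids=table.item_ids)
        fit = _cfa.fit_cfa(matrix, spec, n=n)
        fits[mid] = fit
        if not fit.identified:
            logger.warning(
                "model %s not identified (singular-value ratio %.1e); "
                "parameters reported for completeness only",
                mid, fit.min_singular_ratio,
            )
        fit_rows.append(
            {
                "model_id": mid,
                "factors": spec.n_factors,
                "par": fit.n_par,
                "chi_square": round(fit.chi_square, 1),
                "df": fit.df,
                "CFI": round(fit.cfi, 3),
                "RMSEA": round(fit.rmsea, 3),
                "SRMR": round(fit.srmr, 3),
                "classification": _cfa.classify_fit(fit),
                "converged": fit.converged,
                "identified": fit.identified,
            }
        )
        rel = reliability_report(matrix, fit, scale_map)
        rel_frames[mid] = rel.to_frame()

    fit_table = pd.DataFrame(fit_rows)
    for col in ("CFI", "RMSEA", "SRMR"):
        good = fit_table.loc[fit_table.identified, col]
        best = good.max() if col == "CFI" else good.min()
        fit_table[f"best_{col}"] = fit_table[col].eq(best) & fit_table.identified

    alpha = pd.DataFrame({m: f["ordinal_alpha"] for m, f in rel_frames.items()})
    omega_h = pd.DataFrame({m: f["omega_hierarchical"] for m, f in rel_frames.items()})
    out = {
        "fit_table": fit_table,
        "ordinal_alpha": alpha,
        "omega_hierarchical": omega_h,
        "fits": fits,
        "matrix": matrix,
    }
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        fit_table.to_csv(outdir / "structure_fit_indices.csv", index=False)
        alpha.to_csv(outdir / "structure_ordinal_alpha.csv")
        omega_h.to_csv(outdir / "structure_omega_hierarchical.csv")
    return out


def run_shortform_study(config: RunConfig, *, data=None, matrix=None) -> dict:
    """Ant-colony short form + random-combination benchmark + utility panel."""
    table, scale_map = data if data is not None else load_data(config)
    logger.info(
        "short-form scoring: ULS chi2=(n-1)F convention; logistic gates %s; "
        "evaporation %.2f, iteration-best deposit (reconstructed defaults)",
        {k: (v.center, v.scale, v.direction) for k, v in config.aco.phi_params.items()},
        config.aco.evaporation_rate,
    )
    aco_cfg = dataclasses.replace(config.aco, seed=_stage_seed(config.seed, "aco"))
    ev = CandidateEvaluator(table, scale_map, aco_cfg, matrix=matrix)
    result = run_aco(table, scale_map, aco_cfg, evaluator=ev)

    rng = np.random.default_rng(_stage_seed(config.seed, "baseline"))
    subsets = random_subsets(
        scale_map, aco_cfg.per_domain_quota, config.n_baseline_draws, rng,
        item_ids=table.item_ids,
    )
    baseline = summarize_baseline(subsets, table, scale_map, evaluator=ev)

    aco_metrics = result.score.raw
    scatter = baseline.per_draw[["cfi", "rmsea", "srmr", "adj_r2", "total"]].copy()
    scatter["source"] = "random"
    aco_row = {
        "cfi": aco_metrics["cfi"],
        "rmsea": aco_metrics["rmsea"],
        "srmr": aco_metrics["srmr"],
        "adj_r2": aco_metrics["adj_r2"],
        "total": result.score.total,
        "source": "aco",
    }
    scatter = pd.concat([scatter, pd.DataFrame([aco_row])], ignore_index=True)

    sizes = [len(scale_map.items_in(d)) for d in DOMAINS]
    n_space = combination_count(sizes, aco_cfg.per_domain_quota)
    report = {
        "shortform": result.to_dict(),
        "validity": result.validity.to_dict(),
        "reliability": {
            "ordinal_alpha": result.reliability.ordinal_alpha,
            "omega_hierarchical": result.reliability.omega_hierarchical,
        },
        "baseline": baseline.to_dict(),
        "search_space_size": str(n_space),
        "classification": _cfa.classify_fit(result.fit),
    }
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "shortform_report.json", "w") as fh:
            json.dump(report, fh, indent=1)
        scatter.to_csv(outdir / "shortform_scatter.csv", index=False)
    return {
        "result": result,
        "baseline": baseline,
        "scatter": scatter,
        "report": report,
        "evaluator": ev,
    }


def run_all(config: RunConfig) -> dict:
    data = load_data(config)
    structure = run_structure_study(config, data=data)
    shortform = run_shortform_study(config, data=data, matrix=structure["matrix"])
    return {"structure": structure, "shortform": shortform}
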