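"""End-to-end orchestration: effects -> outlier screen -> pooled fits ->
subgroups -> meta-regressions -> litter/time sensitivity -> Mantel suite.

All randomness derives from one root seed, expanded deterministically
per stage, so a rerun with the same config is byte-identical (the JSON
report carries no timestamps; wall-clock context goes to the log file).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mantel as mantel_mod
from .dataset import ExperimentDataset, read_dataset
from .effects import EffectConfig, EffectTable, compute_effect_table, integrate_over_time, litter_type_cv
from .errors import DecompMetaError
from .meta import fit_random_effects, flag_outliers, meta_regression, subgroup_analysis

logger = logging.getLogger(__name__)

SUBGROUP_FACTORS = ("setting", "environment", "inoculum_complexity", "inoculum_taxa")
METAREG_MODERATORS = (
    "max_richness",
    "time_days",
    "litter_cn",
    "litter_lignin_pct",
    "n_inoculum_treatments",
)

#: the three intercept-only pools: the unitless CV across all studies,
#: and D split by response units
INTERCEPT_POOLS = {
    "CV": {"metric": "CV"},
    "D_ML": {"metric": "D", "response_type": "mass_loss_pct"},
    "D_CO2": {"metric": "D", "response_type": "co2_cum_mg_per_g"},
}


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a full analysis run."""

    summaries_path: str | None = None
    moderators_path: str | None = None
    scores_path: str | None = None  # ordination scores CSV; None skips Mantel
    output_dir: str = "decompmeta_out"
    seed: int = 1
    n_boot: int = 2000
    epsilon: float = 1e-8
    time_integration: str = "mean_trajectory"
    outlier_threshold: float = 3.0
    observation_level_component: bool = True
    subgroup_factors: tuple = SUBGROUP_FACTORS
    metareg_moderators: tuple = METAREG_MODERATORS
    n_perm: int = 9999
    mantel_alternative: str = "greater"
    mantel_method: str = "pearson"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("subgroup_factors", "metareg_moderators"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _stage_seed(root: int, stage: str) -> int:
    import zlib

    return int(
        np.random.SeedSequence([int(root), zlib.crc32(stage.encode())])
        .generate_state(1)[0]
        & 0x7FFFFFFF
    )


def _fit_json(fit) -> dict:
    return fit.to_dict()


def run_pipeline(
    config: PipelineConfig,
    dataset: ExperimentDataset | None = None,
    scores: pd.DataFrame | None = None,
) -> dict:
    """Run the full analysis; returns the report dict and writes all
    artefacts (CSV tables, report.json, exclusions.csv, pipeline.log)
    under ``config.output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    root_logger = logging.getLogger("decompmeta")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)
    try:
        return _run(config, dataset, scores, out)
    finally:
        root_logger.removeHandler(handler)
        handler.close()


def _run(config, dataset, scores, out: Path) -> dict:
    if dataset is None:
        if not (config.summaries_path and config.moderators_path):
            raise ValueError("config must name summaries/moderators paths")
        dataset = read_dataset(config.summaries_path, config.moderators_path)
    if scores is None and config.scores_path:
        scores = pd.read_csv(config.scores_path)

    tau_within = "estimate" if config.observation_level_component else 0.0
    ecfg = EffectConfig(
        n_boot=config.n_boot,
        seed=_stage_seed(config.seed, "effects"),
        epsilon=config.epsilon,
        time_integration=config.time_integration,
    )
    logger.info("computing effect table (n_boot=%d)", ecfg.n_boot)
    effects = compute_effect_table(dataset, ecfg)
    effects.to_csv(out / "effects.csv")

    # the config echo drops output_dir: the analysis is independent of
    # where its artefacts land, and reruns should be byte-comparable
    cfg_echo = asdict(config)
    cfg_echo.pop("output_dir")
    report = {
        "config": cfg_echo,
        "n_studies": len(dataset.study_ids),
        "n_effect_observations": int((effects.records["metric"] == "CV").sum()),
        "variance_structure": {
            "study_level": True,
            "observation_level": config.observation_level_component,
        },
    }
    exclusions = []

    # ---- intercept-only pools with one-pass outlier screening ----------
    report["intercept_fits"] = {}
    report["outliers"] = {}
    kept_pools = {}
    for name, cond in INTERCEPT_POOLS.items():
        pool = effects.filter(**cond)
        if len(pool) < 2:
            logger.warning("pool %s has %d effect(s); skipped", name, len(pool))
            report["intercept_fits"][name] = {"skipped": f"{len(pool)} effect(s)"}
            continue
        fit, oreport, kept = _screen(pool, config.outlier_threshold, tau_within)
        kept_pools[name] = kept
        report["intercept_fits"][name] = _fit_json(fit)
        flagged_rows = pool.records.loc[oreport.flagged]
        report["outliers"][name] = {
            "threshold": config.outlier_threshold,
            "n_flagged": len(oreport.flagged),
            "flagged": flagged_rows[
                ["study_id", "litter_id", "time_days", "response_type"]
            ].to_dict(orient="records"),
        }
        for _, row in flagged_rows.iterrows():
            exclusions.append(
                {
                    "stage": f"outlier_screen:{name}",
                    "study_id": row["study_id"],
                    "litter_id": row["litter_id"],
                    "time_days": row["time_days"],
                    "reason": f"|z| > {config.outlier_threshold}",
                }
            )
        logger.info(
            "%s: pooled=%.4f (k=%d, %d outlier(s) excluded)",
            name,
            fit.pooled_estimate,
            fit.k_effects,
            len(oreport.flagged),
        )

    cv_kept = kept_pools.get("CV", effects.filter(metric="CV"))

    # ---- subgroups on the CV pool --------------------------------------
    report["subgroups"] = {}
    for factor in config.subgroup_factors:
        try:
            sg = subgroup_analysis(
                cv_kept, dataset.moderators, factor, tau2_within=tau_within
            )
        except (DecompMetaError, ValueError) as exc:
            logger.warning("subgroup %s failed: %s", factor, exc)
            report["subgroups"][factor] = {"skipped": str(exc)}
            continue
        report["subgroups"][factor] = sg.to_dict()
        sg.per_level.to_csv(out / f"subgroup_{factor}.csv", index=False)

    # ---- meta-regressions on the CV pool --------------------------------
    metareg_rows = []
    report["meta_regressions"] = {}
    for mod in config.metareg_moderators:
        try:
            mr = meta_regression(
                cv_kept, dataset.moderators, mod, tau2_within=tau_within
            )
        except (DecompMetaError, ValueError, KeyError) as exc:
            logger.warning("meta-regression %s failed: %s", mod, exc)
            report["meta_regressions"][mod] = {"skipped": str(exc)}
            metareg_rows.append(
                {"moderator": mod, "beta": np.nan, "se": np.nan, "p": np.nan,
                 "k_effects": 0, "note": str(exc)}
            )
            continue
        slope = mr.coefficients.iloc[1]
        report["meta_regressions"][mod] = mr.to_dict()
        metareg_rows.append(
            {
                "moderator": mod,
                "beta": float(slope["beta"]),
                "se": float(slope["se"]),
                "p": float(slope["p"]),
                "k_effects": mr.k_effects,
                "note": "",
            }
        )
    pd.DataFrame(metareg_rows).to_csv(out / "meta_regressions.csv", index=False)

    # ---- litter-chemistry CV --------------------------------------------
    lit_cfg = EffectConfig(
        n_boot=config.n_boot,
        seed=_stage_seed(config.seed, "litter_cv"),
        epsilon=config.epsilon,
    )
    lit = litter_type_cv(dataset, lit_cfg)
    lit.to_csv(out / "litter_type_cv.csv")
    if len(lit) >= 2:
        lfit, _, _ = _screen(lit, config.outlier_threshold, tau_within)
        report["litter_type_cv"] = _fit_json(lfit)
    else:
        report["litter_type_cv"] = {"skipped": f"{len(lit)} record(s)"}

    # ---- time-integrated sensitivity ------------------------------------
    ti_cfg = EffectConfig(
        n_boot=config.n_boot,
        seed=_stage_seed(config.seed, "time_integrated"),
        epsilon=config.epsilon,
        time_integration=config.time_integration,
    )
    ti = integrate_over_time(dataset, ti_cfg).filter(metric="CV")
    ti.to_csv(out / "time_integrated_cv.csv")
    if len(ti) >= 2:
        tfit, _, _ = _screen(ti, config.outlier_threshold, tau_within)
        report["time_integrated_cv"] = _fit_json(tfit)
    else:
        report["time_integrated_cv"] = {"skipped": f"{len(ti)} record(s)"}

    # ---- Mantel suite ----------------------------------------------------
    if scores is not None and len(scores):
        results = mantel_mod.run_mantel_suite(
            dataset,
            scores,
            n_perm=config.n_perm,
            seed=_stage_seed(config.seed, "mantel"),
            alternative=config.mantel_alternative,
            method=config.mantel_method,
        )
        mantel_mod.results_to_frame(results).to_csv(out / "mantel.csv", index=False)
        report["mantel"] = [r.to_dict() for r in results]
    else:
        report["mantel"] = "skipped"
        logger.info("no community inputs provided; Mantel section skipped")

    pd.DataFrame(
        exclusions,
        columns=["stage", "study_id", "litter_id", "time_days", "reason"],
    ).to_csv(out / "exclusions.csv", index=False)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return report


def _screen(pool: EffectTable, threshold: float, tau_within):
    """Outlier screen under the configured variance structure: flag once,
    drop, refit once."""
    fit0 = fit_random_effects(pool, tau2_within=tau_within)
    oreport = flag_outliers(pool, threshold, fit=fit0)
    if not oreport.flagged:
        return fit0, oreport, pool
    kept = EffectTable(
        pool.records.drop(index=oreport.flagged).reset_index(drop=True),
        dict(pool.provenance),
    )
    return fit_random_effects(kept, tau2_within=tau_within), oreport, kept


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
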