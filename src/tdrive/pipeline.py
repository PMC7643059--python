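"""End-to-end driver: simulate (or load) litter data, run every estimation
stage, apply the behavioural-polyandry correction, and confront the
simulated genotype-frequency trend with the monandry and polyandry model
predictions."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import drive, inference, io
from .drive import DriveParams, DriveModel, GenotypeDist, monandry_equilibrium
from .popsim import SimConfig, SimResult, simulate

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("tdrive")


@dataclass
class RunConfig:
    """Pipeline configuration: a simulation block (ignored when user tables
    are supplied), output directory and master seed."""

    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: str = "tdrive_run"
    seed: int | None = None
    litters_path: str | None = None
    pedigree_path: str | None = None
    initial_wt_for_prediction: float = 0.25

    def resolved_sim(self) -> SimConfig:
        if self.seed is None:
            return self.sim
        return dataclasses.replace(self.sim, seed=self.seed)


def _try(report: dict, stage: str, fn):
    """Run an estimation stage, recording failures without aborting the
    stages that do not depend on it."""
    try:
        return fn()
    except Exception as exc:  # noqa: BLE001 - reported, not swallowed silently
        logger.warning("stage %s failed: %s", stage, exc)
        report.setdefault("errors", {})[stage] = str(exc)
        return None


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> estimate -> correct -> predict and write all
    outputs under ``config.out_dir``.  Returns the report dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    sim_cfg = config.resolved_sim()
    if config.litters_path:
        litters = io.read_litters(config.litters_path)
        pedigree = io.read_pedigree(config.pedigree_path) if config.pedigree_path else None
        result = SimResult(litters=litters, pedigree=pedigree, gen_counts=pd.DataFrame(), matings=None, config=None)
        report["data_source"] = str(config.litters_path)
    else:
        result = simulate(sim_cfg)
        report["data_source"] = "simulated"
        io.write_litters(result.litters, out / "litters.csv")
        io.write_pedigree(result.pedigree, out / "pedigree.csv")
        result.gen_counts.to_csv(out / "gen_counts.csv", index=False, lineterminator="\n")
        result.matings.to_csv(out / "matings.csv", index=False, lineterminator="\n")

    litters, pedigree = result.litters, result.pedigree
    if litters.empty:
        raise RuntimeError("pipeline aborted at stage 'data': no litters available")

    # --- polyandry -------------------------------------------------------
    poly = _try(report, "polyandry", lambda: inference.estimate_polyandry(litters))
    if poly is not None:
        report["genetic_polyandry"] = dataclasses.asdict(poly)
        pd.DataFrame([dataclasses.asdict(poly)]).to_csv(out / "polyandry.csv", index=False, lineterminator="\n")

    # --- male fitness ----------------------------------------------------
    males = _try(report, "competition_intensity", lambda: inference.competition_intensity(litters, pedigree))
    if males is not None:
        males.to_csv(out / "males.csv", index=False, lineterminator="\n")
        glm = _try(report, "male_fitness_glm", lambda: inference.fit_male_fitness(males))
        if glm is not None:
            report["male_fitness"] = {
                "selected_terms": list(glm.selected_terms),
                "params": glm.params.to_dict(),
                "bse": glm.bse.to_dict(),
                "dispersion": glm.dispersion,
                "deviance_fractions": glm.deviance_fractions,
            }
            coef = pd.DataFrame({"coef": glm.params, "se": glm.bse, "p": glm.pvalues})
            coef.to_csv(out / "fitness_glm.csv", lineterminator="\n")

    # --- drive parameters ------------------------------------------------
    d_hat = _try(report, "drive_strength", lambda: inference.estimate_drive_strength(litters, pedigree))
    c_hat = _try(
        report,
        "competitiveness",
        lambda: inference.estimate_competitiveness(litters, matings=result.matings, pedigree=pedigree),
    )
    params_rows = []
    if d_hat is not None:
        report["d_hat"] = dataclasses.asdict(d_hat)
        params_rows.append({"parameter": "d", **dataclasses.asdict(d_hat)})
    if c_hat is not None:
        report["c_hat"] = dataclasses.asdict(c_hat)
        params_rows.append({"parameter": "c", **dataclasses.asdict(c_hat)})
    if params_rows:
        pd.DataFrame(params_rows).to_csv(out / "params_hat.csv", index=False, lineterminator="\n")

    # --- behavioural correction ------------------------------------------
    c_for_corr = c_hat.estimate if (c_hat is not None and not c_hat.conditional) else sim_cfg.c
    # per-cohort adult male carrier frequencies when the run is simulated
    # (the sire-pair mixture is frequency dependent); pooled otherwise
    if not result.gen_counts.empty:
        wt_freq = {
            int(r["cohort"]): float(r["male_wt"] / r["adult_males"])
            for _, r in result.gen_counts.iterrows()
        }
    elif pedigree is not None:
        wt_freq = float((pedigree["genotype"] == "WT").mean())
    else:
        wt_freq = 0.0
    corr = _try(
        report,
        "behavioural_correction",
        lambda: inference.estimate_behavioural_polyandry(litters, c=c_for_corr, wt_freq=wt_freq)[1],
    )
    if corr is not None:
        report["behavioural_polyandry"] = dataclasses.asdict(corr)

    # --- female selection -------------------------------------------------
    females = _try(report, "female_summaries", lambda: inference.female_summaries(litters))
    if females is not None and not females.empty:
        grad = _try(report, "selection_gradient", lambda: inference.selection_gradient(females))
        if grad is not None:
            report["selection_gradient"] = {
                "gradient": grad.gradient,
                "se": grad.se,
                "pvalue": grad.pvalue,
                "contrast": grad.contrast,
                "contrast_se": grad.contrast_se,
            }
            females.to_csv(out / "selection.csv", index=False, lineterminator="\n")

    # --- model predictions with estimated parameters ----------------------
    d_pred = d_hat.estimate if d_hat is not None else sim_cfg.d
    P_pred = corr.behavioural_rate if corr is not None else (poly.rate if poly else 0.0)
    prediction: dict = {"d": d_pred, "c": c_for_corr, "P": P_pred}
    if d_pred > 0.5:
        prediction["monandry_equilibrium_wt"] = monandry_equilibrium(d_pred)
        thr = drive.invasion_threshold(d_pred, c_for_corr)
        prediction["threshold_P"] = thr.threshold_P
        model = DriveModel(DriveParams(d=d_pred, c=c_for_corr, P=P_pred, max_generations=2000))
        wt_inf = model.long_run_wt(config.initial_wt_for_prediction)
        prediction["long_run_wt"] = wt_inf
        prediction["conclusion"] = "extinction" if wt_inf == 0.0 else "persistence"
        traj = model.trajectory(config.initial_wt_for_prediction)
        traj.to_frame().to_csv(out / "predicted_trajectory.csv", index=False, lineterminator="\n")
    else:
        prediction["conclusion"] = "no drive (d <= 1/2): t cannot persist"
    report["prediction"] = prediction

    counts = {
        "pups": int(len(litters)),
        "litters": int(litters["litter_id"].nunique()),
        "males_with_offspring": 0 if males is None else int(len(males)),
        "females": 0 if females is None else int(len(females)),
    }
    io.write_manifest(out / "manifest.json", sim_cfg if not config.litters_path else config, sim_cfg.seed, counts)
    (out / "report.json").write_text(json.dumps(io._jsonable(report), indent=2) + "\n")
    (out / "report.txt").write_text(_render_report(report))
    return report


def _pct(x: float) -> str:
    return f"{100 * x:.1f}%"


def _render_report(report: dict) -> str:
    lines = ["t-haplotype drive under polyandry — pipeline report", ""]
    gp = report.get("genetic_polyandry")
    if gp:
        lines.append(
            f"Genetic polyandry: {_pct(gp['rate'])} "
            f"({gp['k_multisire']}/{gp['n']} litters; 95% CI {_pct(gp['ci_low'])}-{_pct(gp['ci_high'])})"
        )
    bp = report.get("behavioural_polyandry")
    if bp:
        lines.append(
            f"Behavioural polyandry: {_pct(bp['behavioural_rate'])} "
            f"(misclassified {_pct(bp['misclassified_fraction'])}, "
            f"single-sire prob {_pct(bp['single_sire_prob'])})"
        )
    for key, label in (("d_hat", "drive strength d"), ("c_hat", "competitiveness c")):
        est = report.get(key)
        if est:
            lines.append(
                f"Estimated {label}: {est['estimate']:.4f} "
                f"(95% CI {est['ci_low']:.4f}-{est['ci_high']:.4f}, {est['k']}/{est['n']})"
            )
    pred = report.get("prediction")
    if pred:
        lines.append("")
        lines.append("Model prediction with estimated parameters:")
        if "monandry_equilibrium_wt" in pred:
            lines.append(f"  monandry equilibrium +/t: {_pct(pred['monandry_equilibrium_wt'])}")
        if pred.get("threshold_P") is not None:
            lines.append(f"  extinction threshold polyandry rate: {_pct(pred['threshold_P'])}")
        if "long_run_wt" in pred:
            lines.append(f"  long-run +/t at P={_pct(pred['P'])}: {_pct(pred['long_run_wt'])}")
        lines.append(f"  conclusion: {pred['conclusion']}")
    errs = report.get("errors")
    if errs:
        lines.append("")
        lines.append("Stages skipped with errors:")
        for stage, msg in errs.items():
            lines.append(f"  {stage}: {msg}")
    return "\n".join(lines) + "\n"
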