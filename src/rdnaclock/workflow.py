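"""Pipeline orchestration: simulate -> quantify -> screen -> train -> validate
-> predict -> growth, as one configured, logged, reproducible run.

A single global seed is fanned out to per-stage child seeds through
``numpy.random.SeedSequence([seed, stage_index])`` with a fixed stage index
table (see ``STAGE_SEED_INDEX``), so any stage can be re-run in isolation
with the same stream it saw inside the full pipeline.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, clock, growth, methylation, screen, simdata

logger = logging.getLogger(__name__)

STAGE_SEED_INDEX = {"simulate": 0, "train": 1, "validate": 2, "growth": 3}

DEFAULT_STAGES = (
    "simulate",
    "quantify",
    "screen",
    "train",
    "validate",
    "reduced",
    "predict",
    "growth",
    "report",
)


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global one."""
    idx = STAGE_SEED_INDEX[stage]
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0])


@dataclass
class RunConfig:
    out_dir: Path
    counts_dir: Path | None = None
    samples_csv: Path | None = None
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in DEFAULT_STAGES})
    sim: dict = field(default_factory=dict)
    min_reads: int = 10
    alpha: float = 0.5
    compare_alphas: bool = False
    folds: int = 10
    k_reduced: int = 15
    n_boot: int = 1000
    growth_form: str = "standard"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "out_dir" not in data:
            raise ConfigError("config requires out_dir")
        stages = {s: True for s in DEFAULT_STAGES}
        stages.update(data.pop("stages", {}))
        unknown = set(stages) - set(DEFAULT_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages in config: {sorted(unknown)}")
        cfg = cls(
            out_dir=Path(data.pop("out_dir")),
            counts_dir=Path(data["counts_dir"]) if data.get("counts_dir") else None,
            samples_csv=Path(data["samples_csv"]) if data.get("samples_csv") else None,
            stages=stages,
            sim=data.pop("sim", {}),
            min_reads=int(data.pop("min_reads", 10)),
            alpha=float(data.pop("alpha", 0.5)),
            compare_alphas=bool(data.pop("compare_alphas", False)),
            folds=int(data.pop("folds", 10)),
            k_reduced=int(data.pop("k_reduced", 15)),
            n_boot=int(data.pop("n_boot", 1000)),
            growth_form=str(data.pop("growth_form", "standard")),
            seed=int(data.pop("seed", 0)),
            log_level=str(data.pop("log_level", "INFO")),
        )
        data.pop("counts_dir", None)
        data.pop("samples_csv", None)
        if data:
            raise ConfigError(f"unknown config keys: {sorted(data)}")
        cfg.validate()
        return cfg

    def validate(self) -> None:
        on = self.stages
        if on.get("reduced") and not (on.get("screen") and on.get("train")):
            raise ConfigError("reduced model requires the screen and train stages")
        if on.get("train") and not on.get("quantify"):
            raise ConfigError("train requires the quantify stage")
        if on.get("validate") and not on.get("quantify"):
            raise ConfigError("validate requires the quantify stage")
        if on.get("predict") and not on.get("train"):
            raise ConfigError("predict requires the train stage")
        if not on.get("simulate"):
            if on.get("quantify"):
                if self.counts_dir is None or self.samples_csv is None:
                    raise ConfigError(
                        "quantify without simulate requires counts_dir and samples_csv"
                    )
                if not self.counts_dir.exists():
                    raise ConfigError(f"counts_dir does not exist: {self.counts_dir}")
                if not self.samples_csv.exists():
                    raise ConfigError(f"samples_csv does not exist: {self.samples_csv}")
        if self.min_reads < 0 or self.folds < 2 or self.k_reduced < 1 or self.n_boot < 0:
            raise ConfigError("invalid numeric stage parameter")
        if self.growth_form not in ("standard", "francis"):
            raise ConfigError(f"unknown growth_form {self.growth_form!r}")


@dataclass
class RunReport:
    out_dir: Path
    artifacts: dict[str, Path]
    summary: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages in order; any failure aborts with the stage
    name while earlier artifacts stay on disk."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    summary: dict = {"seed": config.seed, "version": __version__}
    on = config.stages

    counts_dir = config.counts_dir
    samples_csv = config.samples_csv

    if on.get("simulate"):
        try:
            sim_cfg = simdata.SimulationConfig.from_dict(
                {**config.sim, "seed": child_seed(config.seed, "simulate")}
            )
            panel, sheet, table, truth = simdata.simulate_dataset(sim_cfg)
            sim_dir = out / "sim"
            simdata.write_dataset(sim_dir, sheet, table, truth, panel=panel)
            counts_dir = sim_dir
            samples_csv = sim_dir / "samples.csv"
            artifacts["sim_dir"] = sim_dir
            artifacts["samples_csv"] = samples_csv
            summary["n_samples_simulated"] = len(sheet)
        except Exception as exc:
            raise StageError("simulate", exc) from exc

    samplesheet = model = matrix = screen_frame = None
    if on.get("quantify"):
        try:
            samplesheet = pd.read_csv(samples_csv).set_index("sample_id")
            table = methylation.read_count_dir(counts_dir, sample_ids=list(samplesheet.index))
            matrix, qc = methylation.apply_qc(table, min_reads=config.min_reads)
            matrix.to_csv(out / "matrix.csv")
            qc.to_json(out / "qc.json")
            artifacts["matrix"] = out / "matrix.csv"
            artifacts["qc"] = out / "qc.json"
            summary["n_loci_input"] = qc.n_loci_input
            summary["n_loci_retained"] = qc.n_loci_retained
        except Exception as exc:
            raise StageError("quantify", exc) from exc

    known = wild = None
    if samplesheet is not None and matrix is not None:
        known_ids = samplesheet.index[samplesheet["age_months"].notna()]
        wild_ids = samplesheet.index[samplesheet["age_months"].isna()]
        known = matrix.values.loc[[s for s in known_ids if s in matrix.values.index]]
        wild = matrix.values.loc[[s for s in wild_ids if s in matrix.values.index]]
        known_ages = samplesheet.loc[known.index, "age_months"].astype(float)

    if on.get("screen"):
        try:
            sub = methylation.MethylationMatrix(values=known, loci=matrix.loci)
            screen_frame, screen_summary = screen.screen_all(sub, known_ages)
            screen.write_screen_csv(screen_frame, out / "screen.csv")
            artifacts["screen"] = out / "screen.csv"
            summary["n_significant"] = screen_summary.n_significant
            summary["mean_saturation_age"] = screen_summary.mean_saturation_age
            summary["mean_saturation_age_excl_extreme"] = (
                screen_summary.mean_saturation_age_excl_extreme
            )
        except Exception as exc:
            raise StageError("screen", exc) from exc

    if on.get("train"):
        try:
            train_seed = child_seed(config.seed, "train")
            alpha = config.alpha
            if config.compare_alphas:
                comparison = clock.compare_models(
                    known, known_ages, folds=config.folds, seed=train_seed
                )
                comparison.table.to_csv(out / "model_comparison.csv", index=False, float_format="%.10g")
                artifacts["model_comparison"] = out / "model_comparison.csv"
                alpha = comparison.chosen_alpha
                summary["chosen_alpha"] = alpha
            model = clock.fit_final(
                known, known_ages, alpha=alpha, folds=config.folds, seed=train_seed
            )
            model.to_json(out / "model.json")
            artifacts["model"] = out / "model.json"
            summary["n_loci_selected"] = model.n_loci_selected
            summary["training_metrics"] = model.training_metrics
        except Exception as exc:
            raise StageError("train", exc) from exc

    if on.get("validate"):
        try:
            val_seed = child_seed(config.seed, "validate")
            report = clock.loocv(
                known,
                known_ages,
                alpha=config.alpha,
                folds=config.folds,
                seed=val_seed,
                cohorts=samplesheet.loc[known.index, "cohort"],
            )
            loocv_table = report.table.copy()
            loocv_table.to_csv(out / "loocv.csv", float_format="%.10g")
            artifacts["loocv"] = out / "loocv.csv"
            summary["precision_sd"] = report.precision_sd
            summary["loocv_r2"] = report.r2_pearson
            summary["loocv_mae"] = report.mae
            if report.anova is not None:
                summary["cohort_anova"] = report.anova
        except Exception as exc:
            raise StageError("validate", exc) from exc

    if on.get("reduced"):
        try:
            reduced = clock.reduced_model(
                known, known_ages, screen_frame, model.loci, k=min(config.k_reduced, model.n_loci_selected)
            )
            reduced.to_json(out / "reduced_model.json")
            artifacts["reduced_model"] = out / "reduced_model.json"
            red_report = clock.loocv_ols(
                known, known_ages, reduced.loci,
                cohorts=samplesheet.loc[known.index, "cohort"],
            )
            summary["reduced_precision_sd"] = red_report.precision_sd
            summary["reduced_r2"] = red_report.r2_pearson
        except Exception as exc:
            raise StageError("reduced", exc) from exc

    if on.get("predict"):
        try:
            if wild is not None and len(wild) > 0:
                preds = clock.predict_age(model, wild)
                pred_frame = preds.to_frame()
                pred_frame["negative_flag"] = preds < 0
                pred_frame.index.name = "sample_id"
                pred_frame.to_csv(out / "wild_predictions.csv", float_format="%.10g")
                artifacts["wild_predictions"] = out / "wild_predictions.csv"
                summary["wild_mean_age"] = float(preds.mean())
                summary["wild_age_range"] = [float(preds.min()), float(preds.max())]
            else:
                summary["wild_mean_age"] = None
        except Exception as exc:
            raise StageError("predict", exc) from exc

    if on.get("growth"):
        try:
            sizes = samplesheet.loc[known.index, "carapace_length_mm"].astype(float)
            ok = sizes.notna()
            if ok.sum() >= 4 and known_ages[ok].nunique() >= 3:
                fit = growth.bootstrap_ci(
                    known_ages[ok].to_numpy(),
                    sizes[ok].to_numpy(),
                    parameterisation=config.growth_form,
                    n_boot=config.n_boot,
                    seed=child_seed(config.seed, "growth"),
                )
                fit.to_json(out / "growth.json")
                artifacts["growth"] = out / "growth.json"
                summary["growth_params"] = fit.params
                summary["growth_converged"] = fit.converged
            else:
                summary["growth_params"] = None
        except Exception as exc:
            raise StageError("growth", exc) from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seed_index": STAGE_SEED_INDEX,
        "parameters": {
            "min_reads": config.min_reads,
            "alpha": config.alpha,
            "compare_alphas": config.compare_alphas,
            "folds": config.folds,
            "k_reduced": config.k_reduced,
            "n_boot": config.n_boot,
            "growth_form": config.growth_form,
        },
        "inputs": {
            name: _sha256(path)
            for name, path in (("samples_csv", samples_csv),)
            if path is not None and Path(path).exists()
        },
        "artifacts": {name: str(p) for name, p in artifacts.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    artifacts["manifest"] = out / "manifest.json"
    artifacts["summary"] = out / "summary.json"

    if on.get("report"):
        try:
            artifacts["report"] = make_report(out)
        except Exception as exc:
            raise StageError("report", exc) from exc
    return RunReport(out_dir=out, artifacts=artifacts, summary=summary)


def _fmt(value) -> str:
    if isinstance(value, float):
        if math.isnan(value):
            return "NA"
        return f"{value:.6g}"
    return str(value)


def make_report(out_dir: str | Path) -> Path:
    """Assemble a deterministic markdown summary from saved artifacts.

    Sections whose artifact is missing are omitted with a notice line.
    Regenerating from the same artifacts yields identical bytes.
    """
    out = Path(out_dir)
    lines = ["# rdnaclock run report", ""]
    summary = {}
    if (out / "summary.json").exists():
        summary = json.loads((out / "summary.json").read_text())

    lines += ["## Quality control", ""]
    if (out / "qc.json").exists():
        qc = json.loads((out / "qc.json").read_text())
        lines += [
            f"- loci input: {qc['n_loci_input']}",
            f"- loci retained: {qc['n_loci_retained']}",
            f"- loci dropped: {len(qc['drop_reasons'])}",
            "",
        ]
    else:
        lines += ["_QC artifact missing; section omitted._", ""]

    lines += ["## Locus screening", ""]
    if (out / "screen.csv").exists():
        frame = pd.read_csv(out / "screen.csv")
        n_sig = summary.get("n_significant")
        lines += [
            f"- loci screened: {len(frame)}",
            f"- Holm-significant (p < 0.05): {_fmt(n_sig) if n_sig is not None else 'NA'}",
            f"- mean saturation age (months): {_fmt(summary.get('mean_saturation_age', math.nan))}",
            f"- mean saturation age excluding extreme locus: "
            f"{_fmt(summary.get('mean_saturation_age_excl_extreme', math.nan))}",
            "",
        ]
    else:
        lines += ["_Screen artifact missing; section omitted._", ""]

    lines += ["## Age model", ""]
    if (out / "model.json").exists():
        model = clock.ClockModel.from_json(out / "model.json")
        lines += [
            f"- alpha: {_fmt(model.alpha)}; lambda: {_fmt(model.lambda_)}",
            f"- loci selected: {model.n_loci_selected}",
            f"- training MAE (months): {_fmt(model.training_metrics.get('mae', math.nan))}",
            f"- training R2 (Pearson^2): {_fmt(model.training_metrics.get('r2_pearson', math.nan))}",
            "",
        ]
        if (out / "model_comparison.csv").exists():
            comp = pd.read_csv(out / "model_comparison.csv")
            lines += ["### Penalty-family comparison", "", comp.to_markdown(index=False), ""]
        if (out / "screen.csv").exists():
            sel = pd.read_csv(out / "screen.csv")
            sel["locus_id"] = sel["Gene"].astype(str) + "_" + sel["Position"].astype(str)
            sel = sel[sel["locus_id"].isin(model.loci)]
            coefs = model.coefficients
            sel = sel.assign(model_coefficient=[coefs[l] for l in sel["locus_id"]])
            cols = ["Gene", "Position", "model_coefficient", "R2", "Adjusted_p"]
            lines += ["### Selected loci", "", sel[cols].to_markdown(index=False), ""]
    else:
        lines += ["_Model artifact missing; section omitted._", ""]

    lines += ["## Validation (LOOCV)", ""]
    if (out / "loocv.csv").exists():
        lines += [
            f"- precision SD (months): {_fmt(summary.get('precision_sd', math.nan))}",
            f"- LOOCV R2 (Pearson^2): {_fmt(summary.get('loocv_r2', math.nan))}",
            f"- LOOCV MAE (months): {_fmt(summary.get('loocv_mae', math.nan))}",
            "",
        ]
        if "reduced_precision_sd" in summary:
            lines += [
                f"- reduced-model precision SD (months): {_fmt(summary['reduced_precision_sd'])}",
                "",
            ]
    else:
        lines += ["_LOOCV artifact missing; section omitted._", ""]

    lines += ["## Wild-age predictions", ""]
    if (out / "wild_predictions.csv").exists():
        preds = pd.read_csv(out / "wild_predictions.csv")["predicted_age_months"]
        edges = np.arange(
            math.floor(preds.min() / 5.0) * 5.0, math.ceil(preds.max() / 5.0) * 5.0 + 5.0, 5.0
        )
        hist, _ = np.histogram(preds, bins=edges)
        lines += [
            f"- n wild: {len(preds)}",
            f"- mean predicted age (months): {_fmt(float(preds.mean()))}",
            f"- range: {_fmt(float(preds.min()))} to {_fmt(float(preds.max()))}",
            "",
            "| bin start | bin end | count |",
            "|---|---|---|",
        ]
        lines += [
            f"| {_fmt(edges[i])} | {_fmt(edges[i + 1])} | {int(hist[i])} |" for i in range(len(hist))
        ]
        lines += [""]
    else:
        lines += ["_No wild predictions; section omitted._", ""]

    lines += ["## Growth model", ""]
    if (out / "growth.json").exists():
        g = json.loads((out / "growth.json").read_text())
        lines += [f"- parameterisation: {g['parameterisation']}"]
        lines += [f"- {k}: {_fmt(v)}" for k, v in sorted(g["params"].items())]
        lines += [
            f"- residual SD (mm): {_fmt(g['residual_sd'])}",
            f"- converged: {g['converged']}",
        ]
        for k, (lo, hi) in sorted(g.get("bootstrap_ci", {}).items()):
            lines += [f"- {k} 95% CI: [{_fmt(lo)}, {_fmt(hi)}]"]
        lines += [""]
    else:
        lines += ["_Growth artifact missing; section omitted._", ""]

    path = out / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
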