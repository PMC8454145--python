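"""End-to-end study orchestration: simulate → score → partition → VMLOS →
treatment assignment → three cost models → comparison → sensitivity grid.

The three models mirror the study design:

* model (i)   — fixed-day treatment rule t1 plus the baseline covariates;
* model (ii)  — predicted-LOS treatment rule t2 plus the same covariates;
* model (iii) — t1 plus the same covariates plus predicted LOS as an
  additional complexity covariate.

Each stage consumes only artifacts written by earlier stages, so a run can
be resumed from any point, and a manifest records the config hash and
library versions. Rerunning with the same config reproduces every numeric
output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import causal, cohort, diagnostics, schema, scores, synth, treat, vmlos
from .exceptions import ParameterError

log = logging.getLogger("palcost")

MODEL_LABELS = ("i", "ii", "iii")


@dataclass
class RunConfig:
    """Single configuration object for a full study run."""

    outdir: str = "palcost_run"
    n_subjects: int = 2674
    generator: dict = field(default_factory=dict)   # GeneratorParams overrides
    input_cohort: str | None = None                 # use an existing cohort CSV instead
    vw_analytic_floor: int = 20
    vw_derivation_floor: int = 13
    d_threshold: int = 3
    fraction: str = "1/3"
    n_reps: int = 1000
    k_folds: int = 10
    seed_generator: int = 1
    seed_bootstrap: int = 2
    seed_cv: int = 3
    sensitivity_d_values: list[int] = field(default_factory=lambda: [1, 3, 5, 7])
    ci_type: str = "normal"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    @property
    def fraction_value(self) -> Fraction:
        return Fraction(self.fraction)


class StudyRunner:
    """Stage-by-stage execution with on-disk artifacts under ``config.outdir``."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        (self.outdir / "models").mkdir(exist_ok=True)

    # -- stage 1 ------------------------------------------------------------
    def simulate(self) -> pd.DataFrame:
        cfg = self.config
        if cfg.input_cohort:
            records = synth.read_cohort(cfg.input_cohort)
            log.info("loaded %d admissions from %s", len(records), cfg.input_cohort)
        else:
            params = synth.GeneratorParams(
                n_subjects=cfg.n_subjects, seed=cfg.seed_generator, **cfg.generator)
            records, truth = synth.generate_cohort(params)
            synth.write_truth(truth, self.outdir / "truth.json")
            log.info("generated %d admissions (true ATET %.0f)",
                     len(records), truth.true_atet)
        synth.write_cohort(records, self.outdir / "cohort.csv")
        return records

    # -- stage 2 ------------------------------------------------------------
    def partition(self) -> cohort.CohortPartition:
        records = scores.score_cohort(synth.read_cohort(self.outdir / "cohort.csv"))
        part = cohort.partition(records, self.config.vw_analytic_floor,
                                self.config.vw_derivation_floor)
        part.to_frame().to_csv(self.outdir / "partition.csv", index=False)
        log.info("partition counts: %s", part.counts())
        return part

    def _load_partitioned(self):
        records = schema.prepare_model_frame(synth.read_cohort(self.outdir / "cohort.csv"))
        part = pd.read_csv(self.outdir / "partition.csv")
        analytic_ids = part.loc[part["assignment"] == "analytic", "admission_id"].to_numpy()
        derivation_ids = part.loc[part["assignment"] == "derivation", "admission_id"].to_numpy()
        return records, records.loc[analytic_ids], records.loc[derivation_ids]

    # -- stage 3 ------------------------------------------------------------
    def fit_vmlos(self) -> vmlos.VMLOSModel:
        _, _, derivation = self._load_partitioned()
        model = vmlos.fit_vmlos(derivation)
        model.to_json(self.outdir / "vmlos.json")
        log.info("VMLOS retained %d predictors; category LOS %s",
                 len(model.retained_predictors), model.category_los)
        return model

    # -- stage 4 ------------------------------------------------------------
    def assign_treatments(self) -> pd.DataFrame:
        cfg = self.config
        _, analytic, _ = self._load_partitioned()
        model = vmlos.VMLOSModel.from_json(self.outdir / "vmlos.json")
        pred = vmlos.predict_vmlos(model, analytic)
        a1 = treat.assign_t1_cohort(analytic, d=cfg.d_threshold)
        a2 = treat.assign_t2_cohort(analytic, pred["vmlos_pred_days"],
                                    fraction=cfg.fraction_value)
        conc = treat.concurrence(a1, a2)
        out = pd.DataFrame({
            "admission_id": analytic.index,
            "t1": a1.assignment.to_numpy(),
            "t2": a2.assignment.to_numpy(),
            "vmlos_category": pred["vmlos_category"].to_numpy(),
            "vmlos_pred_days": pred["vmlos_pred_days"].to_numpy(),
        })
        out.to_csv(self.outdir / "treatment.csv", index=False)
        (self.outdir / "concurrence.json").write_text(json.dumps(dataclasses.asdict(conc)))
        log.info("treatment groups: t1 %d, t2 %d, both %d (%d%%)",
                 a1.n_treated, a2.n_treated, conc.n_both, conc.percent_overlap)
        return out

    def _analytic_with_treatments(self) -> pd.DataFrame:
        _, analytic, _ = self._load_partitioned()
        tr = pd.read_csv(self.outdir / "treatment.csv").set_index("admission_id")
        return analytic.join(tr)

    def _model_spec(self, label: str) -> dict:
        base = list(schema.BASE_COVARIATES)
        if label == "i":
            return {"treatment": "t1", "predictors": ["t1"] + base}
        if label == "ii":
            return {"treatment": "t2", "predictors": ["t2"] + base}
        if label == "iii":
            return {"treatment": "t1", "predictors": ["t1"] + base + ["vmlos_pred_days"]}
        raise ParameterError(f"unknown model label {label!r}")

    # -- stage 5 ------------------------------------------------------------
    def fit_models(self) -> dict[str, dict]:
        cfg = self.config
        analytic = self._analytic_with_treatments()
        results: dict[str, dict] = {}
        for k, label in enumerate(MODEL_LABELS):
            spec = self._model_spec(label)
            tcol, predictors = spec["treatment"], spec["predictors"]
            prop_covs = schema.BASE_COVARIATES
            prop = causal.fit_propensity(analytic, tcol, prop_covs)
            fit = causal.fit_cost_glm(analytic, "direct_cost", predictors,
                                      weights=prop.weights)
            atet = causal.bootstrap_atet(
                analytic, tcol, predictors, propensity_covariates=prop_covs,
                n_reps=cfg.n_reps, seed=cfg.seed_bootstrap + k, ci_type=cfg.ci_type)
            report = diagnostics.model_report(
                fit, analytic,
                {"treatment": tcol, "predictors": predictors,
                 "propensity_covariates": prop_covs},
                k=cfg.k_folds, seed=cfg.seed_cv)
            balance = causal.balance_table(analytic, tcol, prop_covs, prop.weights)
            payload = {
                "label": label,
                "report": report.to_dict(),
                "atet": {f.name: getattr(atet, f.name)
                         for f in dataclasses.fields(atet) if f.name != "replicates"},
                "ci_width": atet.ci_width,
                "balance": balance.round(4).to_dict(),
            }
            (self.outdir / "models" / f"{label}.json").write_text(
                json.dumps(payload, indent=2))
            results[label] = {"report": report, "atet": atet, "balance": balance}
            log.info("model (%s): ATET %.0f [%.0f, %.0f]", label,
                     atet.estimate, atet.ci_low, atet.ci_high)
        return results

    # -- stage 6 ------------------------------------------------------------
    def compare(self) -> dict[str, diagnostics.ComparisonResult]:
        loaded = {}
        for label in MODEL_LABELS:
            d = json.loads((self.outdir / "models" / f"{label}.json").read_text())
            rep = d["report"]
            rep["hosmer_lemeshow"] = tuple(rep["hosmer_lemeshow"])
            rep["pregibon"] = tuple(rep["pregibon"])
            rep["pearson"] = tuple(rep["pearson"])
            at = {k: v for k, v in d["atet"].items()}
            loaded[label] = (diagnostics.ModelReport(**rep), causal.ATETResult(**at))
        out = {}
        for name, labels in [("aim1", ["i", "ii"]), ("aim2", ["i", "iii"])]:
            comp = diagnostics.compare_models(
                [loaded[l][0] for l in labels], [loaded[l][1] for l in labels], labels)
            comp.table.to_csv(self.outdir / f"comparison_{name}.csv")
            t, p = diagnostics.atet_ttest(loaded[labels[0]][1], loaded[labels[1]][1])
            (self.outdir / f"comparison_{name}.json").write_text(json.dumps({
                "winners": comp.winners, "tally": comp.tally,
                "atet_ttest": {"t": t, "p": p}}, indent=2))
            out[name] = comp
            log.info("comparison %s tally: %s (ATET t-test p=%.3f)", name, comp.tally, p)
        return out

    # -- stage 7 ------------------------------------------------------------
    def sensitivity(self) -> pd.DataFrame:
        analytic = self._analytic_with_treatments()
        tert = analytic["vmlos_category"]
        grid = diagnostics.sensitivity_grid(
            analytic, self.config.sensitivity_d_values, tert,
            predictors=schema.BASE_COVARIATES,
            propensity_covariates=schema.BASE_COVARIATES)
        grid.to_csv(self.outdir / "sensitivity.csv", index=False)
        return grid

    # -- manifest ------------------------------------------------------------
    def write_manifest(self) -> dict:
        import scipy
        import statsmodels

        from . import __version__

        manifest = {
            "config": self.config.to_dict(),
            "config_digest": self.config.digest(),
            "versions": {
                "palcost": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "scipy": scipy.__version__,
                "statsmodels": statsmodels.__version__,
            },
        }
        (self.outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest


def run_study(config: RunConfig) -> dict:
    """Run every stage in order; returns the in-memory result bundle."""
    runner = StudyRunner(config)
    records = runner.simulate()
    part = runner.partition()
    vm = runner.fit_vmlos()
    treatments = runner.assign_treatments()
    models = runner.fit_models()
    comparisons = runner.compare()
    grid = runner.sensitivity()
    manifest = runner.write_manifest()
    return {
        "records": records, "partition": part, "vmlos": vm,
        "treatments": treatments, "models": models,
        "comparisons": comparisons, "sensitivity": grid, "manifest": manifest,
    }
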