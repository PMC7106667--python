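"""End-to-end orchestration: read -> absorbance -> trim -> preprocess ->
(outlier screen) -> model building -> evaluation/transfer.

``run`` drives the three experiments of a cross-population study — train and
evaluate within the laboratory cohort, within the field cohort, and transfer
the laboratory model to the field cohort — from a single config, writing
age-group summary tables (group, n, mean predicted age, SEM, % classed old)
alongside a machine-readable JSON report.  All randomness flows from the
single config seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classification import (
    classify_via_regression,
    resampling_classify,
    transfer_classify,
)
from .model_selection import (
    loocv_curve,
    make_splits,
    resampling_fit_predict,
    resampling_validation,
    select_K_resampling,
    select_K_standard,
    transfer_evaluate,
)
from .pca_diagnostics import fit_pca, hotelling_t2, remove_outliers
from .pls_core import fit_pls, group_summary, predict_age, rmsd
from .preprocess import PreprocessSpec, apply_preprocess
from .spectra_io import (
    REFLECTANCE,
    SampleTable,
    SpectraSet,
    read_spectra,
    to_absorbance,
    trim_window,
    write_spectra,
)
from .synthetic_data import default_config, simulate

__all__ = ["RunConfig", "run"]

TASKS = ("simulate", "regression", "classification", "pca", "transfer")


@dataclass
class RunConfig:
    task: str = "transfer"
    spectra_path: str | None = None
    metadata_path: str | None = None
    output_dir: str = "nirage_out"
    preprocess: PreprocessSpec = field(default_factory=PreprocessSpec)
    window_nm: tuple[float, float] = (700.0, 2350.0)
    mode: str = "resampling"  # or "standard"
    R: int = 100
    Kmax: int = 20
    tol_days: float = 0.5
    auc_tol: float = 0.01
    rel_tol: float = 0.02
    old_threshold_days: float = 8.0
    pca_components: int = 4
    outlier_screen: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; one of {TASKS}")
        if self.mode not in ("standard", "resampling"):
            raise ValueError("mode must be 'standard' or 'resampling'")
        if self.task != "simulate":
            for attr in ("spectra_path", "metadata_path"):
                p = getattr(self, attr)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{attr} missing or not found: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "preprocess" in raw and isinstance(raw["preprocess"], dict):
            raw["preprocess"] = PreprocessSpec(**raw["preprocess"])
        if "window_nm" in raw:
            raw["window_nm"] = tuple(raw["window_nm"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["preprocess"] = self.preprocess.to_dict()
        d["window_nm"] = list(self.window_nm)
        return d

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _prepare(
    spectra: SpectraSet, meta: SampleTable, config: RunConfig
) -> tuple[SpectraSet, SampleTable]:
    if spectra.mode == REFLECTANCE:
        spectra = to_absorbance(spectra)
    spectra = trim_window(spectra, *config.window_nm)
    spectra = apply_preprocess(spectra, config.preprocess)
    if config.outlier_screen:
        spectra, meta, _ = remove_outliers(
            spectra, meta, A=config.pca_components
        )
    else:
        meta = meta.subset(spectra.sample_ids)
    return spectra, meta


def _kmax(config: RunConfig, n_train: int) -> int:
    return max(1, min(config.Kmax, n_train - 2))


def _regression_within(
    spectra: SpectraSet, meta: SampleTable, config: RunConfig, seed: int
) -> dict:
    """Train and evaluate within one population; returns summary + objects."""
    X = spectra.values
    aligned = meta.aligned_to(spectra.sample_ids)
    y = aligned["age_days"].to_numpy(dtype=float)
    groups = aligned["group"].to_numpy()
    if config.mode == "standard":
        Kmax = _kmax(config, X.shape[0] - 1)
        curve = loocv_curve(X, y, Kmax)
        K = select_K_standard(curve, config.rel_tol)
        model = fit_pls(X, y, K)
        # held-out LOOCV predictions at the chosen K are the honest estimates
        loo = np.empty(X.shape[0])
        for i in range(X.shape[0]):
            mask = np.ones(X.shape[0], dtype=bool)
            mask[i] = False
            loo[i] = predict_age(fit_pls(X[mask], y[mask], K), X[i][None, :])[0]
        predictions = pd.DataFrame(
            {
                "sample_id": spectra.sample_ids,
                "y_true": y,
                "y_hat": loo,
                "n_test_appearances": 1,
            }
        )
        overall = rmsd(y, loo)
        fitted = model
    else:
        plan = make_splits(X.shape[0], R=config.R, seed=seed, strata=groups)
        Kmax = _kmax(config, min(len(tr) for tr, _, _ in plan.splits))
        curve = resampling_validation(X, y, plan, Kmax)
        K = select_K_resampling(curve, config.tol_days)
        result = resampling_fit_predict(X, y, plan, K, spectra.sample_ids)
        predictions = result.predictions
        overall = result.rmsd
        fitted = result
    summary = group_summary(
        predictions,
        meta.groups(predictions["sample_id"]),
        config.old_threshold_days,
    )
    return {
        "selected_K": int(K),
        "rmsd": float(overall),
        "predictions": predictions,
        "summary": summary,
        "fitted": fitted,
        "curve": curve,
    }


def _split_cohorts(
    spectra: SpectraSet, meta: SampleTable
) -> dict[str, tuple[SpectraSet, SampleTable]]:
    out = {}
    for cohort in ("lab", "field"):
        ids = meta.df.loc[meta.df["cohort"] == cohort, "sample_id"].tolist()
        if ids:
            out[cohort] = (spectra.subset(ids), meta.subset(ids))
    return out


def _summary_records(df) -> list[dict]:
    return json.loads(df.to_json(orient="records"))


def run(config: RunConfig) -> dict:
    """Execute the configured task and write CSV/JSON outputs.

    Returns the report dict that is also written to ``report.json``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "task": config.task,
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "nirage_version": __version__,
        "seed": config.seed,
    }

    if config.task == "simulate":
        spectra, meta = simulate(default_config(seed=config.seed))
        write_spectra(spectra, out / "spectra.csv", meta, out / "metadata.csv")
        report["n_samples"] = spectra.n_samples
        report["n_channels"] = spectra.n_channels
        _write_report(report, out)
        return report

    spectra, meta = read_spectra(config.spectra_path, config.metadata_path)
    spectra, meta = _prepare(spectra, meta, config)

    if config.task == "pca":
        pca = hotelling_t2(
            fit_pca(spectra.values, config.pca_components)
        )
        pd.DataFrame(
            pca.scores, columns=[f"PC{k+1}" for k in range(pca.n_components)]
        ).assign(sample_id=spectra.sample_ids).to_csv(out / "scores.csv", index=False)
        pd.DataFrame(
            pca.loadings, columns=[f"PC{k+1}" for k in range(pca.n_components)]
        ).assign(wavelength_nm=spectra.wavelengths_nm).to_csv(
            out / "loadings.csv", index=False
        )
        pd.DataFrame(
            {"sample_id": spectra.sample_ids, "t2": pca.t2, "outlier": pca.outlier_mask}
        ).to_csv(out / "t2.csv", index=False)
        report["explained_fraction"] = [float(v) for v in pca.explained_fraction]
        report["t2_limit"] = pca.t2_limit
        report["n_outliers"] = int(pca.outlier_mask.sum())
        _write_report(report, out)
        return report

    if config.task == "regression":
        res = _regression_within(spectra, meta, config, config.seed)
        res["predictions"].to_csv(out / "predictions.csv", index=False)
        res["summary"].to_csv(out / "group_summary.csv", index=False)
        report.update(
            {
                "selected_K": res["selected_K"],
                "rmsd": res["rmsd"],
                "group_summary": _summary_records(res["summary"]),
            }
        )
        _write_report(report, out)
        return report

    if config.task == "classification":
        aligned = meta.aligned_to(spectra.sample_ids)
        is_old = aligned["age_days"].to_numpy() >= config.old_threshold_days
        plan = make_splits(
            spectra.n_samples,
            R=config.R,
            seed=config.seed,
            strata=aligned["group"].to_numpy(),
        )
        Kmax = _kmax(config, min(len(tr) for tr, _, _ in plan.splits))
        cls = resampling_classify(
            spectra.values, is_old, plan, Kmax, spectra.sample_ids, config.auc_tol
        )
        cls.eta.to_csv(out / "linear_predictor.csv", index=False)
        pd.DataFrame({"fpr": cls.roc.fpr, "tpr": cls.roc.tpr}).to_csv(
            out / "roc.csv", index=False
        )
        report.update(
            {
                "selected_K": cls.selected_K,
                "auc": cls.roc.auc,
                "tau_mean": cls.tau_mean,
                "sensitivity": cls.confusion.tpr,
                "specificity": cls.confusion.tnr,
                "accuracy": cls.confusion.accuracy,
            }
        )
        _write_report(report, out)
        return report

    # transfer: lab -> lab, field -> field, lab -> field
    cohorts = _split_cohorts(spectra, meta)
    if set(cohorts) != {"lab", "field"}:
        raise ValueError("transfer task needs both 'lab' and 'field' cohorts")
    (lab_s, lab_m), (field_s, field_m) = cohorts["lab"], cohorts["field"]

    lab_res = _regression_within(lab_s, lab_m, config, config.seed)
    field_res = _regression_within(field_s, field_m, config, config.seed + 1)
    t_rmsd, t_summary, t_preds = transfer_evaluate(
        lab_res["fitted"],
        field_s.values,
        field_m.ages(field_s.sample_ids),
        field_m.groups(field_s.sample_ids),
        field_s.sample_ids,
        config.old_threshold_days,
    )
    for name, res in (("lab_to_lab", lab_res), ("field_to_field", field_res)):
        res["predictions"].to_csv(out / f"predictions_{name}.csv", index=False)
        res["summary"].to_csv(out / f"summary_{name}.csv", index=False)
    t_preds.to_csv(out / "predictions_lab_to_field.csv", index=False)
    t_summary.to_csv(out / "summary_lab_to_field.csv", index=False)

    report["regression"] = {
        "lab_to_lab": {
            "selected_K": lab_res["selected_K"],
            "rmsd": lab_res["rmsd"],
            "group_summary": _summary_records(lab_res["summary"]),
        },
        "field_to_field": {
            "selected_K": field_res["selected_K"],
            "rmsd": field_res["rmsd"],
            "group_summary": _summary_records(field_res["summary"]),
        },
        "lab_to_field": {
            "rmsd": float(t_rmsd),
            "group_summary": _summary_records(t_summary),
        },
    }

    if config.mode == "resampling":
        cls_report = {}
        fitted_cls = {}
        for name, (s, m), seed in (
            ("lab_to_lab", cohorts["lab"], config.seed),
            ("field_to_field", cohorts["field"], config.seed + 1),
        ):
            aligned = m.aligned_to(s.sample_ids)
            is_old = aligned["age_days"].to_numpy() >= config.old_threshold_days
            plan = make_splits(
                s.n_samples, R=config.R, seed=seed, strata=aligned["group"].to_numpy()
            )
            Kmax = _kmax(config, min(len(tr) for tr, _, _ in plan.splits))
            cls = resampling_classify(
                s.values, is_old, plan, Kmax, s.sample_ids, config.auc_tol
            )
            fitted_cls[name] = cls
            cls_report[name] = {
                "selected_K": cls.selected_K,
                "auc": cls.roc.auc,
                "sensitivity": cls.confusion.tpr,
                "specificity": cls.confusion.tnr,
                "accuracy": cls.confusion.accuracy,
            }
        field_old = (
            field_m.ages(field_s.sample_ids) >= config.old_threshold_days
        )
        conf, roc, _ = transfer_classify(
            fitted_cls["lab_to_lab"], field_s.values, field_old, field_s.sample_ids
        )
        cls_report["lab_to_field"] = {
            "auc": roc.auc,
            "sensitivity": conf.tpr,
            "specificity": conf.tnr,
            "accuracy": conf.accuracy,
        }
        report["classification"] = cls_report
    else:
        report["classification"] = {
            "lab_to_lab": {
                "accuracy": classify_via_regression(
                    lab_res["predictions"], config.old_threshold_days
                ).accuracy
            },
            "field_to_field": {
                "accuracy": classify_via_regression(
                    field_res["predictions"], config.old_threshold_days
                ).accuracy
            },
            "lab_to_field": {
                "accuracy": classify_via_regression(
                    t_preds, config.old_threshold_days
                ).accuracy
            },
        }

    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=2, default=float)
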