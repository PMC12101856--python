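"""End-to-end orchestration: simulate -> preprocess -> PCA -> train -> report.

``run_calibration`` reproduces the calibration protocol for one hormone:
generate the log-spaced calibration series, vector-normalize, reduce to six
PC scores, split 75/25 stratified by concentration level, train the hormone's
Rprop+ network, and assemble RMSE/R², k-fold metrics and leverage-based
LOD/LOQ from simulated blank spectra into a :class:`CalibrationReport`.

``run_timecourse`` pushes a simulated four-group animal experiment through a
stored calibration to produce per-group mean predicted concentrations at each
sampling time; ``run_elisa_comparison`` quantifies the same animals with a
simulated plate assay and pairs the two methods.

All randomness derives from one global seed, so a run is reproducible from
its manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ann, elisa, metrics, pca, preprocess, synthdata
from .dataset import SpectrumSet

logger = logging.getLogger("serscal")

HORMONES = ("gh", "te")

#: True plate-assay curves used to synthesize ELISA optical densities.
GH_ELISA_CURVE = {"a1": 0.08, "a2": 2.4, "x0": 12.0, "dx": 8.0}
TE_ELISA_CURVE = {"y0": 0.15, "a": 2.0, "t": 15.0}
#: Standard concentrations of the simulated kits (ng/ml).
ELISA_STANDARDS_NG_ML = (0.05, 0.2, 0.8, 3.0, 10.0, 30.0, 60.0, 100.0)


@dataclasses.dataclass
class RunConfig:
    """Every knob of a full analysis run."""

    generator: synthdata.GeneratorConfig = dataclasses.field(
        default_factory=synthdata.GeneratorConfig
    )
    normalization: str = "vector"
    n_components: int = 6
    n_concentrations: int = 30
    conc_min: float = 0.01
    conc_max: float = 60.0
    n_replicates: int = 30
    n_blanks: int = 30
    n_rats_per_group: int = 6
    train_fraction: float = 0.75
    k_folds: int = 4
    n_restarts: int = 3
    train: ann.TrainConfig = dataclasses.field(default_factory=ann.TrainConfig)
    elisa_od_noise: float = 0.01
    seed: int = 42

    def architecture(self, hormone: str) -> ann.MLPArchitecture:
        arch = {"gh": ann.GH_ARCHITECTURE, "te": ann.TE_ARCHITECTURE}[hormone.lower()]
        return dataclasses.replace(arch, input_size=self.n_components)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage sub-seed derived from the global seed."""
        stages = (
            "data_gh", "data_te", "split", "init", "kfold",
            "blanks", "groups", "elisa",
        )
        if stage not in stages:
            raise KeyError(f"unknown stage {stage!r}")
        state = np.random.SeedSequence(self.seed).generate_state(len(stages))
        return int(state[stages.index(stage)] % (2**31))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = self.generator.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "generator" in d:
            d["generator"] = synthdata.GeneratorConfig.from_dict(d["generator"])
        if "train" in d:
            d["train"] = ann.TrainConfig(**d["train"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclasses.dataclass
class CalibrationResult:
    """Artifacts of one calibrated hormone model."""

    hormone: str
    report: metrics.CalibrationReport | None
    pca_model: pca.PCAModel
    model: ann.MLPEnsemble
    train_idx: np.ndarray
    test_idx: np.ndarray


def _package_version() -> str:
    try:
        return version("serscal")
    except PackageNotFoundError:
        return "unknown"


def _write_manifest(out_dir: Path, config: RunConfig, stages: list[str]) -> None:
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "serscal_version": _package_version(),
        "stages": stages,
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=float)


def run_calibration(
    config: RunConfig,
    hormone: str,
    out_dir=None,
    run_kfold: bool = True,
) -> CalibrationResult:
    """Calibrate one hormone model end to end; optionally persist artifacts."""
    hormone = hormone.lower()
    if hormone not in HORMONES:
        raise ValueError(f"unknown hormone {hormone!r}")
    logger.info("simulating %s calibration set", hormone.upper())
    cal = synthdata.simulate_calibration_set(
        config.generator,
        hormone=hormone,
        n_concentrations=config.n_concentrations,
        conc_min=config.conc_min,
        conc_max=config.conc_max,
        n_replicates=config.n_replicates,
        seed=config.stage_seed(f"data_{hormone}"),
    )
    targets = cal.metadata[f"{hormone}_ng_ml"].to_numpy()

    logger.info("preprocessing (%s normalization)", config.normalization)
    norm = preprocess.normalize(cal, config.normalization)

    logger.info("fitting %d-component PCA", config.n_components)
    pca_model = pca.fit_pca(norm, config.n_components)
    scores = pca.project(pca_model, norm)

    train_idx, test_idx = ann.holdout_split(
        targets, config.train_fraction, seed=config.stage_seed("split")
    )
    logger.info(
        "training %s committee (%d restarts) on %d samples (%d held out)",
        hormone.upper(), config.n_restarts, train_idx.size, test_idx.size,
    )
    model = ann.train_ensemble(
        config.architecture(hormone),
        scores[train_idx], targets[train_idx],
        config.train, n_restarts=config.n_restarts,
        seed=config.stage_seed("init"),
    )

    pred_train = ann.ensemble_forward(model, scores[train_idx])
    pred_test = ann.ensemble_forward(model, scores[test_idx])

    logger.info("estimating detection limits from %d blanks", config.n_blanks)
    blanks = synthdata.simulate_blank_set(
        config.generator, config.n_blanks, seed=config.stage_seed("blanks")
    )
    blank_scores = pca.project(pca_model, preprocess.normalize(blanks, config.normalization))
    blank_pred = ann.ensemble_forward(model, blank_scores)
    h0_min, h0_max = metrics.blank_leverage(scores[train_idx], blank_scores)
    lod_inputs = metrics.LODInputs(
        sigma_b=float(np.std(blank_pred, ddof=1)),
        s0=1.0,
        sigma_ycal=float(np.std(pred_train - targets[train_idx], ddof=1)),
        h0_min=h0_min,
        h0_max=h0_max,
    )

    fold_metrics = None
    if run_kfold and config.k_folds:
        logger.info("%d-fold cross-validation", config.k_folds)
        fold_metrics = ann.kfold_cv(
            scores, targets,
            config.architecture(hormone), config.train,
            k=config.k_folds, seed=config.stage_seed("kfold"),
        )

    report = metrics.build_report(
        hormone,
        pred_train, targets[train_idx],
        pred_test, targets[test_idx],
        lod_inputs,
        fold_metrics=fold_metrics,
    )
    result = CalibrationResult(hormone, report, pca_model, model, train_idx, test_idx)
    if out_dir is not None:
        out = Path(out_dir) / hormone
        out.mkdir(parents=True, exist_ok=True)
        pca_model.to_json(out / "pca.json")
        model.to_json(out / "mlp.json")
        report.to_json(out / "report.json")
        report.to_frame().to_csv(out / "report.csv", index=False)
        _write_manifest(out, config, ["simulate", "normalize", "pca", "train", "report"])
        logger.info("artifacts written to %s", out)
    return result


def load_calibration(artifact_dir, hormone: str) -> tuple[pca.PCAModel, ann.MLPEnsemble]:
    """Read back the serialized PCA and network committee of one hormone."""
    p = Path(artifact_dir) / hormone.lower()
    return (
        pca.PCAModel.from_json(p / "pca.json"),
        ann.MLPEnsemble.from_json(p / "mlp.json"),
    )


def predict_spectra(
    spectrum_set: SpectrumSet,
    pca_model: pca.PCAModel,
    model: ann.MLPEnsemble,
    normalization: str = "vector",
) -> np.ndarray:
    """Concentrations for raw spectra through a stored calibration."""
    if pca_model.wavenumbers is not None and not np.array_equal(
        pca_model.wavenumbers, spectrum_set.wavenumbers
    ):
        raise ValueError("spectrum grid does not match the stored PCA model")
    norm = preprocess.normalize(spectrum_set, normalization)
    return ann.ensemble_forward(model, pca.project(pca_model, norm))


def run_timecourse(
    config: RunConfig,
    calibrations: dict[str, CalibrationResult],
) -> tuple[pd.DataFrame, SpectrumSet, pd.DataFrame]:
    """Predict hormone time-courses for the four-group animal experiment.

    Returns ``(summary, group_set, per_spectrum)``: the per-group/time mean
    and SD of predicted concentrations for each hormone alongside the
    generator's true mean, the simulated spectra, and per-spectrum
    predictions.
    """
    group_set = synthdata.simulate_group_experiment(
        config.generator,
        n_rats_per_group=config.n_rats_per_group,
        seed=config.stage_seed("groups"),
    )
    per_spectrum = group_set.metadata[
        ["spectrum_id", "group", "time_h", "gh_ng_ml", "te_ng_ml"]
    ].copy()
    for hormone, result in calibrations.items():
        per_spectrum[f"pred_{hormone}_ng_ml"] = predict_spectra(
            group_set, result.pca_model, result.model, config.normalization
        )
    rows = []
    for hormone in calibrations:
        for (group, time_h), sub in per_spectrum.groupby(["group", "time_h"]):
            pred = sub[f"pred_{hormone}_ng_ml"]
            rows.append(
                {
                    "hormone": hormone,
                    "group": group,
                    "time_h": float(time_h),
                    "concentration": float(pred.mean()),
                    "sd": float(pred.std(ddof=1)),
                    "true_concentration": float(sub[f"{hormone}_ng_ml"].mean()),
                    "n_rats": int(len(sub)),
                }
            )
    summary = pd.DataFrame(rows).sort_values(
        ["hormone", "group", "time_h"], ignore_index=True
    )
    return summary, group_set, per_spectrum


def run_elisa_comparison(
    config: RunConfig,
    timecourse_summary: pd.DataFrame,
    group_metadata: pd.DataFrame,
) -> dict[str, dict]:
    """Quantify the same animals by simulated ELISA and pair with the network.

    For each hormone: synthesize standards from the kit's true curve, fit the
    standard curve, read each animal sample's OD (true curve + proportional
    noise, clamped to the plate rails), invert, average per group and time,
    then pair with the network's time-course.  Returns per hormone the fitted
    curve, the paired table and the comparison summary.
    """
    rng = np.random.default_rng(config.stage_seed("elisa"))
    results = {}
    specs = {
        "gh": ("boltzmann", lambda c: elisa.boltzmann(c, **GH_ELISA_CURVE)),
        "te": ("exp_decay", lambda c: elisa.exp_decay(c, **TE_ELISA_CURVE)),
    }
    for hormone in timecourse_summary["hormone"].unique():
        form, true_curve = specs[hormone]
        standards = synthdata.simulate_elisa_standards(
            true_curve, ELISA_STANDARDS_NG_ML, config.elisa_od_noise, rng
        )
        curve = elisa.fit_standard_curve(standards["conc_ng_ml"], standards["od"], form)
        logger.info("%s standard curve fit R^2 = %.5f", hormone.upper(), curve.fit_r2)
        true_conc = group_metadata[f"{hormone}_ng_ml"].to_numpy()
        od = true_curve(true_conc) * (
            1.0 + config.elisa_od_noise * rng.standard_normal(true_conc.size)
        )
        od = elisa.clip_to_range(curve, od)
        pred = np.array([elisa.invert_curve(curve, o) for o in od])
        per_sample = group_metadata[["group", "time_h"]].copy()
        per_sample["concentration"] = pred
        elisa_summary = (
            per_sample.groupby(["group", "time_h"], as_index=False)["concentration"]
            .mean()
        )
        ann_summary = timecourse_summary.loc[
            timecourse_summary["hormone"] == hormone,
            ["group", "time_h", "concentration"],
        ]
        table, summary = elisa.compare_methods(ann_summary, elisa_summary)
        results[hormone] = {
            "curve": curve,
            "standards": standards,
            "table": table,
            "summary": summary,
        }
    return results
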