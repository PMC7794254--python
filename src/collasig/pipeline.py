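"""End-to-end orchestration: images + cohort table in, nomogram and
evaluation report out; plus the study simulator that fabricates a full
input directory with known ground truth.

Stage order follows the signature-construction workflow: per-ROI feature
extraction -> patient-level aggregation -> LASSO signature -> cutoff
search -> univariate screen -> multivariate Fine-Gray -> nomogram ->
evaluation.  Every stochastic step receives a child seed spawned from the
config seed, so an identical config yields byte-identical JSON summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohorts import CohortParams, generate_cohort, validate_cohort
from .competing import (
    FineGrayModel,
    build_nomogram,
    fit_fine_gray,
    grays_test,
    predict_cif,
    univariate_screen,
)
from .evaluation import (
    averaged_c_index,
    binary_status_at,
    calibration_curve,
    classification_report,
    decision_curve,
    time_dependent_roc,
)
from .features import FeatureConfig, FEATURE_NAMES, aggregate_patient, extract_all
from .fibers import FiberImageParams, generate_fiber_image
from .image import read_image, write_tiff
from .signature import LassoConfig, SignatureModel, compute_signature, lasso_select, optimal_cutoff

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    image_dir: str = ""
    cohort_csv: str = ""
    output_dir: str = "results"
    roi_per_patient: int = 5
    pixel_size_um: float = 500.0 / 512.0
    clinical_covariates: list[str] = field(
        default_factory=lambda: ["tumour_size", "differentiation", "n_stage"]
    )
    t_star: float = 3.0
    n_boot: int = 100
    n_grid: int = 20
    feature: FeatureConfig = field(default_factory=FeatureConfig)
    lasso: LassoConfig = field(default_factory=LassoConfig)
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = (
            json.loads(path.read_text())
            if path.suffix == ".json"
            else yaml.safe_load(path.read_text())
        )
        feature = FeatureConfig(**raw.pop("feature", {}))
        lasso = LassoConfig(**raw.pop("lasso", {}))
        return cls(feature=feature, lasso=lasso, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("output_dir", None)  # analysis identity, not where it lands
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


class PipelineValidationError(ValueError):
    pass


def fit_signature_model(
    X: pd.DataFrame, labels: np.ndarray, lasso_cfg: LassoConfig
) -> SignatureModel:
    """LASSO selection with a lambda_min fallback.

    The 1-SE model can be empty on small cohorts; rather than producing a
    constant (useless) signature the pipeline falls back to the
    CV-minimum penalty, and errors only if that too selects nothing.
    """
    model = lasso_select(X, labels, lasso_cfg)
    if not model.feature_names and lasso_cfg.rule == "lambda_1se":
        logger.warning(
            "1-SE LASSO selected no features; falling back to lambda_min"
        )
        model = lasso_select(
            X, labels, dataclasses.replace(lasso_cfg, rule="lambda_min")
        )
    if not model.feature_names:
        raise PipelineValidationError(
            "LASSO selected no features at any penalty; "
            "cohort carries no detectable feature-outcome signal"
        )
    return model


# ---------------------------------------------------------------------------
# Cohort-level analysis (shared by the image pipeline and simulations)
# ---------------------------------------------------------------------------

def analyze_cohort(
    cohort: pd.DataFrame,
    signature_col: str,
    clinical_covariates: list[str],
    t_star: float = 3.0,
    n_boot: int = 100,
    n_grid: int = 20,
    seed: int = 0,
) -> dict:
    """The modelling chain downstream of the signature.

    Dichotomizes the signature by the Gray-statistic cutoff search,
    compares the high/low groups, screens candidates univariately
    (selection at p < 0.05), fits the multivariate Fine-Gray model on the
    selected variables, builds the nomogram and evaluates discrimination,
    calibration, clinical utility and classification at the horizon.
    """
    time = cohort["time_yr"].to_numpy(dtype=float)
    event = cohort["event"].to_numpy()
    sig = cohort[signature_col].to_numpy(dtype=float)

    out: dict = {}
    cutoff = optimal_cutoff(sig, time, event)
    high = (sig > cutoff).astype(int)
    g_stat, g_df, g_p = grays_test(time, event, high)
    out["cutoff"] = {
        "value": cutoff,
        "note": "cutoff maximizes the Gray-type statistic and is optimistic",
        "grays_stat_high_vs_low": g_stat,
        "grays_df": g_df,
        "grays_p": g_p,
    }

    screen = univariate_screen(
        cohort, [signature_col] + clinical_covariates
    )
    selected = sorted(
        screen.loc[screen["selected"], "variable"].unique().tolist(),
        key=([signature_col] + clinical_covariates).index,
    )
    out["univariate_screen"] = screen
    out["selected_variables"] = selected

    model = fit_fine_gray(cohort, selected or [signature_col])
    out["fine_gray"] = model
    nomogram = build_nomogram(model, cohort=cohort, t_star=t_star)
    out["nomogram"] = nomogram

    pred = np.array(
        [
            predict_cif(
                model,
                {v: cohort.iloc[i][v] for v in model.variable_terms},
                t_star,
            )
            for i in range(len(cohort))
        ]
    )
    out["predicted_cif"] = pred

    c_avg, c_ci = averaged_c_index(
        pred, time, event, t_max=t_star, n_grid=n_grid, n_boot=n_boot,
        seed=seed,
    )
    out["c_index"] = {"estimate": c_avg, "ci": c_ci}
    roc = time_dependent_roc(pred, time, event, t_star=t_star)
    out["roc"] = roc
    out["calibration"] = calibration_curve(pred, time, event, t_star=t_star)

    labels, determinate = binary_status_at(time, event, t_star)
    out["decision_curve"] = decision_curve(
        pred[determinate], labels[determinate]
    )
    out["classification"] = classification_report(
        pred[determinate], labels[determinate]
    )
    return out


# ---------------------------------------------------------------------------
# Image pipeline
# ---------------------------------------------------------------------------

def _patient_image_paths(
    image_dir: Path, patient_ids: list, roi_per_patient: int
) -> dict:
    paths = {}
    for pid in patient_ids:
        rois = sorted(image_dir.glob(f"patient{pid}_roi*.tif*"))
        if len(rois) < roi_per_patient:
            raise PipelineValidationError(
                f"patient {pid}: found {len(rois)} ROI images, "
                f"need {roi_per_patient}"
            )
        paths[pid] = rois[:roi_per_patient]
    return paths


def extract_features_table(
    image_dir: str | Path,
    patient_ids: list,
    roi_per_patient: int = 5,
    pixel_size_um: float = 500.0 / 512.0,
    feature_config: FeatureConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-ROI and per-patient (ROI-averaged) feature tables."""
    image_dir = Path(image_dir)
    paths = _patient_image_paths(image_dir, patient_ids, roi_per_patient)
    roi_rows = []
    patient_rows = []
    for pid, files in paths.items():
        vecs = []
        for f in files:
            img = read_image(f, pixel_size_um=pixel_size_um)
            v = extract_all(img, feature_config)
            vecs.append(v)
            row = v.copy()
            row["patient_id"] = pid
            row["roi"] = f.name
            roi_rows.append(row)
        agg = aggregate_patient(vecs)
        agg["patient_id"] = pid
        patient_rows.append(agg)
        logger.info("extracted %d ROIs for patient %s", len(files), pid)
    roi_table = pd.DataFrame(roi_rows).reset_index(drop=True)
    patient_table = pd.DataFrame(patient_rows).reset_index(drop=True)
    return roi_table, patient_table


@dataclass
class RunReport:
    config: PipelineConfig
    signature_model: SignatureModel
    fine_gray: FineGrayModel
    summary: dict

    def save(self, output_dir: str | Path) -> None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.signature_model.to_json(out / "signature_model.json")
        self.fine_gray.to_json(out / "fine_gray_model.json")
        (out / "summary.json").write_text(
            json.dumps(self.summary, indent=2, sort_keys=True)
        )


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute the full chain from images + cohort CSV to the report."""
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = pd.read_csv(cfg.cohort_csv)
    validate_cohort(cohort, covariate_cols=cfg.clinical_covariates)
    patient_ids = cohort["patient_id"].tolist()

    roi_table, patient_table = extract_features_table(
        cfg.image_dir,
        patient_ids,
        roi_per_patient=cfg.roi_per_patient,
        pixel_size_um=cfg.pixel_size_um,
        feature_config=cfg.feature,
    )
    roi_table.to_csv(out_dir / "features_roi.csv", index=False)
    patient_table.to_csv(out_dir / "features_patient.csv", index=False)

    X = patient_table[list(FEATURE_NAMES)]
    time = cohort["time_yr"].to_numpy(dtype=float)
    event = cohort["event"].to_numpy()
    labels, determinate = binary_status_at(time, event, cfg.t_star)
    lasso_cfg = dataclasses.replace(cfg.lasso, seed=cfg.seed)
    sig_model = fit_signature_model(
        X[determinate], labels[determinate], lasso_cfg
    )
    scores = compute_signature(X, sig_model)
    cohort = cohort.copy()
    cohort["signature"] = scores

    results = analyze_cohort(
        cohort,
        "signature",
        cfg.clinical_covariates,
        t_star=cfg.t_star,
        n_boot=cfg.n_boot,
        n_grid=cfg.n_grid,
        seed=cfg.seed,
    )
    sig_model.cutoff = results["cutoff"]["value"]

    results["univariate_screen"].to_csv(
        out_dir / "univariate_screen.csv", index=False
    )
    results["calibration"].to_csv(out_dir / "calibration.csv", index=False)
    results["decision_curve"].to_csv(
        out_dir / "decision_curve.csv", index=False
    )
    roc = results["roc"]
    pd.DataFrame(
        {"threshold": roc.thresholds, "tpr": roc.tpr, "fpr": roc.fpr}
    ).to_csv(out_dir / "roc_curve.csv", index=False)
    cohort[["patient_id", "signature"]].to_csv(
        out_dir / "signatures.csv", index=False
    )

    model: FineGrayModel = results["fine_gray"]
    summary = {
        "provenance": {
            "package_version": __version__,
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
        },
        "n_patients": len(cohort),
        "n_events": {
            str(k): int(v)
            for k, v in cohort["event"].value_counts().items()
        },
        "signature": {
            "selected_features": sig_model.feature_names,
            "coefficients": np.asarray(sig_model.coefficients).tolist(),
            "lambda": sig_model.lambda_selected,
            "cutoff": results["cutoff"]["value"],
            "cutoff_note": results["cutoff"]["note"],
        },
        "grays_test_high_vs_low": {
            "statistic": results["cutoff"]["grays_stat_high_vs_low"],
            "df": results["cutoff"]["grays_df"],
            "p": results["cutoff"]["grays_p"],
        },
        "selected_variables": results["selected_variables"],
        "fine_gray": {
            "terms": model.terms,
            "coef": model.beta.tolist(),
            "se": model.se.tolist(),
            "shr": model.shr.tolist(),
            "ci": model.conf_int().tolist(),
            "p": model.wald_p().tolist(),
        },
        "evaluation": {
            "averaged_c_index": results["c_index"],
            "auroc_3yr": results["roc"].auroc,
            "auroc_ci": list(results["roc"].ci),
            "classification": results["classification"].as_dict(),
        },
    }
    report = RunReport(
        config=cfg,
        signature_model=sig_model,
        fine_gray=model,
        summary=summary,
    )
    report.save(out_dir)
    logger.info("pipeline complete: %s", out_dir / "summary.json")
    return report


# ---------------------------------------------------------------------------
# Study simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyParams:
    """Ground-truth configuration of a simulated study.

    A latent per-patient severity z ~ N(0,1) drives both the image
    morphology (fiber count, width, alignment increase with z) and, as
    the true signature, the subdistribution hazard of the event of
    interest together with dummy-coded clinical covariates.
    """

    n_patients: int = 20
    roi_per_patient: int = 5
    image_size_px: int = 128
    pixel_size_um: float = 500.0 / 512.0
    base_fiber_density: float = 6e-4  # fibers per um^2 of field at z = 0
    beta_signature: float = float(np.log(2.5))
    beta_tumour_size: float = 0.7
    beta_differentiation: tuple[float, float] = (0.4, 0.8)
    beta_n_stage: tuple[float, float, float, float] = (0.3, 0.6, 0.9, 1.2)
    p_base: float = 0.12
    competing_rate: float = 0.12
    censor_rate: float = 0.15
    horizon_yr: float = 3.0
    seed: int = 0


DIFFERENTIATION_LEVELS = ["well_moderate", "poor", "undifferentiated"]
N_STAGE_LEVELS = ["N0", "N1", "N2", "N3a", "N3b"]
TUMOUR_SIZE_LEVELS = ["lt4cm", "ge4cm"]


def simulate_clinical_covariates(
    n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Clinical covariates with marginals typical of a serosa-invasive
    gastric-cancer cohort (about 58% large tumours, mostly poor or
    undifferentiated histology, a quarter node-negative)."""
    return pd.DataFrame(
        {
            "tumour_size": pd.Categorical(
                rng.choice(TUMOUR_SIZE_LEVELS, size=n, p=[0.42, 0.58]),
                categories=TUMOUR_SIZE_LEVELS,
            ),
            "differentiation": pd.Categorical(
                rng.choice(
                    DIFFERENTIATION_LEVELS, size=n, p=[0.25, 0.48, 0.27]
                ),
                categories=DIFFERENTIATION_LEVELS,
            ),
            "n_stage": pd.Categorical(
                rng.choice(
                    N_STAGE_LEVELS, size=n, p=[0.26, 0.23, 0.18, 0.19, 0.14]
                ),
                categories=N_STAGE_LEVELS,
            ),
        }
    )


def clinical_design_matrix(clin: pd.DataFrame, params: StudyParams):
    """Dummy design and coefficient vector for the clinical covariates."""
    cols = {}
    betas = []
    cols["tumour_size[ge4cm]"] = (
        clin["tumour_size"].astype(str) == "ge4cm"
    ).astype(float)
    betas.append(params.beta_tumour_size)
    for lev, b in zip(DIFFERENTIATION_LEVELS[1:],
                      params.beta_differentiation):
        cols[f"differentiation[{lev}]"] = (
            clin["differentiation"].astype(str) == lev
        ).astype(float)
        betas.append(b)
    for lev, b in zip(N_STAGE_LEVELS[1:], params.beta_n_stage):
        cols[f"n_stage[{lev}]"] = (
            clin["n_stage"].astype(str) == lev
        ).astype(float)
        betas.append(b)
    return pd.DataFrame(cols), np.array(betas)


def simulate_cohort_with_signature(
    params: StudyParams, severity: np.ndarray | None = None
) -> pd.DataFrame:
    """Cohort whose first covariate is the latent severity (true
    signature), with dummy-coded clinical covariates behind it."""
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 101]))
    n = params.n_patients
    if severity is None:
        severity = rng.standard_normal(n)
    clin = simulate_clinical_covariates(n, rng)
    design, clin_beta = clinical_design_matrix(clin, params)
    X = pd.concat(
        [pd.Series(severity, name="severity"), design], axis=1
    )
    beta = np.concatenate([[params.beta_signature], clin_beta])
    cohort = generate_cohort(
        CohortParams(
            n_patients=n,
            beta_true=tuple(beta),
            p_base=params.p_base,
            competing_rate=params.competing_rate,
            censor_rate=params.censor_rate,
            horizon_yr=params.horizon_yr,
            seed=int(
                np.random.SeedSequence([params.seed, 202]).generate_state(1)[0]
                % (2**31 - 1)
            ),
        ),
        covariates=X,
    )
    cohort = pd.concat([cohort, clin], axis=1)
    return cohort


def fiber_params_for_severity(
    z: float, params: StudyParams, seed: int
) -> FiberImageParams:
    """Image morphology as a function of latent severity: denser, thicker
    and more aligned collagen at higher z."""
    field_um2 = (params.image_size_px * params.pixel_size_um) ** 2
    n_fibers = max(
        3, int(round(params.base_fiber_density * field_um2 * (1 + 0.30 * z)))
    )
    return FiberImageParams(
        image_size_px=params.image_size_px,
        pixel_size_um=params.pixel_size_um,
        n_fibers=n_fibers,
        mean_length_um=60.0,
        mean_width_um=3.0 * (1 + 0.15 * np.clip(z, -2.5, 2.5)),
        orientation_kappa=float(np.exp(0.8 * z)),
        seed=seed,
    )


def simulate_study(
    params: StudyParams, output_dir: str | Path
) -> dict:
    """Write a complete simulated study: ROI images per patient, the
    cohort CSV and a ground-truth JSON (true coefficients and per-patient
    severity) for downstream recovery tests."""
    out = Path(output_dir)
    images_dir = out / "images"
    images_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 7]))
    severity = np.clip(rng.standard_normal(params.n_patients), -2.5, 2.5)
    cohort = simulate_cohort_with_signature(params, severity=severity)

    seed_grid = np.random.SeedSequence([params.seed, 55]).generate_state(
        params.n_patients * params.roi_per_patient
    )
    k = 0
    for i, pid in enumerate(cohort["patient_id"]):
        for roi in range(params.roi_per_patient):
            fp = fiber_params_for_severity(
                float(severity[i]), params, seed=int(seed_grid[k] % (2**31 - 1))
            )
            img, _ = generate_fiber_image(fp)
            write_tiff(images_dir / f"patient{pid}_roi{roi + 1}.tif", img)
            k += 1

    cohort_csv = out / "cohort.csv"
    cohort.to_csv(cohort_csv, index=False)
    truth = {
        "beta_signature": params.beta_signature,
        "beta_clinical": {
            "tumour_size[ge4cm]": params.beta_tumour_size,
            "differentiation": list(params.beta_differentiation),
            "n_stage": list(params.beta_n_stage),
        },
        "p_base": params.p_base,
        "severity": severity.tolist(),
        "seed": params.seed,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return {
        "image_dir": str(images_dir),
        "cohort_csv": str(cohort_csv),
        "ground_truth": str(out / "ground_truth.json"),
        "n_images": params.n_patients * params.roi_per_patient,
    }
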