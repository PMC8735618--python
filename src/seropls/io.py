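"""Readers, writers, configuration, and the end-to-end pipeline.

CSV conventions: comma-separated, UTF-8, header row required. The cohort
table has one subject per row; the spectra file has a ``ppm`` first column
and one subject per subsequent column; bin definitions are
``name,ppm_lo,ppm_hi``. Config files are flat ``key = value`` text.

The pipeline reproduces the whole workflow on synthetic or user data:
simulate/read -> normalize -> bin -> integrate -> repeated external CV plus
permutation null and KS comparison -> all-data model -> ROC + Youden ->
univariate reports. Every run is reconstructible from its logged config and
seed; the JSON report is byte-identical across reruns with the same inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diagnostics import roc, table_one, welch_report, youden_threshold
from .opls import fit_opls, predict_scores, vip
from .preprocess import (
    DEFAULT_BINS,
    DEFAULT_CLINICAL_VARS,
    DEFAULT_EXCLUSION,
    BinDefinition,
    FeatureMatrix,
    bin_spectra,
    fit_scaler,
    integrate_features,
    normalize_spectra,
)
from .synthetic import (
    CLINICAL_VARIABLES,
    MEDICATION_FLAGS,
    SimulationConfig,
    SpectrumSet,
    simulate_cohort,
)
from .validate import (
    ValidationConfig,
    compare_to_null,
    external_cv,
    permutation_null,
)

logger = logging.getLogger("seropls")

REPORT_SCHEMA_VERSION = 1

#: accepted synonyms for the three group labels
GROUP_SYNONYMS = {
    "recent": "recent",
    "current": "recent",
    "lifetime": "lifetime",
    "past": "lifetime",
    "history": "lifetime",
    "none": "none",
    "no": "none",
    "never": "none",
}

_REQUIRED_COHORT_COLUMNS = ("subject_id", "group")

__all__ = [
    "PipelineConfig",
    "read_cohort",
    "write_cohort",
    "read_spectra",
    "write_spectra",
    "read_bins",
    "write_bins",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_config",
    "write_config",
    "binary_labels",
    "run_pipeline",
    "write_report",
]


# ---------------------------------------------------------------------------
# readers / writers


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort table CSV."""
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    known = set(_REQUIRED_COHORT_COLUMNS) | {"age", "sex"} | set(CLINICAL_VARIABLES) | set(
        MEDICATION_FLAGS
    )
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        logger.warning("%s: ignoring unknown column(s) %s", path, unknown)
    df["subject_id"] = df["subject_id"].astype(str)
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if not dup.empty:
        raise ValueError(
            f"{path}: duplicated subject_id(s) {sorted(dup.unique().tolist())}"
        )
    groups = []
    for i, g in enumerate(df["group"]):
        key = str(g).strip().lower()
        if key not in GROUP_SYNONYMS:
            raise ValueError(
                f"{path}: line {i + 2}: unknown group label {g!r} "
                f"(accepted: {sorted(set(GROUP_SYNONYMS))})"
            )
        groups.append(GROUP_SYNONYMS[key])
    df["group"] = groups
    for flag in MEDICATION_FLAGS:
        if flag in df.columns:
            df[flag] = df[flag].astype(bool)
    return df


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def read_spectra(path: str | Path) -> SpectrumSet:
    """Read a spectra CSV: first column ``ppm``, one subject per column."""
    df = pd.read_csv(path)
    if df.columns[0] != "ppm":
        raise ValueError(f"{path}: first column must be 'ppm', got {df.columns[0]!r}")
    ppm = df["ppm"].to_numpy(dtype=float)
    subjects = [str(c) for c in df.columns[1:]]
    if not subjects:
        raise ValueError(f"{path}: no subject columns")
    intensities = df.iloc[:, 1:].to_numpy(dtype=float).T
    return SpectrumSet(ppm, intensities, subjects)


def write_spectra(spectra: SpectrumSet, path: str | Path) -> None:
    df = pd.DataFrame({"ppm": spectra.ppm})
    for i, sid in enumerate(spectra.subject_ids):
        df[sid] = spectra.intensities[i]
    df.to_csv(path, index=False, float_format="%.10g")


def read_bins(path: str | Path) -> list[BinDefinition]:
    df = pd.read_csv(path)
    for col in ("name", "ppm_lo", "ppm_hi"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return [
        BinDefinition(str(r["name"]), float(r["ppm_lo"]), float(r["ppm_hi"]))
        for _, r in df.iterrows()
    ]


def write_bins(bins, path: str | Path) -> None:
    pd.DataFrame(
        [{"name": b.name, "ppm_lo": b.ppm_lo, "ppm_hi": b.ppm_hi} for b in bins]
    ).to_csv(path, index=False)


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    """Feature matrix CSV plus a ``.meta.json`` sidecar with provenance and
    scaling so the exact transform state round-trips."""
    path = Path(path)
    fm.to_frame().rename_axis("subject_id").to_csv(path, float_format="%.17g")
    meta = {
        "provenance": fm.provenance,
        "scaling": fm.scaling,
        "centers": None if fm.centers is None else ["%.17g" % v for v in fm.centers],
        "scales": None if fm.scales is None else ["%.17g" % v for v in fm.scales],
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=1) + "\n"
    )


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col="subject_id", float_precision="round_trip")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    else:
        meta = {"provenance": ["nmr_bin"] * df.shape[1], "scaling": "raw"}
    centers = meta.get("centers")
    scales = meta.get("scales")
    return FeatureMatrix(
        df.to_numpy(dtype=float),
        [str(c) for c in df.columns],
        list(meta["provenance"]),
        [str(i) for i in df.index],
        scaling=meta.get("scaling", "raw"),
        centers=None if centers is None else np.array([float(v) for v in centers]),
        scales=None if scales is None else np.array([float(v) for v in scales]),
    )


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run description.

    Exactly one of (``cohort_csv`` + ``spectra_csv``) or ``simulation``
    feeds the pipeline. ``comparison`` collapses the three-level group label
    into the binary contrast: ``recent_vs_rest`` (recent vs lifetime+none)
    or ``any_history_vs_none`` (recent+lifetime vs none).
    """

    simulation: SimulationConfig | None = None
    cohort_csv: str | None = None
    spectra_csv: str | None = None
    bins_csv: str | None = None
    normalize: str = "total_area"
    exclusion: tuple[float, float] = DEFAULT_EXCLUSION
    clinical_vars: tuple[str, ...] = DEFAULT_CLINICAL_VARS
    missing: str = "drop"
    validation: ValidationConfig = field(default_factory=ValidationConfig)
    comparison: str = "recent_vs_rest"
    rout_q: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        has_paths = self.cohort_csv is not None or self.spectra_csv is not None
        if has_paths and self.simulation is not None:
            raise ValueError("give either input paths or a simulation config, not both")
        if has_paths and (self.cohort_csv is None or self.spectra_csv is None):
            raise ValueError("both cohort_csv and spectra_csv are required")
        if self.comparison not in ("recent_vs_rest", "any_history_vs_none"):
            raise ValueError(f"unknown comparison {self.comparison!r}")


def binary_labels(groups, comparison: str) -> tuple[np.ndarray, str]:
    """Collapse 3-level group labels into the binary contrast.

    Returns ``(labels, positive_label)``.
    """
    groups = np.asarray(groups, dtype=object)
    if comparison == "recent_vs_rest":
        return np.where(groups == "recent", "recent", "rest"), "recent"
    if comparison == "any_history_vs_none":
        return np.where(groups == "none", "none", "history"), "history"
    raise ValueError(f"unknown comparison {comparison!r}")


# flat key = value config files ---------------------------------------------

_SIM_INT_KEYS = ("n_recent", "n_lifetime", "n_none")
_SIM_FLOAT_KEYS = (
    "relative_sd",
    "lipid_coupling",
    "noise_sd",
    "missing_rate",
    "ppm_min",
    "ppm_max",
    "ppm_step",
)


def read_config(path: str | Path) -> PipelineConfig:
    """Parse a flat ``key = value`` pipeline config file."""
    raw: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}: line {i}: expected 'key = value'")
        key, _, value = line.partition("=")
        raw[key.strip()] = value.strip()

    sim_kwargs: dict = {}
    effects: dict[str, float] = {}
    val_kwargs: dict = {}
    pipe_kwargs: dict = {}
    for key, value in raw.items():
        if key in _SIM_INT_KEYS:
            sim_kwargs[key] = int(value)
        elif key in _SIM_FLOAT_KEYS:
            sim_kwargs[key] = float(value)
        elif key == "peak_shape":
            sim_kwargs[key] = value
        elif key.startswith("effect."):
            effects[key.removeprefix("effect.")] = float(value)
        elif key in ("n_folds", "n_repetitions", "k_ortho"):
            val_kwargs[key] = int(value)
        elif key == "matched_classes":
            val_kwargs[key] = value.lower() in ("1", "true", "yes", "on")
        elif key == "scaling":
            val_kwargs[key] = value
        elif key in ("cohort_csv", "spectra_csv", "bins_csv", "normalize", "comparison", "missing"):
            pipe_kwargs[key] = value
        elif key == "clinical_vars":
            pipe_kwargs[key] = tuple(v for v in value.split(",") if v)
        elif key == "exclusion":
            lo, hi = value.split(",")
            pipe_kwargs[key] = (float(lo), float(hi))
        elif key == "rout_q":
            pipe_kwargs[key] = float(value)
        elif key == "seed":
            pipe_kwargs[key] = int(value)
        else:
            raise ValueError(f"{path}: unknown config key {key!r}")

    seed = pipe_kwargs.get("seed", 0)
    simulation = None
    if "cohort_csv" not in pipe_kwargs:
        simulation = SimulationConfig(**sim_kwargs, seed=seed)
        if effects:
            simulation = replace(simulation, effect_map=effects)
    elif sim_kwargs or effects:
        raise ValueError(f"{path}: simulation keys given alongside input paths")
    validation = ValidationConfig(**val_kwargs, seed=seed)
    return PipelineConfig(simulation=simulation, validation=validation, **pipe_kwargs)


def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    lines = [f"seed = {cfg.seed}"]
    if cfg.simulation is not None:
        s = cfg.simulation
        for key in _SIM_INT_KEYS + _SIM_FLOAT_KEYS + ("peak_shape",):
            lines.append(f"{key} = {getattr(s, key)}")
        for name, d in s.effect_map.items():
            lines.append(f"effect.{name} = {d}")
    else:
        lines += [f"cohort_csv = {cfg.cohort_csv}", f"spectra_csv = {cfg.spectra_csv}"]
        if cfg.bins_csv:
            lines.append(f"bins_csv = {cfg.bins_csv}")
    v = cfg.validation
    lines += [
        f"normalize = {cfg.normalize}",
        f"exclusion = {cfg.exclusion[0]},{cfg.exclusion[1]}",
        f"clinical_vars = {','.join(cfg.clinical_vars)}",
        f"missing = {cfg.missing}",
        f"comparison = {cfg.comparison}",
        f"rout_q = {cfg.rout_q}",
        f"n_folds = {v.n_folds}",
        f"n_repetitions = {v.n_repetitions}",
        f"matched_classes = {v.matched_classes}",
        f"k_ortho = {v.k_ortho}",
        f"scaling = {v.scaling}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# end-to-end pipeline


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the failing stage named."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"pipeline stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full workflow and return the report bundle as a dict."""
    cfg.validate()

    with _stage("input"):
        if cfg.simulation is not None:
            sim = replace(cfg.simulation, seed=cfg.seed)
            cohort, spectra = simulate_cohort(sim)
        else:
            cohort = read_cohort(cfg.cohort_csv)
            spectra = read_spectra(cfg.spectra_csv)
        bins = read_bins(cfg.bins_csv) if cfg.bins_csv else list(DEFAULT_BINS)

    with _stage("preprocess"):
        normalized = normalize_spectra(spectra, cfg.normalize, cfg.exclusion)
        nmr = bin_spectra(normalized, bins)
        clinical = tuple(v for v in cfg.clinical_vars if v in cohort.columns)
        features = integrate_features(cohort, nmr, clinical, missing=cfg.missing)

    with _stage("validate"):
        kept = cohort.set_index("subject_id").loc[features.subject_ids]
        y, positive = binary_labels(kept["group"].to_numpy(), cfg.comparison)
        vcfg = replace(cfg.validation, seed=cfg.seed)
        result = external_cv(features, y, vcfg, positive=positive)
        null = permutation_null(features, y, vcfg, positive=positive)
        ks_d, ks_p = compare_to_null(result, null)

    with _stage("model"):
        centers, scales = fit_scaler(features.values, vcfg.scaling)
        model = fit_opls(
            (features.values - centers) / scales,
            y,
            vcfg.k_ortho,
            positive=positive,
            feature_names=features.feature_names,
            centers=centers,
            scales=scales,
        )
        scores, _ = predict_scores(model, features.values)

    with _stage("diagnostics"):
        curve = roc(scores, y, positive=positive)
        threshold, threshold_accuracy = youden_threshold(curve)
        key_bins = [b.name for b in bins if b.name in features.feature_names]
        feat_frame = features.to_frame()
        welch = welch_report(feat_frame, y, key_bins, positive=positive, rout_q=cfg.rout_q)
        continuous = [v for v in clinical if v != "age"]
        categorical = [f for f in MEDICATION_FLAGS if f in cohort.columns]
        clin_table = table_one(kept.reset_index(), ["age", *continuous], categorical)

    n_pos = int((y == positive).sum())
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "software": {"package": "seropls", "version": __version__},
        "seed": cfg.seed,
        "comparison": cfg.comparison,
        "classes": {
            "positive": positive,
            "n_positive": n_pos,
            "n_negative": int(y.size - n_pos),
        },
        "n_subjects": int(y.size),
        "n_features": features.n_features,
        "validation": result.to_dict(),
        "null": null.to_dict(),
        "ks_vs_null": {"D": ks_d, "p": ks_p},
        "all_data_model": {
            "k_ortho": model.k_ortho,
            "R2X_pct": 100.0 * model.r2x,
            "R2Y_pct": 100.0 * model.r2y,
            "Q2_pct": 100.0 * model.q2,
            "auc": curve.auc,
            "auc_ci95": list(curve.auc_ci),
            "youden_threshold": threshold,
            "threshold_accuracy_pct": threshold_accuracy,
        },
        "univariate": {
            "key_metabolites": welch.to_dict(orient="records"),
            "clinical_table": clin_table.to_dict(orient="records"),
        },
    }
    report["_artifacts"] = {
        "cohort": cohort,
        "features": features,
        "model": model,
        "scores": scores,
        "labels": y,
        "curve": curve,
        "result": result,
        "nulldist": null,
    }
    return report


def write_report(report: dict, out_dir: str | Path) -> Path:
    """Write the report bundle: report.json plus CSV side tables and a log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = report.pop("_artifacts", None)
    path = out / "report.json"
    path.write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    if artifacts is not None:
        write_cohort(artifacts["cohort"], out / "cohort.csv")
        write_feature_matrix(artifacts["features"], out / "features.csv")
        artifacts["model"].save(out / "model.txt")
        pd.DataFrame(
            {
                "subject_id": artifacts["features"].subject_ids,
                "score": artifacts["scores"],
                "label": artifacts["labels"],
            }
        ).to_csv(out / "scores.csv", index=False)
        curve = artifacts["curve"]
        pd.DataFrame(
            {"threshold": curve.thresholds, "tpr": curve.tpr, "fpr": curve.fpr}
        ).to_csv(out / "roc.csv", index=False)
        pd.DataFrame(
            report["validation"]["vip"]
        ).to_csv(out / "vip.csv", index=False)
        pd.DataFrame(
            report["univariate"]["key_metabolites"]
        ).to_csv(out / "univariate_metabolites.csv", index=False)
        pd.DataFrame(
            report["univariate"]["clinical_table"]
        ).to_csv(out / "clinical_table.csv", index=False)
        report["_artifacts"] = artifacts
    logger.info("report written to %s", path)
    return path
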