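"""Spectral normalization, binning, and assembly of the scaled feature matrix.

The pipeline here turns raw spectra plus clinical chemistry into the X block
of the multivariate analysis: normalize each spectrum (total-area or
probabilistic quotient), integrate named ppm windows into metabolite
features, join the clinical-chemistry columns, and column-scale.

Bins are half-open ``[lo, hi)`` intervals on the ppm axis; their values are
integrals of the piecewise-linear interpolant of the spectrum, so adjacent
bins never double-count signal and splitting a bin at any interior point is
exactly additive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import SpectrumSet

logger = logging.getLogger("seropls")

__all__ = [
    "BinDefinition",
    "FeatureMatrix",
    "DEFAULT_BINS",
    "DEFAULT_EXCLUSION",
    "DEFAULT_CLINICAL_VARS",
    "uniform_bins",
    "normalize_spectra",
    "bin_spectra",
    "integrate_features",
    "scale_features",
]


@dataclass(frozen=True)
class BinDefinition:
    """A named ppm window ``[ppm_lo, ppm_hi)``."""

    name: str
    ppm_lo: float
    ppm_hi: float

    def __post_init__(self) -> None:
        if not self.ppm_lo < self.ppm_hi:
            raise ValueError(f"bin {self.name!r}: require ppm_lo < ppm_hi")


#: default discriminatory-resonance windows: lipoprotein methyl/methylene
#: regions, the GlycA acetyl resonance and glutamine.
DEFAULT_BINS: tuple[BinDefinition, ...] = (
    BinDefinition("hdl", 0.81, 0.87),
    BinDefinition("vldl_triglyceride", 0.87, 0.92),
    BinDefinition("triglyceride_vldl_a", 1.22, 1.32),
    BinDefinition("triglyceride_vldl_b", 1.34, 1.43),
    BinDefinition("glyca", 2.04, 2.05),
    BinDefinition("glutamine", 2.43, 2.47),
)

#: residual-water region excluded from normalization integrals (ppm).
DEFAULT_EXCLUSION: tuple[float, float] = (4.5, 5.0)

#: continuous clinical-chemistry columns joined into the feature matrix.
DEFAULT_CLINICAL_VARS: tuple[str, ...] = (
    "age",
    "bmi",
    "egfr",
    "alt",
    "ast",
    "hba1c",
    "ferritin",
    "cholesterol",
    "triglycerides",
    "hdl_cholesterol",
    "ldl_cholesterol",
    "lsm_kpa",
)


def uniform_bins(
    lo: float,
    hi: float,
    width: float = 0.04,
    exclude: tuple[float, float] | None = DEFAULT_EXCLUSION,
) -> list[BinDefinition]:
    """Full-spectrum uniform binning, skipping bins inside the excluded window."""
    edges = np.arange(lo, hi, width)
    bins = []
    for e in edges:
        b_lo, b_hi = float(e), float(min(e + width, hi))
        if exclude is not None and b_lo < exclude[1] and b_hi > exclude[0]:
            continue
        bins.append(BinDefinition(f"bin_{b_lo:.2f}_{b_hi:.2f}", b_lo, b_hi))
    return bins


@dataclass
class FeatureMatrix:
    """Subject x feature matrix with provenance and scaling metadata.

    ``provenance`` labels each feature ``nmr_bin`` or ``clinical``.
    ``scaling`` is one of ``raw | centered | unit_variance | pareto``; when
    not raw, ``centers`` and ``scales`` hold the training statistics so the
    transform can be inverted exactly or applied to new data.
    """

    values: np.ndarray
    feature_names: list[str]
    provenance: list[str]
    subject_ids: list[str]
    scaling: str = "raw"
    centers: np.ndarray | None = None
    scales: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.subject_ids), len(self.feature_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.feature_names)} features"
            )
        if len(self.provenance) != len(self.feature_names):
            raise ValueError("provenance length does not match feature names")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.subject_ids, columns=self.feature_names
        )

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values.copy(),
            list(self.feature_names),
            list(self.provenance),
            list(self.subject_ids),
            self.scaling,
            None if self.centers is None else self.centers.copy(),
            None if self.scales is None else self.scales.copy(),
        )

    def inverse_transform(self) -> "FeatureMatrix":
        """Undo centering/scaling exactly, returning a raw matrix."""
        if self.scaling == "raw":
            return self.copy()
        values = self.values * self.scales + self.centers
        return FeatureMatrix(
            values,
            list(self.feature_names),
            list(self.provenance),
            list(self.subject_ids),
        )


# ---------------------------------------------------------------------------
# spectral integrals


def _segment_integral(ppm: np.ndarray, rows: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Integral of each row's linear interpolant over [lo, hi] (clipped to axis)."""
    lo = max(lo, float(ppm[0]))
    hi = min(hi, float(ppm[-1]))
    if hi <= lo:
        return np.zeros(rows.shape[0])
    inner = ppm[(ppm > lo) & (ppm < hi)]
    grid = np.concatenate(([lo], inner, [hi]))
    vals = np.empty((rows.shape[0], grid.size))
    for i in range(rows.shape[0]):
        vals[i] = np.interp(grid, ppm, rows[i])
    return np.trapezoid(vals, grid, axis=1)


def normalize_spectra(
    spectra: SpectrumSet,
    method: str = "total_area",
    exclusion_window: tuple[float, float] = DEFAULT_EXCLUSION,
) -> SpectrumSet:
    """Normalize each spectrum for dilution.

    ``total_area`` divides each spectrum by its integral outside the
    exclusion window (the residual-water region by default). ``pqn`` divides
    each spectrum by its median point-wise quotient against the median
    reference spectrum, computed outside the exclusion window. ``none`` is
    the identity.
    """
    if method == "none":
        return spectra.copy()
    lo, hi = exclusion_window
    if not (spectra.ppm[0] <= lo < hi <= spectra.ppm[-1]):
        raise ValueError(
            f"exclusion window [{lo}, {hi}] not within ppm axis "
            f"[{spectra.ppm[0]}, {spectra.ppm[-1]}]"
        )
    out = spectra.copy()
    if method == "total_area":
        area = _segment_integral(
            spectra.ppm, spectra.intensities, spectra.ppm[0], lo
        ) + _segment_integral(spectra.ppm, spectra.intensities, hi, spectra.ppm[-1])
        for i, a in enumerate(area):
            if a <= 0:
                raise ValueError(
                    f"degenerate spectrum for subject {spectra.subject_ids[i]!r}: "
                    "zero integral outside exclusion window"
                )
        out.intensities = spectra.intensities / area[:, None]
        return out
    if method == "pqn":
        keep = (spectra.ppm < lo) | (spectra.ppm > hi)
        ref = np.median(spectra.intensities[:, keep], axis=0)
        informative = ref > 1e-9 * ref.max()
        if not informative.any():
            raise ValueError("degenerate reference spectrum: no signal for pqn")
        quotients = spectra.intensities[:, keep][:, informative] / ref[informative]
        factors = np.median(quotients, axis=1)
        for i, f in enumerate(factors):
            if f <= 0:
                raise ValueError(
                    f"degenerate spectrum for subject {spectra.subject_ids[i]!r}: "
                    "non-positive median quotient"
                )
        out.intensities = spectra.intensities / factors[:, None]
        return out
    raise ValueError(f"unknown normalization method {method!r}")


def bin_spectra(
    spectra: SpectrumSet, bins: list[BinDefinition] | tuple[BinDefinition, ...] = DEFAULT_BINS
) -> FeatureMatrix:
    """Integrate each named ppm window into one feature per subject."""
    names = [b.name for b in bins]
    if len(set(names)) != len(names):
        raise ValueError("bin names must be unique")
    axis_lo, axis_hi = float(spectra.ppm[0]), float(spectra.ppm[-1])
    values = np.empty((spectra.n_subjects, len(bins)))
    for j, b in enumerate(bins):
        if b.ppm_hi <= axis_lo or b.ppm_lo >= axis_hi:
            raise ValueError(
                f"bin {b.name!r} [{b.ppm_lo}, {b.ppm_hi}) does not overlap the "
                f"ppm axis [{axis_lo}, {axis_hi}]"
            )
        values[:, j] = _segment_integral(
            spectra.ppm, spectra.intensities, b.ppm_lo, b.ppm_hi
        )
    return FeatureMatrix(
        values, names, ["nmr_bin"] * len(bins), list(spectra.subject_ids)
    )


def integrate_features(
    cohort: pd.DataFrame,
    nmr: FeatureMatrix,
    clinical_vars: list[str] | tuple[str, ...] = DEFAULT_CLINICAL_VARS,
    missing: str = "drop",
) -> FeatureMatrix:
    """Join clinical-chemistry columns onto the binned NMR features.

    Subjects must align one-to-one between the cohort table and the NMR
    matrix. Missing clinical values are handled per ``missing``: ``drop``
    removes the subject, ``impute`` fills with the column median.
    """
    cohort_ids = list(cohort["subject_id"].astype(str))
    if cohort_ids != list(nmr.subject_ids):
        extra = sorted(set(cohort_ids) ^ set(nmr.subject_ids)) or ["(ordering differs)"]
        raise ValueError(f"subject ids do not align between cohort and spectra: {extra}")
    if not clinical_vars:
        return nmr.copy()
    missing_cols = [v for v in clinical_vars if v not in cohort.columns]
    if missing_cols:
        raise KeyError(f"clinical variables not in cohort table: {missing_cols}")
    clin = cohort[list(clinical_vars)].astype(float).to_numpy()
    keep = np.ones(len(cohort_ids), dtype=bool)
    if np.isnan(clin).any():
        if missing == "drop":
            keep = ~np.isnan(clin).any(axis=1)
            n_drop = int((~keep).sum())
            logger.warning("dropping %d subject(s) with missing clinical values", n_drop)
            clin = clin[keep]
        elif missing == "impute":
            med = np.nanmedian(clin, axis=0)
            clin = np.where(np.isnan(clin), med, clin)
        else:
            raise ValueError(f"unknown missing-data policy {missing!r}")
    values = np.hstack([nmr.values[keep], clin])
    return FeatureMatrix(
        values,
        list(nmr.feature_names) + list(clinical_vars),
        list(nmr.provenance) + ["clinical"] * len(clinical_vars),
        [s for s, k in zip(cohort_ids, keep) if k],
    )


def fit_scaler(
    values: np.ndarray, method: str = "unit_variance"
) -> tuple[np.ndarray, np.ndarray]:
    """Column centers and scales from training data only.

    Returns ``(centers, scales)``; scales are sd for ``unit_variance``,
    sqrt(sd) for ``pareto`` and 1 for ``center_only``. Zero-variance columns
    get scale 1 (they carry no information either way).
    """
    if method not in ("unit_variance", "pareto", "center_only"):
        raise ValueError(f"unknown scaling method {method!r}")
    centers = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    if method == "center_only":
        scales = np.ones_like(sd)
    else:
        safe = np.where(sd > 0, sd, 1.0)
        scales = safe if method == "unit_variance" else np.sqrt(safe)
    return centers, scales


def scale_features(fm: FeatureMatrix, method: str = "unit_variance") -> FeatureMatrix:
    """Center and scale columns; drop zero-variance columns with a warning."""
    if fm.n_subjects < 2:
        raise ValueError("scaling requires at least 2 subjects")
    sd = fm.values.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all columns have zero variance; nothing to scale")
    if not keep.all():
        dropped = [n for n, k in zip(fm.feature_names, keep) if not k]
        logger.warning("dropping zero-variance feature(s): %s", dropped)
    values = fm.values[:, keep]
    centers, scales = fit_scaler(values, method)
    return FeatureMatrix(
        (values - centers) / scales,
        [n for n, k in zip(fm.feature_names, keep) if k],
        [p for p, k in zip(fm.provenance, keep) if k],
        list(fm.subject_ids),
        scaling={"unit_variance": "unit_variance", "pareto": "pareto", "center_only": "centered"}[method],
        centers=centers,
        scales=scales,
    )
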