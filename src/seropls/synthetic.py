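"""Synthetic serum-metabolomics cohorts: clinical table plus 1D ¹H-NMR spectra.

Generates case/control style cohorts of NAFLD-like subjects split into three
depression-history groups (``recent`` / ``lifetime`` / ``none``), with

* a clinical-chemistry table (lipids, liver enzymes, HbA1c, ferritin, eGFR,
  BMI, liver stiffness, medication flags, age, sex), and
* simulated serum spectra built as sums of Lorentzian (optionally Gaussian)
  resonances on a ppm axis plus i.i.d. noise.

Group differences are injected as standardized mean differences (Cohen's d,
recent group vs the rest) on named features; the same latent per-subject
"lipid factor" drives both the serum triglyceride value and the methylene
resonance amplitudes so clinical and spectral features correlate as they do
in real serum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Peak",
    "GroupCovariates",
    "SimulationConfig",
    "SpectrumSet",
    "simulate_cohort",
    "DEFAULT_PEAKS",
    "DEFAULT_EFFECTS",
    "DEFAULT_COVARIATES",
    "CLINICAL_VARIABLES",
    "MEDICATION_FLAGS",
    "GROUPS",
]

GROUPS = ("recent", "lifetime", "none")

#: clinical variable -> (baseline mean, baseline sd); units follow routine
#: clinical chemistry (lipids mmol/L, enzymes IU/mL, HbA1c %, ferritin ug/L,
#: eGFR mL/min/1.73m2, BMI kg/m2, liver stiffness kPa).
CLINICAL_VARIABLES: dict[str, tuple[float, float]] = {
    "bmi": (33.0, 7.0),
    "egfr": (85.0, 15.0),
    "alt": (30.0, 18.0),
    "ast": (22.0, 11.0),
    "hba1c": (7.3, 1.9),
    "ferritin": (95.0, 80.0),
    "cholesterol": (4.4, 1.2),
    "triglycerides": (1.7, 0.95),
    "hdl_cholesterol": (1.1, 0.30),
    "ldl_cholesterol": (2.4, 0.95),
    "lsm_kpa": (6.0, 2.8),
}

#: medication-use probability per group, in GROUPS order.
MEDICATION_FLAGS: dict[str, tuple[float, float, float]] = {
    "antidepressant": (0.457, 0.400, 0.0),
    "statin": (0.630, 0.567, 0.598),
    "fibrate": (0.148, 0.067, 0.093),
}

#: clinical variables tied to the latent lipid factor (and their loading sign)
_LIPID_COUPLED_CLINICAL = {"triglycerides": 1.0, "hdl_cholesterol": -0.5}


@dataclass(frozen=True)
class Peak:
    """One simulated resonance: name, center (ppm), half-width at half max
    (ppm), base amplitude (arbitrary units), and whether the amplitude rides
    on the latent lipid factor."""

    name: str
    center: float
    width: float
    amplitude: float
    lipid_coupled: bool = False


#: resonances emulating the dominant features of a serum proton spectrum;
#: names of the discriminatory peaks match the default bin names so effects
#: injected on a bin land on the right resonance.
DEFAULT_PEAKS: tuple[Peak, ...] = (
    Peak("hdl", 0.840, 0.020, 8.0),
    Peak("vldl_triglyceride", 0.895, 0.015, 10.0, lipid_coupled=True),
    Peak("triglyceride_vldl_a", 1.270, 0.030, 25.0, lipid_coupled=True),
    Peak("triglyceride_vldl_b", 1.385, 0.025, 12.0, lipid_coupled=True),
    Peak("alanine", 1.480, 0.007, 3.0),
    Peak("glyca", 2.045, 0.008, 6.0),
    Peak("glutamine", 2.450, 0.012, 4.0),
    Peak("creatinine", 3.050, 0.007, 5.0),
    Peak("glucose_a", 3.450, 0.040, 15.0),
    Peak("glucose_b", 3.750, 0.040, 12.0),
    Peak("lactate", 4.120, 0.008, 4.0),
    Peak("water_residual", 4.750, 0.050, 30.0),
)

#: default injected effects (Cohen's d, recent vs rest): elevated VLDL and
#: triglyceride resonances and GlycA, reduced HDL and glutamine, mirrored on
#: the corresponding clinical-chemistry variables; sized for a moderately
#: separable, not trivially separable, classification problem.
DEFAULT_EFFECTS: dict[str, float] = {
    "vldl_triglyceride": 0.45,
    "triglyceride_vldl_a": 0.45,
    "triglyceride_vldl_b": 0.45,
    "glyca": 0.35,
    "hdl": -0.35,
    "glutamine": -0.35,
    "triglycerides": 0.45,
    "hdl_cholesterol": -0.30,
}


@dataclass(frozen=True)
class GroupCovariates:
    """Age distribution (years) and female fraction for one group."""

    age_mean: float
    age_sd: float
    female_fraction: float


#: per-group age/sex structure: the recent-depression group is younger and
#: the lifetime group oldest and most female, preserving the confounding
#: pattern the analysis has to be robust to.
DEFAULT_COVARIATES: dict[str, GroupCovariates] = {
    "recent": GroupCovariates(55.0, 11.0, 0.469),
    "lifetime": GroupCovariates(65.0, 10.0, 0.633),
    "none": GroupCovariates(61.0, 12.0, 0.383),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic cohort.

    Parameters
    ----------
    n_recent, n_lifetime, n_none
        Group sizes (each >= 2). Defaults mirror the 81/30/107 design.
    effect_map
        feature name -> standardized mean difference d (recent vs rest).
        Names may refer to clinical variables or to simulated resonances.
    covariate_model
        per-group age mean/sd and female fraction.
    peak_table
        resonances to simulate.
    relative_sd
        between-subject coefficient of variation of every peak amplitude.
    lipid_coupling
        correlation of lipid-coupled features with the shared latent factor.
    noise_sd
        spectral noise sd as a fraction of the median peak amplitude.
    missing_rate
        MCAR missingness probability applied to clinical-chemistry values.
    peak_shape
        'lorentzian' (NMR lineshape) or 'gaussian'.
    ppm_min, ppm_max, ppm_step
        the simulated chemical-shift axis.
    seed
        master seed; every random sub-stream derives from it.
    """

    n_recent: int = 81
    n_lifetime: int = 30
    n_none: int = 107
    effect_map: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    covariate_model: dict[str, GroupCovariates] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )
    peak_table: tuple[Peak, ...] = DEFAULT_PEAKS
    relative_sd: float = 0.18
    lipid_coupling: float = 0.6
    noise_sd: float = 0.02
    missing_rate: float = 0.0
    peak_shape: str = "lorentzian"
    ppm_min: float = 0.0
    ppm_max: float = 5.5
    ppm_step: float = 0.001
    seed: int = 0

    def with_effects(self, **effects: float) -> "SimulationConfig":
        """Copy of this config with the effect map replaced."""
        return replace(self, effect_map=dict(effects))

    def scaled_effects(self, factor: float) -> "SimulationConfig":
        """Copy with every injected d multiplied by ``factor``."""
        return replace(
            self, effect_map={k: v * factor for k, v in self.effect_map.items()}
        )

    def validate(self) -> None:
        for name, n in [
            ("n_recent", self.n_recent),
            ("n_lifetime", self.n_lifetime),
            ("n_none", self.n_none),
        ]:
            if n < 2:
                raise ValueError(f"group size {name}={n} must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.relative_sd < 0:
            raise ValueError("relative_sd must be >= 0")
        if not 0.0 <= self.lipid_coupling <= 1.0:
            raise ValueError("lipid_coupling must lie in [0, 1]")
        if self.peak_shape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown peak_shape {self.peak_shape!r}")
        if not self.ppm_min < self.ppm_max:
            raise ValueError("require ppm_min < ppm_max")
        peak_names = {p.name for p in self.peak_table}
        for p in self.peak_table:
            if p.width <= 0:
                raise ValueError(f"peak {p.name!r}: width must be > 0")
            if not self.ppm_min <= p.center <= self.ppm_max:
                raise ValueError(
                    f"peak {p.name!r}: center {p.center} outside ppm axis "
                    f"[{self.ppm_min}, {self.ppm_max}]"
                )
        known = set(CLINICAL_VARIABLES) | peak_names
        unknown = set(self.effect_map) - known
        if unknown:
            raise KeyError(
                "effect_map names not among clinical variables or simulated "
                f"resonances: {sorted(unknown)}"
            )


@dataclass
class SpectrumSet:
    """A ppm axis plus one intensity vector per subject.

    ``ppm`` is strictly monotone increasing; ``intensities`` has one row per
    subject, aligned with ``subject_ids``.
    """

    ppm: np.ndarray
    intensities: np.ndarray
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        d = np.diff(self.ppm)
        if d.size and not (np.all(d > 0) or np.all(d < 0)):
            bad = int(np.argmax(np.sign(d) != np.sign(d[0])))
            raise ValueError(f"ppm axis not strictly monotone at index {bad + 1}")
        if d.size and d[0] < 0:  # accept descending input, store ascending
            self.ppm = self.ppm[::-1].copy()
            self.intensities = self.intensities[:, ::-1].copy()
        if self.intensities.shape[0] != len(self.subject_ids):
            raise ValueError(
                f"{self.intensities.shape[0]} spectra for "
                f"{len(self.subject_ids)} subject ids"
            )
        if self.intensities.shape[1] != self.ppm.size:
            raise ValueError("intensity row length does not match ppm axis")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("non-finite intensity values")

    @property
    def n_subjects(self) -> int:
        return self.intensities.shape[0]

    def copy(self) -> "SpectrumSet":
        return SpectrumSet(
            self.ppm.copy(), self.intensities.copy(), list(self.subject_ids)
        )


def _lineshape(ppm: np.ndarray, peak: Peak, shape: str) -> np.ndarray:
    x = ppm - peak.center
    if shape == "lorentzian":
        return peak.width**2 / (x**2 + peak.width**2)
    sigma = peak.width / np.sqrt(2.0 * np.log(2.0))  # match HWHM
    return np.exp(-0.5 * (x / sigma) ** 2)


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, SpectrumSet]:
    """Draw one cohort: a clinical table and the matching spectra.

    Returns
    -------
    cohort : pandas.DataFrame
        One row per subject with ``subject_id``, ``group``, ``age``, ``sex``,
        the clinical-chemistry variables and boolean medication flags.
    spectra : SpectrumSet
        Simulated serum spectra aligned to the cohort rows.

    The recent group's mean on every feature named in ``effect_map`` is
    shifted by d x (between-subject sd) relative to the other two groups,
    both on the clinical value and on the amplitude of the resonance of the
    same name. Identical config (including seed) gives bit-identical output.
    """
    config.validate()
    master = np.random.SeedSequence(config.seed)
    rng_cov, rng_clin, rng_amp, rng_noise, rng_miss = (
        np.random.default_rng(s) for s in master.spawn(5)
    )

    groups = np.repeat(
        GROUPS, [config.n_recent, config.n_lifetime, config.n_none]
    ).astype(object)
    n = groups.size
    subject_ids = [f"S{i + 1:04d}" for i in range(n)]
    is_recent = groups == "recent"

    # --- demographics -----------------------------------------------------
    age = np.empty(n)
    sex = np.empty(n, dtype=object)
    for g in GROUPS:
        cov = config.covariate_model[g]
        mask = groups == g
        k = int(mask.sum())
        age[mask] = np.clip(rng_cov.normal(cov.age_mean, cov.age_sd, k), 18.0, 95.0)
        sex[mask] = np.where(rng_cov.random(k) < cov.female_fraction, "F", "M")

    # --- latent lipid factor couples triglycerides and CH2 resonances -----
    z_lipid = rng_clin.standard_normal(n)
    rho = config.lipid_coupling

    cohort = pd.DataFrame({"subject_id": subject_ids, "group": groups})
    cohort["age"] = np.round(age, 1)
    cohort["sex"] = sex
    for var, (mu, sd) in CLINICAL_VARIABLES.items():
        loading = _LIPID_COUPLED_CLINICAL.get(var)
        if loading is not None:
            eps = rho * np.sign(loading) * z_lipid + np.sqrt(
                1.0 - rho**2
            ) * rng_clin.standard_normal(n)
        else:
            eps = rng_clin.standard_normal(n)
        d = config.effect_map.get(var, 0.0)
        values = mu + sd * (eps + d * is_recent)
        cohort[var] = np.round(np.maximum(values, 0.05 * mu), 3)
    for flag, probs in MEDICATION_FLAGS.items():
        p = np.select([groups == g for g in GROUPS], probs)
        cohort[flag] = rng_clin.random(n) < p

    if config.missing_rate > 0:
        for var in CLINICAL_VARIABLES:
            mask = rng_miss.random(n) < config.missing_rate
            cohort.loc[mask, var] = np.nan

    # --- spectra -----------------------------------------------------------
    ppm = np.arange(config.ppm_min, config.ppm_max + 0.5 * config.ppm_step, config.ppm_step)
    intensities = np.zeros((n, ppm.size))
    for peak in config.peak_table:
        if peak.lipid_coupled:
            eps = rho * z_lipid + np.sqrt(1.0 - rho**2) * rng_amp.standard_normal(n)
        else:
            eps = rng_amp.standard_normal(n)
        d = config.effect_map.get(peak.name, 0.0)
        amps = peak.amplitude * (1.0 + config.relative_sd * (eps + d * is_recent))
        amps = np.maximum(amps, 0.0)
        intensities += np.outer(amps, _lineshape(ppm, peak, config.peak_shape))
    if config.noise_sd > 0:
        scale = config.noise_sd * float(
            np.median([p.amplitude for p in config.peak_table])
        )
        intensities += rng_noise.normal(0.0, scale, intensities.shape)
    np.maximum(intensities, 0.0, out=intensities)

    return cohort, SpectrumSet(ppm, intensities, subject_ids)
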