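"""Synthetic cohorts of multi-frequency impedance recordings.

The generator emulates the reference study design — 5 men and 5 women per
age decade from the 20s through the 60s (50 subjects), eight muscles per
subject with the gastrocnemius recorded bilaterally, 256 frequencies
log-spaced over 4–1000 kHz — with per-muscle/per-gender Cole-parameter
distributions calibrated to the packaged normative means ± SD.

Calibration is an inverse problem over the normative table: for each
muscle × gender cell the mean of R0 is the tabulated Re, the mean of Ri
is tabulated directly, R_inf follows from the two by construction
(rinf = Re·Ri/(Re+Ri), which also induces the only cross-parameter
correlation), fc takes its tabulated mean, and the dispersion exponent
alpha is solved by 1-D root finding so the model reactance at 50 kHz
equals the tabulated Xc mean (an alpha = 1 semicircle over-predicts Xc
in every cell).  R, Z and PA at 50 kHz are then emergent quantities —
they are not calibrated, and their agreement with the tabulated means is
a cross-check of the single-dispersion model.

Sampling uses truncated normals, symmetric about the mean (bounds
[t·mean, (2−t)·mean], default t = 0.1) so cell means are preserved
exactly; SDs larger than their mean (two fc cells in the source table)
are capped at the mean and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cole import (
    ColeParameters,
    REPORT_FREQUENCY_KHZ,
    cole_impedance,
    derive_parameters,
    evaluate_cole,
    rinf_from,
)
from .exceptions import CalibrationError, DomainError, SamplingError
from .reference import load_reference
from .spectra import MUSCLES, ImpedanceSpectrum, SpectrumMeta
from .stats import Cohort, SubjectRecord, OLD_DECADES

__all__ = [
    "GeneratorConfig",
    "CalibratedCell",
    "SimulatedSubject",
    "SimulatedCohort",
    "solve_alpha",
    "calibrate_generator",
    "generate_subject",
    "generate_cohort",
]

DECADES = (20, 30, 40, 50, 60)
_MAX_RETRIES = 1000


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design knobs of the synthetic cohort.

    Defaults are the reference design: 5 subjects per gender × decade,
    1% proportional complex noise, 256 log-spaced frequencies over
    4–1000 kHz, no age effect, truncation bound at 0.1 of the mean,
    side-to-side correlation 0.8 for the bilateral muscle.
    """

    n_per_cell: int = 5
    seed: int = 0
    noise_sd_fraction: float = 0.01
    n_frequencies: int = 256
    f_min: float = 4.0
    f_max: float = 1000.0
    age_effect: float = 1.0
    truncation: float = 0.1
    side_correlation: float = 0.8

    def __post_init__(self) -> None:
        if self.n_per_cell < 1:
            raise DomainError("n_per_cell must be at least 1")
        if not 0.0 <= self.noise_sd_fraction < 0.2:
            raise DomainError("noise_sd_fraction must lie in [0, 0.2)")
        if not 0.0 < self.f_min < self.f_max:
            raise DomainError("require 0 < f_min < f_max")
        if self.n_frequencies < 8:
            raise DomainError("n_frequencies must be at least 8")
        if not 0.0 < self.truncation < 1.0:
            raise DomainError("truncation must lie in (0, 1)")
        if not 0.0 <= self.side_correlation < 1.0:
            raise DomainError("side_correlation must lie in [0, 1)")

    @property
    def frequency_grid(self) -> np.ndarray:
        return np.geomspace(self.f_min, self.f_max, self.n_frequencies)


@dataclass(frozen=True)
class CalibratedCell:
    """Sampling distribution of one muscle × gender cell.

    Means and SDs of (r0, ri, fc); rinf is constructed per draw as
    rinf_from(r0, ri); alpha is fixed per cell by the reactance solve.
    """

    muscle: str
    gender: str
    r0_mean: float
    r0_sd: float
    ri_mean: float
    ri_sd: float
    fc_mean: float
    fc_sd: float
    alpha: float
    fc_sd_capped: bool = False

    @property
    def rinf_mean(self) -> float:
        return rinf_from(self.r0_mean, self.ri_mean)

    def mean_parameters(self) -> ColeParameters:
        return ColeParameters(
            r0=self.r0_mean, rinf=self.rinf_mean, fc=self.fc_mean, alpha=self.alpha
        )


def solve_alpha(
    r0: float, rinf: float, fc: float, xc_target: float, frequency_khz: float = REPORT_FREQUENCY_KHZ
) -> float:
    """Dispersion exponent making the model reactance at 50 kHz hit a target.

    The reactance at a fixed frequency increases monotonically with alpha
    on (0, 1]; the geometric ceiling is the alpha = 1 value (at most the
    arc radius (r0 − rinf)/2).  A target above the ceiling has no
    admissible alpha and raises :class:`CalibrationError`.
    """

    def xc_at(alpha: float) -> float:
        p = ColeParameters(r0=r0, rinf=rinf, fc=fc, alpha=alpha)
        _, xc = evaluate_cole(p, frequency_khz)
        return xc

    if xc_target <= 0.0:
        raise CalibrationError(f"target reactance must be positive, got {xc_target}")
    ceiling = xc_at(1.0)
    if xc_target > ceiling:
        raise CalibrationError(
            f"no alpha in (0, 1] reaches Xc={xc_target:.3g} Ω at {frequency_khz:g} kHz "
            f"(ceiling {ceiling:.3g} Ω at alpha=1)"
        )
    if math.isclose(xc_target, ceiling, rel_tol=1e-12):
        return 1.0
    lo = 1e-6
    return float(brentq(lambda a: xc_at(a) - xc_target, lo, 1.0, xtol=1e-12, rtol=1e-14))


def calibrate_generator(reference: pd.DataFrame | None = None) -> dict[tuple[str, str], CalibratedCell]:
    """Solve the per-cell sampling distributions from the normative table."""
    if reference is None:
        reference = load_reference()
    cells: dict[tuple[str, str], CalibratedCell] = {}
    for muscle in MUSCLES:
        for gender in ("men", "women"):
            def mval(p, which="mean"):
                return float(reference.loc[(muscle, gender, p), which])

            r0_mean, r0_sd = mval("Re"), mval("Re", "sd")
            ri_mean, ri_sd = mval("Ri"), mval("Ri", "sd")
            fc_mean, fc_sd = mval("fc"), mval("fc", "sd")
            fc_capped = fc_sd > fc_mean
            if fc_capped:
                fc_sd = fc_mean
            rinf = rinf_from(r0_mean, ri_mean)
            try:
                alpha = solve_alpha(r0_mean, rinf, fc_mean, mval("Xc"))
            except CalibrationError as err:
                raise CalibrationError(str(err), muscle=muscle, gender=gender) from None
            cells[(muscle, gender)] = CalibratedCell(
                muscle=muscle,
                gender=gender,
                r0_mean=r0_mean,
                r0_sd=r0_sd,
                ri_mean=ri_mean,
                ri_sd=ri_sd,
                fc_mean=fc_mean,
                fc_sd=fc_sd,
                alpha=alpha,
                fc_sd_capped=fc_capped,
            )
    return cells


def _trunc_bounds(mean: float, truncation: float) -> tuple[float, float]:
    # Symmetric about the mean so the truncated mean equals the target mean.
    return truncation * mean, (2.0 - truncation) * mean


def _sample_trunc(rng: np.random.Generator, mean: float, sd: float, truncation: float) -> float:
    lo, hi = _trunc_bounds(mean, truncation)
    for _ in range(_MAX_RETRIES):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    raise SamplingError(f"truncated sampling exhausted (mean={mean}, sd={sd})")


def _sample_trunc_pair(
    rng: np.random.Generator, mean: float, sd: float, truncation: float, rho: float
) -> tuple[float, float]:
    """A correlated pair from the same truncated normal (bilateral muscle)."""
    lo, hi = _trunc_bounds(mean, truncation)
    c = math.sqrt(1.0 - rho**2)
    for _ in range(_MAX_RETRIES):
        z1 = rng.standard_normal()
        z2 = rho * z1 + c * rng.standard_normal()
        v1, v2 = mean + sd * z1, mean + sd * z2
        if lo <= v1 <= hi and lo <= v2 <= hi:
            return float(v1), float(v2)
    raise SamplingError(f"truncated pair sampling exhausted (mean={mean}, sd={sd})")


def _sample_cell_params(
    rng: np.random.Generator, cell: CalibratedCell, config: GeneratorConfig, scale: float, n_sides: int
) -> list[ColeParameters]:
    """Draw Cole parameters for one muscle (one per side, correlated across sides)."""
    if n_sides == 1:
        draws = {
            name: (_sample_trunc(rng, mean * scale, sd * scale, config.truncation),)
            for name, mean, sd in (
                ("r0", cell.r0_mean, cell.r0_sd),
                ("ri", cell.ri_mean, cell.ri_sd),
                ("fc", cell.fc_mean, cell.fc_sd),
            )
        }
    else:
        draws = {
            name: _sample_trunc_pair(
                rng, mean * scale, sd * scale, config.truncation, config.side_correlation
            )
            for name, mean, sd in (
                ("r0", cell.r0_mean, cell.r0_sd),
                ("ri", cell.ri_mean, cell.ri_sd),
                ("fc", cell.fc_mean, cell.fc_sd),
            )
        }
    out = []
    for i in range(n_sides):
        r0, ri, fc = draws["r0"][i], draws["ri"][i], draws["fc"][i]
        out.append(ColeParameters(r0=r0, rinf=rinf_from(r0, ri), fc=fc, alpha=cell.alpha))
    return out


def render_spectrum(
    params: ColeParameters,
    config: GeneratorConfig,
    rng: np.random.Generator,
    meta: SpectrumMeta,
) -> ImpedanceSpectrum:
    """Evaluate the model on the frequency grid and add proportional complex noise."""
    freq = config.frequency_grid
    z = cole_impedance(params, freq)
    if config.noise_sd_fraction > 0.0:
        sd = config.noise_sd_fraction * np.abs(z)
        z = z + sd * (rng.standard_normal(len(freq)) + 1j * rng.standard_normal(len(freq)))
    return ImpedanceSpectrum(
        frequencies=freq, resistance=np.real(z), reactance=-np.imag(z), meta=meta
    )


@dataclass
class SimulatedSubject:
    """One generated subject: record, ground-truth parameters, optional spectra."""

    record: SubjectRecord
    true_params: dict[tuple[str, str], ColeParameters]
    spectra: dict[tuple[str, str], ImpedanceSpectrum] = field(default_factory=dict)


@dataclass
class SimulatedCohort:
    """A generated cohort plus its provenance (config and calibration)."""

    subjects: list[SimulatedSubject]
    config: GeneratorConfig
    calibration: dict[tuple[str, str], CalibratedCell]

    @property
    def cohort(self) -> Cohort:
        """Cohort of records with ground-truth derived parameters."""
        return Cohort([s.record for s in self.subjects])

    def n_spectra(self) -> int:
        return sum(len(s.spectra) for s in self.subjects)


def _load_demographics() -> pd.DataFrame:
    import importlib.resources

    with importlib.resources.files("mfbia.data").joinpath("demographics.tsv").open("r") as fh:
        return pd.read_csv(fh, sep="\t").set_index(["gender", "decade"])


_DEMOGRAPHICS = None


def _demographics() -> pd.DataFrame:
    global _DEMOGRAPHICS
    if _DEMOGRAPHICS is None:
        _DEMOGRAPHICS = _load_demographics()
    return _DEMOGRAPHICS


def generate_subject(
    gender: str,
    age_decade: int,
    config: GeneratorConfig,
    seed,
    *,
    calibration: dict | None = None,
    subject_id: str = "S000",
    muscles: tuple[str, ...] = MUSCLES,
    render: bool = True,
) -> SimulatedSubject:
    """Generate one subject: demographics, per-muscle parameters, spectra.

    Deterministic for a given seed (an int or a numpy SeedSequence/rng).
    The bilateral muscle (gastrocnemius) gets correlated left/right
    draws; all other muscles one recording.  ``render=False`` skips
    spectrum synthesis and keeps only ground-truth derived parameters
    (used for large statistical calibration runs).
    """
    if age_decade not in DECADES:
        raise DomainError(f"age_decade must be one of {DECADES}")
    rng = np.random.default_rng(seed)
    if calibration is None:
        calibration = calibrate_generator()

    demo = _demographics().loc[(gender, age_decade)]
    age = float(rng.integers(age_decade, age_decade + 10))
    weight = _sample_trunc(rng, float(demo["weight_mean"]), float(demo["weight_sd"]), 0.5)
    height = _sample_trunc(rng, float(demo["height_mean"]), float(demo["height_sd"]), 0.5)

    scale = config.age_effect if age_decade in OLD_DECADES else 1.0

    true_params: dict[tuple[str, str], ColeParameters] = {}
    recordings = {}
    spectra: dict[tuple[str, str], ImpedanceSpectrum] = {}
    for muscle in muscles:
        sides = ("left", "right") if muscle == "gastrocnemius" else ("unspecified",)
        # fc scales with age_effect through its sampled mean; Mc then follows.
        params_by_side = _sample_cell_params(
            rng, calibration[(muscle, gender)], config, scale, len(sides)
        )
        for side, params in zip(sides, params_by_side):
            true_params[(muscle, side)] = params
            recordings[(muscle, side)] = derive_parameters(params)
            if render:
                meta = SpectrumMeta(
                    subject_id=subject_id, muscle=muscle, side=side, gender=gender, age=age
                )
                spectra[(muscle, side)] = render_spectrum(params, config, rng, meta)

    record = SubjectRecord(
        subject_id=subject_id,
        gender=gender,
        age=age,
        weight_kg=weight,
        height_m=height,
        recordings=recordings,
    )
    return SimulatedSubject(record=record, true_params=true_params, spectra=spectra)


def generate_cohort(
    config: GeneratorConfig,
    *,
    calibration: dict | None = None,
    muscles: tuple[str, ...] = MUSCLES,
    render: bool = True,
) -> SimulatedCohort:
    """Generate the full crossed design: n_per_cell × 2 genders × 5 decades.

    Deterministic per config.seed; changing the seed changes the data but
    no calibration constant.
    """
    if calibration is None:
        calibration = calibrate_generator()
    seeds = np.random.SeedSequence(config.seed).spawn(2 * len(DECADES) * config.n_per_cell)
    subjects = []
    i = 0
    for gender in ("men", "women"):
        for decade in DECADES:
            for _ in range(config.n_per_cell):
                subjects.append(
                    generate_subject(
                        gender,
                        decade,
                        config,
                        seeds[i],
                        calibration=calibration,
                        subject_id=f"S{i + 1:03d}",
                        muscles=muscles,
                        render=render,
                    )
                )
                i += 1
    return SimulatedCohort(subjects=subjects, config=config, calibration=calibration)
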