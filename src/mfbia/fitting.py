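"""Cole-model fitting of measured impedance spectra.

The fit follows the classical two-stage scheme used for Cole–Cole plot
analysis: an algebraic least-squares circle fit in the complex plane
provides a deterministic initializer (real-axis intercepts give R0 and
R_inf, the depression of the arc center gives alpha, the frequency of
maximal reactance gives fc), and a bounded nonlinear least-squares
refinement on the complex residuals then estimates all four parameters
jointly.  No random starts are used, so the fit is deterministic for a
given spectrum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .cole import ColeParameters, DerivedParameters, cole_impedance, derive_parameters
from .exceptions import DegenerateGeometryError, DomainError
from .spectra import ImpedanceSpectrum

__all__ = [
    "FitDiagnostics",
    "QualityResult",
    "fit_circle",
    "ColeModel",
    "ColeResults",
    "fit_cole",
    "quality_check",
]


@dataclass(frozen=True)
class FitDiagnostics:
    """Goodness-of-fit summary for one Cole fit.

    rmse is the root-mean-square complex-plane residual in Ω;
    arc_coverage the fraction of the fitted arc spanned by the data,
    in [0, 1]; converged the optimizer's success flag.
    """

    rmse: float
    arc_coverage: float
    converged: bool
    n_points_used: int

    def __post_init__(self) -> None:
        if self.rmse < 0.0:
            raise DomainError("rmse must be non-negative")
        if not 0.0 <= self.arc_coverage <= 1.0:
            raise DomainError("arc_coverage must lie in [0, 1]")


@dataclass(frozen=True)
class QualityResult:
    """Outcome of the recording-quality screen."""

    accepted: bool
    reasons: tuple[str, ...]


def fit_circle(points) -> tuple[float, float, float]:
    """Algebraic (Kåsa) least-squares circle through (resistance, reactance) points.

    Solves the linear system for x² + y² + Dx + Ey + F = 0 and returns
    ``(center_r, center_x, radius)``.  Exact for points lying on a circle.

    Raises
    ------
    DegenerateGeometryError
        For fewer than three points or (near-)collinear points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise DegenerateGeometryError("need at least three (r, x) points")
    x, y = pts[:, 0], pts[:, 1]
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[0] == 0.0 or sv[1] / sv[0] < 1e-10:
        raise DegenerateGeometryError("points are collinear; no unique circle")
    a = np.column_stack([x, y, np.ones_like(x)])
    b = -(x**2 + y**2)
    (d, e, f), *_ = np.linalg.lstsq(a, b, rcond=None)
    cr, cx = -d / 2.0, -e / 2.0
    r2 = cr**2 + cx**2 - f
    if r2 <= 0.0:
        raise DegenerateGeometryError("degenerate circle (non-positive radius)")
    return float(cr), float(cx), float(math.sqrt(r2))


def _initial_parameters(spectrum: ImpedanceSpectrum) -> ColeParameters:
    """Deterministic initializer from circle-fit geometry."""
    pts = np.column_stack([spectrum.resistance, spectrum.reactance])
    cr, cx, radius = fit_circle(pts)
    # Real-axis intercepts; the Cole arc center lies at or below the axis
    # (cx <= 0 in the (R, Xc)-up convention the points are plotted in).
    half_chord = math.sqrt(max(radius**2 - cx**2, 1e-12))
    r0 = cr + half_chord
    rinf = cr - half_chord
    if rinf <= 0.0:
        rinf = min(r0 / 2.0, float(spectrum.resistance.min()) * 0.5)
    if rinf >= r0:
        raise DegenerateGeometryError("circle initializer yields rinf >= r0")
    alpha = (2.0 / math.pi) * math.asin(min(half_chord / radius, 1.0))
    alpha = min(max(alpha, 0.05), 1.0)
    fc = float(spectrum.frequencies[int(np.argmax(spectrum.reactance))])
    return ColeParameters(r0=r0, rinf=rinf, fc=fc, alpha=alpha)


def _residuals(theta, freq, z_data, weights, alpha_fixed):
    rinf, dr, fc, alpha = theta
    if alpha_fixed is not None:
        alpha = alpha_fixed
    x = (freq / fc) ** alpha
    z_model = rinf + dr / (1.0 + x * np.exp(1j * alpha * np.pi / 2.0))
    res = (z_model - z_data) * weights
    return np.concatenate([res.real, res.imag])


class ColeModel:
    """Cole impedance model bound to one measured spectrum.

    Follows the model/results idiom: construct from data, call
    :meth:`fit`, inspect the returned :class:`ColeResults`.

    Parameters
    ----------
    spectrum : ImpedanceSpectrum
        The recording to fit.
    proportional_weights : bool
        If True, residuals at each frequency are divided by the measured
        impedance magnitude (relative weighting); default equal weights.
    """

    def __init__(self, spectrum: ImpedanceSpectrum, *, proportional_weights: bool = False):
        self.spectrum = spectrum
        self.proportional_weights = proportional_weights

    @classmethod
    def from_dataframe(cls, df, meta=None, **kwargs) -> "ColeModel":
        """Build from a DataFrame with columns frequency_khz, resistance_ohm, reactance_ohm."""
        from .spectra import SpectrumMeta

        spec = ImpedanceSpectrum(
            frequencies=df["frequency_khz"].to_numpy(),
            resistance=df["resistance_ohm"].to_numpy(),
            reactance=df["reactance_ohm"].to_numpy(),
            meta=meta or SpectrumMeta(),
        )
        return cls(spec, **kwargs)

    def fit(self, alpha_fixed: float | None = None) -> "ColeResults":
        """Fit R0, R_inf, fc (and alpha unless fixed) by nonlinear least squares.

        Parameters
        ----------
        alpha_fixed : float, optional
            Hold the dispersion exponent at this value (e.g. 1.0 for the
            undepressed semicircle) instead of estimating it.
        """
        spec = self.spectrum
        freq = spec.frequencies
        z_data = spec.complex_impedance
        weights = 1.0 / np.abs(z_data) if self.proportional_weights else np.ones(len(spec))

        init = _initial_parameters(spec)
        theta0 = np.array([
            init.rinf,
            init.delta_r,
            init.fc,
            init.alpha if alpha_fixed is None else alpha_fixed,
        ])
        scale = float(np.median(np.abs(z_data)))
        # fc is only estimable inside the swept range; beyond it the arc apex
        # is extrapolation, so the optimizer is confined to the sweep and the
        # quality screen reports fits that rail against its edges.
        lb = [scale * 1e-6, scale * 1e-6, freq[0], 1e-3]
        ub = [np.inf, np.inf, freq[-1], 1.0]
        theta0 = np.clip(theta0, lb, ub)
        sol = least_squares(
            _residuals,
            theta0,
            bounds=(lb, ub),
            args=(freq, z_data, weights, alpha_fixed),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        rinf, dr, fc, alpha = sol.x
        if alpha_fixed is not None:
            alpha = alpha_fixed
        if dr <= 0.0 or rinf <= 0.0:
            raise DegenerateGeometryError("fit collapsed to rinf >= r0")
        params = ColeParameters(r0=rinf + dr, rinf=rinf, fc=fc, alpha=alpha)

        z_model = cole_impedance(params, freq)
        rmse = float(np.sqrt(np.mean(np.abs(z_model - z_data) ** 2)))
        diagnostics = FitDiagnostics(
            rmse=rmse,
            arc_coverage=_arc_coverage(params, freq[0], freq[-1]),
            converged=bool(sol.success),
            n_points_used=len(spec),
        )
        cov = _covariance(sol, n_obs=2 * len(spec), n_free=4 if alpha_fixed is None else 3)
        return ColeResults(self, params, diagnostics, cov=cov, alpha_fixed=alpha_fixed)


def _arc_coverage(params: ColeParameters, f_lo: float, f_hi: float) -> float:
    """Fraction of the fitted Cole arc spanned between the sweep extremes.

    The full arc from (R0, 0) to (R_inf, 0) subtends a central angle of
    alpha·π about the arc center; the data cover the part between the
    model points at the lowest and highest swept frequencies.
    """
    half_chord = params.delta_r / 2.0
    sin_half = math.sin(params.alpha * math.pi / 2.0)
    radius = half_chord / sin_half
    center = (
        (params.r0 + params.rinf) / 2.0,
        -half_chord / math.tan(params.alpha * math.pi / 2.0)
        if params.alpha < 1.0
        else 0.0,
    )

    def angle(f):
        z = cole_impedance(params, f)
        return math.atan2(-z.imag - center[1], z.real - center[0])

    span = abs(angle(f_lo) - angle(f_hi))
    return float(min(span / (params.alpha * math.pi), 1.0))


def _covariance(sol, n_obs: int, n_free: int) -> np.ndarray | None:
    dof = n_obs - n_free
    if dof <= 0:
        return None
    s2 = 2.0 * sol.cost / dof
    jtj = sol.jac.T @ sol.jac
    try:
        return s2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        return None


class ColeResults:
    """Results of a Cole-model fit: estimates, uncertainties, diagnostics."""

    _names = ("rinf", "delta_r", "fc", "alpha")

    def __init__(self, model, params, diagnostics, cov=None, alpha_fixed=None):
        self.model = model
        self.params = params
        self.diagnostics = diagnostics
        self.cov = cov
        self.alpha_fixed = alpha_fixed

    @property
    def bse(self) -> dict[str, float]:
        """Approximate standard errors of (rinf, delta_r, fc, alpha)."""
        if self.cov is None:
            return {n: float("nan") for n in self._names}
        se = np.sqrt(np.clip(np.diag(self.cov), 0.0, None))
        return dict(zip(self._names, map(float, se)))

    def predict(self, frequency_khz):
        """Model (resistance, reactance) at the given frequency/frequencies."""
        from .cole import evaluate_cole

        return evaluate_cole(self.params, frequency_khz)

    def derived(self) -> DerivedParameters:
        """The eight reported muscle parameters implied by the fit."""
        return derive_parameters(self.params)

    def quality(self, **kwargs) -> QualityResult:
        return quality_check(self.model.spectrum, self.params, self.diagnostics, **kwargs)

    def summary(self) -> str:
        """Plain-text fit report in the model/results style."""
        p, d = self.params, self.diagnostics
        se = self.bse
        lines = [
            "Cole impedance model fit",
            "=" * 46,
            f"{'n frequencies':<22}{d.n_points_used:>10d}",
            f"{'converged':<22}{str(d.converged):>10}",
            f"{'rmse (Ω)':<22}{d.rmse:>10.4f}",
            f"{'arc coverage':<22}{d.arc_coverage:>10.3f}",
            "-" * 46,
            f"{'param':<10}{'estimate':>12}{'std err':>12}",
            f"{'R0 (Ω)':<10}{p.r0:>12.3f}{'':>12}",
            f"{'Rinf (Ω)':<10}{p.rinf:>12.3f}{se['rinf']:>12.3f}",
            f"{'fc (kHz)':<10}{p.fc:>12.3f}{se['fc']:>12.3f}",
            f"{'alpha':<10}{p.alpha:>12.4f}"
            + (f"{se['alpha']:>12.4f}" if self.alpha_fixed is None else f"{'(fixed)':>12}"),
            "-" * 46,
        ]
        drv = self.derived()
        lines += [
            f"{'Z@50kHz (Ω)':<14}{drv.z:>10.2f}    {'R@50kHz (Ω)':<14}{drv.r:>10.2f}",
            f"{'Xc@50kHz (Ω)':<14}{drv.xc:>10.2f}    {'PA (°)':<14}{drv.pa:>10.2f}",
            f"{'Re (Ω)':<14}{drv.re:>10.2f}    {'Ri (Ω)':<14}{drv.ri:>10.2f}",
            f"{'Mc (nF)':<14}{drv.mc_nanofarads:>10.3f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Cole–Cole plot: measured points and fitted arc."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        spec = self.model.spectrum
        ax.plot(spec.resistance, spec.reactance, ".", ms=3, label="measured")
        fgrid = np.geomspace(spec.frequencies[0], spec.frequencies[-1], 400)
        r, x = self.predict(fgrid)
        ax.plot(r, x, "-", label="Cole fit")
        ax.set_xlabel("Resistance (Ω)")
        ax.set_ylabel("Reactance (Ω)")
        ax.legend()
        return ax


def fit_cole(spectrum: ImpedanceSpectrum, **kwargs) -> tuple[ColeParameters, FitDiagnostics]:
    """Functional wrapper: fit a spectrum, return (parameters, diagnostics)."""
    res = ColeModel(spectrum).fit(**kwargs)
    return res.params, res.diagnostics


def quality_check(
    spectrum: ImpedanceSpectrum,
    params: ColeParameters,
    diagnostics: FitDiagnostics,
    *,
    rmse_fraction: float = 0.05,
    min_arc_coverage: float = 0.5,
) -> QualityResult:
    """Screen a fitted recording the way an operator screens the live plots.

    Rejects when the complex-plane residual exceeds ``rmse_fraction`` of
    the arc diameter (R0 − R_inf), when the data cover less than
    ``min_arc_coverage`` of the fitted arc, or when the fitted center
    frequency falls outside the swept range.
    """
    reasons = []
    if diagnostics.rmse > rmse_fraction * params.delta_r:
        reasons.append(
            f"rmse {diagnostics.rmse:.3g} Ω exceeds {rmse_fraction:.0%} of R0−Rinf "
            f"({params.delta_r:.3g} Ω)"
        )
    if diagnostics.arc_coverage < min_arc_coverage:
        reasons.append(
            f"arc coverage {diagnostics.arc_coverage:.2f} below {min_arc_coverage:.2f}"
        )
    f_lo, f_hi = float(spectrum.frequencies[0]), float(spectrum.frequencies[-1])
    if not f_lo <= params.fc <= f_hi:
        reasons.append(f"fc {params.fc:.3g} kHz outside swept range [{f_lo:g}, {f_hi:g}] kHz")
    if not diagnostics.converged:
        reasons.append("fit did not converge")
    return QualityResult(accepted=not reasons, reasons=tuple(reasons))
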