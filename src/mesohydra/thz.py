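"""THz/FIR absorption processing and intermolecular-mode decomposition.

Raw attenuated-total-reflection (ATR) intensities are converted to an
absorption coefficient via the Beer-Lambert law with a per-frequency
evanescent effective thickness; the lipid-mixture contribution is
subtracted by volume fraction; and the resulting water spectrum is
decomposed into

    delta_alpha(nu) = a_LF * alpha_LF(nu) + a_HF * alpha_HF(nu) + sum_i L_i(nu)

where alpha_LF is an exponentially damped Debye-type line, alpha_HF the
sum of two fixed high-frequency damped-harmonic-oscillator (DHO) tails,
and the L_i are modified DHO lines for the two intermolecular modes of
water: the hydrogen-bond stretching mode (~150-180 cm^-1, a hindered
translation) and the libration mode (~400-450 cm^-1, a hindered
rotation).  Mode widths map to vibrational lifetimes via
tau = 1/(omega_0 * c), and lifetimes across a temperature series give
Arrhenius activation energies from ln(tau) vs 1/T.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

SPEED_OF_LIGHT_CM_S = 2.99792458e10
GAS_CONSTANT = 8.314  # J mol^-1 K^-1

#: Advisory plausibility band for intermolecular-mode lifetimes (fs).
LIFETIME_BAND_FS = (50.0, 200.0)

__all__ = [
    "RawATRSpectrum",
    "AbsorptionSpectrum",
    "WaterSpectrum",
    "DHOMode",
    "BackgroundShapes",
    "SpectralModel",
    "ModeLifetime",
    "ArrheniusFit",
    "FitResult",
    "SeriesResult",
    "DEFAULT_BACKGROUND",
    "penetration_thickness",
    "absorption_from_atr",
    "subtract_lipid",
    "eval_dho",
    "eval_background",
    "eval_model",
    "fit_model",
    "lifetimes",
    "arrhenius_fit",
    "analyze_series",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

def _check_grid(nu: np.ndarray) -> np.ndarray:
    nu = np.asarray(nu, dtype=float)
    if nu.ndim != 1 or not np.all(np.diff(nu) > 0):
        raise ValueError("wavenumber grid must be 1-D and strictly increasing")
    if nu[0] < 40.0 or nu[-1] > 600.0:
        raise ValueError("wavenumber grid must lie within the far-IR window")
    return nu


@dataclass
class RawATRSpectrum:
    """Incident/transmitted ATR intensities at one temperature."""

    nu: np.ndarray
    I0: np.ndarray
    I: np.ndarray
    temperature: float
    n_C: float = 2.42
    n_s: float = 1.47
    theta: float = math.pi / 4.0
    noise_tolerance: float = 0.0
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.nu = _check_grid(self.nu)
        self.I0 = np.asarray(self.I0, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.I0.shape != self.nu.shape or self.I.shape != self.nu.shape:
            raise ValueError("I0, I must match the nu grid")
        if np.any(self.I0 <= 0) or np.any(self.I <= 0):
            raise ValueError("intensities must be positive")
        if np.any(self.I > self.I0 * (1.0 + self.noise_tolerance)):
            raise ValueError("transmitted intensity exceeds incident intensity")
        if self.n_C * math.sin(self.theta) <= self.n_s:
            raise ValueError("total internal reflection requires n_C*sin(theta) > n_s")


@dataclass
class AbsorptionSpectrum:
    """Absorption coefficient alpha (cm^-1) with the ATR effective thickness used."""

    nu: np.ndarray
    alpha: np.ndarray
    temperature: float
    d_s_um: np.ndarray | None = None
    log_base: str = "natural"
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.nu = _check_grid(self.nu)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape != self.nu.shape:
            raise ValueError("alpha must match the nu grid")
        if not np.all(np.isfinite(self.alpha)):
            raise ValueError("alpha must be finite")
        if self.d_s_um is not None:
            self.d_s_um = np.asarray(self.d_s_um, dtype=float)
            if np.any(self.d_s_um <= 0):
                raise ValueError("effective thickness must be positive")


@dataclass
class WaterSpectrum:
    """Lipid-subtracted water absorption delta_alpha (cm^-1)."""

    nu: np.ndarray
    delta_alpha: np.ndarray
    temperature: float
    phi_m: float = 0.0
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.nu = _check_grid(self.nu)
        self.delta_alpha = np.asarray(self.delta_alpha, dtype=float)
        if self.delta_alpha.shape != self.nu.shape:
            raise ValueError("delta_alpha must match the nu grid")
        if not 0.0 <= self.phi_m <= 1.0:
            raise ValueError("phi_m must be in [0, 1]")


@dataclass(frozen=True)
class DHOMode:
    """One modified damped-harmonic-oscillator line: amplitude, center, width (cm^-1)."""

    amplitude: float
    center: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.center < 0:
            raise ValueError("center must be nonnegative")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")


@dataclass(frozen=True)
class BackgroundShapes:
    """Fixed shape parameters of the Debye-type and high-frequency background.

    These internals are not refined during fitting; only the scale
    factors a_LF, a_HF are free.
    """

    lf_a0: float
    lf_nu0: float
    lf_omega0: float
    t2_a: float
    t2_nu_b: float
    t2_omega: float
    t3_a: float
    t3_nu_b: float
    t3_omega: float

    def __post_init__(self) -> None:
        for name in ("lf_nu0", "lf_omega0", "t2_omega", "t3_omega"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


#: Default background: the Debye-type line rolls off quickly above its
#: <50 cm^-1 home range and the high-frequency oscillators sit beyond
#: 600 cm^-1, so both stay smooth and subdominant across 100-500 cm^-1.
#: The synthetic generator uses the same values, keeping round trips
#: self-consistent.
DEFAULT_BACKGROUND = BackgroundShapes(
    lf_a0=1.0, lf_nu0=45.0, lf_omega0=15.0,
    t2_a=1.0, t2_nu_b=620.0, t2_omega=250.0,
    t3_a=1.0, t3_nu_b=800.0, t3_omega=350.0,
)


@dataclass
class SpectralModel:
    """Full decomposition parameter set: background scales + two DHO modes."""

    a_LF: float
    a_HF: float
    stretching: DHOMode
    libration: DHOMode
    background: BackgroundShapes = DEFAULT_BACKGROUND

    def __post_init__(self) -> None:
        if self.a_LF < 0 or self.a_HF < 0:
            raise ValueError("background scale factors must be nonnegative")
        if not self.stretching.center < self.libration.center:
            raise ValueError("stretching center must lie below the libration center")

    @property
    def modes(self) -> dict[str, DHOMode]:
        return {"stretching": self.stretching, "libration": self.libration}


@dataclass
class ModeLifetime:
    mode: str
    tau_fs: float
    tau_err_fs: float
    temperature: float
    outside_band: bool = False


@dataclass
class ArrheniusFit:
    """ln(value) vs 1/T regression: value = prefactor * exp(E_a / (R*T))."""

    E_a_kJ_mol: float
    prefactor: float
    r_squared: float
    E_a_stderr: float
    prefactor_stderr: float
    n_points: int
    label: str = ""
    degenerate: bool = False


# ---------------------------------------------------------------------------
# ATR optics
# ---------------------------------------------------------------------------

def penetration_thickness(nu, n_C: float = 2.42, n_s: float = 1.47,
                          theta: float = math.pi / 4.0):
    """ATR effective thickness d_s = lambda / (2*pi*sqrt(n_C^2 sin^2(theta) - n_s^2)).

    ``nu`` in cm^-1; result in micrometres (lambda[um] = 1e4/nu).
    Raises outside the evanescent regime (radicand <= 1e-12).
    """
    nu = np.asarray(nu, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("wavenumber must be positive")
    radicand = (n_C * math.sin(theta)) ** 2 - n_s**2
    if radicand <= 1e-12:
        raise ValueError("no evanescent regime: n_C*sin(theta) must exceed n_s")
    lam_um = 1.0e4 / nu
    return lam_um / (2.0 * math.pi * math.sqrt(radicand))


def absorption_from_atr(raw: RawATRSpectrum, decadic: bool = False) -> AbsorptionSpectrum:
    """Beer-Lambert inversion alpha = log(I0/I) / d_s per frequency.

    Natural logarithm by default (the standard for absorption
    coefficients in cm^-1); ``decadic=True`` uses log10.
    """
    ratio = raw.I0 / raw.I
    if np.any(ratio <= 0):
        raise ValueError("intensity ratio must be positive")
    d_s_um = penetration_thickness(raw.nu, raw.n_C, raw.n_s, raw.theta)
    d_s_cm = d_s_um * 1.0e-4
    log = np.log10(ratio) if decadic else np.log(ratio)
    return AbsorptionSpectrum(
        nu=raw.nu, alpha=log / d_s_cm, temperature=raw.temperature,
        d_s_um=d_s_um, log_base="decadic" if decadic else "natural",
        sample_id=raw.sample_id,
    )


def subtract_lipid(alpha: AbsorptionSpectrum, alpha_m: AbsorptionSpectrum,
                   phi_m: float) -> WaterSpectrum:
    """Remove the lipid-mixture contribution: delta_alpha = alpha - phi_m * alpha_m.

    The reference is linearly resampled (with a warning) when its grid
    differs; non-overlapping grids are an error.
    """
    if not 0.0 <= phi_m <= 1.0:
        raise ValueError("phi_m must be in [0, 1]")
    if alpha_m.nu.shape == alpha.nu.shape and np.allclose(alpha_m.nu, alpha.nu):
        ref = alpha_m.alpha
    else:
        if alpha_m.nu[0] > alpha.nu[-1] or alpha_m.nu[-1] < alpha.nu[0]:
            raise ValueError("lipid reference grid does not overlap the spectrum")
        if alpha_m.nu[0] > alpha.nu[0] or alpha_m.nu[-1] < alpha.nu[-1]:
            raise ValueError("lipid reference grid does not cover the spectrum")
        warnings.warn("resampling lipid reference onto the spectrum grid")
        ref = np.interp(alpha.nu, alpha_m.nu, alpha_m.alpha)
    return WaterSpectrum(
        nu=alpha.nu, delta_alpha=alpha.alpha - phi_m * ref,
        temperature=alpha.temperature, phi_m=phi_m, sample_id=alpha.sample_id,
    )


# ---------------------------------------------------------------------------
# line shapes (pi-factor groupings are deliberately isolated here)
# ---------------------------------------------------------------------------

def eval_dho(nu, amplitude: float, center: float, width: float):
    """Modified DHO line L(nu) = a*w^2*nu^2 / (4*pi^3*[(nu0^2-nu^2)^2 + (w^2/pi^2)*nu^2]).

    At nu = nu0 the value is a/(4*pi), independent of the width.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    nu = np.asarray(nu, dtype=float)
    num = amplitude * width**2 * nu**2
    den = 4.0 * math.pi**3 * ((center**2 - nu**2) ** 2
                              + (width**2 / math.pi**2) * nu**2)
    return num / den


def _eval_lf(nu, a0: float, nu0: float, omega0: float):
    """Exponentially damped Debye-type line a0*exp(-nu/nu0)*nu^2/(nu^2+omega0^2)."""
    nu = np.asarray(nu, dtype=float)
    return a0 * np.exp(-nu / nu0) * nu**2 / (nu**2 + omega0**2)


def _eval_hf_term(nu, a: float, nu_b: float, omega: float):
    """High-frequency DHO tail with the center shifted by omega^2/(4*pi)."""
    nu = np.asarray(nu, dtype=float)
    num = a * omega**2 * nu**2
    den = 4.0 * math.pi**3 * (
        (nu_b**2 + omega**2 / (4.0 * math.pi) - nu**2) ** 2
        + (omega**2 / math.pi**2) * nu**2
    )
    return num / den


def eval_background(nu, shapes: BackgroundShapes, a_LF: float, a_HF: float):
    """a_LF * alpha_LF(nu) + a_HF * (t2(nu) + t3(nu)) with fixed shapes."""
    lf = _eval_lf(nu, shapes.lf_a0, shapes.lf_nu0, shapes.lf_omega0)
    t2 = _eval_hf_term(nu, shapes.t2_a, shapes.t2_nu_b, shapes.t2_omega)
    t3 = _eval_hf_term(nu, shapes.t3_a, shapes.t3_nu_b, shapes.t3_omega)
    return a_LF * lf + a_HF * (t2 + t3)


def eval_model(nu, model: SpectralModel):
    """Full decomposition: background plus both intermolecular DHO modes."""
    total = eval_background(nu, model.background, model.a_LF, model.a_HF)
    for mode in (model.stretching, model.libration):
        total = total + eval_dho(nu, mode.amplitude, mode.center, mode.width)
    return total


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

DEFAULT_FREE = ("a_LF", "a_HF",
                "str_a", "str_nu0", "str_om",
                "lib_a", "lib_nu0", "lib_om")

FIT_WINDOW = (60.0, 540.0)
WIDTH_BOUNDS = (10.0, 2000.0)
CENTER_HALF_RANGE = 60.0


@dataclass
class FitResult:
    model: SpectralModel
    success: bool
    redchi: float
    stderr: dict[str, float]
    residual: np.ndarray
    nu: np.ndarray
    message: str = ""


def _params_from_model(init: SpectralModel, free: tuple[str, ...]) -> lmfit.Parameters:
    p = lmfit.Parameters()
    p.add("a_LF", value=init.a_LF, min=0.0, vary="a_LF" in free)
    p.add("a_HF", value=init.a_HF, min=0.0, vary="a_HF" in free)
    for tag, mode in (("str", init.stretching), ("lib", init.libration)):
        p.add(f"{tag}_a", value=mode.amplitude, min=0.0, vary=f"{tag}_a" in free)
        p.add(f"{tag}_nu0", value=mode.center,
              min=max(0.0, mode.center - CENTER_HALF_RANGE),
              max=mode.center + CENTER_HALF_RANGE, vary=f"{tag}_nu0" in free)
        p.add(f"{tag}_om", value=mode.width, min=WIDTH_BOUNDS[0],
              max=WIDTH_BOUNDS[1], vary=f"{tag}_om" in free)
    return p


def _model_from_params(p, background: BackgroundShapes) -> SpectralModel:
    return SpectralModel(
        a_LF=float(p["a_LF"]), a_HF=float(p["a_HF"]),
        stretching=DHOMode(float(p["str_a"]), float(p["str_nu0"]), float(p["str_om"])),
        libration=DHOMode(float(p["lib_a"]), float(p["lib_nu0"]), float(p["lib_om"])),
        background=background,
    )


def fit_model(ws: WaterSpectrum, init: SpectralModel,
              free: tuple[str, ...] = DEFAULT_FREE) -> FitResult:
    """Nonlinear least-squares decomposition of a water spectrum.

    Background shapes stay fixed; by default the two scale factors and
    the six DHO mode parameters are free (centers bounded within +/-60
    cm^-1 of the initial guess, widths in [10, 2000] cm^-1, amplitudes
    nonnegative).  Non-convergence is reported via the ``success`` flag
    with best-so-far parameters, never silently.
    """
    if ws.nu[0] > FIT_WINDOW[0] or ws.nu[-1] < FIT_WINDOW[1]:
        raise ValueError(f"spectrum must cover at least {FIT_WINDOW} cm^-1")
    mask = (ws.nu >= FIT_WINDOW[0]) & (ws.nu <= FIT_WINDOW[1])
    nu, y = ws.nu[mask], ws.delta_alpha[mask]
    params = _params_from_model(init, free)
    bg = init.background

    def residual(p):
        return eval_model(nu, _model_from_params(p, bg)) - y

    try:
        out = lmfit.minimize(residual, params, method="least_squares")
    except Exception as exc:  # pragma: no cover - lmfit failure path
        return FitResult(model=init, success=False, redchi=float("inf"),
                         stderr={}, residual=np.array([]), nu=nu, message=str(exc))
    model = _model_from_params(out.params, bg)
    stderr = {name: (out.params[name].stderr or float("nan"))
              for name in out.params if out.params[name].vary}
    return FitResult(model=model, success=bool(out.success),
                     redchi=float(out.redchi), stderr=stderr,
                     residual=np.asarray(out.residual), nu=nu,
                     message=getattr(out, "message", ""))


# ---------------------------------------------------------------------------
# lifetimes and Arrhenius analysis
# ---------------------------------------------------------------------------

def lifetimes(fit: FitResult | SpectralModel, temperature: float,
              stderr: dict[str, float] | None = None) -> list[ModeLifetime]:
    """Per-mode lifetimes tau = 1/(omega_0 * c) in femtoseconds.

    Uncertainty is propagated as |dtau/domega| * sigma_omega.  Values
    outside the 50-200 fs plausibility band carry an advisory flag.
    """
    if isinstance(fit, FitResult):
        model, stderr = fit.model, fit.stderr
    else:
        model = fit
        stderr = stderr or {}
    out = []
    for tag, name in (("str", "stretching"), ("lib", "libration")):
        mode = model.modes[name]
        tau_s = 1.0 / (mode.width * SPEED_OF_LIGHT_CM_S)
        tau_fs = tau_s * 1.0e15
        sig_om = stderr.get(f"{tag}_om", float("nan"))
        tau_err = tau_fs / mode.width * sig_om if np.isfinite(sig_om) else float("nan")
        out.append(ModeLifetime(
            mode=name, tau_fs=tau_fs, tau_err_fs=tau_err, temperature=temperature,
            outside_band=not LIFETIME_BAND_FS[0] <= tau_fs <= LIFETIME_BAND_FS[1],
        ))
    return out


def arrhenius_fit(values, T, label: str = "") -> ArrheniusFit:
    """Ordinary least squares of ln(value) on 1/T.

    E_a = slope * R (kJ/mol), positive when values decrease with
    increasing temperature under value = prefactor * exp(E_a/(R*T)).
    A constant series yields E_a = 0 with r^2 reported as 0 and the
    degenerate flag set.
    """
    values = np.asarray(values, dtype=float)
    T = np.asarray(T, dtype=float)
    if values.shape != T.shape or values.ndim != 1:
        raise ValueError("values and T must be matching 1-D arrays")
    if len(values) < 3:
        raise ValueError("Arrhenius fit requires at least 3 points")
    if np.any(values <= 0) or np.any(T <= 0):
        raise ValueError("values and temperatures must be positive")
    x, y = 1.0 / T, np.log(values)
    if np.allclose(y, y[0]):
        return ArrheniusFit(E_a_kJ_mol=0.0, prefactor=float(np.exp(y[0])),
                            r_squared=0.0, E_a_stderr=0.0, prefactor_stderr=0.0,
                            n_points=len(values), label=label, degenerate=True)
    res = stats.linregress(x, y)
    ea = res.slope * GAS_CONSTANT / 1000.0
    pref = math.exp(res.intercept)
    return ArrheniusFit(
        E_a_kJ_mol=ea, prefactor=pref,
        r_squared=float(res.rvalue**2),
        E_a_stderr=res.stderr * GAS_CONSTANT / 1000.0,
        prefactor_stderr=pref * res.intercept_stderr,
        n_points=len(values), label=label,
    )


@dataclass
class SeriesResult:
    fits: list[FitResult]
    lifetime_table: pd.DataFrame
    arrhenius: dict[str, ArrheniusFit]
    skipped: dict[str, str]
    failed_temperatures: list[float]


def analyze_series(spectra: list[WaterSpectrum], init: SpectralModel,
                   free: tuple[str, ...] = DEFAULT_FREE) -> SeriesResult:
    """Fit a temperature series sequentially with warm starts.

    Spectra are fit in ascending temperature order, each fit seeding the
    next (centers do not shift appreciably with temperature, widths
    drift smoothly).  Per-mode Arrhenius fits of the lifetimes are
    attempted when at least 3 temperatures converged; otherwise the step
    is skipped with the reason recorded.
    """
    if len(spectra) < 1:
        raise ValueError("no spectra supplied")
    ordered = sorted(spectra, key=lambda s: s.temperature)
    fits: list[FitResult] = []
    rows = []
    failed = []
    current = init
    for ws in ordered:
        fit = fit_model(ws, current, free)
        fits.append(fit)
        if fit.success:
            # warm start, re-centring bounds on the new solution
            current = replace(fit.model)
        else:
            failed.append(ws.temperature)
        for lt in lifetimes(fit, ws.temperature):
            rows.append({"T": ws.temperature, "mode": lt.mode, "tau_fs": lt.tau_fs,
                         "tau_err_fs": lt.tau_err_fs, "converged": fit.success,
                         "outside_band": lt.outside_band})
    table = pd.DataFrame(rows)
    arr: dict[str, ArrheniusFit] = {}
    skipped: dict[str, str] = {}
    for name in ("stretching", "libration"):
        sub = table[(table["mode"] == name) & table["converged"]]
        if len(sub) < 3:
            skipped[name] = (
                f"only {len(sub)} converged temperatures; Arrhenius needs >= 3"
            )
            continue
        arr[name] = arrhenius_fit(sub["tau_fs"].to_numpy(), sub["T"].to_numpy(),
                                  label=name)
    return SeriesResult(fits=fits, lifetime_table=table, arrhenius=arr,
                        skipped=skipped, failed_temperatures=failed)
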