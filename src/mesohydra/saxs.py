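"""Cubic-mesophase SAXS indexing and geometry.

Inverse bicontinuous cubic phases (gyroid Ia3d, diamond Pn3m, primitive
Im3m) produce Bragg reflections whose spacings follow d_hkl = a/sqrt(N)
with N = h^2 + k^2 + l^2 restricted by the space group's extinction
rules.  This module detects peaks in 1-D scattering profiles, indexes
them against candidate space groups by a through-origin regression of q
on 2*pi*sqrt(N), and converts the fitted lattice parameter into
mesophase geometry: water-channel radius/diameter, lipid monolayer
length and the interfacial water fraction of the confined water.

Geometry relations used here (triply periodic minimal surface algebra):

* channel radius     r = sqrt(A0 / (-2*pi*chi)) * a - l
* lipid length       phi_L = 2*A0*(l/a) + (4*pi*chi/3)*(l/a)^3
* interfacial water  f_w,int = (-0.543*K0 - 2.092) / Gamma,
                     Gamma = f_w * a^3 / (4*pi*|chi|)   (a in nm)

where A0 is the dimensionless minimal-surface area per unit cell and
chi its Euler-Poincare characteristic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import minimum_filter1d, uniform_filter1d
from scipy.optimize import brentq
from scipy.signal import find_peaks


__all__ = [
    "ScatteringProfile",
    "SpaceGroupSpec",
    "PhaseAssignment",
    "CubicGeometry",
    "SPACE_GROUPS",
    "k0_gaussian_curvature",
    "detect_peaks",
    "index_phase",
    "channel_diameter",
    "lipid_length",
    "interfacial_water_fraction",
    "geometry_series",
]


@dataclass(frozen=True)
class SpaceGroupSpec:
    """A cubic space group admissible for an inverse bicontinuous phase.

    ``reflection_integers`` are the allowed N = h^2+k^2+l^2 in ascending
    order; ``A0`` is the normalized unit-cell minimal-surface area and
    ``chi`` the (negative) Euler-Poincare characteristic.
    """

    name: str
    reflection_integers: tuple[int, ...]
    A0: float
    chi: int

    def __post_init__(self) -> None:
        if self.chi >= 0:
            raise ValueError("chi must be negative for a bicontinuous surface")
        if list(self.reflection_integers) != sorted(set(self.reflection_integers)):
            raise ValueError("reflection_integers must be strictly increasing")

    @property
    def radius_slope(self) -> float:
        """sqrt(A0 / (-2*pi*chi)): channel radius per unit lattice parameter at l=0."""
        return math.sqrt(self.A0 / (-2.0 * math.pi * self.chi))


#: Canonical space groups.  First two reflections: {6,8} for Ia3d,
#: {2,3} for Pn3m, {2,4} for Im3m (body-centred extinction rules).
SPACE_GROUPS: dict[str, SpaceGroupSpec] = {
    "Ia3d": SpaceGroupSpec(
        "Ia3d", (6, 8, 14, 16, 20, 22, 24, 26, 30, 32, 38, 40, 42, 46, 48, 50),
        3.091, -8,
    ),
    "Pn3m": SpaceGroupSpec(
        "Pn3m", (2, 3, 4, 6, 8, 9, 10, 11, 12, 14, 16, 17, 18, 19, 20),
        1.919, -2,
    ),
    "Im3m": SpaceGroupSpec(
        "Im3m", (2, 4, 6, 8, 10, 12, 14, 16, 18, 20, 22, 24, 26),
        2.345, -4,
    ),
}


def k0_gaussian_curvature(group: SpaceGroupSpec) -> float:
    """Dimensionless integrated Gaussian curvature per unit surface, 2*pi*chi/A0.

    Offered as one documented convention for the K0 entering
    :func:`interfacial_water_fraction`; callers remain free to supply
    their own value.
    """
    return 2.0 * math.pi * group.chi / group.A0


@dataclass
class ScatteringProfile:
    """A 1-D azimuthally averaged SAXS curve at one temperature.

    q in inverse Angstrom on a strictly increasing grid within
    [0.01, 1.0]; intensity in arbitrary units, finite and nonnegative.
    """

    q: np.ndarray
    intensity: np.ndarray
    temperature: float = 298.0
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must be matching 1-D arrays")
        if not np.all(np.diff(self.q) > 0):
            raise ValueError("q grid must be strictly increasing")
        if self.q[0] <= 0 or self.q[0] < 0.01 or self.q[-1] > 1.0:
            raise ValueError("q range must lie within [0.01, 1.0] 1/A")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError("intensity must be finite and nonnegative")


@dataclass
class PhaseAssignment:
    """Result of indexing one profile against one space group."""

    space_group: SpaceGroupSpec
    matched_peaks: list[tuple[float, int, float]]  # (q_obs 1/A, N, d-spacing A)
    lattice_parameter_nm: float
    lattice_stderr_nm: float
    relative_rms_residual: float
    ambiguous_with: list[str] = field(default_factory=list)
    temperature: float = float("nan")
    sample_id: str = ""

    def to_record(self) -> dict:
        return {
            "sample": self.sample_id,
            "T": self.temperature,
            "phase": self.space_group.name,
            "a_nm": self.lattice_parameter_nm,
            "a_stderr": self.lattice_stderr_nm,
            "residual": self.relative_rms_residual,
            "ambiguous_with": list(self.ambiguous_with),
            "matched_peaks": [
                {"q": q, "N": n, "d_A": d} for q, n, d in self.matched_peaks
            ],
        }


@dataclass
class CubicGeometry:
    """Mesophase geometry for one phase at one temperature."""

    temperature: float
    phase: str
    a_nm: float
    l_nm: float
    channel_radius_nm: float
    channel_diameter_nm: float
    phi_L: float
    f_w: float
    Gamma: float
    K0: float
    f_w_int: float
    clamped: bool = False
    available: bool = True
    reason: str = ""


# ---------------------------------------------------------------------------
# peak detection
# ---------------------------------------------------------------------------

def detect_peaks(
    profile: ScatteringProfile,
    min_prominence: float = 0.02,
    smoothing_window: int = 5,
    baseline_window: int | None = None,
) -> np.ndarray:
    """Locate Bragg-peak positions in a scattering profile.

    The curve is smoothed with an odd, centred moving average; local
    maxima rising at least ``min_prominence * max(intensity)`` above a
    rolling-minimum baseline qualify.  Positions are refined with a
    parabolic fit through the three points around each maximum and are
    returned ascending in q (1/A).  A flat profile yields an empty
    array.
    """
    if not 0.0 < min_prominence < 1.0:
        raise ValueError("min_prominence must be in (0, 1)")
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be a positive odd integer")
    q, y = profile.q, profile.intensity
    smooth = uniform_filter1d(y, size=smoothing_window, mode="nearest")
    if baseline_window is None:
        baseline_window = max(4 * smoothing_window + 1, 25)
    baseline = minimum_filter1d(smooth, size=baseline_window, mode="nearest")
    height = smooth - baseline
    threshold = min_prominence * float(np.max(y)) if np.max(y) > 0 else np.inf
    idx, _ = find_peaks(smooth)
    idx = idx[height[idx] >= threshold]
    positions = []
    for i in idx:
        if 0 < i < len(q) - 1:
            y0, y1, y2 = smooth[i - 1], smooth[i], smooth[i + 1]
            denom = y0 - 2.0 * y1 + y2
            shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            shift = float(np.clip(shift, -0.5, 0.5))
            positions.append(q[i] + shift * (q[min(i + 1, len(q) - 1)] - q[i]))
        else:
            positions.append(q[i])
    return np.asarray(sorted(positions))


# ---------------------------------------------------------------------------
# indexing
# ---------------------------------------------------------------------------

def _fit_candidate(
    peaks: np.ndarray, group: SpaceGroupSpec, max_peaks_used: int
) -> tuple[float, float, float, list[tuple[float, int, float]]]:
    m = min(len(peaks), max_peaks_used, len(group.reflection_integers))
    q = peaks[:m]
    ns = np.asarray(group.reflection_integers[:m], dtype=float)
    x = 2.0 * math.pi * np.sqrt(ns)  # q = x / a
    sxx = float(np.dot(x, x))
    slope = float(np.dot(x, q)) / sxx  # 1/a
    if slope <= 0:
        raise ValueError(f"candidate {group.name} yields nonpositive lattice parameter")
    a_A = 1.0 / slope
    pred = slope * x
    rel = (q - pred) / pred
    residual = float(np.sqrt(np.mean(rel**2)))
    if m > 1:
        se_slope = math.sqrt(float(np.sum((q - pred) ** 2)) / (m - 1) / sxx)
    else:
        se_slope = 0.0
    se_a = se_slope / slope**2
    matched = [
        (float(qi), int(ni), 2.0 * math.pi / float(qi)) for qi, ni in zip(q, ns)
    ]
    return a_A / 10.0, se_a / 10.0, residual, matched


def index_phase(
    peaks,
    candidates: list[SpaceGroupSpec] | None = None,
    max_peaks_used: int = 4,
    tie_fraction: float = 0.10,
    temperature: float = float("nan"),
    sample_id: str = "",
) -> tuple[PhaseAssignment, pd.DataFrame]:
    """Index peak positions against candidate space groups.

    The first ``min(len(peaks), max_peaks_used)`` peaks are assigned in
    order to each candidate's lowest allowed sqrt(N) values and the
    lattice parameter is fit by least squares of q on 2*pi*sqrt(N)
    through the origin.  The candidate with the lowest relative RMS
    residual wins; candidates whose residual lies within
    ``tie_fraction`` (relative) of the winner are flagged as ambiguous
    rather than silently dropped.

    Returns the winning :class:`PhaseAssignment` and a residual table
    for all candidates (columns: phase, a_nm, a_stderr_nm, residual,
    tied).
    """
    peaks = np.asarray(sorted(float(p) for p in np.atleast_1d(peaks)))
    if len(peaks) < 2:
        raise ValueError("indexing requires at least 2 peaks")
    if candidates is None:
        candidates = list(SPACE_GROUPS.values())
    if not candidates:
        raise ValueError("no candidate space groups supplied")

    rows = []
    fits = {}
    for group in candidates:
        a_nm, se_nm, residual, matched = _fit_candidate(peaks, group, max_peaks_used)
        fits[group.name] = (group, a_nm, se_nm, residual, matched)
        rows.append({"phase": group.name, "a_nm": a_nm, "a_stderr_nm": se_nm,
                     "residual": residual})
    table = pd.DataFrame(rows).sort_values("residual").reset_index(drop=True)
    best_name = table.loc[0, "phase"]
    best_res = table.loc[0, "residual"]
    # relative near-ties (sqrt2:sqrt3 vs sqrt6:sqrt8 doublets are near-degenerate)
    tied = [
        r["phase"]
        for _, r in table.iterrows()
        if r["phase"] != best_name
        and (r["residual"] - best_res) <= tie_fraction * max(best_res, 1e-30)
    ]
    table["tied"] = table["phase"].isin(tied + [best_name] if tied else [])
    group, a_nm, se_nm, residual, matched = fits[best_name]
    assignment = PhaseAssignment(
        space_group=group,
        matched_peaks=matched,
        lattice_parameter_nm=a_nm,
        lattice_stderr_nm=se_nm,
        relative_rms_residual=residual,
        ambiguous_with=tied,
        temperature=temperature,
        sample_id=sample_id,
    )
    return assignment, table


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def channel_diameter(
    a: float, l: float, group: SpaceGroupSpec
) -> tuple[float, float]:
    """Water-channel radius and diameter (nm) from lattice parameter and lipid length.

    r = sqrt(A0/(-2*pi*chi)) * a - l; the diameter is 2r.  Raises when
    the lipid length exceeds the closed-channel limit (negative radius).
    """
    if a <= 0:
        raise ValueError("lattice parameter must be positive")
    rmax = group.radius_slope * a
    if l < 0 or l > rmax:
        raise ValueError(
            f"lipid length {l} outside [0, {rmax:.4f}] nm for {group.name}, a={a}"
        )
    radius = rmax - l
    return radius, 2.0 * radius


def _phi_of_x(x: float, group: SpaceGroupSpec) -> float:
    return 2.0 * group.A0 * x + (4.0 * math.pi * group.chi / 3.0) * x**3


def lipid_length(phi_L: float, a: float, group: SpaceGroupSpec) -> float:
    """Invert phi_L = 2*A0*(l/a) + (4*pi*chi/3)*(l/a)^3 for the lipid length l (nm).

    The smallest positive root on the physically monotone branch
    (derivative of the cubic positive) is returned; the branch ends at
    x_turn = sqrt(A0/(-2*pi*chi)) where the channel closes.
    """
    if not 0.0 < phi_L < 1.0:
        raise ValueError("phi_L must be in (0, 1)")
    if a <= 0:
        raise ValueError("lattice parameter must be positive")
    x_turn = group.radius_slope
    phi_max = _phi_of_x(x_turn, group)
    if phi_L > phi_max:
        raise ValueError(
            f"phi_L={phi_L} exceeds the maximum {phi_max:.4f} attainable for "
            f"{group.name}: no physical solution"
        )
    x = brentq(lambda t: _phi_of_x(t, group) - phi_L, 0.0, x_turn, xtol=1e-14)
    return x * a


def interfacial_water_fraction(
    f_w: float, a: float, group: SpaceGroupSpec, K0: float
) -> tuple[float, float, bool]:
    """Interfacial water fraction from the analytic swollen-mesophase expression.

    Gamma = f_w * a^3 / (4*pi*|chi|) with a numerically in nm;
    f_w,int = (-0.543*K0 - 2.092) / Gamma, clamped to [0, 1].

    Returns ``(Gamma, f_w_int, clamped)``.  K0 is caller-supplied; see
    :func:`k0_gaussian_curvature` for one documented convention.
    """
    if not 0.0 < f_w <= 1.0:
        raise ValueError("f_w must be in (0, 1]")
    if a <= 0:
        raise ValueError("lattice parameter must be positive")
    gamma = f_w * a**3 / (4.0 * math.pi * abs(group.chi))
    if gamma == 0.0:
        raise ValueError("Gamma is zero")
    raw = (-0.543 * K0 - 2.092) / gamma
    clamped = raw < 0.0 or raw > 1.0
    return gamma, float(np.clip(raw, 0.0, 1.0)), clamped


def geometry_series(
    assignments: list[PhaseAssignment],
    phi_L: float,
    K0: float,
    f_w: float | None = None,
) -> pd.DataFrame:
    """Per-temperature mesophase geometry table.

    Temperatures carrying more than one assignment (phase coexistence)
    are emitted with geometry fields unavailable — the water partition
    between coexisting phases cannot be resolved from the composition —
    and the reason recorded.  ``f_w`` defaults to 1 - phi_L (no
    co-solutes declared).
    """
    if f_w is None:
        f_w = 1.0 - phi_L
    by_T: dict[float, list[PhaseAssignment]] = {}
    for asg in assignments:
        by_T.setdefault(asg.temperature, []).append(asg)

    rows = []
    for T in sorted(by_T):
        group_list = by_T[T]
        if len(group_list) > 1:
            names = "+".join(g.space_group.name for g in group_list)
            rows.append(CubicGeometry(
                temperature=T, phase=names, a_nm=float("nan"), l_nm=float("nan"),
                channel_radius_nm=float("nan"), channel_diameter_nm=float("nan"),
                phi_L=phi_L, f_w=f_w, Gamma=float("nan"), K0=K0,
                f_w_int=float("nan"), available=False,
                reason="phase coexistence: geometry computed only for pure phases",
            ))
            continue
        asg = group_list[0]
        group = asg.space_group
        a = asg.lattice_parameter_nm
        l = lipid_length(phi_L, a, group)
        radius, diameter = channel_diameter(a, l, group)
        gamma, f_int, clamped = interfacial_water_fraction(f_w, a, group, K0)
        rows.append(CubicGeometry(
            temperature=T, phase=group.name, a_nm=a, l_nm=l,
            channel_radius_nm=radius, channel_diameter_nm=diameter,
            phi_L=phi_L, f_w=f_w, Gamma=gamma, K0=K0, f_w_int=f_int,
            clamped=clamped,
        ))
    return pd.DataFrame([vars(r) for r in rows])
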