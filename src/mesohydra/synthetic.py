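"""Synthetic data with recorded ground truth for every pipeline stage.

Three generators emulate the statistical structure the analysis
assumes — not the underlying physics:

* :func:`gen_saxs` — cubic-phase Bragg peak series (Gaussian peaks at
  q = 2*pi*sqrt(N)/a with 1/N-decaying amplitudes) on a linear
  background with multiplicative noise.
* :func:`gen_thz_series` — temperature series of water far-IR spectra
  composed from the Debye + two-DHO model, mode widths driven by
  Arrhenius lifetime laws, optionally inverted to raw ATR intensities
  plus a lipid reference.
* :func:`gen_slab_frames` — lamellar slab coordinate frames whose
  per-water hydrogen-bond statistics are imposed by construction:
  waters come in two-molecule units that are bonded with a position-
  and temperature-dependent Bernoulli probability, so every expected
  profile is exactly computable and recorded.

Every generator returns its output together with a :class:`GroundTruth`
whose parameters suffice to recompute the expected analysis results.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .hbond import Frame
from .saxs import SPACE_GROUPS, ScatteringProfile, SpaceGroupSpec
from .thz import (
    DEFAULT_BACKGROUND,
    GAS_CONSTANT,
    SPEED_OF_LIGHT_CM_S,
    AbsorptionSpectrum,
    BackgroundShapes,
    DHOMode,
    RawATRSpectrum,
    SpectralModel,
    WaterSpectrum,
    eval_model,
    penetration_thickness,
)

__all__ = [
    "GroundTruth",
    "ModeTruth",
    "gen_saxs",
    "gen_thz_series",
    "gen_slab_frames",
    "DEFAULT_MODE_TRUTHS",
]


@dataclass
class GroundTruth:
    """True parameters and noise model recorded alongside generated data."""

    generator: str
    seed: int
    parameters: dict
    noise_model: str

    def to_json(self, path=None) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(f"not serializable: {type(o)}")
        text = json.dumps(dataclasses.asdict(self), default=default, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# SAXS
# ---------------------------------------------------------------------------

def gen_saxs(
    group: str | SpaceGroupSpec = "Pn3m",
    a: float = 10.0,
    n_peaks: int = 4,
    peak_width: float = 0.003,
    background: tuple[float, float] = (5.0, -5.0),
    noise_sd: float = 0.01,
    seed: int = 0,
    temperature: float = 298.0,
    amplitude: float = 100.0,
    n_points: int = 1001,
) -> tuple[ScatteringProfile, GroundTruth]:
    """Synthetic cubic-phase SAXS profile on the 0.05-0.45 1/A window.

    Gaussian peaks sit at q_N = 2*pi*sqrt(N)/a (a in nm) with
    amplitudes decaying as 1/N on a linear background; noise is
    multiplicative Gaussian.  Raises when any requested peak falls
    outside the grid.
    """
    spec = SPACE_GROUPS[group] if isinstance(group, str) else group
    if a <= 0:
        raise ValueError("lattice parameter must be positive")
    if n_peaks > len(spec.reflection_integers):
        raise ValueError("n_peaks exceeds available reflections")
    rng = np.random.default_rng(seed)
    q = np.linspace(0.05, 0.45, n_points)
    a_A = 10.0 * a
    ns = np.asarray(spec.reflection_integers[:n_peaks], dtype=float)
    q_peaks = 2.0 * math.pi * np.sqrt(ns) / a_A
    if q_peaks[0] < q[0] or q_peaks[-1] > q[-1]:
        raise ValueError(
            f"peaks {q_peaks.min():.4f}-{q_peaks.max():.4f} fall outside the "
            "0.05-0.45 1/A grid")
    level, slope = background
    intensity = level + slope * q
    for n_int, qp in zip(ns, q_peaks):
        intensity = intensity + (amplitude / n_int) * np.exp(
            -((q - qp) ** 2) / (2.0 * peak_width**2))
    noisy = intensity * (1.0 + noise_sd * rng.standard_normal(q.shape))
    noisy = np.clip(noisy, 0.0, None)
    profile = ScatteringProfile(q=q, intensity=noisy, temperature=temperature,
                                sample_id=f"synthetic-{spec.name}")
    truth = GroundTruth(
        generator="gen_saxs", seed=seed,
        parameters={
            "space_group": spec.name, "a_nm": a, "n_peaks": n_peaks,
            "peak_positions": q_peaks, "reflection_N": ns,
            "peak_width": peak_width, "amplitude": amplitude,
            "background_level": level, "background_slope": slope,
        },
        noise_model=f"multiplicative Gaussian, sd={noise_sd}",
    )
    return profile, truth


# ---------------------------------------------------------------------------
# THz
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModeTruth:
    """Arrhenius-driven DHO mode: width follows omega(T) = 1/(c * tau(T))."""

    amplitude: float
    center: float                 # cm^-1, fixed with temperature
    E_a_kJ_mol: float
    tau_prefactor_fs: float

    def tau_fs(self, T: float) -> float:
        return self.tau_prefactor_fs * math.exp(
            self.E_a_kJ_mol * 1000.0 / (GAS_CONSTANT * T))

    def width_cm1(self, T: float) -> float:
        return 1.0e15 / (self.tau_fs(T) * SPEED_OF_LIGHT_CM_S)


#: Study-condition defaults: stretching ~190 cm^-1 wide at 298 K
#: (tau ~ 176 fs, E_a 3.5 kJ/mol), libration ~280 cm^-1 (tau ~ 119 fs,
#: E_a 7.4 kJ/mol).
DEFAULT_MODE_TRUTHS: dict[str, ModeTruth] = {
    "stretching": ModeTruth(amplitude=1800.0, center=147.0,
                            E_a_kJ_mol=3.5, tau_prefactor_fs=42.8),
    "libration": ModeTruth(amplitude=3800.0, center=412.0,
                           E_a_kJ_mol=7.4, tau_prefactor_fs=6.0),
}

DEFAULT_BACKGROUND_SCALES = (150.0, 6000.0)  # (a_LF, a_HF)


def _lipid_reference(nu: np.ndarray, temperature: float) -> AbsorptionSpectrum:
    # broad featureless lipid-mixture absorption
    alpha_m = 250.0 * nu**2 / (nu**2 + 200.0**2)
    return AbsorptionSpectrum(nu=nu, alpha=alpha_m, temperature=temperature,
                              sample_id="synthetic-lipid-reference")


def gen_thz_series(
    T_grid=None,
    mode_truths: dict[str, ModeTruth] | None = None,
    background: BackgroundShapes = DEFAULT_BACKGROUND,
    background_scales: tuple[float, float] = DEFAULT_BACKGROUND_SCALES,
    noise_sd: float = 0.01,
    seed: int = 0,
    raw: bool = False,
    phi_m: float = 0.5,
    n_C: float = 2.42,
    n_s: float = 1.41,
    theta: float = math.pi / 4.0,
):
    """Temperature series of synthetic water spectra with Arrhenius widths.

    Spectra are evaluated on 50-550 cm^-1 at 2 cm^-1 steps from the
    Debye + two-DHO composition; additive Gaussian noise is scaled to
    the peak of the noiseless spectrum.  With ``raw=True`` the series
    is inverted through the ATR optics into I0/I pairs and a lipid
    reference spectrum is emitted alongside.

    Returns ``(spectra, truth)`` or ``(raw_spectra, lipid_ref, truth)``.
    """
    if T_grid is None:
        T_grid = np.arange(298.0, 341.0, 3.0)
    T_grid = np.asarray(T_grid, dtype=float)
    if np.any(T_grid < 290.0) or np.any(T_grid > 350.0):
        raise ValueError("temperatures must lie within 290-350 K")
    if mode_truths is None:
        mode_truths = DEFAULT_MODE_TRUTHS
    for name, mt in mode_truths.items():
        if mt.E_a_kJ_mol <= 0:
            raise ValueError(f"{name}: activation energy must be positive")
        for T in T_grid:
            tau = mt.tau_fs(T)
            if not 10.0 < tau < 2000.0:
                raise ValueError(
                    f"{name}: implied lifetime {tau:.1f} fs at {T} K leaves "
                    "(10, 2000) fs")
    rng = np.random.default_rng(seed)
    nu = np.arange(50.0, 550.0 + 1e-9, 2.0)
    a_LF, a_HF = background_scales

    spectra = []
    models = {}
    for T in T_grid:
        model = SpectralModel(
            a_LF=a_LF, a_HF=a_HF,
            stretching=DHOMode(mode_truths["stretching"].amplitude,
                               mode_truths["stretching"].center,
                               mode_truths["stretching"].width_cm1(T)),
            libration=DHOMode(mode_truths["libration"].amplitude,
                              mode_truths["libration"].center,
                              mode_truths["libration"].width_cm1(T)),
            background=background,
        )
        clean = eval_model(nu, model)
        noise = noise_sd * float(np.max(clean)) * rng.standard_normal(nu.shape)
        spectra.append(WaterSpectrum(
            nu=nu, delta_alpha=clean + noise, temperature=float(T),
            phi_m=phi_m if raw else 0.0, sample_id="synthetic-thz"))
        models[float(T)] = model

    truth = GroundTruth(
        generator="gen_thz_series", seed=seed,
        parameters={
            "T_grid": T_grid,
            "modes": {k: dataclasses.asdict(v) for k, v in mode_truths.items()},
            "true_widths_cm1": {
                k: np.array([mt.width_cm1(T) for T in T_grid])
                for k, mt in mode_truths.items()},
            "true_tau_fs": {
                k: np.array([mt.tau_fs(T) for T in T_grid])
                for k, mt in mode_truths.items()},
            "background": dataclasses.asdict(background),
            "background_scales": background_scales,
            "phi_m": phi_m, "n_C": n_C, "n_s": n_s, "theta": theta,
            "raw": raw,
        },
        noise_model=f"additive Gaussian on delta_alpha, sd={noise_sd} x peak",
    )
    if not raw:
        return spectra, truth

    lipid = _lipid_reference(nu, float(T_grid[0]))
    d_s_cm = penetration_thickness(nu, n_C, n_s, theta) * 1.0e-4
    raw_spectra = []
    for ws in spectra:
        alpha = ws.delta_alpha + phi_m * lipid.alpha
        I0 = np.ones_like(nu)
        I = I0 * np.exp(-np.clip(alpha, 0.0, None) * d_s_cm)
        raw_spectra.append(RawATRSpectrum(
            nu=nu, I0=I0, I=I, temperature=ws.temperature,
            n_C=n_C, n_s=n_s, theta=theta, sample_id="synthetic-thz-raw"))
    return raw_spectra, lipid, truth


# ---------------------------------------------------------------------------
# slab frames
# ---------------------------------------------------------------------------

_COL_SPACING = 1.6   # nm lateral grid pitch; keeps units beyond the HB cutoff
_SLOT_HEIGHT = 1.0   # nm vertical slot; >= 0.4 nm O-O gap between stacked units
_OO_BONDED = 0.28    # nm donor-acceptor distance of a bonded pair
_OO_UNBONDED = 0.45  # nm beyond the 0.35 nm cutoff
_OH = 0.1            # nm covalent O-H length


def _deficit(dz: np.ndarray, depth: float, head_center: float,
             shell_extent: float) -> np.ndarray:
    """Square-root undercoordination ramp, full depth inside the headgroup
    layer, vanishing at head_center + shell_extent."""
    edge = head_center + shell_extent
    u = np.clip((edge - dz) / shell_extent, 0.0, 1.0)
    return depth * np.sqrt(u)


def _bulk_probability(T: float, E_a_kJ_mol: float, prefactor: float) -> float:
    p = prefactor * math.exp(E_a_kJ_mol * 1000.0 / (GAS_CONSTANT * T))
    if not 0.0 < p < 1.0:
        raise ValueError(f"bulk bond probability {p:.3f} outside (0, 1) at {T} K")
    return p


def _build_unit_frame(rng, n_cols_side: int, n_per_col: int, Lz: float,
                      z_mid: float, p_of_z, lipid_lambda, wl_lambda,
                      temperature: float) -> tuple[Frame, np.ndarray, np.ndarray]:
    """One frame of two-molecule units on a jittered column grid.

    Columns sit on a lateral grid whose pitch keeps units of different
    columns beyond the bond cutoff; within a column, units occupy
    vertical slots with a per-column random phase so the z coverage is
    uniform while stacked oxygens stay >= 0.4 nm apart.

    Returns the frame plus (water folded distances, water bond
    probabilities) for ground-truth bookkeeping.
    """
    L = n_cols_side * _COL_SPACING
    box = np.array([L, L, Lz])
    n_cols = n_cols_side * n_cols_side
    n_slots = n_cols * n_per_col

    cx, cy = np.meshgrid(np.arange(n_cols_side), np.arange(n_cols_side))
    colx = np.repeat((cx.ravel() + 0.5) * _COL_SPACING, n_per_col)
    coly = np.repeat((cy.ravel() + 0.5) * _COL_SPACING, n_per_col)
    slot = np.tile(np.arange(n_per_col), n_cols)
    phase = np.repeat(rng.uniform(0.0, _SLOT_HEIGHT, n_cols), n_per_col)
    z = np.mod(slot * _SLOT_HEIGHT + phase + rng.uniform(0.2, 0.8, n_slots), Lz)
    ax_ = colx + rng.uniform(-0.15, 0.15, n_slots)
    ay = coly + rng.uniform(-0.15, 0.15, n_slots)

    dz = np.abs(z - z_mid)
    dz = np.minimum(dz, Lz - dz)
    p = p_of_z(dz)
    lam_lipid = lipid_lambda(dz)
    lam_wl = wl_lambda(dz)

    u_draw = rng.uniform(size=n_slots)
    is_lip = u_draw < lam_lipid
    is_wl = (~is_lip) & (u_draw < lam_lipid + lam_wl)
    is_ww = ~(is_lip | is_wl)
    bonded = rng.uniform(size=n_slots) < p
    phi = rng.uniform(0.0, 2.0 * math.pi, n_slots)
    direction = np.column_stack([np.cos(phi), np.sin(phi), np.zeros(n_slots)])
    anchor = np.column_stack([ax_, ay, z])
    partner = anchor + np.where(bonded, _OO_BONDED, _OO_UNBONDED)[:, None] * direction
    up = np.array([0.0, 0.0, _OH])

    blocks: list[tuple[np.ndarray, list[str], np.ndarray]] = []
    mol_base = 0

    def stack(mask, atom_positions, atom_roles, mols_per_slot, mol_pattern):
        nonlocal mol_base
        n = int(mask.sum())
        if n == 0:
            return
        pos = np.stack(atom_positions, axis=1)[mask]          # (n, k, 3)
        mols = (mol_base + mols_per_slot * np.arange(n)[:, None]
                + np.asarray(mol_pattern)[None, :])
        blocks.append((pos.reshape(-1, 3), atom_roles * n, mols.reshape(-1)))
        mol_base += mols_per_slot * n

    # isolated headgroup site: O-H that can donate (and accept)
    stack(is_lip, [anchor, anchor + _OH * direction],
          ["lipid_donor_heavy", "lipid_H"], 1, [0, 0])
    # lipid donor O-H pointing at a water acceptor; water H's point away
    stack(is_wl,
          [anchor, anchor + _OH * direction,
           partner, partner + _OH * direction, partner + up],
          ["lipid_donor_heavy", "lipid_H", "water_O", "water_H", "water_H"],
          2, [0, 0, 1, 1, 1])
    # water-water unit: anchor donates along the pair axis
    stack(is_ww,
          [anchor, anchor + _OH * direction, anchor + up,
           partner, partner + _OH * direction, partner - up],
          ["water_O", "water_H", "water_H", "water_O", "water_H", "water_H"],
          2, [0, 0, 0, 1, 1, 1])

    positions = np.concatenate([b[0] for b in blocks])
    roles = np.concatenate([np.array(b[1]) for b in blocks])
    molecule = np.concatenate([b[2] for b in blocks])
    frame = Frame(
        positions=positions, roles=roles, molecule=molecule, box=box,
        temperature=temperature, membrane_normal="z", z_mid=z_mid,
    )
    water_dz = np.concatenate([dz[is_wl], np.repeat(dz[is_ww], 2)])
    water_p = np.concatenate([p[is_wl], np.repeat(p[is_ww], 2)])
    return frame, water_dz, water_p


def gen_slab_frames(
    n_water: int = 45000,
    head_center: float = 1.5,
    head_sd: float = 0.3,
    shell_extent: float = 0.9,
    deficit_depth: float = 0.14,
    T_grid=None,
    frames_per_T: int = 10,
    seed: int = 0,
    slab_height: float = 7.0,
    E_a_kJ_mol: float = 1.48,
    bulk_p_prefactor: float = 0.44,
    lipid_site_fraction: float = 0.25,
    wl_fraction: float = 0.4,
    bulk_box: float = 10.0,
    bulk_frames_per_T: int = 300,
    bin_width: float = 0.1,
):
    """Slab coordinate frames with imposed hydrogen-bond statistics.

    Waters are generated in two-molecule units bonded with probability
    p(z, T) = p_bulk(T) * (1 - deficit(z)) where p_bulk follows an
    Arrhenius law (activation energy ``E_a_kJ_mol``) and the deficit is
    a square-root ramp of depth ``deficit_depth`` vanishing at
    ``head_center + shell_extent`` from the midplane.  Pseudo-lipid
    headgroup sites are Gaussian-placed around +/-``head_center``; a
    fraction of interfacial units are water-lipid bonded pairs.
    Matching pure-water bulk boxes are emitted per temperature.

    Returns ``(frames_by_T, bulk_by_T, truth)``; expected per-bin
    profile means are recorded in the ground truth.
    """
    if T_grid is None:
        T_grid = np.arange(308.0, 339.0, 5.0)
    T_grid = np.asarray(T_grid, dtype=float)
    if head_center + shell_extent > slab_height / 2.0:
        raise ValueError("deficit shell must fit within half the slab height")
    z_mid = slab_height / 2.0
    n_per_col = int(slab_height / _SLOT_HEIGHT)
    n_units = max(1, n_water // 2)
    n_cols_side = max(2, int(math.ceil(math.sqrt(n_units / n_per_col))))

    def lipid_lambda(dz):
        return lipid_site_fraction * np.exp(
            -((dz - head_center) ** 2) / (2.0 * head_sd**2))

    def wl_lambda(dz):
        return wl_fraction * np.exp(
            -((dz - head_center) ** 2) / (2.0 * head_sd**2))

    n_bulk_per_col = int(bulk_box / _SLOT_HEIGHT)
    n_bulk_side = max(2, int(bulk_box / _COL_SPACING))
    zeros = lambda dz: np.zeros_like(dz)

    rng = np.random.default_rng(seed)
    frames_by_T: dict[float, list[Frame]] = {}
    bulk_by_T: dict[float, list[Frame]] = {}
    edge = head_center + shell_extent
    n_bins = int(math.ceil(z_mid / bin_width))
    expected = {}
    p_bulk_by_T = {}
    for T in T_grid:
        p_bulk = _bulk_probability(T, E_a_kJ_mol, bulk_p_prefactor)
        p_bulk_by_T[float(T)] = p_bulk

        def p_of_z(dz, p_bulk=p_bulk):
            return p_bulk * (1.0 - _deficit(dz, deficit_depth, head_center,
                                            shell_extent))

        frames = []
        psum = np.zeros(n_bins)
        pcount = np.zeros(n_bins)
        for _ in range(frames_per_T):
            frame, wdz, wp = _build_unit_frame(
                rng, n_cols_side, n_per_col, slab_height, z_mid,
                p_of_z, lipid_lambda, wl_lambda, float(T))
            frames.append(frame)
            idx = np.minimum((wdz / bin_width).astype(int), n_bins - 1)
            np.add.at(psum, idx, wp)
            np.add.at(pcount, idx, 1.0)
        frames_by_T[float(T)] = frames

        bulks = []
        for _ in range(bulk_frames_per_T):
            bframe, _, _ = _build_unit_frame(
                rng, n_bulk_side, n_bulk_per_col, bulk_box, bulk_box / 2.0,
                lambda dz, p_bulk=p_bulk: np.full_like(dz, p_bulk),
                zeros, zeros, float(T))
            bulks.append(bframe)
        bulk_by_T[float(T)] = bulks

        with np.errstate(invalid="ignore", divide="ignore"):
            expected[float(T)] = {
                "bin_centers": (np.arange(n_bins) + 0.5) * bin_width,
                "expected_mean": psum / pcount,
                "water_counts": pcount,
            }

    truth = GroundTruth(
        generator="gen_slab_frames", seed=seed,
        parameters={
            "head_center": head_center, "head_sd": head_sd,
            "shell_extent": shell_extent, "deficit_depth": deficit_depth,
            "deficit_shape": "depth * sqrt(clip((edge - z)/shell, 0, 1))",
            "x_c_true": edge, "T_grid": T_grid,
            "E_a_kJ_mol": E_a_kJ_mol, "bulk_p_prefactor": bulk_p_prefactor,
            "p_bulk_by_T": p_bulk_by_T,
            "frames_per_T": frames_per_T, "n_water_requested": n_water,
            "slab_height": slab_height, "bulk_box": bulk_box,
            "expected_profiles": expected,
        },
        noise_model="Bernoulli pair bonding; binomial sampling noise only",
    )
    return frames_by_T, bulk_by_T, truth
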