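"""File interfaces: SAXS ASCII, THz CSV, coordinate frames, role maps.

SAXS profiles are two-column ASCII (q in 1/A, intensity) with optional
``# key = value`` comment headers.  THz spectra are CSV with the same
comment-header dialect and columns ``nu_cm1`` plus either ``I0``/``I``
or ``alpha_cm1``.  Coordinate frames travel as multi-model PDB (written
and read through MDAnalysis) with a YAML role map translating atom
names to hydrogen-bond roles.
"""

from __future__ import annotations

import io as _io
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .hbond import ROLES, Frame
from .saxs import ScatteringProfile
from .thz import AbsorptionSpectrum, RawATRSpectrum, WaterSpectrum

__all__ = [
    "read_saxs_profile", "write_saxs_profile",
    "read_thz_csv", "write_thz_csv",
    "write_frames_pdb", "read_frames_pdb",
    "read_role_map", "write_role_map",
    "write_json",
]

#: Atom names emitted by the synthetic slab generator.
DEFAULT_ROLE_MAP = {
    "OW": "water_O", "HW1": "water_H", "HW2": "water_H",
    "OLD": "lipid_donor_heavy", "OLA": "lipid_acceptor_heavy", "HL": "lipid_H",
}


def _parse_header(path) -> dict[str, str]:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def read_saxs_profile(path) -> ScatteringProfile:
    """Two-column (q 1/A, intensity) ASCII, whitespace- or comma-delimited."""
    meta = _parse_header(path)
    text = Path(path).read_text()
    rows = [ln.replace(",", " ") for ln in text.splitlines()
            if ln.strip() and not ln.startswith("#")]
    data = np.loadtxt(_io.StringIO("\n".join(rows)))
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (q, intensity)")
    return ScatteringProfile(
        q=data[:, 0], intensity=data[:, 1],
        temperature=float(meta.get("temperature_K", 298.0)),
        sample_id=meta.get("sample_id", Path(path).stem),
    )


def write_saxs_profile(profile: ScatteringProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# temperature_K = {profile.temperature}\n")
        fh.write(f"# sample_id = {profile.sample_id}\n")
        for q, i in zip(profile.q, profile.intensity):
            fh.write(f"{q:.8f} {i:.8f}\n")


def read_thz_csv(path):
    """THz CSV -> RawATRSpectrum (I0/I columns) or spectrum (alpha_cm1 column).

    Header keys: temperature_K, sample_id, phi_m, n_s, n_C, theta, kind.
    ``kind = water`` marks a lipid-subtracted spectrum (WaterSpectrum);
    otherwise an alpha column is returned as an AbsorptionSpectrum.
    """
    meta = _parse_header(path)
    df = pd.read_csv(path, comment="#")
    T = float(meta.get("temperature_K", 298.0))
    sample = meta.get("sample_id", Path(path).stem)
    if {"I0", "I"}.issubset(df.columns):
        return RawATRSpectrum(
            nu=df["nu_cm1"].to_numpy(), I0=df["I0"].to_numpy(),
            I=df["I"].to_numpy(), temperature=T,
            n_C=float(meta.get("n_C", 2.42)), n_s=float(meta.get("n_s", 1.47)),
            theta=float(meta.get("theta", np.pi / 4)),
            noise_tolerance=float(meta.get("noise_tolerance", 0.0)),
            sample_id=sample)
    if "alpha_cm1" in df.columns:
        if meta.get("kind", "absorption") == "water":
            return WaterSpectrum(
                nu=df["nu_cm1"].to_numpy(), delta_alpha=df["alpha_cm1"].to_numpy(),
                temperature=T, phi_m=float(meta.get("phi_m", 0.0)),
                sample_id=sample)
        return AbsorptionSpectrum(
            nu=df["nu_cm1"].to_numpy(), alpha=df["alpha_cm1"].to_numpy(),
            temperature=T, sample_id=sample)
    raise ValueError(f"{path}: need columns nu_cm1 + (I0, I) or alpha_cm1")


def write_thz_csv(spectrum, path) -> None:
    meta = {"temperature_K": spectrum.temperature, "sample_id": spectrum.sample_id}
    if isinstance(spectrum, RawATRSpectrum):
        meta.update(n_C=spectrum.n_C, n_s=spectrum.n_s, theta=spectrum.theta)
        df = pd.DataFrame({"nu_cm1": spectrum.nu, "I0": spectrum.I0,
                           "I": spectrum.I})
    elif isinstance(spectrum, WaterSpectrum):
        meta.update(phi_m=spectrum.phi_m, kind="water")
        df = pd.DataFrame({"nu_cm1": spectrum.nu, "alpha_cm1": spectrum.delta_alpha})
    else:
        df = pd.DataFrame({"nu_cm1": spectrum.nu, "alpha_cm1": spectrum.alpha})
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k} = {v}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# coordinate frames
# ---------------------------------------------------------------------------

_ROLE_TO_NAME = {
    "water_O": "OW", "lipid_donor_heavy": "OLD",
    "lipid_acceptor_heavy": "OLA", "lipid_H": "HL", "other": "X",
}


def _atom_names(frame: Frame) -> list[str]:
    names = []
    h_seen: dict[int, int] = {}
    for role, mol in zip(frame.roles, frame.molecule):
        if role == "water_H":
            h_seen[mol] = h_seen.get(mol, 0) + 1
            names.append(f"HW{h_seen[mol]}")
        else:
            names.append(_ROLE_TO_NAME[role])
    return names


def write_frame_pdb(frame: Frame, path) -> None:
    """Write a single frame as a PDB file."""
    write_frames_pdb([frame], path)


def write_frames_pdb(frames: list[Frame], path) -> None:
    """Write frames as a multi-model PDB (coordinates nm -> Angstrom).

    All frames must share one topology (same roles and molecule
    arrays); stochastic frame sets with varying composition should be
    written one file per frame via :func:`write_frame_pdb`.
    """
    import MDAnalysis as mda

    first = frames[0]
    for frame in frames[1:]:
        if (len(frame.positions) != len(first.positions)
                or not np.array_equal(frame.roles, first.roles)
                or not np.array_equal(frame.molecule, first.molecule)):
            raise ValueError(
                "frames differ in topology; write them one file per frame "
                "with write_frame_pdb")
    n = len(first.positions)
    u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n),
                           trajectory=True)
    names = _atom_names(first)
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resids", first.molecule + 1)
    u.add_TopologyAttr("resnames", ["SOL" if r.startswith("water") else "LIP"
                                    for r in first.roles])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), multiframe=True) as writer:
            for frame in frames:
                u.atoms.positions = frame.positions * 10.0
                u.dimensions = [*(frame.box * 10.0), 90.0, 90.0, 90.0]
                writer.write(u.atoms)


def read_frames_pdb(path, role_map: dict[str, str] | None = None,
                    temperature: float = 298.0,
                    z_mid: float | None = None,
                    membrane_normal: str = "z") -> list[Frame]:
    """Read a (multi-model) PDB into Frames using an atom-name role map."""
    import MDAnalysis as mda

    if role_map is None:
        role_map = DEFAULT_ROLE_MAP
    # multi-model PDBs keep CRYST1 in the header, which some readers drop
    # per-frame; recover it directly as a fallback
    cryst = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                cryst.append([float(line[6:15]), float(line[15:24]),
                              float(line[24:33])])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        roles = np.array([role_map.get(name, "other") for name in u.atoms.names])
        molecule = u.atoms.resids - 1
        frames = []
        for k, ts in enumerate(u.trajectory):
            if ts.dimensions is not None:
                box = np.asarray(ts.dimensions[:3])
            elif cryst:
                box = np.asarray(cryst[min(k, len(cryst) - 1)])
            else:
                raise ValueError(f"{path}: no box information (CRYST1) found")
            frames.append(Frame(
                positions=u.atoms.positions / 10.0, roles=roles,
                molecule=molecule, box=box / 10.0,
                temperature=temperature, membrane_normal=membrane_normal,
                z_mid=z_mid))
    return frames


def read_role_map(path) -> dict[str, str]:
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise ValueError(f"{path}: role map must be a mapping")
    bad = {k: v for k, v in mapping.items() if v not in ROLES}
    if bad:
        raise ValueError(f"{path}: invalid roles {bad}")
    return mapping


def write_role_map(mapping: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(mapping, fh)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not serializable: {type(o)}")
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
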