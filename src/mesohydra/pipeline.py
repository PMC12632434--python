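"""End-to-end orchestration: simulate -> index -> fit -> Arrhenius -> correlate.

A :class:`RunConfig` (YAML or dict) selects stages and per-stage
parameter blocks; :func:`run_pipeline` executes them in dependency
order, writes JSON/CSV artifacts into the output directory and returns
a combined report.  Failures are fail-fast with the offending stage
named; artifacts written before the failure are retained.

The final ``correlate`` stage pairs the SAXS-derived interfacial water
fraction with the THz mode lifetimes by nearest temperature (within
+/-1.5 K) and fits the nonlinear relation tau = p + q * f^r.
"""

from __future__ import annotations

import dataclasses
import platform
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import curve_fit

from . import __version__, io, saxs, synthetic, thz
from .hbond import bulk_recovery_distance, bulk_value, hb_arrhenius, hb_profile

ALL_STAGES = (
    "simulate_saxs", "saxs_index", "saxs_geometry",
    "simulate_thz", "thz_fit",
    "simulate_slab", "hbond_profile",
    "correlate",
)

_BLOCK_KEYS = {
    "saxs": {"group", "a", "a_slope_per_K", "n_peaks", "peak_width", "background",
             "noise_sd", "T_grid", "amplitude", "n_points"},
    "geometry": {"phi_L", "K0", "f_w", "min_prominence", "smoothing_window",
                 "max_peaks_used"},
    "thz": {"T_grid", "noise_sd", "raw", "phi_m", "n_C", "n_s",
            "init_offset"},
    "slab": {"n_water", "head_center", "head_sd", "shell_extent", "deficit_depth",
             "T_grid", "frames_per_T", "bulk_frames_per_T", "E_a_kJ_mol",
             "bin_width", "tol"},
    "correlate": {"mode", "tolerance_K"},
}


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs were retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    seed: int = 0
    outdir: str = "mesohydra_out"
    verbosity: int = 1
    saxs: dict = field(default_factory=dict)
    geometry: dict = field(default_factory=dict)
    thz: dict = field(default_factory=dict)
    slab: dict = field(default_factory=dict)
    correlate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown_stages = set(self.stages) - set(ALL_STAGES)
        if unknown_stages:
            raise ValueError(f"unknown stages: {sorted(unknown_stages)}")
        for block, allowed in _BLOCK_KEYS.items():
            extra = set(getattr(self, block)) - allowed
            if extra:
                raise ValueError(f"unknown keys in '{block}': {sorted(extra)}")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(raw) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def resolved(self) -> dict:
        return dataclasses.asdict(self)


def _simulate_saxs(cfg: RunConfig, state: dict) -> dict:
    block = dict(cfg.saxs)
    T_grid = np.asarray(block.pop("T_grid", np.arange(298.0, 341.0, 3.0)), float)
    a0 = block.pop("a", 10.0)
    slope = block.pop("a_slope_per_K", 0.01)  # lattice contracts on heating
    profiles = []
    truths = []
    for k, T in enumerate(T_grid):
        profile, truth = synthetic.gen_saxs(
            a=a0 - slope * (T - T_grid[0]), temperature=float(T),
            seed=cfg.seed + k, **block)
        profiles.append(profile)
        truths.append(truth)
    state["saxs_profiles"] = profiles
    return {"n_profiles": len(profiles),
            "true_a_nm": [t.parameters["a_nm"] for t in truths]}


def _saxs_index(cfg: RunConfig, state: dict) -> dict:
    g = cfg.geometry
    assignments = []
    records = []
    for profile in state["saxs_profiles"]:
        peaks = saxs.detect_peaks(
            profile, min_prominence=g.get("min_prominence", 0.02),
            smoothing_window=g.get("smoothing_window", 5))
        asg, _ = saxs.index_phase(
            peaks, max_peaks_used=g.get("max_peaks_used", 4),
            temperature=profile.temperature, sample_id=profile.sample_id)
        assignments.append(asg)
        records.append(asg.to_record())
    state["assignments"] = assignments
    return {"assignments": records}


def _saxs_geometry(cfg: RunConfig, state: dict) -> dict:
    g = cfg.geometry
    phi_L = g.get("phi_L", 0.5)
    assignments = state["assignments"]
    K0 = g.get("K0")
    if K0 is None:
        K0 = saxs.k0_gaussian_curvature(assignments[0].space_group)
    table = saxs.geometry_series(assignments, phi_L=phi_L, K0=K0,
                                 f_w=g.get("f_w"))
    state["geometry_table"] = table
    return {"geometry": table.to_dict(orient="records"), "K0": K0}


def _simulate_thz(cfg: RunConfig, state: dict) -> dict:
    block = dict(cfg.thz)
    block.pop("init_offset", None)
    if block.pop("raw", False):
        raw_spectra, lipid_ref, truth = synthetic.gen_thz_series(
            seed=cfg.seed, raw=True, **block)
        spectra = [thz.subtract_lipid(thz.absorption_from_atr(r), lipid_ref,
                                      truth.parameters["phi_m"])
                   for r in raw_spectra]
    else:
        block.pop("phi_m", None), block.pop("n_C", None), block.pop("n_s", None)
        spectra, truth = synthetic.gen_thz_series(seed=cfg.seed, **block)
    state["thz_spectra"] = spectra
    state["thz_truth"] = truth
    return {"n_spectra": len(spectra),
            "true_E_a": {k: v["E_a_kJ_mol"]
                         for k, v in truth.parameters["modes"].items()}}


def _thz_fit(cfg: RunConfig, state: dict) -> dict:
    offset = 1.0 + cfg.thz.get("init_offset", 0.1)
    truth = state.get("thz_truth")
    if truth is not None:
        modes = truth.parameters["modes"]
        scales = truth.parameters["background_scales"]
        init = thz.SpectralModel(
            a_LF=scales[0] * offset, a_HF=scales[1] * offset,
            stretching=thz.DHOMode(modes["stretching"]["amplitude"] * offset,
                                   modes["stretching"]["center"] * offset,
                                   180.0),
            libration=thz.DHOMode(modes["libration"]["amplitude"] * offset,
                                  modes["libration"]["center"] * offset,
                                  300.0))
    else:
        init = thz.SpectralModel(
            a_LF=150.0, a_HF=6000.0,
            stretching=thz.DHOMode(1800.0, 150.0, 180.0),
            libration=thz.DHOMode(3800.0, 420.0, 300.0))
    series = thz.analyze_series(state["thz_spectra"], init)
    state["thz_series"] = series
    return {
        "lifetimes": series.lifetime_table.to_dict(orient="records"),
        "arrhenius": {k: dataclasses.asdict(v) for k, v in series.arrhenius.items()},
        "skipped": series.skipped,
        "failed_temperatures": series.failed_temperatures,
    }


def _simulate_slab(cfg: RunConfig, state: dict) -> dict:
    block = dict(cfg.slab)
    block.pop("tol", None)
    frames_by_T, bulk_by_T, truth = synthetic.gen_slab_frames(
        seed=cfg.seed, **block)
    state["slab"] = (frames_by_T, bulk_by_T, truth)
    return {"temperatures": sorted(frames_by_T),
            "x_c_true": truth.parameters["x_c_true"]}


def _hbond_profile(cfg: RunConfig, state: dict) -> dict:
    frames_by_T, bulk_by_T, truth = state["slab"]
    tol = cfg.slab.get("tol", 0.02)
    bin_width = cfg.slab.get("bin_width", 0.1)
    profiles = []
    rows = []
    for T in sorted(frames_by_T):
        profile = hb_profile(frames_by_T[T], bin_width=bin_width)
        profile.n_HB_bulk = bulk_value(bulk_by_T[T])
        bulk_recovery_distance(profile, tol=tol)
        profiles.append(profile)
        rows.append({"T": T, "n_HB_mean": profile.mean_total,
                     "n_HB_bulk": profile.n_HB_bulk, "x_c_nm": profile.x_c,
                     "x_c_reached": profile.x_c_reached})
    arr = hb_arrhenius(profiles) if len(profiles) >= 3 else None
    state["hb_profiles"] = profiles
    return {"summary": rows,
            "arrhenius": dataclasses.asdict(arr) if arr else None}


def _correlate(cfg: RunConfig, state: dict) -> dict:
    """Pair lifetimes with f_w_int by nearest temperature, fit tau = p + q*f^r."""
    tol_K = cfg.correlate.get("tolerance_K", 1.5)
    mode = cfg.correlate.get("mode", "stretching")
    geom = state["geometry_table"]
    lt = state["thz_series"].lifetime_table
    lt = lt[(lt["mode"] == mode) & lt["converged"]]
    pairs = []
    for _, row in lt.iterrows():
        avail = geom[geom["available"]]
        if avail.empty:
            continue
        i = (avail["temperature"] - row["T"]).abs().idxmin()
        if abs(avail.loc[i, "temperature"] - row["T"]) <= tol_K:
            pairs.append({"T": row["T"], "tau_fs": row["tau_fs"],
                          "f_w_int": avail.loc[i, "f_w_int"]})
    result = {"mode": mode, "pairs": pairs, "fit": None}
    if len(pairs) >= 4:
        f = np.array([p["f_w_int"] for p in pairs])
        tau = np.array([p["tau_fs"] for p in pairs])
        try:
            popt, _ = curve_fit(
                lambda x, p, q, r: p + q * np.power(np.clip(x, 1e-12, None), r),
                f, tau, p0=[tau.min(), np.ptp(tau) + 1.0, 1.0], maxfev=20000)
            result["fit"] = {"p": float(popt[0]), "q": float(popt[1]),
                             "r": float(popt[2]),
                             "form": "tau = p + q * f_w_int^r"}
        except RuntimeError as exc:
            result["fit"] = {"error": str(exc)}
    return result


_STAGE_FUNCS = {
    "simulate_saxs": _simulate_saxs,
    "saxs_index": _saxs_index,
    "saxs_geometry": _saxs_geometry,
    "simulate_thz": _simulate_thz,
    "thz_fit": _thz_fit,
    "simulate_slab": _simulate_slab,
    "hbond_profile": _hbond_profile,
    "correlate": _correlate,
}


def run_pipeline(config: RunConfig, outdir=None) -> dict:
    """Execute the configured stages in dependency order.

    Returns the combined report (also written to ``report.json`` in the
    output directory together with per-stage CSV tables and the
    resolved configuration).
    """
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "package": "mesohydra", "version": __version__,
            "python": sys.version.split()[0], "platform": platform.platform(),
            "seed": config.seed, "resolved_config": config.resolved(),
        },
        "stages": {},
    }
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(config.resolved(), fh)

    state: dict = {}
    ordered = [s for s in ALL_STAGES if s in config.stages]
    for stage in ordered:
        try:
            report["stages"][stage] = _STAGE_FUNCS[stage](config, state)
        except Exception as exc:
            report["failed_stage"] = stage
            io.write_json(report, out / "report.json")
            raise StageError(stage, exc) from exc
        io.write_json(report, out / "report.json")

    if "geometry_table" in state:
        state["geometry_table"].to_csv(out / "geometry.csv", index=False)
    if "thz_series" in state:
        state["thz_series"].lifetime_table.to_csv(out / "lifetimes.csv", index=False)
    if "hb_profiles" in state:
        pd.concat(
            [p.to_frame().assign(T=p.temperature) for p in state["hb_profiles"]]
        ).to_csv(out / "hb_profiles.csv", index=False)
    io.write_json(report, out / "report.json")
    return report
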