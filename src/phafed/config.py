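"""Run configuration, seeded titration scans over a pH grid, and reports.

The run configuration is a YAML document with a versioned schema.  A scan
executes one simulation per (pH, replicate) with a seed derived purely from
(base_seed, pH index, replicate) via counter-based stream splitting, so
re-running the same configuration reproduces every output bitwise.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import analysis
from .dafed import ExtendedVariable, attach_dafed
from .engine import Trajectory, run_simulation
from .io import write_trajectory
from .model import (
    BURIED_PRESET,
    SURFACE_PRESET,
    HisSiteSpec,
    ModelSystem,
    SiteClass,
    SiteSpec,
    EnvCoordinate,
)

__all__ = ["RunConfig", "load_config", "save_config", "titration_scan",
           "derive_seed", "report", "REFERENCE_COMPOUNDS",
           "reference_scan_config"]

SCHEMA_VERSION = 1

PRESETS = {"surface": SURFACE_PRESET, "buried": BURIED_PRESET}

_TOP_KEYS = {
    "schema_version", "mode", "T_physical", "ph_min", "ph_max", "ph_step",
    "n_steps", "dt", "sample_stride", "replicates", "base_seed",
    "output_dir", "sites", "dafed",
}
_SITE_KEYS = {
    "site_id", "site_class", "pKa_ref", "pKa_micro", "q_A", "q_B", "N_p",
    "preset", "T_lambda", "m_lambda", "barrier_height", "env_offset_dG",
    "gate_height", "env_min_A", "env_min_B", "env_curv_A", "env_curv_B",
}


@dataclass
class RunConfig:
    """Validated titration-scan configuration."""

    sites: List[dict]
    mode: str = "ph_afed"
    T_physical: float = 300.0
    ph_min: float = 0.0
    ph_max: float = 9.0
    ph_step: float = 1.0
    n_steps: int = 200_000  # desk-scale analogue of a 10 ns production run
    dt: float = 0.002
    sample_stride: int = 10
    replicates: int = 3
    base_seed: int = 1
    output_dir: str = "phafed_runs"
    dafed: List[str] = field(default_factory=list)  # site ids to drive
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(
                f"schema_version: expected {SCHEMA_VERSION}, got {self.schema_version}"
            )
        if self.mode not in ("ph_afed", "standard"):
            raise ValueError(f"mode: must be 'ph_afed' or 'standard', got {self.mode!r}")
        if self.ph_min > self.ph_max:
            raise ValueError("ph_min: must be <= ph_max")
        if not self.ph_step > 0:
            raise ValueError("ph_step: must be > 0")
        if self.replicates < 1:
            raise ValueError("replicates: must be >= 1")
        if self.n_steps < 1:
            raise ValueError("n_steps: must be >= 1")
        if not self.dt > 0:
            raise ValueError("dt: must be > 0")
        if self.sample_stride < 1:
            raise ValueError("sample_stride: must be >= 1")
        if not self.sites:
            raise ValueError("sites: at least one titratable site is required")
        for s in self.sites:
            unknown = set(s) - _SITE_KEYS
            if unknown:
                raise ValueError(f"sites: unknown key(s) {sorted(unknown)}")
            if "site_id" not in s:
                raise ValueError("sites: every site needs a site_id")
        ids = [s["site_id"] for s in self.sites]
        if len(ids) != len(set(ids)):
            raise ValueError("sites: duplicate site_id")
        for sid in self.dafed:
            if sid not in ids:
                raise ValueError(f"dafed: unknown site_id {sid!r}")
        self.build_system(self.ph_min)  # fail early on bad site specs

    @property
    def ph_values(self) -> np.ndarray:
        n = int(round((self.ph_max - self.ph_min) / self.ph_step)) + 1
        return self.ph_min + self.ph_step * np.arange(n)

    def build_site(self, s: dict):
        s = dict(s)
        preset = dict(PRESETS[s.pop("preset", "surface")])
        cls = SiteClass(s.pop("site_class", "GENERIC"))
        env = EnvCoordinate(
            min_A=s.pop("env_min_A", 0.0), min_B=s.pop("env_min_B", 0.0),
            curv_A=s.pop("env_curv_A", 100.0), curv_B=s.pop("env_curv_B", 100.0),
        )
        for key in ("T_lambda", "m_lambda", "barrier_height"):
            if key in s:
                preset[key] = s.pop(key)
        if cls is SiteClass.HIS_TAUTOMER and "pKa_micro" in s:
            site = HisSiteSpec(
                site_id=s.pop("site_id"),
                pKa_micro=tuple(s.pop("pKa_micro")),
                env_offset_dG=s.pop("env_offset_dG", 0.0),
                gate_height=s.pop("gate_height", 0.0),
                **preset,
            )
            s.pop("pKa_ref", None)
        else:
            kwargs = {}
            for key in ("pKa_ref", "q_A", "q_B", "N_p", "env_offset_dG",
                        "gate_height"):
                if key in s:
                    kwargs[key] = s.pop(key)
            site = SiteSpec(site_id=s.pop("site_id"), site_class=cls,
                            **preset, **kwargs)
        return site, env

    def build_system(self, pH: float) -> ModelSystem:
        sites, envs = [], []
        for s in self.sites:
            site, env = self.build_site(s)
            sites.append(site)
            envs.append(env)
        return ModelSystem(sites=sites, envs=envs,
                           T_physical=self.T_physical, pH=pH)

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "mode": self.mode,
            "T_physical": self.T_physical,
            "ph_min": self.ph_min, "ph_max": self.ph_max,
            "ph_step": self.ph_step,
            "n_steps": self.n_steps, "dt": self.dt,
            "sample_stride": self.sample_stride,
            "replicates": self.replicates, "base_seed": self.base_seed,
            "output_dir": self.output_dir,
            "dafed": list(self.dafed),
            "sites": [dict(s) for s in self.sites],
        }


# Single-site reference model compounds: ungated, no environment free-energy
# perturbation, parameterized with the standard reference pKa of each residue
# class (His tautomer 1 is represented as a single titration coordinate
# carrying its microscopic value).  The pH grid spans the reference value
# with 6 points at unit spacing.
REFERENCE_COMPOUNDS = {
    "glu": {"site": {"site_id": "glu", "site_class": "GLU", "pKa_ref": 4.25,
                     "q_A": 0.0, "q_B": -1.0, "preset": "surface"},
            "ph_min": 2.0},
    "asp": {"site": {"site_id": "asp", "site_class": "ASP", "pKa_ref": 3.65,
                     "q_A": 0.0, "q_B": -1.0, "preset": "surface"},
            "ph_min": 1.0},
    "his_tautomer1": {
        "site": {"site_id": "his1", "site_class": "GENERIC", "pKa_ref": 6.53,
                 "q_A": 1.0, "q_B": 0.0, "preset": "surface"},
        "ph_min": 4.0},
}


def reference_scan_config(compound: str, base_seed: int = 1,
                          n_steps: int = 200_000, replicates: int = 3,
                          output_dir: str = "phafed_runs") -> RunConfig:
    """Canonical titration-scan settings for a reference model compound."""
    spec = REFERENCE_COMPOUNDS[compound]
    return RunConfig(
        sites=[dict(spec["site"])],
        ph_min=spec["ph_min"], ph_max=spec["ph_min"] + 5.0, ph_step=1.0,
        n_steps=n_steps, replicates=replicates, base_seed=base_seed,
        output_dir=output_dir,
    )


def load_config(path: str) -> RunConfig:
    """Load and fully validate a YAML run configuration.

    Unknown keys are rejected (no silently ignored typos); every invariant
    violation names the offending key.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown key(s) {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def derive_seed(base_seed: int, ph_index: int, replicate: int) -> int:
    """Pure counter-based per-run seed: (base, pH index, replicate) → stream."""
    ss = np.random.SeedSequence(entropy=int(base_seed),
                                spawn_key=(int(ph_index), int(replicate)))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def titration_scan(cfg: RunConfig, write_files: bool = True,
                   log=None) -> Dict[str, object]:
    """Run the full (pH × replicate) scan and aggregate pKa estimates.

    Returns a dict with the per-site pKa report DataFrame (`pka_report`),
    the titration table (`titration`), all trajectories (`trajectories`)
    and any per-run failures (`failures`).  With `write_files`, trajectory
    TSVs and the CSV reports are written under cfg.output_dir.
    """
    log = log or (lambda msg: None)
    trajs: List[Trajectory] = []
    failures = []
    out_dir = cfg.output_dir
    if write_files:
        os.makedirs(out_dir, exist_ok=True)
    for ip, ph in enumerate(cfg.ph_values):
        for rep in range(cfg.replicates):
            seed = derive_seed(cfg.base_seed, ip, rep)
            try:
                system = cfg.build_system(float(ph))
                if cfg.dafed:
                    for sid in cfg.dafed:
                        system = attach_dafed(system, sid)
                traj = run_simulation(
                    system, mode=cfg.mode, n_steps=cfg.n_steps, dt=cfg.dt,
                    seed=seed, sample_stride=cfg.sample_stride,
                )
                traj.metadata["replicate"] = rep
                trajs.append(traj)
                if write_files:
                    write_trajectory(
                        traj, os.path.join(out_dir, f"traj_pH{ph:g}_rep{rep}.tsv"))
                log(f"pH {ph:g} replicate {rep}: ok (seed {seed})")
            except Exception as exc:  # scan continues past per-run failures
                failures.append({"pH": float(ph), "replicate": rep,
                                 "error": str(exc)})
                log(f"pH {ph:g} replicate {rep}: FAILED ({exc})")
    site_ids = [s["site_id"] for s in cfg.sites]
    pka_rows = []
    tit_frames = []
    for sid in site_ids:
        try:
            pka, std, table = analysis.pka_from_trajectories(
                trajs, sid, T=cfg.T_physical)
            fits = table.attrs.get("replicate_fits", [])
            hill = float(np.mean([f.hill_n for f in fits
                                  if f.converged])) if fits else math.nan
            flags = ";".join(table.attrs.get("flags", []))
        except (ValueError, KeyError) as exc:
            pka, std, hill, flags = math.nan, math.nan, math.nan, str(exc)
            table = pd.DataFrame()
        pka_rows.append({"site": sid, "pKa": pka, "pKa_std": std,
                         "hill_n": hill, "flags": flags})
        if len(table):
            table = table.copy()
            table.insert(0, "site", sid)
            tit_frames.append(table)
    pka_report = pd.DataFrame(pka_rows)
    titration = (pd.concat(tit_frames, ignore_index=True)
                 if tit_frames else pd.DataFrame())
    if write_files:
        pka_report.to_csv(os.path.join(out_dir, "pka_report.csv"), index=False)
        if len(titration):
            titration.to_csv(os.path.join(out_dir, "titration.csv"), index=False)
        if failures:
            pd.DataFrame(failures).to_csv(
                os.path.join(out_dir, "failures.csv"), index=False)
    return {"pka_report": pka_report, "titration": titration,
            "trajectories": trajs, "failures": failures}


def report(results_dir: str, experimental_csv: Optional[str] = None,
           make_plots: bool = False) -> Dict[str, object]:
    """Summarize a completed scan directory.

    Reads the pKa report and titration CSVs; if an experimental table
    (columns: site, experimental) is supplied, adds MUE/RMSE/Pearson-r
    prediction metrics.  Optional matplotlib overlays of the fitted curves.
    """
    pka_path = os.path.join(results_dir, "pka_report.csv")
    tit_path = os.path.join(results_dir, "titration.csv")
    if not os.path.exists(pka_path):
        raise FileNotFoundError(f"no pKa report found at {pka_path}")
    out: Dict[str, object] = {"pka_report": pd.read_csv(pka_path)}
    if os.path.exists(tit_path):
        out["titration"] = pd.read_csv(tit_path)
    if experimental_csv is not None:
        exp = pd.read_csv(experimental_csv)
        merged = out["pka_report"].merge(exp, on="site", how="inner")
        ok = merged["pKa"].notna() & merged["experimental"].notna()
        if ok.sum() >= 2:
            out["metrics"] = analysis.prediction_metrics(
                merged.loc[ok, "pKa"], merged.loc[ok, "experimental"])
        else:
            out["metrics"] = None
    if make_plots and "titration" in out and len(out["titration"]):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        tit = out["titration"]
        fig, ax = plt.subplots(figsize=(5, 4))
        for sid, grp in tit.groupby("site"):
            ax.errorbar(grp["pH"], grp["fraction"],
                        yerr=grp.get("fraction_std"), marker="o", label=sid)
            row = out["pka_report"].set_index("site").loc[sid]
            if np.isfinite(row["pKa"]):
                ph = np.linspace(tit["pH"].min(), tit["pH"].max(), 200)
                ax.plot(ph, 1.0 / (1.0 + 10 ** (row["hill_n"] * (row["pKa"] - ph))),
                        "--", alpha=0.7)
        ax.set_xlabel("pH")
        ax.set_ylabel("deprotonated fraction")
        ax.legend(fontsize=8)
        fig.tight_layout()
        plot_path = os.path.join(results_dir, "titration_curves.png")
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
        out["plot"] = plot_path
    return out
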