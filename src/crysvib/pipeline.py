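"""Declarative end-to-end pipeline: one config, dependency-ordered stages,
a JSON manifest of every artifact produced.

Stages
------
synth           generate a toy crystal, force constants, Born charges and
                write structure + numeric-array files
static_spectrum Γ phonons → oscillator strengths → effective-medium powder
                spectrum (CSV/JSON) + mode table with T/R/internal percentages
md_spectrum     Langevin MD on the toy force field → dipole CSV → windowed
                ACF spectrum (CSV/JSON)
torsions        two-well Langevin torsion series → distribution, flip table,
                occupancy (CSV)
thermo          relative Gibbs curves on a pressure grid for toy polymorph
                records (CSV)

Reruns with the same config and seed are byte-identical for every
deterministic stage; the manifest records a config snapshot and a sha256
checksum per output, which is sufficient to re-execute without the
original command line.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fileio
from .dynamic_spectra import WindowSpec, dynamic_spectrum
from .errors import ConfigurationError
from .harmonic import PolymorphRecord, decompose_modes, relative_stability_curves
from .static_spectra import SpectrumConfig, static_spectrum
from .synthetic import (
    make_toy_molecular_crystal,
    simulate_harmonic_md,
    simulate_torsion_langevin,
    two_well_coefficients,
)
from .trajectory import (
    DEFAULT_BASINS,
    TorsionTrajectory,
    detect_flips,
    motif_occupancy,
    torsion_distribution,
)

log = logging.getLogger(__name__)

STAGE_ORDER = ["synth", "static_spectrum", "md_spectrum", "torsions", "thermo"]
_NEEDS_SYNTH = {"static_spectrum", "md_spectrum"}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    stages: list = field(default_factory=list)
    output_dir: str = "crysvib_run"
    seed: int = 0
    log_level: str = "INFO"
    params: dict = field(default_factory=dict)  # per-stage parameter blocks

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        stages = list(raw.get("stages", []))
        unknown = [s for s in stages if s not in STAGE_ORDER]
        if unknown:
            raise ConfigurationError(f"unknown stage(s): {unknown}")
        params = {k: v for k, v in raw.items()
                  if k not in ("stages", "output_dir", "seed", "log_level")}
        return cls(
            stages=stages,
            output_dir=raw.get("output_dir", "crysvib_run"),
            seed=int(raw.get("seed", 0)),
            log_level=raw.get("log_level", "INFO"),
            params=params,
        )

    def snapshot(self) -> dict:
        return {
            "stages": self.stages,
            "output_dir": self.output_dir,
            "seed": self.seed,
            "params": self.params,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order.

    Returns (and writes) the manifest: every produced file with its sha256,
    per-stage status, and the full config snapshot.  A failed stage marks
    its dependents skipped; the manifest is still written.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)

    manifest = {"config": config.snapshot(), "stages": {}, "outputs": {}}
    state: dict = {}
    ordered = [s for s in STAGE_ORDER if s in config.stages]
    failed: set[str] = set()
    try:
        for stage in ordered:
            if stage in _NEEDS_SYNTH and "synth" in failed:
                manifest["stages"][stage] = {"status": "skipped", "reason": "synth failed"}
                continue
            fn = _STAGES[stage]
            try:
                files = fn(config, out, state)
            except Exception as exc:  # noqa: BLE001 - manifest must record failures
                log.exception("stage %s failed", stage)
                manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
                failed.add(stage)
                continue
            manifest["stages"][stage] = {"status": "ok", "outputs": files}
            for f in files:
                manifest["outputs"][f] = _sha256(out / f)
    finally:
        log.removeHandler(fh)
        fh.close()
    manifest["outputs"]["run.log"] = _sha256(out / "run.log")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# --------------------------------------------------------------------------
# stage implementations

def _get_system(config: RunConfig, state: dict):
    if "system" not in state:
        p = config.params.get("synth", {})
        state["system"] = make_toy_molecular_crystal(
            n_molecules=int(p.get("n_molecules", 2)),
            springs=tuple(p.get("springs", (12.0, 1.5))),
            charge=float(p.get("charge", 0.6)),
            seed=config.seed,
        )
    return state["system"]


def _stage_synth(config: RunConfig, out: Path, state: dict) -> list:
    system = _get_system(config, state)
    files = []
    fileio.write_structure(system.crystal, out / "toy_crystal.cif")
    files.append("toy_crystal.cif")
    fileio.write_structure(system.crystal, out / "toy_crystal.vasp", dialect="poscar")
    files.append("toy_crystal.vasp")
    np.savetxt(out / "force_constants.dat", system.force_constants,
               header="3N x 3N Cartesian force constants, eV/A^2, row-major")
    files.append("force_constants.dat")
    np.savetxt(out / "born_charges.dat", system.born_charges.reshape(-1, 9),
               header="per-site Born tensors, one row = 3x3 row-major, e")
    files.append("born_charges.dat")
    return files


def _stage_static(config: RunConfig, out: Path, state: dict) -> list:
    system = _get_system(config, state)
    p = config.params.get("static_spectrum", {})
    grid = p.get("grid", [1.0, 400.0, 800])
    cfg = SpectrumConfig(
        gamma=float(p.get("gamma", 5.0)),
        volume_fraction=float(p.get("volume_fraction", 0.10)),
        host_eps=float(p.get("host_eps", 2.0)),
        grid=np.linspace(float(grid[0]), float(grid[1]), int(grid[2])),
    )
    modes = system.phonons()
    spec = static_spectrum(modes, system.crystal.volume, cfg)
    spec.write_csv(out / "static_spectrum.csv")
    spec.write_json(out / "static_spectrum.json")
    trv = decompose_modes(modes, system.crystal)
    pd.DataFrame(
        {
            "mode": np.arange(len(modes.frequencies)),
            "wavenumber_cm1": modes.frequencies,
            "imaginary": modes.imaginary,
            "trans_pct": trv[:, 0],
            "rot_pct": trv[:, 1],
            "internal_pct": trv[:, 2],
        }
    ).to_csv(out / "mode_table.csv", index=False)
    return ["static_spectrum.csv", "static_spectrum.json", "mode_table.csv"]


def _stage_md(config: RunConfig, out: Path, state: dict) -> list:
    system = _get_system(config, state)
    p = config.params.get("md_spectrum", {})
    result = simulate_harmonic_md(
        system,
        temperature=float(p.get("temperature", 300.0)),
        dt=float(p.get("dt_fs", 0.5)),
        n_steps=int(p.get("n_steps", 20000)),
        friction=float(p.get("friction", 0.02)),
        seed=config.seed,
    )
    df = pd.DataFrame(result.dipole.dipoles, columns=["Mx", "My", "Mz"])
    df.insert(0, "t_fs", result.dipole.times)
    df.to_csv(out / "dipole.csv", index=False)
    window = WindowSpec.preset(p.get("window", "thz")) if isinstance(
        p.get("window", "thz"), str
    ) else WindowSpec(**p["window"])
    spec = dynamic_spectrum(result.dipole, window=window,
                            max_lag=p.get("max_lag"))
    spec.write_csv(out / "md_spectrum.csv")
    spec.write_json(out / "md_spectrum.json")
    return ["dipole.csv", "md_spectrum.csv", "md_spectrum.json"]


def _stage_torsions(config: RunConfig, out: Path, state: dict) -> list:
    p = config.params.get("torsions", {})
    coeffs = two_well_coefficients(
        offset=float(p.get("offset_kjmol", 1.0)),
        barrier=float(p.get("barrier_kjmol", 6.3)),
    )
    times, series = simulate_torsion_langevin(
        coeffs,
        temperature=float(p.get("temperature", 300.0)),
        dt=float(p.get("dt_ps", 0.01)),
        n_steps=int(p.get("n_steps", 200000)),
        seed=config.seed,
    )
    traj = TorsionTrajectory.from_angles(times, series[:, None])
    dist = torsion_distribution(traj.wrapped, bin_width=float(p.get("bin_width", 5.0)))
    dist.to_csv(out / "torsion_distribution.csv", index=False)
    flips = detect_flips(traj, dwell=float(p.get("dwell_ps", 0.5)))
    pd.DataFrame(
        [
            {"torsion": f.torsion, "time_ps": f.time, "from": f.from_basin,
             "to": f.to_basin, "dwell_ps": f.dwell}
            for f in flips
        ],
        columns=["torsion", "time_ps", "from", "to", "dwell_ps"],
    ).to_csv(out / "flips.csv", index=False)
    motif_occupancy(traj, DEFAULT_BASINS).to_csv(out / "occupancy.csv", index=False)
    return ["torsion_distribution.csv", "flips.csv", "occupancy.csv"]


def _stage_thermo(config: RunConfig, out: Path, state: dict) -> list:
    p = config.params.get("thermo", {})
    grid = p.get("pressures", [0.0, 7.0, 36])
    pressures = np.linspace(float(grid[0]), float(grid[1]), int(grid[2]))
    records = []
    for rec in p.get(
        "polymorphs",
        [
            {"name": "alpha", "energy": 0.0, "volume": 520.0, "modes": [60, 120, 200]},
            {"name": "beta", "energy": 0.05, "volume": 470.0, "modes": [70, 130, 210]},
        ],
    ):
        records.append(
            PolymorphRecord(
                name=rec["name"],
                energy=float(rec["energy"]),
                volumes=np.asarray(rec["volume"], dtype=float),
                modes=np.asarray(rec.get("modes", []), dtype=float),
                n_molecules=int(rec.get("n_molecules", 1)),
            )
        )
    curve = relative_stability_curves(
        records,
        reference=p.get("reference", records[0].name),
        pressures=pressures,
        temperature=float(p.get("temperature", 300.0)),
        include_pv=bool(p.get("include_pv", True)),
        include_phonons=bool(p.get("include_phonons", True)),
    )
    df = pd.DataFrame({"pressure_GPa": curve.pressures})
    for name, dg in curve.delta_g.items():
        df[f"dG_{name}_kJmol"] = dg
    df.to_csv(out / "stability_curves.csv", index=False)
    pd.DataFrame(curve.crossovers, columns=["a", "b", "P_GPa"]).to_csv(
        out / "crossovers.csv", index=False
    )
    return ["stability_curves.csv", "crossovers.csv"]


_STAGES = {
    "synth": _stage_synth,
    "static_spectrum": _stage_static,
    "md_spectrum": _stage_md,
    "torsions": _stage_torsions,
    "thermo": _stage_thermo,
}
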