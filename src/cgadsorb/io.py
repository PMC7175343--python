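"""Reading and writing run artifacts.

Bead models go to TSV (index, label, x, y, z, radius, charge, mass) and
extended-XYZ for visualization; trajectories to extended-XYZ; run summaries
to JSON with every parameter, the seed and the physical-constants table
embedded, so a run is reproducible from its summary alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .conditions import SolutionConditions
from .constants import CONSTANTS_TABLE
from .geometry import SimulationCell, SurfaceLayout
from .mc import MoveSpec, RunSchedule, SampleSet
from .model import BeadModel

__all__ = [
    "bead_model_to_tsv", "bead_model_from_tsv", "write_xyz",
    "write_trajectory_xyz", "write_run_summary", "layout_to_tsv",
    "load_config", "RunConfig",
]


def layout_to_tsv(layout: "SurfaceLayout", path) -> None:
    """Nanoparticle centers, radii and charges as TSV."""
    centers, radii, charges = layout.np_arrays()
    pd.DataFrame({
        "x": centers[:, 0], "y": centers[:, 1], "z": centers[:, 2],
        "radius": radii, "charge": charges,
    }).to_csv(path, sep="\t", index=False, float_format="%.17g")


def bead_model_to_tsv(model: BeadModel, path) -> None:
    df = pd.DataFrame({
        "index": np.arange(model.n_beads),
        "label": model.labels,
        "x": model.positions[:, 0],
        "y": model.positions[:, 1],
        "z": model.positions[:, 2],
        "radius": model.radii,
        "charge": model.charges,
        "mass": model.masses,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def bead_model_from_tsv(path, rigid: bool = True) -> BeadModel:
    df = pd.read_csv(path, sep="\t")
    n = len(df)
    bonds = (np.empty((0, 2), dtype=np.intp) if rigid else
             np.column_stack([np.arange(n - 1), np.arange(1, n)]))
    return BeadModel(
        positions=df[["x", "y", "z"]].to_numpy(),
        radii=df["radius"].to_numpy(),
        charges=df["charge"].to_numpy(),
        masses=df["mass"].to_numpy(),
        labels=[str(x) for x in df["label"]],
        bonds=bonds,
        rigid=rigid,
    )


def _xyz_frame(labels, positions, comment: str = "") -> str:
    lines = [f"{len(labels)}", comment]
    for lb, p in zip(labels, positions):
        lines.append(f"{lb.replace(' ', '_'):<8s} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}")
    return "\n".join(lines) + "\n"


def write_xyz(model: BeadModel, path, comment: str = "bead model") -> None:
    Path(path).write_text(_xyz_frame(model.labels, model.positions, comment))


def write_trajectory_xyz(samples: SampleSet, labels, path) -> None:
    with open(path, "w") as fh:
        for k, (pos, e) in enumerate(zip(samples.positions, samples.energies)):
            fh.write(_xyz_frame(labels, pos, f"frame={k} energy_kBT={e:.8g}"))


def write_run_summary(samples: SampleSet, path, extra: dict | None = None) -> None:
    summary = {
        "provenance": samples.provenance,
        "constants": CONSTANTS_TABLE,
        "n_samples": samples.n_samples,
        "acceptance": samples.acceptance,
        "mean_energy_kBT": (
            float(samples.energies.mean()) if samples.n_samples else None
        ),
    }
    if extra:
        summary.update(extra)
    Path(path).write_text(json.dumps(summary, indent=2, default=float))


# ---------------------------------------------------------------------------
# run configuration

_CONFIG_KEYS = {
    "structure_file": str, "sequence": str, "model_kind": str,
    "exclude_chains": list, "assembly": str,
    "temperature_K": float, "rel_permittivity": float, "salt_molar_M": float,
    "surface_kind": str, "surface_charge_e_per_A2": float,
    "np_radius_A": float, "np_spacing_A": float, "np_coverage": float,
    "cell_lx_A": float, "cell_ly_A": float, "cell_lz_A": float,
    "equilibration_sweeps": int, "production_sweeps": int,
    "sample_interval": int, "seed": int,
    "adsorption_cutoff_A": float, "bin_width_A": float,
    "cosine_bin_width": float,
}


class RunConfig(dict):
    """Validated flat key-value run configuration (YAML on disk).

    Unit conventions are part of the key names (…_A for Å, …_M for mol/L,
    surface charge in e/Å^2).
    """

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError("config must be a mapping of keys to values")
        bad_keys = sorted(set(data) - set(_CONFIG_KEYS))
        bad_types = []
        for key, value in data.items():
            if key in _CONFIG_KEYS:
                want = _CONFIG_KEYS[key]
                if want in (float, int):
                    if not isinstance(value, (int, float)) or isinstance(value, bool):
                        bad_types.append(key)
                elif not isinstance(value, want):
                    bad_types.append(key)
        if bad_keys or bad_types:
            raise ValueError(
                "invalid config: "
                + (f"unknown keys {bad_keys}" if bad_keys else "")
                + (" " if bad_keys and bad_types else "")
                + (f"wrongly typed keys {sorted(bad_types)}" if bad_types else "")
            )
        kind = data.get("model_kind", "rigid")
        if kind not in ("rigid", "chain"):
            raise ValueError("model_kind must be 'rigid' or 'chain'")
        if kind == "chain" and not data.get("sequence") and not data.get("structure_file"):
            raise ValueError("chain runs need a 'sequence'")
        return cls(data)

    def conditions(self) -> SolutionConditions:
        return SolutionConditions(
            temperature=self.get("temperature_K", 298.15),
            rel_permittivity=self.get("rel_permittivity", 78.5),
            salt_molar=self.get("salt_molar_M", 0.025),
        )

    def cell(self) -> SimulationCell:
        return SimulationCell(
            self.get("cell_lx_A", 1500.0),
            self.get("cell_ly_A", 1500.0),
            self.get("cell_lz_A", 1500.0),
        )

    def schedule(self) -> RunSchedule:
        return RunSchedule(
            equilibration=self.get("equilibration_sweeps", 1000),
            production=self.get("production_sweeps", 10000),
            sample_interval=self.get("sample_interval", 10),
            seed=self.get("seed", 0),
        )


def load_config(path) -> RunConfig:
    return RunConfig.from_yaml(Path(path).read_text())
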