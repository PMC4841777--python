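"""Configuration, CSV/TIFF plumbing and run manifests.

File conventions: flat snake_case JSON configs; CSV with a header row,
UTF-8, '.' decimal; TIFF for images (multi-page stacks are reduced by
maximum projection downstream). Every run writes a ``manifest.json``
(config + seed + package version) alongside its outputs so results are
reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .if_quant import CellIFRecord, NucleusMeasurement
from .population_sim import CELL_COLUMNS, GrowthConfig
from .synthetic_data import SyntheticConfig
from .titration_model import DivisionOutcome, ModelParams

__all__ = [
    "model_params_to_dict",
    "model_params_from_dict",
    "growth_config_from_dict",
    "synthetic_config_from_dict",
    "load_run_config",
    "write_manifest",
    "write_cells_csv",
    "read_cells_csv",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_histogram_csv",
    "write_nucleus_csv",
    "read_nucleus_csv",
    "write_cell_if_csv",
    "read_cell_if_csv",
    "write_image",
    "read_image",
]

SUBCOMMANDS = ("gen-data", "simulate", "quantify", "fit", "report")


def _from_dict(cls, data: dict, name: str):
    """Instantiate a config dataclass, rejecting unknown keys by name."""
    if not isinstance(data, dict):
        raise ValueError(f"{name} block must be a JSON object")
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - fields)
    if unknown:
        raise ValueError(f"unknown keys in {name}: {', '.join(unknown)}")
    coerced = dict(data)
    for key in ("stage_list", "nucleus_radius_by_stage"):
        if coerced.get(key) is not None and cls is SyntheticConfig:
            coerced[key] = tuple(coerced[key])
    return cls(**coerced)


def model_params_to_dict(params: ModelParams) -> dict:
    """Flat JSON-ready dict with exactly the ModelParams field names."""
    return dataclasses.asdict(params)


def model_params_from_dict(data: dict) -> ModelParams:
    return _from_dict(ModelParams, data, "model_params")


def growth_config_from_dict(data: dict) -> GrowthConfig:
    return _from_dict(GrowthConfig, data, "growth_config")


def synthetic_config_from_dict(data: dict) -> SyntheticConfig:
    return _from_dict(SyntheticConfig, data, "synthetic_config")


_RUN_KEYS = {
    "subcommand",
    "seed",
    "out_dir",
    "inputs",
    "model_params",
    "growth_config",
    "synthetic_config",
    "genotype",
    "n_cells",
    "what",
}


def load_run_config(path) -> dict:
    """Parse and validate a run configuration JSON file.

    Returns a dict with validated config blocks materialized as dataclasses.
    Unknown keys anywhere raise a validation error listing them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = json.loads(path.read_text())
    unknown = sorted(set(raw) - _RUN_KEYS)
    if unknown:
        raise ValueError(f"unknown keys in run config: {', '.join(unknown)}")
    sub = raw.get("subcommand")
    if sub not in SUBCOMMANDS:
        raise ValueError(f"subcommand must be one of {SUBCOMMANDS}, got {sub!r}")
    cfg = dict(raw)
    cfg["seed"] = int(raw.get("seed", 0))
    cfg["model_params"] = model_params_from_dict(raw.get("model_params", {}))
    if "growth_config" in raw:
        cfg["growth_config"] = growth_config_from_dict(raw["growth_config"])
    if "synthetic_config" in raw:
        cfg["synthetic_config"] = synthetic_config_from_dict(raw["synthetic_config"])
    return cfg


def write_manifest(out_dir, config: dict, seed: int) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(type(o).__name__)

    path = out_dir / "manifest.json"
    path.write_text(
        json.dumps(
            {"config": config, "seed": seed, "version": __version__},
            indent=2,
            default=default,
        )
    )
    return path


# ---------------------------------------------------------------- CSV I/O


def write_cells_csv(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, index=False, columns=CELL_COLUMNS)


def read_cells_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cell CSV missing columns: {', '.join(missing)}")
    return df[CELL_COLUMNS]


_TRAJ_COLUMNS = ["round", "nuclei", "per_nucleus_amount", "concentration", "per_dna_ratio"]


def write_trajectory_csv(outcome: DivisionOutcome, path) -> None:
    outcome.to_frame().to_csv(path, index=False)


def read_trajectory_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {', '.join(missing)}")
    return df[_TRAJ_COLUMNS]


def write_histogram_csv(hist: pd.DataFrame, path) -> None:
    hist.to_csv(path, index=False, columns=["bin_left", "bin_right", "count"])


_NUCLEUS_COLUMNS = [
    "nucleus_id",
    "cell_id",
    "projected_area",
    "volume",
    "intensity_sum",
    "concentration",
]


def write_nucleus_csv(nuclei: list[NucleusMeasurement], path) -> None:
    pd.DataFrame([dataclasses.asdict(n) for n in nuclei], columns=_NUCLEUS_COLUMNS).to_csv(
        path, index=False
    )


def read_nucleus_csv(path) -> list[NucleusMeasurement]:
    df = pd.read_csv(path)
    return [NucleusMeasurement(**row) for row in df[_NUCLEUS_COLUMNS].to_dict("records")]


_CELL_IF_COLUMNS = [
    "cell_id",
    "stage",
    "total_intensity_in_cell",
    "nuclear_fraction",
    "per_dna_ratio",
    "mother_volume",
]


def write_cell_if_csv(cells: list[CellIFRecord], cells_path, nuclei_path=None) -> None:
    """Cell-level records to one CSV and (optionally) all nuclei to another."""
    pd.DataFrame(
        [
            {
                "cell_id": c.cell_id,
                "stage": c.stage,
                "total_intensity_in_cell": c.total_intensity_in_cell,
                "nuclear_fraction": c.nuclear_fraction,
                "per_dna_ratio": c.per_dna_ratio,
                "mother_volume": c.mother_volume,
            }
            for c in cells
        ],
        columns=_CELL_IF_COLUMNS,
    ).to_csv(cells_path, index=False)
    if nuclei_path is not None:
        write_nucleus_csv([n for c in cells for n in c.nuclei], nuclei_path)


def read_cell_if_csv(cells_path, nuclei_path=None) -> list[CellIFRecord]:
    df = pd.read_csv(cells_path)
    nuclei_by_cell: dict[str, list[NucleusMeasurement]] = {}
    if nuclei_path is not None:
        for n in read_nucleus_csv(nuclei_path):
            nuclei_by_cell.setdefault(n.cell_id, []).append(n)
    out = []
    for row in df.to_dict("records"):
        mv = row.get("mother_volume")
        out.append(
            CellIFRecord(
                cell_id=row["cell_id"],
                nuclei=nuclei_by_cell.get(row["cell_id"], []),
                stage=int(row["stage"]),
                total_intensity_in_cell=float(row["total_intensity_in_cell"]),
                nuclear_fraction=float(row["nuclear_fraction"]),
                per_dna_ratio=float(row["per_dna_ratio"]),
                mother_volume=None if mv is None or pd.isna(mv) else float(mv),
            )
        )
    return out


# --------------------------------------------------------------- TIFF I/O


def write_image(image: np.ndarray, path) -> None:
    arr = np.asarray(image)
    if arr.dtype == np.uint16:
        tifffile.imwrite(path, arr)
    else:
        tifffile.imwrite(path, arr.astype(np.float32))


def read_image(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    return tifffile.imread(path)
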