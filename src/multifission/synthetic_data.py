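"""Synthetic-data generators with the statistical structure of dividing cells.

Every generator is a pure function of (config, seed) and emits ground truth
next to the data, so each downstream module has a known-truth recovery
test. The generators emulate:

* daughter-size populations (lognormal, mean 75 µm³ for wild type);
* division-stage IF records for cells with 1/2/4/8/16 nuclei, where the
  total nuclear volume is constant across stages (per-nucleus volume
  halves as nuclei double) and the scheduled nuclear concentration declines
  geometrically by (1 - delta) per round (or linearly), so the per-DNA
  ratio falls by a factor (1 - delta)/2 per stage;
* two-channel (DAPI + tagged protein) images of multinucleate cells with a
  ground-truth label image;
* nuclear-marker geometry records (one representative nucleus diameter plus
  cell ellipsoid axes) at constant true N/C.

Noise is multiplicative lognormal for sizes and intensities and additive
Gaussian for pixels; real images additionally contain PSF blur, photo-
bleaching and z-attenuation, which these generators deliberately omit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .if_quant import CellIFRecord, NucleusMeasurement
from .population_sim import new_population

__all__ = [
    "SyntheticConfig",
    "gen_size_population",
    "gen_if_records",
    "render_cell_image",
    "gen_ble_gfp_geometry",
    "gen_division_observations",
]


def _lognormal(rng: np.random.Generator, cv: float, size=None):
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generators.

    Defaults encode the measured anchors: wild-type daughters 75 µm³ with
    SD 3 µm³ (CV 0.04); stages 1..16 nuclei with nuclear radius shrinking
    as s**(-1/3) so total nuclear volume stays constant; a geometric
    concentration schedule with 10% net degradation per round; N/C ratio
    0.1. intensity_noise_cv is the generic multiplicative measurement CV
    (also used for geometry records).
    """

    seed: int = 0
    n_cells: int = 500
    daughter_volume_mean: float = 75.0
    daughter_volume_cv: float = 0.04
    stage_list: tuple[int, ...] = (1, 2, 4, 8, 16)
    concentration_start: float = 50.0
    concentration_decrement_mode: str = "geometric"
    degradation_fraction: float = 0.1
    intensity_noise_cv: float = 0.1
    image_pixel_size: float = 0.1
    nucleus_radius_by_stage: tuple[float, ...] | None = None
    cytoplasm_signal_fraction: float = 0.0
    nc_ratio: float = 0.1

    def __post_init__(self) -> None:
        for name in ("daughter_volume_cv", "intensity_noise_cv"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if not (0.0 <= self.degradation_fraction < 1.0):
            raise ValueError("degradation_fraction must be in [0, 1)")
        if not (0.0 <= self.cytoplasm_signal_fraction < 1.0):
            raise ValueError("cytoplasm_signal_fraction must be in [0, 1)")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.image_pixel_size <= 0:
            raise ValueError("image_pixel_size must be > 0")
        if self.concentration_decrement_mode not in ("geometric", "linear"):
            raise ValueError("concentration_decrement_mode must be geometric|linear")
        if self.nc_ratio <= 0:
            raise ValueError("nc_ratio must be > 0")
        stages = self.stage_list
        if any(s < 1 or (s & (s - 1)) for s in stages) or list(stages) != sorted(
            set(stages)
        ):
            raise ValueError("stage_list must be strictly increasing powers of 2")
        if self.nucleus_radius_by_stage is None:
            base = 2.5  # µm, stage-1 nucleus
            object.__setattr__(
                self,
                "nucleus_radius_by_stage",
                tuple(base * s ** (-1.0 / 3.0) for s in stages),
            )
        radii = self.nucleus_radius_by_stage
        if len(radii) != len(stages):
            raise ValueError("nucleus_radius_by_stage must match stage_list")
        totals = [s * (4.0 / 3.0) * math.pi * r**3 for s, r in zip(stages, radii)]
        if any(abs(t - totals[0]) > 1e-9 * totals[0] for t in totals):
            raise ValueError(
                "nucleus_radius_by_stage must keep total nuclear volume constant"
            )

    @property
    def total_nuclear_volume(self) -> float:
        s0, r0 = self.stage_list[0], self.nucleus_radius_by_stage[0]
        return s0 * (4.0 / 3.0) * math.pi * r0**3

    def stage_concentration_schedule(self) -> np.ndarray:
        """Scheduled mean nuclear concentration per stage (AU/µm³)."""
        k = np.arange(len(self.stage_list), dtype=float)
        c0 = self.concentration_start
        if self.concentration_decrement_mode == "geometric":
            return c0 * (1.0 - self.degradation_fraction) ** k
        return np.clip(c0 - self.degradation_fraction * c0 * k, 0.0, None)


def gen_size_population(cfg: SyntheticConfig) -> pd.DataFrame:
    """Lognormal daughter-volume population with the configured mean and CV."""
    rng = np.random.default_rng(cfg.seed)
    volumes = cfg.daughter_volume_mean * _lognormal(
        rng, cfg.daughter_volume_cv, cfg.n_cells
    )
    return new_population(volumes, population="custom", genotype="wild_type")


def gen_if_records(
    cfg: SyntheticConfig, cells_per_stage: int | None = None
) -> tuple[list[CellIFRecord], dict]:
    """Division-stage IF records plus their generating ground truth.

    For each stage s the cell carries s nuclei of volume V_total/s; each
    nucleus draws its concentration around the stage's scheduled mean with
    multiplicative noise, and intensity_sum = concentration * volume. The
    per-DNA ratio therefore emerges as concentration * V_total / s. Mother
    volume is set to V_total / nc_ratio, a size predicting >= 3 divisions
    under the default model.
    """
    if cells_per_stage is None:
        cells_per_stage = max(1, cfg.n_cells // len(cfg.stage_list))
    rng = np.random.default_rng(cfg.seed)
    schedule = cfg.stage_concentration_schedule()
    v_total = cfg.total_nuclear_volume
    mother_volume = v_total / cfg.nc_ratio
    cyt = cfg.cytoplasm_signal_fraction
    records: list[CellIFRecord] = []
    for k, stage in enumerate(cfg.stage_list):
        v_nuc = v_total / stage
        for i in range(cells_per_stage):
            cid = f"s{stage}_c{i:04d}"
            conc = schedule[k] * _lognormal(rng, cfg.intensity_noise_cv, stage)
            nuclei = [
                NucleusMeasurement(
                    nucleus_id=j + 1,
                    cell_id=cid,
                    projected_area=math.pi
                    * (cfg.nucleus_radius_by_stage[k]) ** 2,
                    volume=v_nuc,
                    intensity_sum=float(conc[j] * v_nuc),
                    concentration=float(conc[j]),
                )
                for j in range(stage)
            ]
            nuclear = sum(n.intensity_sum for n in nuclei)
            total = nuclear / (1.0 - cyt)
            records.append(
                CellIFRecord(
                    cell_id=cid,
                    nuclei=nuclei,
                    stage=stage,
                    total_intensity_in_cell=total,
                    nuclear_fraction=(nuclear / total) if total > 0 else 0.0,
                    per_dna_ratio=nuclear / stage,
                    mother_volume=mother_volume,
                )
            )
    truth = {
        "stage_list": list(cfg.stage_list),
        "concentration_means": schedule.tolist(),
        "per_dna_means": (schedule * v_total / np.asarray(cfg.stage_list)).tolist(),
        "total_nuclear_volume": v_total,
        "mother_volume": mother_volume,
    }
    return records, truth


def gen_division_observations(
    params,
    n_cells: int = 500,
    volume_range: tuple[float, float] = (200.0, 1000.0),
    noise_cv: float = 0.1,
    seed: int = 0,
) -> dict:
    """Observed division counts plus noisy concentration trajectories for a
    cohort of mothers, as inputs for parameter recovery.

    Mother volumes are log-uniform over ``volume_range`` and observed
    directly (electronic volume sensing is far more precise than
    fluorescence intensities); division counts come from the titration
    model; each round's nuclear concentration is measured with
    multiplicative lognormal noise of the given CV. Returns a dict with

    * ``observed``: DataFrame (mother_volume, n_rounds);
    * ``stage_concentration_means``: per-stage geometric means of per-cell
      concentrations normalized to each cell's first round (unbiased for
      ``(1-delta)**k`` in log space, and free of the cohort-composition
      shift caused by larger mothers reaching later stages);
    * ``volume_concentration``: per-cell (mother_volume, first-round
      concentration) pairs.
    """
    from .titration_model import make_mother, run_division_series

    rng = np.random.default_rng(seed)
    lo, hi = volume_range
    volumes = np.exp(rng.uniform(math.log(lo), math.log(hi), n_cells))
    n_rounds = np.empty(n_cells, dtype=int)
    first_conc = np.empty(n_cells)
    log_ratios: dict[int, list[float]] = {}
    for i, vol in enumerate(volumes):
        outcome = run_division_series(make_mother(vol, params), params)
        n_rounds[i] = outcome.n_rounds
        meas = [
            t.concentration * _lognormal(rng, noise_cv) for t in outcome.trajectory
        ]
        first_conc[i] = meas[0]
        for k, c in enumerate(meas):
            log_ratios.setdefault(k, []).append(math.log(c / meas[0]))
    stage_gm = np.array(
        [math.exp(np.mean(log_ratios[k])) for k in sorted(log_ratios)]
    )
    return {
        "observed": pd.DataFrame(
            {"mother_volume": volumes, "n_rounds": n_rounds}
        ),
        "stage_concentration_means": stage_gm,
        "volume_concentration": np.column_stack([volumes, first_conc]),
    }


def _disk(shape: tuple[int, int], center: tuple[float, float], radius: float):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def render_cell_image(
    cell: CellIFRecord,
    cfg: SyntheticConfig,
    background: float = 0.0,
    pixel_noise_cv: float = 0.0,
    rng: np.random.Generator | None = None,
    dapi_level: float = 100.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one cell as (DAPI, HA, ground-truth label) images.

    Nuclei are filled disks of the stage radius placed on a jittered grid
    (non-overlapping by construction). DAPI is constant inside nuclei; the
    HA channel puts exactly the record's intensity_sum inside each disk,
    spreads the cytoplasmic remainder uniformly over the cell mask, and
    adds the scalar background. Optional Gaussian pixel noise has SD
    ``pixel_noise_cv`` times the local signal. The label image is uint16.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    stage = cell.stage
    if stage < 1:
        raise ValueError("cell has no nuclei to render")
    k = cfg.stage_list.index(stage)
    r_px = cfg.nucleus_radius_by_stage[k] / cfg.image_pixel_size
    ncols = int(np.ceil(np.sqrt(stage)))
    nrows = int(np.ceil(stage / ncols))
    pitch = 2 * r_px + 6  # >= 2 px clearance after +-1 px jitter
    margin = r_px + 4
    h = int(np.ceil(2 * margin + nrows * pitch))
    w = int(np.ceil(2 * margin + ncols * pitch))
    shape = (h, w)

    dapi = np.zeros(shape)
    ha = np.zeros(shape)
    labels = np.zeros(shape, dtype=np.uint16)
    for j, nuc in enumerate(cell.nuclei):
        row, col = divmod(j, ncols)
        cy = margin + (row + 0.5) * pitch + rng.uniform(-1, 1)
        cx = margin + (col + 0.5) * pitch + rng.uniform(-1, 1)
        disk = _disk(shape, (cy, cx), r_px)
        if np.any(labels[disk]):
            raise RuntimeError("nucleus placement overlap; frame too small")
        npix = int(disk.sum())
        dapi[disk] = dapi_level
        ha[disk] += nuc.intensity_sum / npix
        labels[disk] = j + 1
    cyto_total = cell.total_intensity_in_cell - cell.nuclear_intensity
    cell_mask = _disk(shape, ((h - 1) / 2.0, (w - 1) / 2.0), min(h, w) / 2.0 - 1)
    cell_mask |= labels > 0
    if cyto_total > 0:
        cyto_pixels = cell_mask & (labels == 0)
        ha[cyto_pixels] += cyto_total / int(cyto_pixels.sum())
    ha += background
    if pixel_noise_cv > 0:
        ha = ha + rng.normal(0.0, pixel_noise_cv * np.abs(ha))
        ha = np.clip(ha, 0.0, None)
    return dapi, ha, labels


def gen_ble_gfp_geometry(
    cfg: SyntheticConfig,
    cells_per_group: int = 24,
    n_last_group: int = 11,
) -> pd.DataFrame:
    """Per-cell nuclear-marker geometry records at constant true N/C.

    Each row gives a cell's stage (nuclei count), the measured diameter of
    one representative nucleus (µm) and the cell's ellipsoid axes (µm).
    True N/C is cfg.nc_ratio for every cell; measurement noise
    (cfg.intensity_noise_cv, multiplicative) applies independently to the
    diameter and to the cell volume, identically across stages, so N/C
    differences between stage groups are null by construction. Group sizes
    default to 24 cells, 11 for the last (16-nucleus) group.
    """
    rng = np.random.default_rng(cfg.seed)
    aspect = 1.25  # major/minor axis ratio of the cell ellipsoid
    rows = []
    for k, stage in enumerate(cfg.stage_list):
        r = cfg.nucleus_radius_by_stage[k]
        d_true = 2.0 * r
        v_nuc_true = math.pi * d_true**3 / 6.0
        c_true = stage * v_nuc_true / cfg.nc_ratio
        n = n_last_group if k == len(cfg.stage_list) - 1 else cells_per_group
        for i in range(n):
            d_obs = d_true * _lognormal(rng, cfg.intensity_noise_cv)
            c_obs = c_true * _lognormal(rng, cfg.intensity_noise_cv)
            minor = (6.0 * c_obs / (math.pi * aspect)) ** (1.0 / 3.0)
            rows.append(
                {
                    "cell_id": f"g{stage}_c{i:03d}",
                    "stage": stage,
                    "nucleus_diameter_um": float(d_obs),
                    "major_axis_um": float(aspect * minor),
                    "minor_axis_um": float(minor),
                }
            )
    return pd.DataFrame(rows)
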