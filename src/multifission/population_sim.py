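"""Diurnal population simulation around the titration model.

Daughters grow exponentially in volume during the light period (with
lognormal cell-to-cell noise), pass commitment when they reach the
commitment size, and divide during the dark period according to the
titration model. The module also reproduces the dark-shift experiment
design: splitting one synchronized culture into a pre-commitment control
(population I), small mothers (II) and large mothers (III), then comparing
division-number histograms and total regulator content normalized either
per biomass (equal-protein-load analog) or per cell (equal-cell-number
analog).

Populations are plain pandas DataFrames with the CellRecord columns
``cell_id, volume_um3, committed, division_count, population, genotype``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .titration_model import (
    GENOTYPES,
    ModelParams,
    cdkg1_production,
    make_mother,
    run_division_series,
    scenario_params,
)

__all__ = [
    "CELL_COLUMNS",
    "CellRecord",
    "GrowthConfig",
    "new_population",
    "grow_population",
    "run_divisions",
    "division_histogram",
    "size_distribution",
    "default_dark_shift_configs",
    "dark_shift_experiment",
]

CELL_COLUMNS = [
    "cell_id",
    "volume_um3",
    "committed",
    "division_count",
    "population",
    "genotype",
]


@dataclass(frozen=True)
class CellRecord:
    """One cell: volume (µm³), commitment status, divisions completed,
    population label (I/II/III/custom) and genotype label."""

    cell_id: str
    volume: float
    committed: bool = False
    division_count: int = 0
    population_label: str = "custom"
    genotype: str = "wild_type"

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("volume must be positive")
        if self.division_count < 0:
            raise ValueError("division_count must be >= 0")


@dataclass(frozen=True)
class GrowthConfig:
    """Growth during the light period.

    Volume multiplies by ``2**(t / size_doubling_time)`` with
    ``t = min(light_hours, dark_shift_hour)`` — growth stops at a dark
    shift and newborn daughters do not grow in the dark. If
    ``target_median_volume`` is set, the deterministic fold is instead chosen
    so the population median lands on the target (used for the packaged
    dark-shift populations). Cell-to-cell noise is multiplicative lognormal
    with the given CV.
    """

    light_hours: float = 14.0
    size_doubling_time: float = 4.0
    growth_noise_cv: float = 0.15
    dark_shift_hour: float | None = None
    seed: int = 0
    target_median_volume: float | None = None

    def __post_init__(self) -> None:
        if self.light_hours < 0:
            raise ValueError("light_hours must be >= 0")
        if self.size_doubling_time <= 0:
            raise ValueError("size_doubling_time must be > 0")
        if not (0.0 <= self.growth_noise_cv < 1.0):
            raise ValueError("growth_noise_cv must be in [0, 1)")
        if self.dark_shift_hour is not None and self.dark_shift_hour < 0:
            raise ValueError("dark_shift_hour must be >= 0")


def new_population(
    volumes,
    population: str = "custom",
    genotype: str = "wild_type",
    prefix: str = "c",
) -> pd.DataFrame:
    """Fresh daughter population from an array of volumes (µm³)."""
    v = np.asarray(volumes, dtype=float)
    if np.any(v <= 0):
        raise ValueError("all volumes must be positive")
    return pd.DataFrame(
        {
            "cell_id": [f"{prefix}{i:05d}" for i in range(len(v))],
            "volume_um3": v,
            "committed": False,
            "division_count": 0,
            "population": population,
            "genotype": genotype,
        }
    )


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative lognormal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size))


def grow_population(
    cells: pd.DataFrame,
    cfg: GrowthConfig,
    commitment_size: float = 195.0,
) -> pd.DataFrame:
    """Grow daughter cells through the light period and set commitment flags.

    Returns a new DataFrame; the input is not modified.
    """
    out = cells.copy()
    t = cfg.light_hours
    if cfg.dark_shift_hour is not None:
        t = min(t, cfg.dark_shift_hour)
    if cfg.target_median_volume is not None:
        fold = cfg.target_median_volume / float(np.median(out["volume_um3"]))
    else:
        fold = 2.0 ** (t / cfg.size_doubling_time)
    rng = np.random.default_rng(cfg.seed)
    noise = _lognormal_factor(rng, cfg.growth_noise_cv, len(out))
    out["volume_um3"] = out["volume_um3"].to_numpy() * fold * noise
    out["committed"] = out["volume_um3"] >= commitment_size
    return out


def run_divisions(
    mothers: pd.DataFrame,
    params: ModelParams,
    genotype: str = "wild_type",
    seed: int = 0,
    threshold_noise_cv: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Divide every committed mother according to the titration model.

    Returns ``(mothers, daughters)``: the mothers with their
    ``division_count`` filled in, and the pooled daughter population (each
    mother of volume M yields 2**n daughters of volume M/2**n, conserving
    volume exactly). ``threshold_noise_cv`` adds per-cell lognormal noise to
    the exit threshold, modelling cell-to-cell sloppiness of the sizer.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
    p = scenario_params(genotype, params)
    fallback = genotype == "cdkg1_null"
    rng = np.random.default_rng(seed)
    noise = _lognormal_factor(rng, threshold_noise_cv, len(mothers))

    out = mothers.copy()
    out["genotype"] = genotype
    counts = np.zeros(len(out), dtype=int)
    daughter_volumes: list[np.ndarray] = []
    for i, (vol, committed) in enumerate(
        zip(out["volume_um3"].to_numpy(), out["committed"].to_numpy())
    ):
        p_i = (
            replace(p, exit_threshold=p.exit_threshold * noise[i])
            if threshold_noise_cv > 0
            else p
        )
        mother = make_mother(vol, p_i, committed=bool(committed))
        outcome = run_division_series(mother, p_i, fallback_for_null=fallback)
        counts[i] = outcome.n_rounds
        daughter_volumes.append(
            np.full(outcome.n_daughters, outcome.daughter_volume)
        )
    out["division_count"] = counts
    daughters = new_population(
        np.concatenate(daughter_volumes) if daughter_volumes else np.empty(0),
        population=str(out["population"].iloc[0]) if len(out) else "custom",
        genotype=genotype,
        prefix="d",
    )
    return out, daughters


def division_histogram(cells: pd.DataFrame | np.ndarray) -> dict[str, float]:
    """Fractions of cells with 0, 1, 2 and 3+ completed divisions."""
    if isinstance(cells, pd.DataFrame):
        counts = cells["division_count"].to_numpy()
    else:
        counts = np.asarray(cells)
    if len(counts) == 0:
        raise ValueError("empty population")
    n = len(counts)
    return {
        "0": float(np.sum(counts == 0)) / n,
        "1": float(np.sum(counts == 1)) / n,
        "2": float(np.sum(counts == 2)) / n,
        "3+": float(np.sum(counts >= 3)) / n,
    }


def size_distribution(
    cells: pd.DataFrame | np.ndarray, bin_edges
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Coulter-counter style volume histogram plus summary statistics.

    Returns (histogram DataFrame with bin_left/bin_right/count, summary dict
    with median, mean and SD).
    """
    if isinstance(cells, pd.DataFrame):
        v = cells["volume_um3"].to_numpy(dtype=float)
    else:
        v = np.asarray(cells, dtype=float)
    if len(v) == 0:
        raise ValueError("empty population")
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing")
    counts, _ = np.histogram(v, bins=edges)
    hist = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
    summary = {
        "median": float(np.median(v)),
        "mean": float(np.mean(v)),
        "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
        "n": int(len(v)),
    }
    return hist, summary


def default_dark_shift_configs(seed: int = 0) -> dict[str, GrowthConfig]:
    """Packaged defaults for the dark-shift experiment.

    Population I is dark-shifted pre-commitment at 3 h (median ~80 µm³),
    population II at 7 h (small mothers, ~350 µm³), population III stays in
    the light for the full 14 h (large mothers, ~600 µm³). The three configs
    share one seed-split scheme.
    """
    return {
        "I": GrowthConfig(
            light_hours=14.0,
            dark_shift_hour=3.0,
            target_median_volume=80.0,
            growth_noise_cv=0.15,
            seed=seed * 3 + 1,
        ),
        "II": GrowthConfig(
            light_hours=14.0,
            dark_shift_hour=7.0,
            target_median_volume=350.0,
            growth_noise_cv=0.15,
            seed=seed * 3 + 2,
        ),
        "III": GrowthConfig(
            light_hours=14.0,
            dark_shift_hour=None,
            target_median_volume=600.0,
            growth_noise_cv=0.15,
            seed=seed * 3 + 3,
        ),
    }


def dark_shift_experiment(
    base_daughters: pd.DataFrame,
    configs: dict[str, GrowthConfig],
    params: ModelParams,
    genotype: str = "wild_type",
    threshold_noise_cv: float = 0.0,
) -> dict[str, dict]:
    """Split one daughter culture, grow each split per its config, divide,
    and summarize.

    For each population the result carries the grown mothers (with division
    counts), the daughters, the division-number histogram, and total
    regulator content normalized per biomass (sum of amounts / sum of mother
    volumes) and per cell — the two gel-loading modes. With an allometric
    exponent b > 1 the per-biomass value is higher in large than in small
    mothers.
    """
    results: dict[str, dict] = {}
    genotype_params = scenario_params(genotype, params)
    for label, cfg in configs.items():
        cells = base_daughters.copy()
        cells["population"] = label
        mothers = grow_population(cells, cfg, commitment_size=params.commitment_size)
        mothers, daughters = run_divisions(
            mothers,
            params,
            genotype=genotype,
            seed=cfg.seed,
            threshold_noise_cv=threshold_noise_cv,
        )
        amounts = np.array(
            [cdkg1_production(v, genotype_params) for v in mothers["volume_um3"]]
        )
        results[label] = {
            "mothers": mothers,
            "daughters": daughters,
            "histogram": division_histogram(mothers),
            "cdkg1_per_biomass": float(amounts.sum() / mothers["volume_um3"].sum()),
            "cdkg1_per_cell": float(amounts.sum() / len(mothers)),
        }
    return results
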