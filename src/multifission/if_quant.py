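"""Quantitative immunofluorescence pipeline for dividing cells.

Nuclei are segmented from the DAPI channel by a global Otsu threshold and
8-connected component labeling; per-nucleus regulator signal is the
background-subtracted sum of the tagged-protein channel over the DAPI
region. Nuclear volume comes from the projected area (sphere
approximation, see :mod:`multifission.geometry`), nuclear concentration is
signal/volume, and the per-DNA ratio of a multinucleate cell is the summed
nuclear signal divided by the nuclei count (one genome copy per nucleus).
Cells are grouped by division stage (1, 2, 4, 8, 16 nuclei) and compared
with rank-based tests; N/C ratio groups are compared by one-way ANOVA.

Coordinates are 0-based row-major pixel indices; areas are pixel counts
times pixel_size**2; no sub-pixel interpolation is attempted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label

from .geometry import nuclear_volume_from_area
from .titration_model import ModelParams, predict_n_rounds

logger = logging.getLogger(__name__)

__all__ = [
    "NucleusMeasurement",
    "CellIFRecord",
    "max_project",
    "segment_nuclei",
    "measure_nuclei",
    "quantify_cell",
    "stage_summaries",
    "per_dna_series",
    "linear_fit_means",
    "compare_stages",
    "nc_anova",
    "nuclear_fraction_score",
]

#: Largest exact-enumeration size for the rank-sum test; above this the
#: tie-corrected normal approximation is used.
_EXACT_ENUMERATION_LIMIT = 20_000


@dataclass(frozen=True)
class NucleusMeasurement:
    """One nucleus: projected area (µm²), volume (µm³), summed
    background-subtracted intensity (AU) and concentration (AU/µm³)."""

    nucleus_id: int
    cell_id: str
    projected_area: float
    volume: float
    intensity_sum: float
    concentration: float


@dataclass
class CellIFRecord:
    """One (possibly multinucleate) cell's IF measurements.

    stage equals the nuclei count; per_dna_ratio is the summed nuclear
    intensity divided by stage; nuclear_fraction is nuclear / total signal
    in the cell. mother_volume (µm³), when known, supports the
    size-predicted-divisions inclusion filter.
    """

    cell_id: str
    nuclei: list[NucleusMeasurement] = field(default_factory=list)
    stage: int = 0
    total_intensity_in_cell: float = 0.0
    nuclear_fraction: float = 0.0
    per_dna_ratio: float = 0.0
    mother_volume: float | None = None

    @property
    def nuclear_intensity(self) -> float:
        return sum(n.intensity_sum for n in self.nuclei)


def max_project(stack: np.ndarray) -> np.ndarray:
    """Maximum projection of a z-stack (pages-first 3-D array); 2-D images
    pass through unchanged."""
    arr = np.asarray(stack)
    if arr.ndim == 2:
        return arr
    if arr.ndim != 3:
        raise ValueError("stack must be 2-D or 3-D")
    return arr.max(axis=0)


def segment_nuclei(
    dapi_image: np.ndarray,
    pixel_size: float,
    min_area: float = 1.0,
) -> tuple[np.ndarray, dict[int, float]]:
    """Segment nuclei from a DAPI image.

    Global Otsu threshold, 8-connected labeling, components below
    ``min_area`` (µm²) discarded. Returns the label image (0 = background)
    and a mapping label -> area in µm². An all-zero image yields no nuclei;
    a constant non-zero (saturated) image raises, since no threshold exists.
    """
    img = np.asarray(dapi_image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if img.max() == img.min():
        if img.max() == 0:
            return np.zeros(img.shape, dtype=np.int32), {}
        raise ValueError("constant (saturated) image: Otsu threshold undefined")
    thresh = threshold_otsu(img)
    mask = img > thresh
    labels = sk_label(mask, connectivity=2).astype(np.int32)
    areas: dict[int, float] = {}
    for lab in range(1, labels.max() + 1):
        area = float(np.sum(labels == lab)) * pixel_size**2
        if area < min_area:
            labels[labels == lab] = 0
        else:
            areas[lab] = area
    # relabel compactly so labels are 1..k after the min-area filter
    if len(areas) != labels.max():
        old = sorted(areas)
        remap = np.zeros(labels.max() + 1, dtype=np.int32)
        new_areas: dict[int, float] = {}
        for new, lab in enumerate(old, start=1):
            remap[lab] = new
            new_areas[new] = areas[lab]
        labels = remap[labels]
        areas = new_areas
    return labels, areas


def measure_nuclei(
    ha_image: np.ndarray,
    labels: np.ndarray,
    background: float,
    pixel_size: float,
    cell_id: str = "cell0",
    corrected: bool = False,
) -> list[NucleusMeasurement]:
    """Per-nucleus background-subtracted intensity sums and concentrations.

    For each label, ``intensity_sum = sum(max(HA - background, 0))`` over
    member pixels; volume from the projected area; concentration =
    intensity_sum / volume.
    """
    ha = np.asarray(ha_image, dtype=float)
    lab = np.asarray(labels)
    if ha.shape != lab.shape:
        raise ValueError("HA image and label image shapes differ")
    signal = np.clip(ha - background, 0.0, None)
    out: list[NucleusMeasurement] = []
    for k in range(1, int(lab.max()) + 1):
        member = lab == k
        npix = int(member.sum())
        if npix == 0:
            continue
        area = npix * pixel_size**2
        volume = nuclear_volume_from_area(area, corrected=corrected)
        total = float(signal[member].sum())
        out.append(
            NucleusMeasurement(
                nucleus_id=k,
                cell_id=cell_id,
                projected_area=area,
                volume=volume,
                intensity_sum=total,
                concentration=total / volume if volume > 0 else float("nan"),
            )
        )
    return out


def quantify_cell(
    dapi_image: np.ndarray,
    ha_image: np.ndarray,
    pixel_size: float,
    background: float = 0.0,
    min_area: float = 1.0,
    cell_mask: np.ndarray | None = None,
    cell_id: str = "cell0",
    mother_volume: float | None = None,
    corrected: bool = False,
) -> CellIFRecord:
    """Full single-cell pipeline: segment, measure, aggregate.

    ``cell_mask`` restricts the total-signal denominator to the cell;
    without it the whole frame counts as the cell.
    """
    dapi = max_project(np.asarray(dapi_image))
    ha = max_project(np.asarray(ha_image))
    labels, _ = segment_nuclei(dapi, pixel_size, min_area=min_area)
    nuclei = measure_nuclei(
        ha, labels, background, pixel_size, cell_id=cell_id, corrected=corrected
    )
    signal = np.clip(ha - background, 0.0, None)
    if cell_mask is not None:
        total = float(signal[np.asarray(cell_mask, dtype=bool)].sum())
    else:
        total = float(signal.sum())
    nuclear = sum(n.intensity_sum for n in nuclei)
    stage = len(nuclei)
    return CellIFRecord(
        cell_id=cell_id,
        nuclei=nuclei,
        stage=stage,
        total_intensity_in_cell=total,
        nuclear_fraction=(nuclear / total) if total > 0 else 0.0,
        per_dna_ratio=(nuclear / stage) if stage > 0 else 0.0,
        mother_volume=mother_volume,
    )


def _stage_filter(
    cells: list[CellIFRecord],
    params: ModelParams | None,
    min_predicted_rounds: int,
) -> list[CellIFRecord]:
    if params is None:
        return list(cells)
    kept = []
    for c in cells:
        if c.mother_volume is None:
            continue
        if predict_n_rounds(c.mother_volume, params) >= min_predicted_rounds:
            kept.append(c)
    return kept


def stage_summaries(
    cells: list[CellIFRecord],
    min_cells_per_stage: int = 68,
    params: ModelParams | None = None,
    min_predicted_rounds: int = 3,
) -> pd.DataFrame:
    """Per-stage mean/SD/n of per-nucleus concentration.

    When model parameters are supplied, only cells whose mother size
    predicts at least ``min_predicted_rounds`` divisions are included, so
    stages are comparable within one size class. Stages with fewer than
    ``min_cells_per_stage`` cells are kept but flagged; if no stage meets
    the minimum an error is raised.
    """
    kept = _stage_filter(cells, params, min_predicted_rounds)
    by_stage: dict[int, list[float]] = {}
    n_cells: dict[int, int] = {}
    for c in kept:
        vals = [n.concentration for n in c.nuclei]
        by_stage.setdefault(c.stage, []).extend(vals)
        n_cells[c.stage] = n_cells.get(c.stage, 0) + 1
    if not by_stage:
        raise ValueError("no cells left after filtering")
    rows = []
    for stage in sorted(by_stage):
        vals = np.asarray(by_stage[stage], dtype=float)
        rows.append(
            {
                "stage": stage,
                "mean_concentration": float(vals.mean()),
                "sd_concentration": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "n_cells": n_cells[stage],
                "n_nuclei": len(vals),
                "flagged": n_cells[stage] < min_cells_per_stage,
            }
        )
    df = pd.DataFrame(rows)
    if df["flagged"].all():
        raise ValueError(
            f"no stage reaches min_cells_per_stage={min_cells_per_stage}"
        )
    return df


def per_dna_series(cells: list[CellIFRecord]) -> pd.DataFrame:
    """Per-stage mean per-DNA ratio normalized so the first stage is 1 AU."""
    by_stage: dict[int, list[float]] = {}
    for c in cells:
        by_stage.setdefault(c.stage, []).append(c.per_dna_ratio)
    if len(by_stage) < 2:
        raise ValueError("need at least two stages")
    stages = sorted(by_stage)
    means = np.array([np.mean(by_stage[s]) for s in stages])
    if means[0] == 0:
        raise ValueError("first-stage mean per-DNA ratio is zero; cannot normalize")
    return pd.DataFrame(
        {
            "stage": stages,
            "mean_per_dna": means,
            "normalized": means / means[0],
        }
    )


def linear_fit_means(stage_means) -> tuple[float, float, float]:
    """OLS of stage-mean concentration against stage index (1..k).

    Returns (slope, intercept, R²) with R² = 1 - SSres/SStot.
    """
    y = np.asarray(stage_means, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 stage means")
    x = np.arange(1, len(y) + 1, dtype=float)
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def compare_stages(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum comparison of two stage groups.

    Small samples are tested exactly (full enumeration; with ties an exact
    permutation test), larger samples with the tie-corrected normal
    approximation. Returns (U statistic of the first group, p-value);
    identical groups give p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if np.array_equal(np.sort(a), np.sort(b)):
        # fully exchangeable: no assignment is more extreme than observed
        return float(len(a) * len(b) / 2.0), 1.0
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    n_assignments = math.comb(len(a) + len(b), len(a))
    if n_assignments <= _EXACT_ENUMERATION_LIMIT:
        if has_ties:
            method = stats.PermutationMethod(n_resamples=n_assignments + 1)
        else:
            method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def nc_anova(groups) -> tuple[float, float]:
    """One-way ANOVA of per-stage N/C values: returns (F, p).

    Degenerate inputs with zero within-group variance give F = 0, p = 1
    when all means are equal (nothing to detect) and F = inf, p = 0 when
    they differ.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for g in arrays:
        if len(g) < 2:
            raise ValueError("each group needs n >= 2")
    if all(np.ptp(g) == 0 for g in arrays):
        means = [g[0] for g in arrays]
        if np.ptp(means) == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def nuclear_fraction_score(cells: list[CellIFRecord]) -> pd.DataFrame:
    """Per stage, the fraction of cells with strictly more than half of
    their signal inside nuclei.

    Cells with zero total signal cannot be scored and are excluded (the
    count is logged and reported).
    """
    by_stage: dict[int, list[bool]] = {}
    excluded = 0
    for c in cells:
        if c.total_intensity_in_cell <= 0:
            excluded += 1
            continue
        by_stage.setdefault(c.stage, []).append(c.nuclear_fraction > 0.5)
    if excluded:
        logger.info("nuclear_fraction_score: excluded %d zero-signal cells", excluded)
    if not by_stage:
        raise ValueError("no scorable cells")
    rows = [
        {
            "stage": s,
            "fraction_majority_nuclear": float(np.mean(flags)),
            "n_cells": len(flags),
        }
        for s, flags in sorted(by_stage.items())
    ]
    df = pd.DataFrame(rows)
    df.attrs["n_excluded"] = excluded
    return df
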