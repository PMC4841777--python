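"""Titration model of mitotic division counting in multiple fission.

A mother cell accumulates a fixed stock of the nuclear sizer kinase CDKG1
before entering the S/M phase; the amount produced scales allometrically
with mother volume, ``amount = a * M**b`` with b > 1 so that larger mothers
carry a higher *concentration* as well as a higher total. During S/M the
stock is not replenished: each round of division doubles the number of
nuclei (and genome copies) while the total is reduced by net degradation.
The per-genome ratio therefore drops by a factor ``2/(1-delta)`` (>= 2) per
round, while nuclear concentration falls only shallowly, by ``(1-delta)``.
Division continues while the sensed quantity is at or above an exit
threshold; committed mothers always divide at least once. The result is a
sizer: the number of rounds n grows with mother volume, and 2**n
uniform-sized daughters of volume M/2**n are produced.

A discrete "unit accounting" variant treats the stock as integer units, one
consumed per mitosis: round k costs 2**(k-1) units, so U units buy the
largest n with 2**n - 1 <= U.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SENSED_QUANTITIES",
    "DECREMENT_MODES",
    "GENOTYPES",
    "ModelParams",
    "MotherState",
    "TrajectoryPoint",
    "DivisionOutcome",
    "cdkg1_production",
    "make_mother",
    "run_division_series",
    "predict_n_rounds",
    "unit_accounting_rounds",
    "scenario_params",
    "fit_params",
]

SENSED_QUANTITIES = ("per_dna_ratio", "per_nucleus_amount", "nuclear_concentration")
DECREMENT_MODES = ("geometric", "linear")
GENOTYPES = ("wild_type", "cdkg1_null", "overexpression")

#: Supplement applied by the constitutive mis-expression scenario when the
#: base parameters leave the field at 0 (AU per nucleus per round).
DEFAULT_OVEREXPRESSION_SUPPLEMENT = 800.0

#: Default nucleus:cell volume ratio used to set a mother's total nuclear
#: volume, which stays fixed across division rounds.
DEFAULT_NC_RATIO = 0.1


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the titration sizer.

    production_coeff (a) and production_exponent (b) define pre-mitotic
    production ``a * M**b`` (AU); exit_threshold (theta) is the level of the
    sensed quantity below which no further round starts; degradation_fraction
    (delta) is the per-round net loss. commitment_size is the mid-G1 sizer
    gate (µm³): below it no regulator is produced and cells do not divide.
    """

    production_coeff: float = 1.0
    production_exponent: float = 1.5
    exit_threshold: float = 2000.0
    degradation_fraction: float = 0.1
    commitment_size: float = 195.0
    sensed_quantity: str = "per_dna_ratio"
    decrement_mode: str = "geometric"
    unit_mode: bool = False
    max_rounds: int = 5
    null_exit_threshold: float = 220.0
    overexpression_supplement: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0.0 <= self.degradation_fraction < 1.0):
            raise ValueError(
                "degradation_fraction must be in [0, 1), got "
                f"{self.degradation_fraction}"
            )
        if self.exit_threshold <= 0:
            raise ValueError("exit_threshold must be > 0")
        if self.production_coeff < 0:
            raise ValueError("production_coeff must be >= 0")
        if self.production_exponent <= 0:
            raise ValueError("production_exponent must be > 0")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")
        if self.commitment_size < 0:
            raise ValueError("commitment_size must be >= 0")
        if self.sensed_quantity not in SENSED_QUANTITIES:
            raise ValueError(
                f"sensed_quantity must be one of {SENSED_QUANTITIES}, "
                f"got {self.sensed_quantity!r}"
            )
        if self.decrement_mode not in DECREMENT_MODES:
            raise ValueError(
                f"decrement_mode must be one of {DECREMENT_MODES}, "
                f"got {self.decrement_mode!r}"
            )
        if self.null_exit_threshold <= 0:
            raise ValueError("null_exit_threshold must be > 0")
        if self.overexpression_supplement < 0:
            raise ValueError("overexpression_supplement must be >= 0")


@dataclass
class MotherState:
    """State of a mother cell entering (or progressing through) S/M.

    total_nuclear_volume (µm³) is fixed for the whole division series:
    nuclear volume halves per round while nuclei double.
    """

    volume: float
    cdkg1_total: float
    nuclei_count: int = 1
    total_nuclear_volume: float = 0.0
    committed: bool = True

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("volume must be positive")
        if self.cdkg1_total < 0:
            raise ValueError("cdkg1_total must be non-negative")
        n = self.nuclei_count
        if n < 1 or (n & (n - 1)) != 0:
            raise ValueError("nuclei_count must be a power of 2 and >= 1")
        if self.total_nuclear_volume < 0:
            raise ValueError("total_nuclear_volume must be non-negative")


@dataclass(frozen=True)
class TrajectoryPoint:
    """Per-round record taken after a round of division completes."""

    round: int
    nuclei: int
    per_nucleus_amount: float
    concentration: float
    per_dna_ratio: float


@dataclass
class DivisionOutcome:
    """Result of a full S/M division series."""

    n_rounds: int
    daughter_volume: float
    trajectory: list[TrajectoryPoint] = field(default_factory=list)

    @property
    def n_daughters(self) -> int:
        return 2**self.n_rounds

    def to_frame(self) -> pd.DataFrame:
        """Trajectory as a DataFrame (columns: round, nuclei, per_nucleus_amount,
        concentration, per_dna_ratio)."""
        return pd.DataFrame(
            [
                {
                    "round": p.round,
                    "nuclei": p.nuclei,
                    "per_nucleus_amount": p.per_nucleus_amount,
                    "concentration": p.concentration,
                    "per_dna_ratio": p.per_dna_ratio,
                }
                for p in self.trajectory
            ],
            columns=[
                "round",
                "nuclei",
                "per_nucleus_amount",
                "concentration",
                "per_dna_ratio",
            ],
        )


def cdkg1_production(mother_volume: float, params: ModelParams) -> float:
    """Pre-mitotic regulator amount (AU) produced by a mother of given volume.

    Below the commitment size production is a negligible baseline (0):
    non-dividing control cells carry essentially no detectable regulator.
    At or above commitment the amount is the allometric power law
    ``a * M**b``.
    """
    if mother_volume <= 0:
        raise ValueError("mother_volume must be positive")
    if mother_volume < params.commitment_size:
        return 0.0
    return params.production_coeff * mother_volume**params.production_exponent


def make_mother(
    volume: float,
    params: ModelParams,
    committed: bool | None = None,
    nc_ratio: float = DEFAULT_NC_RATIO,
) -> MotherState:
    """Build a pre-division MotherState from a volume and model parameters.

    Commitment defaults to ``volume >= params.commitment_size``; the fixed
    total nuclear volume is ``nc_ratio * volume``.
    """
    if committed is None:
        committed = volume >= params.commitment_size
    return MotherState(
        volume=volume,
        cdkg1_total=cdkg1_production(volume, params),
        nuclei_count=1,
        total_nuclear_volume=nc_ratio * volume,
        committed=committed,
    )


def _sensed(total: float, nuclei: int, nuc_volume: float, params: ModelParams) -> float:
    if params.sensed_quantity == "nuclear_concentration":
        if nuc_volume <= 0:
            raise ValueError(
                "total_nuclear_volume must be positive to sense nuclear_concentration"
            )
        return total / nuc_volume
    # per_dna_ratio and per_nucleus_amount coincide numerically: one genome
    # copy per nucleus.
    return total / nuclei


def run_division_series(
    mother: MotherState,
    params: ModelParams,
    fallback_for_null: bool = False,
) -> DivisionOutcome:
    """Run the S/M division series for one committed mother.

    Each round doubles the nuclei and depletes the regulator stock
    (geometric: ``total *= 1-delta``; linear: ``total -= delta*initial``),
    then adds any constitutive mis-expression supplement. A round r >= 2
    starts only if the sensed quantity, evaluated on the state left by the
    previous round, is at or above ``exit_threshold``. Committed mothers
    always complete round 1. Uncommitted mothers return ``n_rounds = 0``.

    With ``fallback_for_null`` the exit decision ignores the regulator and a
    backup sizer is used instead: round r starts while the per-nucleus cell
    volume ``M / nuclei`` is at or above ``null_exit_threshold``.

    With ``params.unit_mode`` the stock is a discrete unit ledger: each round
    consumes one unit per nucleus present and runs only if the per-nucleus
    stock is at or above the threshold (no free first round, so the ledger
    alone decides — see unit_accounting_rounds).
    """
    if not mother.committed:
        return DivisionOutcome(0, mother.volume, [])

    total = float(mother.cdkg1_total)
    nuclei = int(mother.nuclei_count)
    initial_total = total
    nuc_vol = mother.total_nuclear_volume
    traj: list[TrajectoryPoint] = []
    n_rounds = 0

    for r in range(1, params.max_rounds + 1):
        if params.unit_mode:
            go = total / nuclei >= params.exit_threshold
        elif fallback_for_null:
            go = r == 1 or (mother.volume / nuclei >= params.null_exit_threshold)
        else:
            go = r == 1 or _sensed(total, nuclei, nuc_vol, params) >= params.exit_threshold
        if not go:
            break

        if params.unit_mode:
            total -= nuclei  # one unit consumed per mitosis
            nuclei *= 2
        else:
            nuclei *= 2
            if params.decrement_mode == "geometric":
                total *= 1.0 - params.degradation_fraction
            else:
                total = max(total - params.degradation_fraction * initial_total, 0.0)
            total += params.overexpression_supplement * nuclei
        n_rounds = r
        traj.append(
            TrajectoryPoint(
                round=r,
                nuclei=nuclei,
                per_nucleus_amount=total / nuclei,
                concentration=(total / nuc_vol) if nuc_vol > 0 else float("nan"),
                per_dna_ratio=total / nuclei,
            )
        )
    else:
        # max_rounds exhausted with the continuation condition still holding
        still_going = (
            (total / nuclei >= params.exit_threshold)
            if params.unit_mode
            else (mother.volume / nuclei >= params.null_exit_threshold)
            if fallback_for_null
            else (_sensed(total, nuclei, nuc_vol, params) >= params.exit_threshold)
        )
        if still_going:
            logger.warning(
                "division series truncated at max_rounds=%d with sensed quantity "
                "still above threshold",
                params.max_rounds,
            )

    return DivisionOutcome(n_rounds, mother.volume / 2**n_rounds, traj)


def predict_n_rounds(mother_volume, params: ModelParams, fallback_for_null: bool = False):
    """Number of division rounds for mother volume(s), vectorized.

    Uses the closed form for the default configuration (geometric decrement,
    per-DNA or per-nucleus sensing, no supplement): with f = (1-delta)/2 the
    sensed quantity after round r is ``a*M**b * f**r``, so
    ``n = 1 + floor(log(a*M**b/theta) / log(1/f))`` clipped to
    [1, max_rounds]; below commitment n = 0. Other configurations fall back
    to iterating run_division_series. Agrees with run_division_series
    everywhere (tested property).
    """
    m = np.asarray(mother_volume, dtype=float)
    closed_form_ok = (
        params.decrement_mode == "geometric"
        and not params.unit_mode
        and params.overexpression_supplement == 0
        and params.sensed_quantity in ("per_dna_ratio", "per_nucleus_amount")
    )
    if fallback_for_null:
        with np.errstate(divide="ignore", invalid="ignore"):
            extra = np.floor(np.log2(m / params.null_exit_threshold) + 1e-9)
        n = 1 + np.clip(extra, 0, None)
        n = np.minimum(n, params.max_rounds)
        n = np.where(m >= params.commitment_size, n, 0).astype(int)
        return n if n.ndim else int(n)
    if closed_form_ok:
        amount = params.production_coeff * m**params.production_exponent
        f = (1.0 - params.degradation_fraction) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(amount > 0, amount / params.exit_threshold, np.nan)
            extra = np.floor(np.log(ratio) / np.log(1.0 / f) + 1e-9)
        extra = np.nan_to_num(extra, nan=0.0)
        n = 1 + np.clip(extra, 0, None)
        n = np.minimum(n, params.max_rounds)
        n = np.where(m >= params.commitment_size, n, 0).astype(int)
        return n if n.ndim else int(n)
    # general path
    out = np.array(
        [
            run_division_series(make_mother(v, params), params, fallback_for_null).n_rounds
            for v in np.atleast_1d(m)
        ]
    )
    return out.reshape(m.shape) if m.ndim else int(out[0])


def unit_accounting_rounds(units: int) -> tuple[int, int, int]:
    """Discrete unit-accounting of division rounds.

    Round k costs 2**(k-1) units (one per nucleus present), so the cumulative
    cost of n rounds is 2**n - 1 mitoses. Returns
    ``(n_rounds, n_daughters, total_mitoses)`` for the largest affordable n:
    one unit buys one division (two daughters); seven units buy three rounds
    (1+2+4 mitoses, eight daughters).
    """
    if units < 0:
        raise ValueError("units must be non-negative")
    n = int(np.floor(np.log2(units + 1)))
    return n, 2**n, 2**n - 1


def scenario_params(genotype: str, base: ModelParams) -> ModelParams:
    """Model parameters for a genotype scenario.

    wild_type: unchanged. cdkg1_null: no regulator production; exit is
    governed by the backup size threshold (run with
    ``fallback_for_null=True``), giving fewer rounds and larger daughters.
    overexpression: a constitutive supplement is added to the stock every
    round, giving extra rounds and smaller daughters.
    """
    if genotype == "wild_type":
        return base
    if genotype == "cdkg1_null":
        return replace(base, production_coeff=0.0, overexpression_supplement=0.0)
    if genotype == "overexpression":
        supp = base.overexpression_supplement or DEFAULT_OVEREXPRESSION_SUPPLEMENT
        return replace(base, overexpression_supplement=supp)
    raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")


def _fit_loss(
    theta: float,
    delta: float,
    b: float,
    volumes: np.ndarray,
    n_obs: np.ndarray,
    stage_means: np.ndarray | None,
    conc_by_volume: np.ndarray | None,
    nc_ratio: float,
    base: ModelParams,
) -> float:
    params = replace(
        base,
        exit_threshold=theta,
        degradation_fraction=delta,
        production_exponent=b,
    )
    n_pred = predict_n_rounds(volumes, params)
    loss = float(np.mean((n_pred - n_obs) ** 2))
    if stage_means is not None and len(stage_means) >= 2:
        # per-stage decay pins delta: concentration falls by (1-delta)/round
        r_obs = np.log(np.asarray(stage_means, dtype=float) / stage_means[0])
        k = np.arange(len(stage_means))
        r_pred = k * np.log(1.0 - delta)
        loss += 10.0 * float(np.sum((r_obs - r_pred) ** 2))
    if conc_by_volume is not None and len(conc_by_volume) > 0:
        # first-round concentration vs mother volume pins the allometric
        # exponent: c1 = a*(1-delta)*M**(b-1)/nc_ratio (total nuclear volume
        # is nc_ratio*M)
        m = conc_by_volume[:, 0]
        c1 = conc_by_volume[:, 1]
        pred = np.log(base.production_coeff * (1.0 - delta) / nc_ratio) + (
            b - 1.0
        ) * np.log(m)
        loss += 10.0 * float(np.mean((np.log(c1) - pred) ** 2))
    return loss


def fit_params(
    observed,
    search_grid: dict[str, tuple[float, float]],
    seed: int = 0,
    stage_concentration_means: Sequence[float] | None = None,
    volume_concentration: np.ndarray | None = None,
    nc_ratio: float = DEFAULT_NC_RATIO,
    base: ModelParams | None = None,
    grid_points: int = 13,
    n_refine: int = 2,
) -> tuple[ModelParams, dict]:
    """Recover (exit_threshold, degradation_fraction, production_exponent)
    from observed (mother_volume, n_rounds) pairs by grid search with local
    grid refinement on the squared error in n_rounds.

    ``observed`` is a DataFrame with columns mother_volume and n_rounds (or a
    2-column array). ``search_grid`` maps each of the three parameter names
    to a (low, high) range that should bracket the truth. Two optional
    stage-trajectory summaries sharpen the fit:

    * ``stage_concentration_means`` — per-stage mean nuclear concentrations
      relative to the first stage (use per-cell-normalized geometric means:
      unbiased in log space and immune to the cohort-composition shift from
      larger mothers reaching later stages); these pin delta.
    * ``volume_concentration`` — per-cell (mother_volume, first-round
      nuclear concentration) pairs, which pin the allometric exponent via
      ``log c1 = const + (b-1) log M`` at fixed N/C (``nc_ratio``).

    Without them the three parameters are confounded along lines of equal
    ``b / log(2/(1-delta))`` and equal ``log(a/theta) / log(2/(1-delta))``;
    the degeneracy is flagged in diagnostics. The production coefficient a
    is taken from ``base`` (a and theta are exactly degenerate in division
    counts, so one must be fixed).

    Deterministic for a given seed and grid. Returns the fitted parameters
    and a diagnostics dict (loss, boundary flags, grid history).
    """
    if isinstance(observed, pd.DataFrame):
        volumes = observed["mother_volume"].to_numpy(dtype=float)
        n_obs = observed["n_rounds"].to_numpy(dtype=float)
    else:
        arr = np.asarray(observed, dtype=float)
        volumes, n_obs = arr[:, 0], arr[:, 1]
    if len(volumes) < 20:
        raise ValueError("need at least 20 observations")
    if np.ptp(volumes) == 0:
        raise ValueError("degenerate observations: all mother volumes identical")
    required = {"exit_threshold", "degradation_fraction", "production_exponent"}
    if not search_grid or set(search_grid) != required:
        raise ValueError(f"search_grid must provide ranges for {sorted(required)}")
    for name, (lo, hi) in search_grid.items():
        if not (hi > lo):
            raise ValueError(f"empty grid range for {name}")

    base = base or ModelParams()
    conc_by_volume = (
        None if volume_concentration is None else np.asarray(volume_concentration, float)
    )
    bounds = {k: tuple(map(float, v)) for k, v in search_grid.items()}
    ranges = dict(bounds)
    best = None
    history = []
    for _ in range(n_refine + 1):
        axes = {
            k: np.linspace(ranges[k][0], ranges[k][1], grid_points) for k in required
        }
        # keep degradation_fraction inside its validity domain
        axes["degradation_fraction"] = np.clip(
            axes["degradation_fraction"], 0.0, 1.0 - 1e-9
        )
        for theta, delta, b in itertools.product(
            axes["exit_threshold"],
            axes["degradation_fraction"],
            axes["production_exponent"],
        ):
            loss = _fit_loss(
                theta,
                delta,
                b,
                volumes,
                n_obs,
                stage_concentration_means,
                conc_by_volume,
                nc_ratio,
                base,
            )
            cand = (loss, float(theta), float(delta), float(b))
            if best is None or cand[0] < best[0]:
                best = cand
        history.append({k: (float(axes[k][0]), float(axes[k][-1])) for k in required})
        # shrink ranges around the incumbent, staying within the caller's grid
        steps = {k: (ranges[k][1] - ranges[k][0]) / (grid_points - 1) for k in required}
        center = dict(
            zip(("exit_threshold", "degradation_fraction", "production_exponent"), best[1:])
        )
        ranges = {
            k: (
                max(bounds[k][0], center[k] - 1.5 * steps[k]),
                min(bounds[k][1], center[k] + 1.5 * steps[k]),
            )
            for k in required
        }

    loss, theta, delta, b = best
    fitted = replace(
        base,
        exit_threshold=theta,
        degradation_fraction=delta,
        production_exponent=b,
    )
    tol = {k: 0.02 * (bounds[k][1] - bounds[k][0]) for k in required}
    at_boundary = {
        "exit_threshold": min(theta - bounds["exit_threshold"][0], bounds["exit_threshold"][1] - theta)
        < tol["exit_threshold"],
        "degradation_fraction": min(
            delta - bounds["degradation_fraction"][0], bounds["degradation_fraction"][1] - delta
        )
        < tol["degradation_fraction"],
        "production_exponent": min(
            b - bounds["production_exponent"][0], bounds["production_exponent"][1] - b
        )
        < tol["production_exponent"],
    }
    diagnostics = {
        "loss": loss,
        "at_grid_boundary": at_boundary,
        "degenerate_without_trajectories": stage_concentration_means is None
        and conc_by_volume is None,
        "grid_history": history,
        "seed": seed,
        "n_observations": int(len(volumes)),
    }
    return fitted, diagnostics
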