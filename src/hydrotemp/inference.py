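"""Temperature binning, resampling significance, split errors, parabola fits."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .amino_acids import REFERENCE_TYPES
from .errors import (
    DegenerateFit,
    EmptyBin,
    MissingCell,
    TooFewChains,
    ZeroCountError,
)
from .ingest import ChainCounts, ChainRecord
from .potentials import (
    DEFAULT_BURIAL_CUTOFF,
    DEFAULT_Q,
    BinCounts,
    aggregate_bin_counts,
    energy,
    get_cell,
    reference_energy,
)

#: Inclusive integer-kelvin bin bounds, low to high.
TEMPERATURE_BINS: tuple[tuple[str, int, int], ...] = (
    ("265-290", 265, 290),
    ("291-296", 291, 296),
    ("297-299", 297, 299),
    ("300-305", 300, 305),
    ("306-340", 306, 340),
)

BIN_LOW = "265-290"
BIN_ROOM = "297-299"


def assign_bin(temperature: float) -> str | None:
    """Map a temperature (K) to its bin id, or None when out of range.

    The temperature is rounded to the nearest integer kelvin before the
    inclusive-range lookup (bounds are integer kelvin; half-kelvin
    values round up).
    """
    if not math.isfinite(temperature):
        return None
    t = int(math.floor(temperature + 0.5))
    for bin_id, lo, hi in TEMPERATURE_BINS:
        if lo <= t <= hi:
            return bin_id
    return None


def bin_chains(
    chains: Sequence[ChainRecord | ChainCounts],
) -> dict[str, list]:
    """Group chains by temperature bin; out-of-range chains are dropped."""
    groups: dict[str, list] = {bin_id: [] for bin_id, _, _ in TEMPERATURE_BINS}
    for chain in chains:
        bin_id = assign_bin(chain.temperature)
        if bin_id is not None:
            groups[bin_id].append(chain)
    return {b: g for b, g in groups.items() if g}


def bin_mean_temperatures(
    groups: Mapping[str, Sequence],
) -> dict[str, float]:
    """Mean chain temperature per bin — the abscissa used for fitting."""
    return {
        bin_id: float(np.mean([c.temperature for c in chains]))
        for bin_id, chains in groups.items()
    }


def delta_delta_g(
    table: pd.DataFrame,
    entity: str,
    method: str,
    bin_low: str = BIN_LOW,
    bin_room: str = BIN_ROOM,
    corrected: bool = False,
) -> float:
    """Room-bin minus low-bin transfer energy (kT); positive when the
    transfer cost is larger at room temperature."""
    low = get_cell(table, bin_low, entity, method, corrected)
    room = get_cell(table, bin_room, entity, method, corrected)
    if math.isnan(low) or math.isnan(room):
        raise MissingCell(f"{entity}/{method}: missing cell in {bin_low} or {bin_room}")
    return room - low


# --------------------------------------------------------------------------
# Estimator plumbing
# --------------------------------------------------------------------------

def make_bin_estimator(
    entity: str,
    method: str,
    corrected: bool = False,
    burial_cutoff: float = DEFAULT_BURIAL_CUTOFF,
    q: float = DEFAULT_Q,
    reference_types: Sequence[str] = REFERENCE_TYPES,
    max_asa=None,
) -> Callable[[Sequence], float]:
    """Build a callable evaluating one potential cell on a chain list."""

    def estimator(chains: Sequence) -> float:
        counts = aggregate_bin_counts(chains, burial_cutoff=burial_cutoff, q=q)
        value = energy(counts, entity, method, max_asa=max_asa)
        if corrected:
            value -= reference_energy(
                counts, method, reference_types, max_asa=max_asa
            )
        return value

    return estimator


def _as_counts(chains, burial_cutoff: float) -> list[ChainCounts]:
    from .potentials import chain_to_counts

    return [
        c if isinstance(c, ChainCounts) else chain_to_counts(c, burial_cutoff)
        for c in chains
    ]


def _stack(counts: Sequence[ChainCounts]):
    n = np.stack([c.n for c in counts])
    buried = np.stack([c.buried for c in counts])
    alpha = np.stack([c.alpha_sum for c in counts])
    return n, buried, alpha


# --------------------------------------------------------------------------
# Split-sample standard error
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitError:
    estimate: float          # estimator on the full bin
    part_estimates: tuple[float, ...]
    se: float                # sd(parts) / sqrt(k)
    seed: int | None

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.estimate - 2 * self.se, self.estimate + 2 * self.se)


def split_standard_error(
    chains_in_bin: Sequence,
    estimator: Callable[[Sequence], float],
    k: int = 5,
    seed: int | None = None,
) -> SplitError:
    """Standard error from a random equal-size k-way split of the bin.

    Chains are shuffled (seeded) and dealt round-robin into ``k`` parts,
    so part sizes differ by at most one. The estimator is recomputed on
    each part; the SE is the standard deviation of the part estimates
    divided by sqrt(k), and the 95% interval is the estimate ± 2 SE.
    """
    n = len(chains_in_bin)
    if n < k:
        raise TooFewChains(f"{n} chains < {k} parts")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    parts: list[list] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        parts[pos % k].append(chains_in_bin[idx])
    part_estimates = tuple(float(estimator(p)) for p in parts)
    se = float(np.std(part_estimates, ddof=1) / math.sqrt(k))
    return SplitError(
        estimate=float(estimator(chains_in_bin)),
        part_estimates=part_estimates,
        se=se,
        seed=seed,
    )


# --------------------------------------------------------------------------
# Resampling significance
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SignificanceResult:
    observed_ddg: float
    n_resamples: int
    n_exceed: int
    p_value: float
    seed: int | None

    def formatted_p(self, floor: float = 1e-3) -> str:
        """Human-readable p; 0 exceedances prints as '<1/n'."""
        if self.n_exceed == 0:
            return f"<{1.0 / self.n_resamples:g}"
        return f"{self.p_value:.3f}"


def resample_pvalue(
    chains_low: Sequence,
    chains_room: Sequence,
    entity: str,
    method: str,
    corrected: bool = False,
    n_resamples: int = 1000,
    seed: int | None = None,
    burial_cutoff: float = DEFAULT_BURIAL_CUTOFF,
    q: float = DEFAULT_Q,
    reference_types: Sequence[str] = REFERENCE_TYPES,
    max_asa=None,
) -> SignificanceResult:
    """Label-shuffle significance of the between-bin energy difference.

    Chains from the two bins are pooled and whole chains are permuted
    between them, preserving both bin sizes; the statistic (room minus
    low energy for the entity/method, reference-corrected inside every
    resample when ``corrected``) is recomputed per permutation. The
    p-value is the fraction of resamples whose |statistic| is at least
    |observed| (ties count as exceedances; resamples where the statistic
    is undefined are counted as exceedances, which is conservative).
    """
    if len(chains_low) == 0 or len(chains_room) == 0:
        raise EmptyBin("both bins must be non-empty")
    low = _as_counts(chains_low, burial_cutoff)
    room = _as_counts(chains_room, burial_cutoff)
    pool = low + room
    n_mat, b_mat, a_mat = _stack(pool)
    n_low = len(low)
    n_tot = len(pool)

    def stat(idx_low: np.ndarray, idx_room: np.ndarray) -> float:
        value = 0.0
        for sign, idx in ((-1.0, idx_low), (+1.0, idx_room)):
            counts = BinCounts(
                bin_id="",
                n=n_mat[idx].sum(axis=0),
                buried=b_mat[idx].sum(axis=0),
                alpha_sum=a_mat[idx].sum(axis=0),
                q=q,
            )
            e = energy(counts, entity, method, max_asa=max_asa)
            if corrected:
                e -= reference_energy(
                    counts, method, reference_types, max_asa=max_asa
                )
            value += sign * e
        return value

    all_idx = np.arange(n_tot)
    observed = stat(all_idx[:n_low], all_idx[n_low:])

    rng = np.random.default_rng(seed)
    abs_obs = abs(observed)
    n_exceed = 0
    for _ in range(n_resamples):
        perm = rng.permutation(n_tot)
        try:
            s = stat(perm[:n_low], perm[n_low:])
        except ZeroCountError:
            n_exceed += 1
            continue
        a = abs(s)
        if a > abs_obs or np.isclose(a, abs_obs, rtol=1e-9, atol=1e-12):
            n_exceed += 1
    return SignificanceResult(
        observed_ddg=float(observed),
        n_resamples=n_resamples,
        n_exceed=n_exceed,
        p_value=n_exceed / n_resamples,
        seed=seed,
    )


# --------------------------------------------------------------------------
# Parabola fitting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ParabolaFit:
    """Weighted least-squares fit of dG(T) = a2 T^2 + a1 T + a0."""

    a2: float
    a1: float
    a0: float
    weights: tuple[float, ...]
    residuals: tuple[float, ...]
    weighted_residual_sum: float  # S = sum(w_i r_i^2)

    @property
    def vertex_temperature(self) -> float:
        """Stationary temperature -a1 / (2 a2); NaN for a degenerate a2."""
        if self.a2 == 0.0:
            return float("nan")
        return -self.a1 / (2.0 * self.a2)

    @property
    def is_maximum(self) -> bool:
        """True when the parabola opens downward (vertex is a maximum)."""
        return self.a2 < 0.0

    def predict(self, temperature) -> np.ndarray:
        t = np.asarray(temperature, dtype=float)
        return self.a2 * t * t + self.a1 * t + self.a0


def fit_parabola(
    points: Sequence[tuple[float, float]],
    weights: Sequence[float] | None = None,
) -> ParabolaFit:
    """Fit a parabola by weighted least squares, minimising S = Σ w r².

    ``points`` are (mean bin temperature, dG) pairs; NaN dG values are
    dropped. ``weights`` default to 1 (ordinary least squares); the
    intended weights are per-bin residue counts of the fitted entity.
    """
    pts = [(t, g) for t, g in points]
    if weights is None:
        weights = [1.0] * len(pts)
    if len(weights) != len(pts):
        raise ValueError("weights length must match points")
    keep = [i for i, (t, g) in enumerate(pts) if math.isfinite(t) and math.isfinite(g)]
    t = np.array([pts[i][0] for i in keep], dtype=float)
    y = np.array([pts[i][1] for i in keep], dtype=float)
    w = np.array([weights[i] for i in keep], dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if len(t) < 3 or len(np.unique(t)) < 3:
        raise DegenerateFit(f"need >=3 distinct temperatures, have {len(np.unique(t))}")
    design = np.column_stack([t * t, t, np.ones_like(t)])
    sw = np.sqrt(w)
    coef, _, rank, _ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    if rank < 3:
        raise DegenerateFit("design matrix is rank-deficient")
    resid = y - design @ coef
    s = float(np.sum(w * resid * resid))
    return ParabolaFit(
        a2=float(coef[0]),
        a1=float(coef[1]),
        a0=float(coef[2]),
        weights=tuple(w.tolist()),
        residuals=tuple(resid.tolist()),
        weighted_residual_sum=s,
    )
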