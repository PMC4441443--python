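"""Core→surface transfer free-energy estimators from per-bin counts.

All energies are in kT units (natural log of count ratios; kT divided
out) and share one sign convention: positive means burial-favouring,
i.e. a transfer cost from the hydrophobic core to the water-exposed
surface.

Four estimators are provided:

``contact``
    Quasi-chemical solvent-contact energy. Each residue carries ``q``
    contact slots of which a fraction ``alpha`` touches water, so the
    observed solvent contacts of type *a* are ``c_a = q * sum(alpha)``
    and the expectation under random mixing is
    ``omega_a = n_a q * W / (q N + W)`` with ``W`` the total number of
    water contact points. The energy is ``-ln(c_a / omega_a)``.
``surface``
    Burial propensity expressed as a partition coefficient,
    ``ln[(N_ab / N_anb) / (N_b / N_nb)]`` at a strict exposure cutoff
    (``alpha < 0.07`` counts as buried). This form is exactly
    antisymmetric under swapping the buried / non-buried labels.
``area``
    Continuous variant (infinite coordination number):
    ``-ln[(N / n_a) * sum_{r in a}(alpha_r) / sum_all(alpha_r)]``.
``scaled_area``
    The area energy multiplied by the type's maximum accessible area
    (count-weighted mean over members when types are pooled).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .amino_acids import (
    AA_INDEX,
    AMINO_ACIDS,
    MAX_ASA_THEORETICAL,
    REFERENCE_TYPES,
    resolve_entity,
)
from .errors import (
    EmptyBin,
    MissingReference,
    ZeroArea,
    ZeroCell,
    ZeroContacts,
    ZeroCountError,
)
from .ingest import ChainCounts, ChainRecord

DEFAULT_BURIAL_CUTOFF = 0.07
DEFAULT_Q = 4.0

METHODS = ("contact", "surface", "area", "scaled_area")


@dataclass(frozen=True)
class BinCounts:
    """Aggregated counts for one temperature bin.

    Per-type arrays follow the canonical residue order; ``q`` is the
    coordination number the contact estimator was configured with.
    """

    bin_id: str
    n: np.ndarray          # (20,) residues per type
    buried: np.ndarray     # (20,) residues with alpha < cutoff
    alpha_sum: np.ndarray  # (20,) sum of exposure fractions
    q: float = DEFAULT_Q

    @property
    def nonburied(self) -> np.ndarray:
        return self.n - self.buried

    @property
    def total_residues(self) -> int:
        return int(self.n.sum())

    @property
    def total_buried(self) -> int:
        return int(self.buried.sum())

    @property
    def total_nonburied(self) -> int:
        return int(self.nonburied.sum())

    @property
    def contacts(self) -> np.ndarray:
        """Solvent contact counts per type, c_a = q * sum(alpha)."""
        return self.q * self.alpha_sum

    @property
    def total_water_contacts(self) -> float:
        """W: total number of water contact points in the bin."""
        return float(self.q * self.alpha_sum.sum())


def chain_to_counts(
    chain: ChainRecord,
    burial_cutoff: float = DEFAULT_BURIAL_CUTOFF,
) -> ChainCounts:
    """Collapse a chain's residues to per-type counts at a burial cutoff."""
    k = len(AMINO_ACIDS)
    n = np.zeros(k, dtype=np.int64)
    buried = np.zeros(k, dtype=np.int64)
    alpha_sum = np.zeros(k, dtype=float)
    for res in chain.residues:
        i = AA_INDEX[res.aa_type]
        n[i] += 1
        if res.exposure_fraction < burial_cutoff:  # strict
            buried[i] += 1
        alpha_sum[i] += res.exposure_fraction
    return ChainCounts(
        structure_id=chain.structure_id,
        chain_id=chain.chain_id,
        temperature=chain.temperature,
        n=n, buried=buried, alpha_sum=alpha_sum,
    )


def aggregate_bin_counts(
    chains: Sequence[ChainRecord | ChainCounts],
    bin_id: str = "",
    burial_cutoff: float = DEFAULT_BURIAL_CUTOFF,
    q: float = DEFAULT_Q,
) -> BinCounts:
    """Sum per-chain counts into one :class:`BinCounts`.

    Accepts either :class:`ChainRecord` (counted at ``burial_cutoff``)
    or pre-aggregated :class:`ChainCounts` rows (whose burial cutoff is
    whatever the table was built with).
    """
    if not 0.0 < burial_cutoff < 1.0:
        raise ValueError("burial_cutoff must lie in (0, 1)")
    if len(chains) == 0:
        raise EmptyBin(f"bin {bin_id!r} has no chains")
    k = len(AMINO_ACIDS)
    n = np.zeros(k, dtype=np.int64)
    buried = np.zeros(k, dtype=np.int64)
    alpha_sum = np.zeros(k, dtype=float)
    for chain in chains:
        cc = chain if isinstance(chain, ChainCounts) else chain_to_counts(
            chain, burial_cutoff
        )
        n += cc.n
        buried += cc.buried
        alpha_sum += cc.alpha_sum
    return BinCounts(bin_id=bin_id, n=n, buried=buried, alpha_sum=alpha_sum, q=q)


# --------------------------------------------------------------------------
# Estimators
# --------------------------------------------------------------------------

def _pool_indices(entity) -> list[int]:
    if isinstance(entity, str):
        types = resolve_entity(entity)
    else:
        types = tuple(entity)
    return [AA_INDEX[t] for t in types]


def contact_energy(counts: BinCounts, entity) -> float:
    """Solvent-contact transfer energy, kT units.

    Pooling sums counts over member types before the log-ratio is taken.
    """
    idx = _pool_indices(entity)
    n_pool = float(counts.n[idx].sum())
    c_pool = float(counts.contacts[idx].sum())
    if c_pool <= 0.0 or n_pool <= 0.0:
        raise ZeroContacts(f"{entity}: no solvent contacts in bin {counts.bin_id!r}")
    w = counts.total_water_contacts
    denom = counts.q * counts.total_residues + w
    omega = n_pool * counts.q * w / denom
    return float(-np.log(c_pool / omega))


def surface_energy(counts: BinCounts, entity) -> float:
    """Partition-coefficient burial propensity energy, kT units."""
    idx = _pool_indices(entity)
    n_b = float(counts.buried[idx].sum())
    n_nb = float(counts.nonburied[idx].sum())
    tot_b = float(counts.total_buried)
    tot_nb = float(counts.total_nonburied)
    if min(n_b, n_nb, tot_b, tot_nb) <= 0.0:
        raise ZeroCell(f"{entity}: zero count in bin {counts.bin_id!r}")
    return float(np.log((n_b / n_nb) / (tot_b / tot_nb)))


def area_energy(
    counts: BinCounts,
    entity,
    scaled: bool = False,
    max_asa: Mapping[str, float] | None = None,
) -> float:
    """Exposed-area transfer energy; optionally scaled by max area (Å²·kT)."""
    idx = _pool_indices(entity)
    n_pool = float(counts.n[idx].sum())
    a_pool = float(counts.alpha_sum[idx].sum())
    a_tot = float(counts.alpha_sum.sum())
    if n_pool <= 0.0 or a_pool <= 0.0 or a_tot <= 0.0:
        raise ZeroArea(f"{entity}: zero area in bin {counts.bin_id!r}")
    value = float(-np.log((counts.total_residues / n_pool) * a_pool / a_tot))
    if scaled:
        asa = max_asa or MAX_ASA_THEORETICAL
        areas = np.array([asa[AMINO_ACIDS[i]] for i in idx])
        weights = counts.n[idx].astype(float)
        # count-weighted mean of member max areas; single types reduce
        # to their own tabulated maximum
        value *= float(np.average(areas, weights=weights))
    return value


def energy(
    counts: BinCounts,
    entity,
    method: str,
    max_asa: Mapping[str, float] | None = None,
) -> float:
    """Dispatch on method name; see module docstring for definitions."""
    if method == "contact":
        return contact_energy(counts, entity)
    if method == "surface":
        return surface_energy(counts, entity)
    if method == "area":
        return area_energy(counts, entity, scaled=False)
    if method == "scaled_area":
        return area_energy(counts, entity, scaled=True, max_asa=max_asa)
    raise ValueError(f"unknown method {method!r}")


def reference_energy(
    counts: BinCounts,
    method: str,
    reference_types: Sequence[str] = REFERENCE_TYPES,
    max_asa: Mapping[str, float] | None = None,
) -> float:
    """Energy of the pooled reference (charged+polar by default)."""
    idx = [AA_INDEX[t] for t in reference_types]
    if counts.n[idx].sum() == 0:
        raise MissingReference(f"reference pool empty in bin {counts.bin_id!r}")
    try:
        return energy(counts, tuple(reference_types), method, max_asa=max_asa)
    except ZeroCountError as exc:
        raise MissingReference(str(exc))


# --------------------------------------------------------------------------
# Potential table
# --------------------------------------------------------------------------

TABLE_COLUMNS = [
    "bin", "temperature_mean", "entity", "method", "corrected", "dG_kT", "se_kT",
]


def compute_potential_table(
    bin_counts: Mapping[str, BinCounts],
    bin_mean_temperature: Mapping[str, float],
    entities: Iterable[str],
    methods: Iterable[str] = METHODS,
    include_corrected: bool = True,
    reference_types: Sequence[str] = REFERENCE_TYPES,
    max_asa: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Evaluate every (bin, entity, method) cell into a long-format table.

    Cells whose counts make a log-ratio undefined are stored as NaN
    (missing), never as ±inf. When ``include_corrected`` is set, a
    second block of rows holds the reference-corrected energies: the
    pooled charged+polar energy of the same bin and method subtracted
    from every cell.
    """
    rows = []
    methods = tuple(methods)
    entities = tuple(entities)
    for bin_id, counts in bin_counts.items():
        t_mean = float(bin_mean_temperature.get(bin_id, np.nan))
        for method in methods:
            try:
                ref = reference_energy(
                    counts, method, reference_types, max_asa=max_asa
                )
            except MissingReference:
                ref = np.nan
            for entity in entities:
                try:
                    val = energy(counts, entity, method, max_asa=max_asa)
                except ZeroCountError:
                    val = np.nan
                rows.append((bin_id, t_mean, entity, method, False, val, np.nan))
                if include_corrected:
                    rows.append(
                        (bin_id, t_mean, entity, method, True, val - ref, np.nan)
                    )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def reference_correct(
    table: pd.DataFrame,
    bin_counts: Mapping[str, BinCounts],
    reference_types: Sequence[str] = REFERENCE_TYPES,
    max_asa: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Return the corrected counterpart of an uncorrected table.

    Subtracts, per bin and method, the pooled-reference energy from
    every cell; a constant within-bin shift, so differences between
    entities in the same bin are preserved exactly.
    """
    out = table[~table["corrected"]].copy()
    refs = {
        (bin_id, method): reference_energy(
            bin_counts[bin_id], method, reference_types, max_asa=max_asa
        )
        for bin_id in out["bin"].unique()
        for method in out["method"].unique()
    }
    out["dG_kT"] = [
        row.dG_kT - refs[(row.bin, row.method)]
        for row in out.itertuples()
    ]
    out["corrected"] = True
    return out.reset_index(drop=True)


def get_cell(
    table: pd.DataFrame,
    bin_id: str,
    entity: str,
    method: str,
    corrected: bool = False,
) -> float:
    """Look up one dG value; NaN when the cell is absent or missing."""
    mask = (
        (table["bin"] == bin_id)
        & (table["entity"] == entity)
        & (table["method"] == method)
        & (table["corrected"] == corrected)
    )
    sub = table.loc[mask, "dG_kT"]
    if sub.empty:
        return float("nan")
    return float(sub.iloc[0])


def write_potential_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_potential_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
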