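"""Parsing of structure metadata and accessibility records.

Chains — not whole structures — are the statistical unit throughout the
package; the acquisition temperature is read once per structure from the
PDB-format header and inherited by every chain of that structure.
Accessibility comes from standard DSSP output files (one per NMR model,
or several models passed together); per-residue areas are averaged over
models before the exposure fraction is formed.
"""

from __future__ import annotations

import csv
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.PDB.DSSP import make_dssp_dict

from .amino_acids import (
    AA_INDEX,
    AMINO_ACIDS,
    MAX_ASA_THEORETICAL,
    ONE_TO_THREE,
    validate_max_asa,
)
from .errors import (
    ImplausibleTemperature,
    MalformedRow,
    MissingTemperature,
    ModelMismatch,
    MultipleTemperatures,
    TemperatureError,
    UnknownResidue,
)

logger = logging.getLogger(__name__)

#: Below this temperature (K) an entry is assumed to be a unit mistake
#: (celsius typed into the kelvin field) and is rejected.
IMPLAUSIBLE_BELOW_K = 150.0


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidueExposure:
    """One residue of a chain with its per-model accessible areas (Å²)."""

    aa_type: str
    per_model_area: tuple[float, ...]
    mean_area: float
    exposure_fraction: float  # alpha, clamped to [0, 1]

    def __post_init__(self):
        if self.aa_type not in AA_INDEX:
            raise UnknownResidue(self.aa_type)
        if not 0.0 <= self.exposure_fraction <= 1.0:
            raise ValueError(
                f"exposure_fraction out of [0,1]: {self.exposure_fraction}"
            )


@dataclass(frozen=True)
class ChainRecord:
    """A protein chain with its acquisition temperature and residues."""

    structure_id: str
    chain_id: str
    temperature: float  # kelvin
    residues: tuple[ResidueExposure, ...]

    def __post_init__(self):
        if not math.isfinite(self.temperature):
            raise ValueError("temperature must be finite")
        if not self.residues:
            raise ValueError("chain has no residues")

    @property
    def full_id(self) -> str:
        return f"{self.structure_id}_{self.chain_id}"


@dataclass(frozen=True)
class FailedChain:
    """A chain that could not be turned into a :class:`ChainRecord`."""

    structure_id: str
    chain_id: str
    reason: str  # "temperature" | "parse"
    detail: str = ""


@dataclass
class FilterResult:
    retained: list[ChainRecord]
    tally: dict[str, int]


@dataclass(frozen=True)
class ChainCounts:
    """Per-chain aggregated counts, one row of the counts table.

    Arrays follow the canonical residue order of
    :data:`hydrotemp.amino_acids.AMINO_ACIDS`; ``buried`` is counted at
    the burial cutoff the table was built with (7% by default).
    """

    structure_id: str
    chain_id: str
    temperature: float
    n: np.ndarray          # (20,) residue counts per type
    buried: np.ndarray     # (20,) residues with alpha < cutoff
    alpha_sum: np.ndarray  # (20,) sum of exposure fractions

    def __post_init__(self):
        for name in ("n", "buried", "alpha_sum"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (len(AMINO_ACIDS),):
                raise ValueError(f"{name} must have shape (20,)")
        if np.any(self.buried > self.n):
            raise ValueError("buried counts exceed residue counts")


# --------------------------------------------------------------------------
# PDB-header temperature
# --------------------------------------------------------------------------

_TEMP_RE = re.compile(
    r"^REMARK\s+210\s+TEMPERATURE\s*\(KELVIN\)\s*:\s*(?P<val>.*?)\s*$",
    re.MULTILINE,
)


def parse_acquisition_temperature(header_text: str) -> float:
    """Extract the single acquisition temperature (K) from a PDB header.

    Raises
    ------
    MissingTemperature
        No temperature field, or the field is NULL/empty.
    MultipleTemperatures
        Several differing temperatures from multiple data collection
        sessions.
    ImplausibleTemperature
        Value at or below 150 K (celsius entered in the kelvin field).
    """
    values: list[float] = []
    for m in _TEMP_RE.finditer(header_text):
        raw = m.group("val").strip()
        if not raw or raw.upper() == "NULL":
            continue
        for tok in re.split(r"[;,]", raw):
            tok = tok.strip()
            if not tok:
                continue
            try:
                values.append(float(tok))
            except ValueError:
                raise MissingTemperature(f"unparseable temperature field {raw!r}")
    if not values:
        raise MissingTemperature("no acquisition temperature in header")
    if len(set(values)) > 1:
        raise MultipleTemperatures(f"differing temperatures: {sorted(set(values))}")
    temp = values[0]
    if temp <= IMPLAUSIBLE_BELOW_K:
        raise ImplausibleTemperature(f"{temp} K <= {IMPLAUSIBLE_BELOW_K} K")
    return temp


# --------------------------------------------------------------------------
# DSSP accessibility files
# --------------------------------------------------------------------------

def read_dssp_accessibility(path) -> dict[str, list[tuple[str, float]]]:
    """Read one DSSP output file (one NMR model).

    Returns a mapping ``chain_id -> [(aa_type, accessible_area), ...]``
    in file order. Residues outside the 20-type alphabet are dropped
    with a logged warning; lower-case DSSP codes (bridged cysteines)
    map to CYS.
    """
    dssp, keys = make_dssp_dict(str(path))
    chains: dict[str, list[tuple[str, float]]] = {}
    for key in keys:
        chain_id, _res_id = key
        aa1, _ss, acc = dssp[key][:3]
        if aa1.islower():  # disulphide-bridged cysteine
            aa3 = "CYS"
        else:
            aa3 = ONE_TO_THREE.get(aa1)
        if aa3 is None:
            logger.warning("%s: dropping nonstandard residue %r", path, aa1)
            continue
        chains.setdefault(chain_id, []).append((aa3, float(acc)))
    return chains


def build_chain_record(
    structure_id: str,
    chain_id: str,
    temperature: float,
    per_model_accessibility: Sequence[Sequence[tuple[str, float]]],
    max_asa: Mapping[str, float] | None = None,
) -> ChainRecord:
    """Average accessibilities over NMR models and form exposure fractions.

    ``per_model_accessibility`` holds, per model, the ordered
    ``(aa_type, area)`` list of the chain. All models must agree on
    residue count and types (:class:`ModelMismatch` otherwise). The
    exposure fraction is the model-mean area over the type's maximum
    accessible area, clamped to 1 when an extended conformation exceeds
    the tabulated maximum.
    """
    max_asa = validate_max_asa(dict(max_asa or MAX_ASA_THEORETICAL))
    if not per_model_accessibility:
        raise ModelMismatch("no models")
    types0 = [aa for aa, _ in per_model_accessibility[0]]
    for i, model in enumerate(per_model_accessibility[1:], start=2):
        types = [aa for aa, _ in model]
        if types != types0:
            raise ModelMismatch(
                f"{structure_id}_{chain_id}: model {i} residues differ from model 1"
            )
    residues = []
    for pos, aa in enumerate(types0):
        if aa not in AA_INDEX:
            logger.warning(
                "%s_%s: dropping nonstandard residue %r at position %d",
                structure_id, chain_id, aa, pos,
            )
            continue
        areas = tuple(float(model[pos][1]) for model in per_model_accessibility)
        mean_area = float(np.mean(areas))
        alpha = min(1.0, max(0.0, mean_area / max_asa[aa]))
        residues.append(ResidueExposure(aa, areas, mean_area, alpha))
    if not residues:
        raise UnknownResidue(f"{structure_id}_{chain_id}: no standard residues")
    return ChainRecord(structure_id, chain_id, float(temperature), tuple(residues))


# --------------------------------------------------------------------------
# Filters
# --------------------------------------------------------------------------

def failure_reason(exc: Exception) -> str:
    """Map a chain-construction error to an exclusion-tally reason."""
    if isinstance(exc, TemperatureError):
        return "temperature"
    return "parse"


def apply_filters(
    chains: Iterable[ChainRecord | FailedChain],
    select25_ids: set[str],
) -> FilterResult:
    """Apply the redundancy / temperature / parse filters.

    ``select25_ids`` holds ``STRUCTURE_CHAIN`` identifiers (one per line
    in a PDB-select-25 style list). Filtering is total: every input chain
    lands either in ``retained`` or in exactly one tally bucket, so
    ``sum(tally.values()) + len(retained) == n_input``.
    """
    ids = {s.strip().upper() for s in select25_ids if s.strip()}
    retained: list[ChainRecord] = []
    tally = {"temperature": 0, "redundancy": 0, "parse": 0}
    for chain in chains:
        if isinstance(chain, FailedChain):
            tally[chain.reason] = tally.get(chain.reason, 0) + 1
            continue
        if f"{chain.structure_id}_{chain.chain_id}".upper() not in ids:
            tally["redundancy"] += 1
            continue
        if chain.temperature <= IMPLAUSIBLE_BELOW_K:
            tally["temperature"] += 1
            continue
        retained.append(chain)
    return FilterResult(retained=retained, tally=tally)


def read_select25_list(path) -> set[str]:
    """Read a plain-text chain list, one ``1ABC_A`` identifier per line."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#")[0].strip()
        if line:
            out.add(line.upper())
    return out


# --------------------------------------------------------------------------
# Counts table (S1-style TSV)
# --------------------------------------------------------------------------

_ID_COLUMNS = ("structure_id", "chain_id", "temperature_K")


def _counts_columns() -> list[str]:
    cols = list(_ID_COLUMNS)
    for aa in AMINO_ACIDS:
        cols += [f"{aa}_n", f"{aa}_buried", f"{aa}_alpha_sum"]
    return cols


def write_counts_table(records: Iterable[ChainCounts], path) -> None:
    """Write per-chain aggregated counts as a tab-separated table."""
    cols = _counts_columns()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(cols)
        for rec in records:
            row: list = [rec.structure_id, rec.chain_id, repr(float(rec.temperature))]
            for i in range(len(AMINO_ACIDS)):
                row += [int(rec.n[i]), int(rec.buried[i]),
                        repr(float(rec.alpha_sum[i]))]
            w.writerow(row)


def read_counts_table(path) -> list[ChainCounts]:
    """Read a counts table written by :func:`write_counts_table`.

    The reader is schema-driven: columns are located by header name, so
    column order is free. A row with the wrong number of fields raises
    :class:`MalformedRow` with file and line number.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise MalformedRow(path, 1, "empty file")
        idx = {name: i for i, name in enumerate(header)}
        missing = [c for c in _counts_columns() if c not in idx]
        if missing:
            raise MalformedRow(path, 1, f"missing columns: {missing[:5]}...")
        records = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise MalformedRow(
                    path, lineno,
                    f"expected {len(header)} columns, found {len(row)}",
                )
            try:
                n = np.array([int(row[idx[f"{aa}_n"]]) for aa in AMINO_ACIDS])
                buried = np.array(
                    [int(row[idx[f"{aa}_buried"]]) for aa in AMINO_ACIDS]
                )
                alpha = np.array(
                    [float(row[idx[f"{aa}_alpha_sum"]]) for aa in AMINO_ACIDS]
                )
                rec = ChainCounts(
                    structure_id=row[idx["structure_id"]],
                    chain_id=row[idx["chain_id"]],
                    temperature=float(row[idx["temperature_K"]]),
                    n=n, buried=buried, alpha_sum=alpha,
                )
            except (ValueError, IndexError) as exc:
                raise MalformedRow(path, lineno, str(exc))
            records.append(rec)
    return records


def write_exclusion_tally(tally: Mapping[str, int], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["reason", "chains"])
        for reason in sorted(tally):
            w.writerow([reason, tally[reason]])
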