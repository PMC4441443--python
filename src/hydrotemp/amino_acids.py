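"""Amino-acid alphabet, class pooling, and maximum accessible surface areas.

The 20 standard residues are kept in a fixed canonical order so that
per-type count vectors can be plain numpy arrays indexed by
:data:`AA_INDEX`.
"""

from __future__ import annotations

from types import MappingProxyType

#: Canonical residue order (alphabetical three-letter codes). All count
#: arrays in :mod:`hydrotemp.potentials` follow this order.
AMINO_ACIDS: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS",
    "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO",
    "SER", "THR", "TRP", "TYR", "VAL",
)

AA_INDEX: MappingProxyType = MappingProxyType(
    {aa: i for i, aa in enumerate(AMINO_ACIDS)}
)

#: DSSP/one-letter to three-letter mapping. Lower-case letters in DSSP
#: output denote half-cystines in disulphide bridges and map to CYS.
ONE_TO_THREE: MappingProxyType = MappingProxyType({
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
})

#: Residue classes used for pooled statistics.
CLASSES: MappingProxyType = MappingProxyType({
    "hydrophobic": ("ALA", "ILE", "LEU", "MET", "VAL"),
    "aromatic": ("HIS", "PHE", "TRP", "TYR"),
    "charged": ("ARG", "ASP", "GLU", "LYS"),
    "polar": ("ASN", "GLN", "SER", "THR"),
    "other": ("CYS", "GLY", "PRO"),
})

#: Pool used as the per-bin reference state: charged + polar residues.
REFERENCE_TYPES: tuple[str, ...] = CLASSES["charged"] + CLASSES["polar"]

#: Theoretical maximum accessible surface areas (Å²) in an extended
#: Gly-X-Gly tripeptide, Tien et al. 2013 (doi:10.1371/journal.pone.0080635).
#: Used as the default normalisation for exposure fractions; any mapping
#: covering all 20 types with positive values may be substituted.
MAX_ASA_THEORETICAL: MappingProxyType = MappingProxyType({
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
})


def validate_max_asa(table: dict) -> dict:
    """Check a max-ASA mapping covers all 20 types with positive areas."""
    missing = [aa for aa in AMINO_ACIDS if aa not in table]
    if missing:
        raise ValueError(f"max-ASA table missing residue types: {missing}")
    bad = [aa for aa in AMINO_ACIDS if not table[aa] > 0]
    if bad:
        raise ValueError(f"max-ASA table has non-positive areas for: {bad}")
    return dict(table)


def resolve_entity(entity: str) -> tuple[str, ...]:
    """Map an entity name (residue type or class name) to member types."""
    if entity in AA_INDEX:
        return (entity,)
    if entity in CLASSES:
        return CLASSES[entity]
    if entity == "reference":
        return REFERENCE_TYPES
    raise KeyError(f"unknown residue type or class: {entity!r}")
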