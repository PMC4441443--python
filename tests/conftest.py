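import numpy as np
import pytest

from hydrotemp.amino_acids import AMINO_ACIDS, MAX_ASA_THEORETICAL
from hydrotemp.ingest import ChainRecord, ResidueExposure


def chain_from_alphas(alphas, structure_id="1ABC", chain_id="A", temperature=298.0):
    """Build a ChainRecord from (aa_type, exposure_fraction) pairs.

    Areas are back-filled as alpha * max_asa so ingest invariants hold.
    """
    residues = []
    for aa, alpha in alphas:
        area = alpha * MAX_ASA_THEORETICAL[aa]
        residues.append(ResidueExposure(aa, (area,), area, alpha))
    return ChainRecord(structure_id, chain_id, float(temperature), tuple(residues))


@pytest.fixture
def simple_chain():
    return chain_from_alphas(
        [("ALA", 0.5), ("ALA", 0.5), ("ARG", 0.1), ("ARG", 0.1)]
    )


@pytest.fixture
def typed_uniform_chains():
    """Exposure distribution independent of residue type: every type
    carries the same alpha pattern (buried fraction 1/3, same mean),
    with type-dependent multiplicities."""
    pattern = (0.05, 0.3, 0.9)
    chains = []
    for temp, mult in ((278.0, 2), (298.0, 3)):
        pairs = []
        for i, aa in enumerate(AMINO_ACIDS):
            for _ in range(1 + (i % 3) * mult):
                pairs.extend((aa, a) for a in pattern)
        chains.append(
            chain_from_alphas(pairs, structure_id=f"U{int(temp)}", temperature=temp)
        )
    return chains


# ---------------------------------------------------------------------------
# DSSP fixture writer: emits standards-compliant fixed-column DSSP output
# ---------------------------------------------------------------------------

_DSSP_PREAMBLE = """\
==== Secondary Structure Definition by the program DSSP, CMBI version 2.0                          ==== DATE=2014-04-01        .
REFERENCE W. KABSCH AND C.SANDER, BIOPOLYMERS 22 (1983) 2577-2637                                                              .
HEADER    TEST PROTEIN                            01-JAN-14   1ABC                                                             .
  {n:4d}  1  0  0  0                                                                                                           .
  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA
"""


def _dssp_line(index, resseq, chain, aa1, acc):
    buf = [" "] * 136
    def put(text, start):
        for k, ch in enumerate(text):
            buf[start + k] = ch
    put(f"{index:5d}", 0)
    put(f"{resseq:5d}", 5)
    put(chain, 11)
    put(aa1, 13)
    put("-", 16)
    put(f"{acc:4d}", 34)
    for int_start, flt_start in ((38, 46), (50, 57), (61, 68), (72, 79)):
        put(f"{0:{45 - 38}d}" if int_start == 38 else f"{0:6d}", int_start)
        buf[flt_start - 1] = ","
        put(f"{0.0:4.1f}", flt_start)
    put(f"{0.0:6.1f}", 103)  # phi
    put(f"{0.0:6.1f}", 109)  # psi
    return "".join(buf).rstrip() + "\n"


def write_dssp_file(path, chains):
    """Write a DSSP file; ``chains`` maps chain_id -> [(aa1, acc), ...]."""
    n = sum(len(v) for v in chains.values())
    lines = [_DSSP_PREAMBLE.format(n=n)]
    index = 0
    for chain_id, residues in chains.items():
        for resseq, (aa1, acc) in enumerate(residues, start=1):
            index += 1
            lines.append(_dssp_line(index, resseq, chain_id, aa1, acc))
    with open(path, "w") as fh:
        fh.writelines(lines)
    return path


@pytest.fixture
def dssp_writer():
    return write_dssp_file


PDB_HEADER_298 = """\
HEADER    HYDROLASE                               01-JAN-14   1ABC
EXPDTA    SOLUTION NMR
REMARK 210  EXPERIMENT TYPE                : NMR
REMARK 210  TEMPERATURE           (KELVIN) : 298
REMARK 210  PH                             : 7.0
"""
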