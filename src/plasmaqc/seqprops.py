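"""Physicochemical protein properties computed from sequence.

Six features feed the enrichment-bias tests: molecular weight, sequence
length, isoelectric point, GRAVY hydropathy, aromaticity and the Guruprasad
instability index.  Everything is recomputed from the amino-acid sequence
(no annotation-database lookups): hydropathy uses the Kyte-Doolittle scale
and instability the Guruprasad dipeptide weight table, both taken from
Biopython's ProtParam data; average residue masses come from Biopython's
IUPAC data.  The isoelectric point is found by bisection of the
Henderson-Hasselbalch net-charge function on pH in [0, 14] with the EMBOSS
pKa set, to |charge| < 1e-4.

Non-standard letters (B, Z, X, U, O) are tolerated: they count toward the
sequence length and the aromaticity denominator but are excluded from the
mass sum, hydropathy average, charge model and instability dipeptides.
"""

from __future__ import annotations

import dataclasses

from Bio.Data.IUPACData import protein_weights
from Bio.SeqUtils.ProtParamData import DIWV, kd

__all__ = ["ProteinProperties", "sequence_properties", "net_charge"]

_STANDARD = set("ACDEFGHIKLMNPQRSTVWY")
_AMBIGUOUS = set("BZXUO")
_WATER = 18.0153

#: average residue masses (free amino acid minus water)
_RESIDUE_MASS = {aa: protein_weights[aa] - _WATER for aa in _STANDARD}

#: EMBOSS pKa values for the charge model
PKA = {
    "nterm": 8.6,
    "cterm": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}
_POSITIVE = ("K", "R", "H")
_NEGATIVE = ("D", "E", "C", "Y")


@dataclasses.dataclass(frozen=True)
class ProteinProperties:
    protein_id: str
    molecular_weight: float   # Da, average masses
    length: int               # residues, ambiguous letters included
    isoelectric_point: float  # pH
    gravy: float              # mean Kyte-Doolittle hydropathy
    aromaticity: float        # (F + W + Y) / length
    instability_index: float  # Guruprasad dipeptide statistic


def _validate(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty protein sequence")
    seq = sequence.upper()
    for pos, letter in enumerate(seq):
        if letter not in _STANDARD and letter not in _AMBIGUOUS:
            raise ValueError(
                f"invalid amino-acid letter {letter!r} at position {pos + 1}"
            )
    return seq


def net_charge(sequence: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge of a sequence at a given pH."""
    seq = _validate(sequence)
    charge = 1.0 / (1.0 + 10.0 ** (ph - PKA["nterm"]))
    charge -= 1.0 / (1.0 + 10.0 ** (PKA["cterm"] - ph))
    for aa in _POSITIVE:
        charge += seq.count(aa) / (1.0 + 10.0 ** (ph - PKA[aa]))
    for aa in _NEGATIVE:
        charge -= seq.count(aa) / (1.0 + 10.0 ** (PKA[aa] - ph))
    return charge


def _isoelectric_point(sequence: str, tol: float = 1e-4) -> float:
    # net charge is strictly decreasing in pH, so plain bisection suffices
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(sequence, mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def sequence_properties(sequence: str, protein_id: str = "") -> ProteinProperties:
    """Compute the six physicochemical features of a protein sequence."""
    seq = _validate(sequence)
    length = len(seq)
    standard = [aa for aa in seq if aa in _STANDARD]
    mw = sum(_RESIDUE_MASS[aa] for aa in standard) + _WATER
    gravy = (
        sum(kd[aa] for aa in standard) / len(standard) if standard else float("nan")
    )
    aromaticity = sum(seq.count(aa) for aa in "FWY") / length
    weight_sum = 0.0
    for a, b in zip(seq, seq[1:]):
        if a in _STANDARD and b in _STANDARD:
            weight_sum += DIWV[a][b]
    instability = 10.0 / length * weight_sum
    return ProteinProperties(
        protein_id=protein_id,
        molecular_weight=mw,
        length=length,
        isoelectric_point=_isoelectric_point(seq),
        gravy=gravy,
        aromaticity=aromaticity,
        instability_index=instability,
    )
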