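"""Protein physical properties: average molecular mass and theoretical pI.

The pI model counts ionizable groups by composition (side chains of
D, E, C, Y, H, K, R plus both termini), evaluates the Henderson-Hasselbalch
net charge, and bisects for its unique root. The default pKa set follows the
Bjellqvist convention used by the ExPASy Compute pI/MW tool, including its
residue-specific terminal pKa adjustments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List

import pandas as pd

#: Average (isotope-abundance-weighted) residue masses in Da.
AVERAGE_RESIDUE_MASS: Dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

WATER_MASS = 18.0153  # Da


class ProteinError(ValueError):
    """Raised for empty or non-canonical amino-acid input."""


def average_mass(protein: str) -> float:
    """Average molecular mass of a protein in kDa.

    Sum of average residue masses plus one water. Raises
    :class:`ProteinError` naming the first offending position if the
    sequence is empty or contains a letter outside the 20 canonical amino
    acids (no ambiguous-residue averaging).
    """
    if not protein:
        raise ProteinError("empty protein sequence")
    total = WATER_MASS
    for i, aa in enumerate(protein):
        try:
            total += AVERAGE_RESIDUE_MASS[aa]
        except KeyError:
            raise ProteinError(
                f"non-canonical amino acid {aa!r} at position {i + 1}"
            ) from None
    return total / 1000.0


@dataclass(frozen=True)
class PkaSet:
    """Named pKa values for the ionizable groups used by the pI model.

    ``nterm_by_residue`` / ``cterm_by_residue`` optionally override the
    terminal pKa depending on the terminal residue identity (the Bjellqvist
    convention); the plain ``nterm``/``cterm`` values apply otherwise.
    """

    name: str
    nterm: float
    cterm: float
    acidic: Dict[str, float]  # side chains deprotonating to -1: D, E, C, Y
    basic: Dict[str, float]   # side chains protonating to +1: H, K, R
    nterm_by_residue: Dict[str, float] = field(default_factory=dict)
    cterm_by_residue: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for v in (
            [self.nterm, self.cterm]
            + list(self.acidic.values())
            + list(self.basic.values())
            + list(self.nterm_by_residue.values())
            + list(self.cterm_by_residue.values())
        ):
            if not 0.0 < v < 14.0:
                raise ValueError(f"pKa {v} outside (0, 14) in set {self.name!r}")


#: ExPASy/Bjellqvist pKa values.
BJELLQVIST = PkaSet(
    name="Bjellqvist",
    nterm=7.5,
    cterm=3.55,
    acidic={"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
    basic={"H": 5.98, "K": 10.0, "R": 12.0},
    nterm_by_residue={"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7},
    cterm_by_residue={"D": 4.55, "E": 4.75},
)


def net_charge(protein: str, ph: float, pka: PkaSet = BJELLQVIST) -> float:
    """Henderson-Hasselbalch net charge of a protein at a given pH."""
    if not protein:
        raise ProteinError("empty protein sequence")

    def pos(pk: float) -> float:
        return 1.0 / (1.0 + 10 ** (ph - pk))

    def neg(pk: float) -> float:
        return -1.0 / (1.0 + 10 ** (pk - ph))

    q = pos(pka.nterm_by_residue.get(protein[0], pka.nterm))
    q += neg(pka.cterm_by_residue.get(protein[-1], pka.cterm))
    for aa, pk in pka.basic.items():
        n = protein.count(aa)
        if n:
            q += n * pos(pk)
    for aa, pk in pka.acidic.items():
        n = protein.count(aa)
        if n:
            q += n * neg(pk)
    return q


def isoelectric_point(protein: str, pka: PkaSet = BJELLQVIST, tol: float = 0.01) -> float:
    """Theoretical pI by bisection of the net-charge function on [0, 14].

    ``net_charge`` is strictly decreasing in pH, so the root is unique; the
    termini alone guarantee a sign change inside the interval.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(protein, mid, pka) > 0.0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def cds_table(features: Iterable) -> pd.DataFrame:
    """Tabulate CDS features: label, lengths, location, strand, mass, pI.

    Mass is formatted to 1 decimal (kDa) and pI to 2 decimals; rows are
    ordered by start coordinate. Mirrors a per-gene annotation table.
    """
    rows: List[dict] = []
    for f in sorted(features, key=lambda f: (f.start, f.end)):
        rows.append(
            {
                "label": f.label,
                "nt_length": f.nt_length,
                "start": f.start,
                "end": f.end,
                "strand": f.strand,
                "aa_length": f.aa_length,
                "mass_kda": round(f.product_mass, 1),
                "pi": round(f.product_pi, 2),
            }
        )
    columns = ["label", "nt_length", "start", "end", "strand", "aa_length", "mass_kda", "pi"]
    return pd.DataFrame(rows, columns=columns)
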