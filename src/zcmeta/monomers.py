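"""Bundled monomer formula/energy table.

Ships formulas and standard Gibbs energies of formation (25 C, 1 bar) for
the 20 amino acids, (deoxy)ribonucleosides, nucleobases, sugars, the
charge -2 nucleoside-5'-monophosphate ions used in DNA formation
energetics, and the inorganic basis species.  Energies are stored
internally in J/mol; the TSV may declare cal/mol or kJ/mol per row.
"""

from __future__ import annotations

import functools
import math
from importlib import resources
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from .chem import ElementalComposition, parse_formula

__all__ = ["MonomerTable", "load_monomers", "AA3", "AA1TO3"]

AA3 = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
)

AA1TO3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}

_UNIT_TO_J = {"J/mol": 1.0, "kJ/mol": 1000.0, "cal/mol": 4.184, "kcal/mol": 4184.0}


class MonomerTable:
    """Lookup of :class:`ElementalComposition` and Gibbs energy by monomer id."""

    def __init__(self, frame: pd.DataFrame):
        self._frame = frame
        self._comps: Dict[str, ElementalComposition] = {}
        self._gibbs: Dict[str, Optional[float]] = {}
        for row in frame.itertuples(index=False):
            comp = parse_formula(
                "" if pd.isna(row.formula) else str(row.formula),
                charge=float(row.charge),
            )
            self._comps[row.id] = comp
            if pd.isna(row.gibbs_energy):
                self._gibbs[row.id] = None
            else:
                factor = _UNIT_TO_J[str(row.gibbs_units)]
                self._gibbs[row.id] = float(row.gibbs_energy) * factor

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MonomerTable":
        frame = pd.read_csv(path, sep="\t", comment="#")
        required = {"id", "formula", "charge", "gibbs_energy", "gibbs_units", "source"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"monomer table missing columns: {sorted(missing)}")
        return cls(frame)

    def __contains__(self, monomer_id: str) -> bool:
        return monomer_id in self._comps

    def ids(self):
        return list(self._comps)

    def composition(self, monomer_id: str) -> ElementalComposition:
        try:
            return self._comps[monomer_id]
        except KeyError:
            raise KeyError(f"unknown monomer id {monomer_id!r}") from None

    def gibbs(self, monomer_id: str) -> float:
        """Standard Gibbs energy of formation in J/mol."""
        if monomer_id not in self._comps:
            raise KeyError(f"unknown monomer id {monomer_id!r}")
        value = self._gibbs[monomer_id]
        if value is None or math.isnan(value):
            raise ValueError(f"no Gibbs energy tabulated for {monomer_id!r}")
        return value

    def charge(self, monomer_id: str) -> float:
        return self.composition(monomer_id).z

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()


@functools.lru_cache(maxsize=1)
def load_monomers() -> MonomerTable:
    """The bundled monomer table (cached)."""
    with resources.as_file(resources.files("zcmeta.data") / "monomers.tsv") as path:
        return MonomerTable.from_tsv(path)
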