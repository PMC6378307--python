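"""Per-monomer formation-reaction energetics along an Eh gradient.

The overall synthesis of an average DNA base pair (two charge -2
nucleotide-monophosphate ions) or an average amino acid is written as a
formation reaction from a fixed set of inorganic basis species, with the
electron as the redox handle: log a(e-) = -F*Eh/(2.303*R*T).  Chemical
affinity A = RT ln(K/Q) is reported in dimensionless log units
A/(2.303*R*T); because the basis activities are constants, each curve is
affine in Eh with slope -n_e * F/(2.303*R*T), where n_e is the number of
electrons in the reaction.  For products built from C, H, N, O, S with the
default basis (N as NH4+, S as HS-), n_e = c*(4 - Z_C): the mechanism that
ties carbon oxidation state to redox sensitivity.

Relative affinities subtract, at each Eh, the mean over all samples in a
dataset; they are the reported quantity and are invariant to any constant
common to all samples (product activity convention, polymerisation water).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import ElementalComposition, combine, zc
from .monomers import AA1TO3, MonomerTable, load_monomers
from .sequences import SamplePool

__all__ = [
    "FARADAY",
    "GAS_CONSTANT",
    "BasisSet",
    "MonomerReaction",
    "AffinityCurve",
    "default_basis",
    "default_eh_grid",
    "average_monomer",
    "balance",
    "affinity_curve",
    "relative_affinity",
    "quadrant_classify",
]

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.31446  # J/(mol K)
LN10 = 2.302585092994046

#: basis species and fixed log-activities: H2O (0), HCO3- (-3), H2PO4- (-5),
#: NH4+ (-7), HS- (-9), H+ (-7, i.e. pH 7); the electron is Eh-driven.
DEFAULT_LOG_ACTIVITIES: Dict[str, float] = {
    "H2O": 0.0,
    "HCO3-": -3.0,
    "H2PO4-": -5.0,
    "NH4+": -7.0,
    "HS-": -9.0,
    "H+": -7.0,
}

ELECTRON = "e-"
_ELEMENT_ROWS = ("c", "h", "n", "o", "s", "p", "z")


@dataclass
class BasisSet:
    """Full-rank set of basis species with fixed log-activities.

    The electron is a distinguished member whose log-activity is supplied
    per Eh point rather than fixed.
    """

    names: List[str]
    compositions: List[ElementalComposition]
    gibbs: List[float]  # J/mol
    log_activities: Dict[str, float]
    electron: str = ELECTRON

    def __post_init__(self) -> None:
        if self.electron not in self.names:
            raise ValueError("basis must include the electron")
        matrix = self.matrix()
        if np.linalg.matrix_rank(matrix) < len(self.names):
            raise ValueError("basis element/charge matrix is rank-deficient")

    def matrix(self) -> np.ndarray:
        """Element+charge matrix, rows C,H,N,O,S,P,charge x columns species."""
        return np.array(
            [[getattr(comp, row) for comp in self.compositions] for row in _ELEMENT_ROWS]
        )

    @property
    def electron_index(self) -> int:
        return self.names.index(self.electron)


def default_basis(
    table: Optional[MonomerTable] = None,
    log_activities: Optional[Mapping[str, float]] = None,
) -> BasisSet:
    """The default basis: H2O, HCO3-, H2PO4-, NH4+, HS-, H+, e-."""
    table = table or load_monomers()
    acts = dict(DEFAULT_LOG_ACTIVITIES)
    if log_activities:
        acts.update(log_activities)
    names = ["H2O", "HCO3-", "H2PO4-", "NH4+", "HS-", "H+", ELECTRON]
    return BasisSet(
        names=names,
        compositions=[table.composition(n) for n in names],
        gibbs=[table.gibbs(n) for n in names],
        log_activities=acts,
    )


def default_eh_grid(eh_min: float = -0.35, eh_max: float = 0.05, steps: int = 128) -> np.ndarray:
    """Default Eh grid in volts."""
    return np.linspace(eh_min, eh_max, steps)


@dataclass
class MonomerReaction:
    """Balanced formation reaction of one average monomer from the basis."""

    product: ElementalComposition
    product_gibbs: float  # J/mol
    basis: BasisSet
    coefficients: Dict[str, float]
    label: str = ""

    @property
    def n_electrons(self) -> float:
        return self.coefficients[self.basis.electron]

    def delta_g_standard(self) -> float:
        """Standard Gibbs energy of the reaction (J/mol of product)."""
        consumed = sum(
            self.coefficients[name] * g
            for name, g in zip(self.basis.names, self.basis.gibbs)
        )
        return self.product_gibbs - consumed

    def log_k(self, temperature: float = 298.15) -> float:
        return -self.delta_g_standard() / (LN10 * GAS_CONSTANT * temperature)


_DNA_PAIR_MONOMERS = {"AT": ("dAMP", "dTMP"), "GC": ("dGMP", "dCMP")}


def average_monomer(
    pool: SamplePool,
    kind: str,
    table: Optional[MonomerTable] = None,
) -> Tuple[ElementalComposition, float]:
    """Mole-weighted mean formula and Gibbs energy of the sample's monomer.

    ``kind="dna"``: one average nucleotide-monophosphate base pair (two
    NMP2- ions summed), weighted by A-T and G-C pair counts.  Z_C of this
    product equals the nucleoside-based dsDNA value because the phosphate
    is carried in the formula but cancels in Z_C.
    ``kind="protein"``: one average amino acid, weighted by aa counts.
    Raises naming the species if a Gibbs entry is missing.
    """
    table = table or load_monomers()
    parts: List[Tuple[ElementalComposition, float]] = []
    gibbs_terms: List[Tuple[float, float]] = []
    if kind == "dna":
        weights = {p: float(pool.pair_counts.get(p, 0)) for p in ("AT", "GC")}
        total = sum(weights.values())
        if total == 0:
            raise ValueError("average_monomer: pool has no base pairs")
        for pair, w in weights.items():
            comp = ElementalComposition()
            g = 0.0
            for monomer in _DNA_PAIR_MONOMERS[pair]:
                comp = comp + table.composition(monomer)
                g += table.gibbs(monomer)
            parts.append((comp, w))
            gibbs_terms.append((g, w))
    elif kind == "protein":
        total = sum(pool.aa_counts.values())
        if total == 0:
            raise ValueError("average_monomer: pool has no amino acids")
        for aa, count in pool.aa_counts.items():
            name = AA1TO3.get(aa, aa)
            parts.append((table.composition(name), float(count)))
            gibbs_terms.append((table.gibbs(name), float(count)))
    else:
        raise ValueError(f"unknown kind {kind!r}")
    wsum = sum(w for _, w in parts)
    comp = combine(parts) * (1.0 / wsum)
    gibbs = sum(g * w for g, w in gibbs_terms) / wsum
    return comp, gibbs


def balance(
    product: ElementalComposition,
    product_gibbs: float,
    basis: Optional[BasisSet] = None,
    label: str = "",
    residual_tol: float = 1e-9,
) -> MonomerReaction:
    """Unique basis-species coefficients forming ``product``.

    Solves element (C,H,N,O,S,P) and charge conservation; a negative
    coefficient means the species is produced (e.g. water released by the
    condensation-balanced reaction).
    """
    basis = basis or default_basis()
    matrix = basis.matrix()
    target = np.array([getattr(product, row) for row in _ELEMENT_ROWS], dtype=float)
    try:
        coeffs = np.linalg.solve(matrix, target)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular basis matrix: {exc}") from exc
    residual = np.abs(matrix @ coeffs - target).max()
    if residual > residual_tol:
        raise ValueError(f"balance residual {residual:g} exceeds {residual_tol:g}")
    return MonomerReaction(
        product=product,
        product_gibbs=product_gibbs,
        basis=basis,
        coefficients=dict(zip(basis.names, coeffs)),
        label=label,
    )


@dataclass
class AffinityCurve:
    """Per-monomer affinity (dimensionless log units) on an Eh grid."""

    eh: np.ndarray
    loga: np.ndarray
    sample: str = ""
    kind: str = ""
    relative: bool = False

    def to_kj_per_mol(self, temperature: float = 298.15) -> np.ndarray:
        """Affinity in kJ per mol of monomer."""
        return self.loga * LN10 * GAS_CONSTANT * temperature / 1000.0


def affinity_curve(
    rxn: MonomerReaction,
    eh_grid: Optional[np.ndarray] = None,
    temperature: float = 298.15,
    kind: str = "",
) -> AffinityCurve:
    """Affinity of the formation reaction as a function of Eh.

    A/(2.303RT) = log K - log Q with unit product activity, fixed basis
    activities, and log a(e-) = -F*Eh/(2.303*R*T).  Strictly decreasing in
    Eh whenever the reaction consumes electrons.
    """
    eh = default_eh_grid() if eh_grid is None else np.asarray(eh_grid, dtype=float)
    log_k = rxn.log_k(temperature)
    fixed = sum(
        coeff * rxn.basis.log_activities[name]
        for name, coeff in rxn.coefficients.items()
        if name != rxn.basis.electron
    )
    log_a_electron = -FARADAY * eh / (LN10 * GAS_CONSTANT * temperature)
    loga = log_k + fixed + rxn.n_electrons * log_a_electron
    return AffinityCurve(eh=eh, loga=loga, sample=rxn.label, kind=kind)


def relative_affinity(curves: Sequence[AffinityCurve]) -> List[AffinityCurve]:
    """Subtract, at every Eh, the mean affinity over all samples.

    The returned curves sum to zero at each grid point.  Requires at least
    two samples on a common grid.
    """
    if len(curves) < 2:
        raise ValueError("relative_affinity requires >= 2 samples")
    grid = curves[0].eh
    for c in curves[1:]:
        if c.eh.shape != grid.shape or not np.allclose(c.eh, grid):
            raise ValueError("all curves must share the same Eh grid")
    mean = np.mean([c.loga for c in curves], axis=0)
    return [
        AffinityCurve(eh=grid, loga=c.loga - mean, sample=c.sample,
                      kind=c.kind, relative=True)
        for c in curves
    ]


def quadrant_classify(
    dna_rel: Sequence[AffinityCurve],
    protein_rel: Sequence[AffinityCurve],
    reducing_samples: Sequence[str],
    oxidizing_samples: Sequence[str],
) -> Tuple[bool, pd.DataFrame]:
    """Do the designated gradient endpoints land in quadrant I?

    The most-reducing samples are evaluated at the low-Eh end of the grid
    and the most-oxidizing samples at the high-Eh end; the model "hangs
    together" (returns True) iff every designated (DNA, protein) relative
    affinity pair is strictly positive in both coordinates.
    """
    dna_by = {c.sample: c for c in dna_rel}
    pro_by = {c.sample: c for c in protein_rel}
    rows = []
    verdict = True
    for role, samples in (("reducing", reducing_samples), ("oxidizing", oxidizing_samples)):
        for sample in samples:
            if sample not in dna_by or sample not in pro_by:
                raise ValueError(f"sample {sample!r} missing from relative-affinity curves")
            idx = 0 if role == "reducing" else -1
            d = float(dna_by[sample].loga[idx])
            p = float(pro_by[sample].loga[idx])
            in_q1 = d > 0 and p > 0
            verdict = verdict and in_q1
            rows.append(
                {"sample": sample, "role": role,
                 "eh": float(dna_by[sample].eh[idx]),
                 "rel_affinity_dna": d, "rel_affinity_protein": p,
                 "quadrant_1": in_q1}
            )
    return verdict, pd.DataFrame(rows)
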