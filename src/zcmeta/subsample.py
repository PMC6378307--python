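"""Subsampling-based uncertainty for Z_C estimates.

Intra-sample variation is estimated by drawing random subsamples of reads
(or protein sequences) that contain, on average, a target number of bases
or amino acids, recomputing Z_C on each subsample, and reporting the mean
and standard deviation over replicates.  The subsampling unit is the whole
read: each sequence enters a replicate independently with probability
p = target_units / total_units (Bernoulli inclusion), the only
interpretation consistent with hitting a base target "on average" over
variable-length reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .monomers import AA1TO3, MonomerTable, load_monomers
from .sequences import ReadSet

__all__ = ["ZcEstimate", "subsample_zc", "species_zc"]

_DNA_BASES = "ACGT"
_RNA_BASES = "ACGU"
_AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ZcEstimate:
    """Mean and sd of Z_C over subsampling replicates."""

    mean: float
    sd: float
    reps: int
    target_units: int
    unit_kind: str  # "bases" | "amino-acids"


def _monomer_weights(
    kind: str, table: MonomerTable, thymine_variant: bool = False
) -> Tuple[str, np.ndarray, np.ndarray]:
    """Per-symbol Z_C numerator and carbon count for pooled counts.

    Z_C of a pooled composition is linear in the counts:
    zc = (counts . num) / (counts . carbon), which lets each replicate be
    scored from a masked count-matrix sum without rebuilding compositions.
    """
    def numcar(comp):
        return (-comp.h + 3 * comp.n + 2 * comp.o + 2 * comp.s, comp.c)

    if kind == "dna":
        at = table.composition("dA") + table.composition("dT")
        gc = table.composition("dG") + table.composition("dC")
        per = {"A": numcar(at), "T": numcar(at), "G": numcar(gc), "C": numcar(gc)}
        alphabet = _DNA_BASES
    elif kind == "rna":
        names = (
            {"A": "rA", "C": "rC", "G": "rG", "U": "rT"}
            if thymine_variant
            else {"A": "rA", "C": "rC", "G": "rG", "U": "rU"}
        )
        per = {b: numcar(table.composition(m)) for b, m in names.items()}
        alphabet = _RNA_BASES
    elif kind == "protein":
        per = {a: numcar(table.composition(AA1TO3[a])) for a in _AA_ORDER}
        alphabet = _AA_ORDER
    else:
        raise ValueError(f"unknown kind {kind!r}")
    num = np.array([per[ch][0] for ch in alphabet], dtype=float)
    car = np.array([per[ch][1] for ch in alphabet], dtype=float)
    return alphabet, num, car


def _count_matrix(seqs, alphabet: str, map_t_to_u: bool) -> np.ndarray:
    mat = np.zeros((len(seqs), len(alphabet)), dtype=np.int64)
    for i, seq in enumerate(seqs):
        for j, ch in enumerate(alphabet):
            mat[i, j] = seq.count(ch)
        if map_t_to_u:
            mat[i, alphabet.index("U")] += seq.count("T")
    return mat


def subsample_zc(
    source: ReadSet,
    kind: str = "dna",
    target_units: int = 50000,
    reps: int = 100,
    seed: int | np.random.SeedSequence = 0,
    table: Optional[MonomerTable] = None,
    thymine_variant: bool = False,
    return_compositions: bool = False,
):
    """Z_C mean and sd over ``reps`` random read subsamples.

    ``kind`` selects the pooled Z_C function: "dna" (double-strand paired
    nucleoside composition), "rna" (ribonucleosides, T read as U) or
    "protein" (amino-acid compositions; sequences are protein strings).
    A replicate that happens to include zero countable units is redrawn so
    that the replicate count stays fixed.  Fully reproducible from ``seed``.

    With ``return_compositions=True`` also returns the per-replicate
    monomer-count table (one row per replicate).
    """
    table = table or load_monomers()
    alphabet, num, car = _monomer_weights(kind, table, thymine_variant)
    mat = _count_matrix(source.seqs, alphabet, map_t_to_u=(kind == "rna"))
    units = mat.sum(axis=1)
    total = int(units.sum())
    if total <= 0:
        raise ValueError("subsample_zc: source has no countable units")
    if target_units > total:
        raise ValueError(
            f"target_units ({target_units}) exceeds source total ({total})"
        )
    p = target_units / total
    rng = np.random.default_rng(seed)
    n = len(source.seqs)
    sums = np.empty((reps, len(alphabet)), dtype=float)
    for r in range(reps):
        while True:
            mask = rng.random(n) < p
            rep_sum = mask @ mat
            if rep_sum.sum() > 0:
                break
            # zero-unit replicate: redraw to keep the replicate count fixed
        sums[r] = rep_sum
    values = (sums @ num) / (sums @ car)
    estimate = ZcEstimate(
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if reps >= 2 else 0.0,
        reps=reps,
        target_units=target_units,
        unit_kind="amino-acids" if kind == "protein" else "bases",
    )
    if return_compositions:
        comp = pd.DataFrame(sums.astype(np.int64), columns=list(alphabet))
        comp.insert(0, "replicate", np.arange(1, reps + 1))
        comp["zc"] = values
        return estimate, comp
    return estimate


def species_zc(
    taxon_reads: Mapping[str, ReadSet],
    target_units: int = 10000,
    reps: int = 100,
    seed: int = 0,
    table: Optional[MonomerTable] = None,
) -> Dict[str, ZcEstimate]:
    """Per-taxon dsDNA Z_C estimates from smaller (10 kb) subsamples.

    Taxa are processed in sorted order with independent child seeds so the
    result does not depend on mapping iteration order.
    """
    root = np.random.SeedSequence(seed)
    taxa = sorted(taxon_reads)
    children = root.spawn(len(taxa))
    return {
        taxon: subsample_zc(
            taxon_reads[taxon], kind="dna", target_units=target_units,
            reps=reps, seed=child, table=table,
        )
        for taxon, child in zip(taxa, children)
    }
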