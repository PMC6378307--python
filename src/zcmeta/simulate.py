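"""Synthetic metagenome gradients with known truth.

Generates read sets, coding sequences and proteins whose composition is
controlled, so that every pipeline stage (filtering, dereplication, base
pairing, subsampling, thermodynamics) can be tested without downloading
real data.  Bases are i.i.d. with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2;
no dinucleotide structure is simulated because every downstream statistic
depends only on composition.  An optional GC-skew knob shifts G vs C (and
A vs T) on the emitted single strands, which lets the double-strand
pairing invariance be verified.  Amino-acid usage along a gradient is
tilted by a single parameter alpha: weights proportional to
exp(alpha * Z_C(aa)), so alpha < 0 favours reduced residues (Leu-like) and
alpha > 0 oxidised ones (Gly-like).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .chem import zc
from .monomers import AA1TO3, load_monomers
from .sequences import ReadSet, zc_dsdna_gc, zc_protein, zc_rna

__all__ = [
    "GradientSpec",
    "aa_profile",
    "gen_reads",
    "gen_cds",
    "gen_gradient",
]

_AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"


def _codons_by_aa() -> Dict[str, List[str]]:
    table = CodonTable.unambiguous_dna_by_id[1]  # the standard genetic code
    out: Dict[str, List[str]] = {}
    for codon, aa in table.forward_table.items():
        out.setdefault(aa, []).append(codon)
    return {aa: sorted(codons) for aa, codons in out.items()}


def aa_profile(alpha: float) -> Dict[str, float]:
    """Amino-acid frequencies tilted by carbon oxidation state.

    Starts from the uniform distribution over the 20 amino acids and
    re-weights by exp(alpha * Z_C); alpha = 0 recovers uniform usage.
    """
    table = load_monomers()
    weights = {
        aa: float(np.exp(alpha * zc(table.composition(AA1TO3[aa]))))
        for aa in _AA_ORDER
    }
    total = sum(weights.values())
    return {aa: w / total for aa, w in weights.items()}


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _draw_lengths(rng, n: int, mean: float, sd: float, minimum: int) -> np.ndarray:
    lengths = np.rint(rng.normal(mean, sd, size=n)).astype(int)
    return np.maximum(lengths, minimum)


def gen_reads(
    gc: float,
    n_reads: int,
    length_mean: float = 150.0,
    length_sd: float = 20.0,
    ambig_rate: float = 0.0,
    dup_rate: float = 0.0,
    gc_skew: float = 0.0,
    dup_mode: str = "exact",
    prefix_len: int = 50,
    seed=0,
    label: str = "sample",
) -> Tuple[ReadSet, Dict]:
    """i.i.d. reads at a known GC fraction, with controlled contamination.

    ``ambig_rate`` replaces bases by N independently; ``dup_rate`` is the
    expected fraction of artificial duplicate reads appended to the set
    (``dup_mode="exact"`` copies whole reads, ``"prefix"`` copies the
    leading ``prefix_len`` bases and regenerates the tail).  ``gc_skew``
    in [-1, 1] shifts G vs C (and A vs T) on the emitted strand while
    keeping the GC fraction fixed.  Returns the reads and a truth record
    (true GC, number of injected duplicates, ...).
    """
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    if not -1.0 <= gc_skew <= 1.0:
        raise ValueError("gc_skew must lie in [-1, 1]")
    if not 0.0 <= ambig_rate <= 1.0 or not 0.0 <= dup_rate <= 1.0:
        raise ValueError("rates must lie in [0, 1]")
    rng = _rng(seed)
    probs = np.array(
        [
            (1 - gc) / 2 * (1 + gc_skew),  # A
            gc / 2 * (1 - gc_skew),        # C
            gc / 2 * (1 + gc_skew),        # G
            (1 - gc) / 2 * (1 - gc_skew),  # T
        ]
    )
    lengths = _draw_lengths(rng, n_reads, length_mean, length_sd, minimum=30)
    total = int(lengths.sum())
    letters = np.frombuffer(b"ACGT", dtype=np.uint8)
    bases = rng.choice(letters, size=total, p=probs)
    if ambig_rate > 0:
        bases = bases.copy()
        bases[rng.random(total) < ambig_rate] = ord("N")
    bounds = np.cumsum(lengths)[:-1]
    seqs = [chunk.tobytes().decode() for chunk in np.split(bases, bounds)]
    ids = [f"{label}_r{i}" for i in range(n_reads)]

    n_dup = int(rng.binomial(n_reads, dup_rate))
    dup_origins = rng.integers(0, n_reads, size=n_dup)
    for k, origin in enumerate(dup_origins):
        src = seqs[origin]
        if dup_mode == "exact":
            dup = src
        elif dup_mode == "prefix":
            tail_len = max(len(src) - prefix_len, 0)
            tail = rng.choice(letters, size=tail_len, p=probs).tobytes().decode()
            dup = src[:prefix_len] + tail
        else:
            raise ValueError(f"unknown dup_mode {dup_mode!r}")
        seqs.append(dup)
        ids.append(f"{label}_dup{k}_of_r{origin}")

    truth = {
        "label": label,
        "gc_true": gc,
        "n_reads": n_reads,
        "n_duplicates": n_dup,
        "zc_dna_true": zc_dsdna_gc(gc),
    }
    return ReadSet(ids, seqs, label), truth


def gen_cds(
    aa_freqs: Optional[Dict[str, float]] = None,
    codon_weights: Optional[Dict[str, float]] = None,
    n_genes: int = 200,
    length_mean: float = 50.0,
    length_sd: float = 10.0,
    neg_fraction: float = 0.5,
    seed=0,
    label: str = "sample",
) -> Dict:
    """Coding sequences drawn from an amino-acid (or codon) usage table.

    Either ``aa_freqs`` (codons uniform among synonyms) or explicit
    ``codon_weights`` must be given.  Lengths are in codons.  A random
    fraction of genes is emitted negative-sense with '-' strand labels, to
    exercise re-orientation.  Returns a dict with the emitted ``cds``
    ReadSet, ``strands`` labels, ``proteins`` ReadSet, the positive-sense
    ``cds_positive`` truth, and a ``truth`` record with the expected
    protein and mRNA Z_C implied by the usage table.
    """
    rng = _rng(seed)
    syn = _codons_by_aa()
    if codon_weights is not None:
        codons = sorted(codon_weights)
        w = np.array([codon_weights[c] for c in codons], dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("invalid codon weights")
        probs = w / w.sum()
        table = CodonTable.unambiguous_dna_by_id[1]
        for c in codons:
            if c not in table.forward_table:
                raise ValueError(f"codon {c!r} is not an amino-acid codon")
    elif aa_freqs is not None:
        w = np.array([aa_freqs.get(aa, 0.0) for aa in _AA_ORDER], dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("invalid amino-acid frequencies")
        aa_probs = w / w.sum()
        codons, probs_list = [], []
        for aa, p_aa in zip(_AA_ORDER, aa_probs):
            for codon in syn[aa]:
                codons.append(codon)
                probs_list.append(p_aa / len(syn[aa]))
        probs = np.array(probs_list)
    else:
        raise ValueError("provide aa_freqs or codon_weights")

    lengths = _draw_lengths(rng, n_genes, length_mean, length_sd, minimum=10)
    gene_codons = [rng.choice(len(codons), size=int(m), p=probs) for m in lengths]
    cds_pos = ["".join(codons[j] for j in g) for g in gene_codons]
    translate = CodonTable.unambiguous_dna_by_id[1].forward_table
    proteins = ["".join(translate[codons[j]] for j in g) for g in gene_codons]

    strands = ["-" if rng.random() < neg_fraction else "+" for _ in range(n_genes)]
    emitted = [
        str(Seq(s).reverse_complement()) if strand == "-" else s
        for s, strand in zip(cds_pos, strands)
    ]
    ids = [f"{label}_g{i}_1_{len(cds_pos[i])}_{strands[i]}" for i in range(n_genes)]

    # expectations implied by the usage table, via the same Z_C machinery
    exp_rna = Counter()
    exp_aa = Counter()
    for codon, p in zip(codons, probs):
        for ch in codon:
            exp_rna["U" if ch == "T" else ch] += p
        exp_aa[translate[codon]] += p
    truth = {
        "label": label,
        "zc_protein_true": zc_protein(exp_aa),
        "zc_rna_true": zc_rna(exp_rna),
        "n_genes": n_genes,
    }
    return {
        "cds": ReadSet(ids, emitted, label),
        "strands": strands,
        "proteins": ReadSet(ids, proteins, label),
        "cds_positive": ReadSet(ids, cds_pos, label),
        "truth": truth,
    }


@dataclass
class GradientSpec:
    """Study conditions for a synthetic multi-sample redox gradient.

    Defaults describe a five-sample gradient whose DNA GC content rises
    from 0.30 to 0.60 and whose protein composition co-varies (alpha from
    -0.8 to +0.8), i.e. both DNA and proteins become more oxidised toward
    the oxidizing end, the configuration the thermodynamic model calls
    coherent.  Setting ``gc_range`` decreasing while alpha increases makes
    an OMZ-like inverted gradient.
    """

    n_samples: int = 5
    gc_range: Tuple[float, float] = (0.30, 0.60)
    alpha_range: Tuple[float, float] = (-0.8, 0.8)
    reads_per_sample: int = 1000
    length_mean: float = 150.0
    length_sd: float = 20.0
    ambig_rate: float = 0.002
    dup_rate: float = 0.02
    coding_fraction: float = 0.3
    cds_length_mean: float = 50.0
    cds_length_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for g in self.gc_range:
            if not 0.0 < g < 1.0:
                raise ValueError("gc_range values must lie in (0, 1)")
        for r in (self.ambig_rate, self.dup_rate, self.coding_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


def gen_gradient(spec: GradientSpec, out_dir: str | Path) -> Tuple[Path, pd.DataFrame]:
    """Write one synthetic sample per gradient point plus manifest and truth.

    Returns the manifest path and the truth table (per-sample true GC,
    closed-form DNA Z_C, and usage-implied RNA/protein Z_C).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.n_samples)
    gcs = np.linspace(*spec.gc_range, spec.n_samples)
    alphas = np.linspace(*spec.alpha_range, spec.n_samples)
    manifest_rows = []
    truth_rows = []
    for i, (gc, alpha, child) in enumerate(zip(gcs, alphas, children)):
        label = f"S{i + 1}"
        read_seed, cds_seed = child.spawn(2)
        reads, read_truth = gen_reads(
            gc=float(gc),
            n_reads=spec.reads_per_sample,
            length_mean=spec.length_mean,
            length_sd=spec.length_sd,
            ambig_rate=spec.ambig_rate,
            dup_rate=spec.dup_rate,
            seed=np.random.default_rng(read_seed),
            label=label,
        )
        n_genes = max(1, round(spec.coding_fraction * spec.reads_per_sample))
        genes = gen_cds(
            aa_freqs=aa_profile(float(alpha)),
            n_genes=n_genes,
            length_mean=spec.cds_length_mean,
            length_sd=spec.cds_length_sd,
            seed=np.random.default_rng(cds_seed),
            label=label,
        )
        reads_path = out_dir / f"{label}_reads.fasta"
        cds_path = out_dir / f"{label}_cds.fasta"
        prot_path = out_dir / f"{label}_proteins.fasta"
        strands_path = out_dir / f"{label}_strands.tsv"
        reads.to_fasta(reads_path)
        genes["cds"].to_fasta(cds_path)
        genes["proteins"].to_fasta(prot_path)
        with open(strands_path, "w") as fh:
            for rid, strand in zip(genes["cds"].ids, genes["strands"]):
                fh.write(f"{rid}\t{strand}\n")
        redox = (
            "reducing" if i == 0
            else "oxidizing" if i == spec.n_samples - 1
            else "transition"
        )
        manifest_rows.append(
            {"label": label, "reads": reads_path.name, "cds": cds_path.name,
             "proteins": prot_path.name, "strands": strands_path.name,
             "taxa": "", "rank": i + 1, "redox": redox, "kind": "reads"}
        )
        truth_rows.append(
            {"label": label, "gc_true": gc, "alpha": alpha,
             "zc_dna_true": read_truth["zc_dna_true"],
             "zc_rna_true": genes["truth"]["zc_rna_true"],
             "zc_protein_true": genes["truth"]["zc_protein_true"],
             "n_duplicates": read_truth["n_duplicates"]}
        )
    manifest = pd.DataFrame(manifest_rows)
    truth = pd.DataFrame(truth_rows)
    manifest_path = out_dir / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False, float_format="%.6g")
    return manifest_path, truth
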