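"""From sequence files to pooled elemental compositions.

Implements the read-level processing that precedes the Z_C calculation:
length/ambiguity filtering, dereplication of artificial duplicate reads,
base counting with double-strand pairing, mRNA and protein pooling, and
per-taxon pools.  Adapter trimming, rRNA identification, gene calling and
taxonomic classification are deliberately external: this module ingests
their outputs (FASTA/FASTQ, strand labels, read-to-taxon tables).
"""

from __future__ import annotations

import statistics
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq

from .chem import ElementalComposition, combine, zc
from .monomers import AA1TO3, AA3, MonomerTable, load_monomers

__all__ = [
    "ReadSet",
    "SamplePool",
    "read_fasta",
    "length_filter",
    "dereplicate",
    "pool_dsdna",
    "gc_content",
    "zc_dsdna",
    "zc_dsdna_gc",
    "zc_rna",
    "zc_protein",
    "orient_cds",
    "rna_counts_from_cds",
    "aa_counts_from_proteins",
    "taxon_read_sets",
    "taxon_pools",
    "strand_from_fgs_header",
]

_ACGT = frozenset("ACGT")


@dataclass
class ReadSet:
    """An ordered set of nucleotide (or amino-acid) sequences with ids."""

    ids: List[str]
    seqs: List[str]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs length mismatch")

    def __len__(self) -> int:
        return len(self.seqs)

    def __iter__(self):
        return iter(zip(self.ids, self.seqs))

    @property
    def total_bases(self) -> int:
        return sum(len(s) for s in self.seqs)

    def subset(self, keep: Sequence[int]) -> "ReadSet":
        return ReadSet(
            [self.ids[i] for i in keep], [self.seqs[i] for i in keep], self.label
        )

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid, seq in self:
                fh.write(f">{rid}\n{seq}\n")


def read_fasta(path: str | Path, label: str = "", max_bases: Optional[int] = None) -> ReadSet:
    """Load FASTA or FASTQ (qualities ignored); format chosen by extension.

    ``max_bases`` truncates the file after that many sequence characters
    have been read, emulating analysis of partial downloads.
    """
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fq", ".fastq"} else "fasta"
    ids: List[str] = []
    seqs: List[str] = []
    total = 0
    for rec in SeqIO.parse(str(path), fmt):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
        total += len(seqs[-1])
        if max_bases is not None and total >= max_bases:
            break
    return ReadSet(ids, seqs, label or path.stem)


def _n_ambiguous(seq: str) -> int:
    return sum(1 for ch in seq if ch not in _ACGT)


def length_filter(reads: ReadSet, max_ambiguous: int = 5) -> ReadSet:
    """Drop reads with length outside mean +/- 2 sd, or too many ambiguous bases.

    The standard deviation is the population sd of the input read lengths;
    reads exactly on the boundary are kept.  Reads with more than
    ``max_ambiguous`` non-ACGT characters are removed regardless of length.
    """
    if len(reads) == 0:
        raise ValueError("length_filter: empty read set")
    lengths = [len(s) for s in reads.seqs]
    if len(lengths) >= 2:
        mean = statistics.fmean(lengths)
        sd = statistics.pstdev(lengths)
        lo, hi = mean - 2.0 * sd, mean + 2.0 * sd
    else:
        lo, hi = float("-inf"), float("inf")
    keep = [
        i
        for i, s in enumerate(reads.seqs)
        if lo <= len(s) <= hi and _n_ambiguous(s) <= max_ambiguous
    ]
    return reads.subset(keep)


def dereplicate(reads: ReadSet, prefix_len: int = 50) -> ReadSet:
    """Remove artificial duplicate reads by identical leading prefix.

    Reads sharing the same first ``prefix_len`` bases (or the same full
    sequence, if shorter) are collapsed to the first occurrence, following
    the MG-RAST artificial-duplicate-read convention.
    """
    if prefix_len < 1:
        raise ValueError("prefix_len must be >= 1")
    seen = set()
    keep = []
    for i, seq in enumerate(reads.seqs):
        key = seq[:prefix_len]
        if key not in seen:
            seen.add(key)
            keep.append(i)
    return reads.subset(keep)


@dataclass
class SamplePool:
    """Per-sample monomer counts with gradient metadata.

    ``pair_counts`` follows double-strand base pairing: every counted A or
    T contributes one A-T pair and every counted G or C one G-C pair, so
    ``pair_counts['AT'] == base_counts['A'] + base_counts['T']``.
    """

    name: str = ""
    base_counts: Counter = field(default_factory=Counter)
    pair_counts: Counter = field(default_factory=Counter)
    aa_counts: Counter = field(default_factory=Counter)
    rna_counts: Counter = field(default_factory=Counter)
    gradient_rank: Optional[float] = None
    redox: str = ""


def pool_dsdna(
    reads: ReadSet,
    name: str = "",
    gradient_rank: Optional[float] = None,
    redox: str = "",
) -> SamplePool:
    """Count bases (ambiguity codes excluded) and base-pair them to dsDNA."""
    counts: Counter = Counter()
    for seq in reads.seqs:
        counts.update(seq)
    base_counts = Counter({b: counts.get(b, 0) for b in "ACGT"})
    total = sum(base_counts.values())
    if total == 0:
        raise ValueError("pool_dsdna: no unambiguous bases to count")
    pair_counts = Counter(
        {"AT": base_counts["A"] + base_counts["T"],
         "GC": base_counts["G"] + base_counts["C"]}
    )
    return SamplePool(
        name=name or reads.label,
        base_counts=base_counts,
        pair_counts=pair_counts,
        gradient_rank=gradient_rank,
        redox=redox,
    )


def gc_content(pool: SamplePool) -> float:
    total = pool.pair_counts["AT"] + pool.pair_counts["GC"]
    if total == 0:
        raise ValueError("gc_content: empty pool")
    return pool.pair_counts["GC"] / total


def _pair_compositions(table: MonomerTable) -> Tuple[ElementalComposition, ElementalComposition]:
    at = table.composition("dA") + table.composition("dT")
    gc = table.composition("dG") + table.composition("dC")
    return at, gc


def zc_dsdna(pool: SamplePool, table: Optional[MonomerTable] = None) -> float:
    """Z_C of double-stranded DNA from nucleoside base-pair compositions.

    One dA+dT nucleoside pair is summed per A-T count and one dG+dC pair
    per G-C count; the closed form at GC fraction f is (10+4f)/(20-f).
    """
    table = table or load_monomers()
    at, gc = _pair_compositions(table)
    n_at = pool.pair_counts["AT"]
    n_gc = pool.pair_counts["GC"]
    if n_at + n_gc == 0:
        raise ValueError("zc_dsdna: pool has no base pairs")
    return zc(combine([(at, float(n_at)), (gc, float(n_gc))]))


def zc_dsdna_gc(f: float, table: Optional[MonomerTable] = None) -> float:
    """Z_C of dsDNA at GC fraction ``f`` via the full nucleoside compositions."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("GC fraction must lie in [0, 1]")
    table = table or load_monomers()
    at, gc = _pair_compositions(table)
    return zc(combine([(at, 1.0 - f), (gc, f)]))


_RNA_MONOMER = {"A": "rA", "C": "rC", "G": "rG", "U": "rU", "T": "rU"}
_RNA_MONOMER_T = {"A": "rA", "C": "rC", "G": "rG", "U": "rT", "T": "rT"}


def zc_rna(
    rna_counts: Mapping[str, float],
    table: Optional[MonomerTable] = None,
    thymine_variant: bool = False,
) -> float:
    """Z_C of single-stranded RNA from ribonucleoside compositions.

    Counts may be keyed A/C/G/U (T treated as U).  With
    ``thymine_variant=True`` the hypothetical T-containing ssRNA is
    computed (ribose sugar, thymine base), which isolates the
    sugar-substitution contribution to the RNA-DNA difference.
    """
    table = table or load_monomers()
    key = _RNA_MONOMER_T if thymine_variant else _RNA_MONOMER
    parts = []
    for base, count in rna_counts.items():
        if count == 0:
            continue
        if base not in key:
            raise ValueError(f"unknown RNA base {base!r}")
        parts.append((table.composition(key[base]), float(count)))
    if not parts:
        raise ValueError("zc_rna: empty counts")
    return zc(combine(parts))


def zc_protein(aa_counts: Mapping[str, float], table: Optional[MonomerTable] = None) -> float:
    """Z_C of protein from summed free amino-acid compositions.

    Counts may be keyed by one- or three-letter codes.  Free amino acids
    and peptide residues give the same answer by dehydration invariance.
    """
    table = table or load_monomers()
    parts = []
    for aa, count in aa_counts.items():
        if count == 0:
            continue
        name = AA1TO3.get(aa, aa)
        if name not in AA3:
            raise ValueError(f"unknown amino acid {aa!r}")
        parts.append((table.composition(name), float(count)))
    if not parts:
        raise ValueError("zc_protein: empty counts")
    return zc(combine(parts))


def strand_from_fgs_header(header: str) -> str:
    """Strand from a FragGeneScan-style id ``<read>_<start>_<end>_<strand>``."""
    strand = header.rsplit("_", 1)[-1]
    if strand not in {"+", "-"}:
        raise ValueError(f"cannot parse strand from header {header!r}")
    return strand


def orient_cds(cds_reads: ReadSet, strand_labels: Sequence[str]) -> ReadSet:
    """Reverse-complement negative-sense coding sequences.

    ``strand_labels`` holds '+' or '-' per read; the output is entirely
    positive-sense (mRNA-equivalent once T is read as U).
    """
    if len(strand_labels) != len(cds_reads):
        raise ValueError("one strand label required per read")
    seqs = []
    for seq, strand in zip(cds_reads.seqs, strand_labels):
        if strand == "+":
            seqs.append(seq)
        elif strand == "-":
            seqs.append(str(Seq(seq).reverse_complement()))
        else:
            raise ValueError(f"unknown strand label {strand!r}")
    return ReadSet(list(cds_reads.ids), seqs, cds_reads.label)


def rna_counts_from_cds(cds_reads: ReadSet) -> Counter:
    """Base counts of the mRNA corresponding to positive-sense CDS (T->U)."""
    counts: Counter = Counter()
    for seq in cds_reads.seqs:
        counts.update(seq)
    return Counter(
        {"A": counts.get("A", 0), "C": counts.get("C", 0),
         "G": counts.get("G", 0), "U": counts.get("U", 0) + counts.get("T", 0)}
    )


def aa_counts_from_proteins(proteins: Iterable[str]) -> Counter:
    """Amino-acid counts over protein sequences; non-standard letters dropped."""
    counts: Counter = Counter()
    for seq in proteins:
        counts.update(seq.upper())
    return Counter({aa: counts[aa] for aa in AA1TO3 if counts.get(aa, 0)})


def taxon_read_sets(
    reads: ReadSet,
    assignments: Mapping[str, str],
    min_fraction: float = 0.01,
    min_bases: int = 20000,
) -> Dict[str, ReadSet]:
    """Per-taxon read sets for taxa passing both abundance thresholds.

    A taxon is kept only when it holds at least ``min_fraction`` of the
    classified reads and its reads total at least ``min_bases`` bases.
    """
    by_taxon: Dict[str, List[int]] = {}
    n_classified = 0
    for i, rid in enumerate(reads.ids):
        taxon = assignments.get(rid)
        if taxon is None:
            continue
        n_classified += 1
        by_taxon.setdefault(taxon, []).append(i)
    out: Dict[str, ReadSet] = {}
    for taxon, idx in by_taxon.items():
        if n_classified == 0 or len(idx) / n_classified < min_fraction:
            continue
        subset = reads.subset(idx)
        if subset.total_bases < min_bases:
            continue
        subset.label = taxon
        out[taxon] = subset
    return out


def taxon_pools(
    reads: ReadSet,
    assignments: Mapping[str, str],
    min_fraction: float = 0.01,
    min_bases: int = 20000,
) -> Dict[str, SamplePool]:
    """dsDNA pools per taxon passing the thresholds (see taxon_read_sets)."""
    return {
        taxon: pool_dsdna(subset, name=taxon)
        for taxon, subset in taxon_read_sets(
            reads, assignments, min_fraction, min_bases
        ).items()
    }


def read_taxon_assignments(path: str | Path) -> Dict[str, str]:
    """Two-column TSV (read_id, taxon_id) -> mapping."""
    out: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rid, taxon = line.split("\t")[:2]
            out[rid] = taxon
    return out


def read_strand_table(path: str | Path) -> Dict[str, str]:
    """Two-column TSV (read_id, strand) -> mapping."""
    out: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rid, strand = line.split("\t")[:2]
            out[rid] = strand
    return out
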