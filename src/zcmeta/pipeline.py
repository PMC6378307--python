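"""End-to-end orchestration over multi-sample datasets.

Consumes a dataset manifest (sample labels, read/CDS/protein/taxon file
paths, gradient order), runs the composition, subsampling and
thermodynamic stages, and emits tidy TSV tables: per-sample Z_C with
subsampling error bars, a gradient trend table, a DNA-vs-protein mean
table, affinity/relative-affinity curves, the quadrant verdict, and
per-stage read counts.  Outputs are byte-stable under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import sequences as seqs
from .monomers import load_monomers
from .sequences import ReadSet, SamplePool
from .subsample import ZcEstimate, species_zc, subsample_zc
from .thermo import (
    affinity_curve,
    average_monomer,
    balance,
    default_basis,
    default_eh_grid,
    quadrant_classify,
    relative_affinity,
)

__all__ = ["SampleEntry", "DatasetManifest", "PipelineConfig", "ResultBundle", "run_dataset"]

log = logging.getLogger("zcmeta")

_FLOAT_FORMAT = "%.6g"


@dataclass
class SampleEntry:
    label: str
    reads: Path
    cds: Optional[Path] = None
    proteins: Optional[Path] = None
    strands: Optional[Path] = None
    taxa: Optional[Path] = None
    rank: float = 0.0
    redox: str = ""
    kind: str = "reads"  # "reads" | "contigs"


@dataclass
class DatasetManifest:
    """Ordered samples of one dataset, ranked along the redox gradient."""

    name: str
    samples: List[SampleEntry]

    def __post_init__(self) -> None:
        ranks = [s.rank for s in self.samples]
        if len(set(ranks)) != len(ranks):
            raise ValueError("gradient ranks must be unique")
        for s in self.samples:
            if s.kind not in {"reads", "contigs"}:
                raise ValueError(f"unknown input kind {s.kind!r} for {s.label}")

    @classmethod
    def from_tsv(cls, path: str | Path, name: str = "") -> "DatasetManifest":
        path = Path(path)
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        samples = []
        for row in frame.to_dict("records"):
            def p(key):
                value = row.get(key, "")
                return path.parent / value if value else None
            samples.append(
                SampleEntry(
                    label=row["label"], reads=p("reads"), cds=p("cds"),
                    proteins=p("proteins"), strands=p("strands"), taxa=p("taxa"),
                    rank=float(row.get("rank", 0) or 0),
                    redox=row.get("redox", ""), kind=row.get("kind", "reads") or "reads",
                )
            )
        return cls(name or path.parent.name, samples)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DatasetManifest":
        path = Path(path)
        doc = yaml.safe_load(path.read_text())
        samples = []
        for row in doc["samples"]:
            def p(key):
                return path.parent / row[key] if row.get(key) else None
            samples.append(
                SampleEntry(
                    label=row["label"], reads=p("reads"), cds=p("cds"),
                    proteins=p("proteins"), strands=p("strands"), taxa=p("taxa"),
                    rank=float(row.get("rank", 0)), redox=row.get("redox", ""),
                    kind=row.get("kind", "reads"),
                )
            )
        return cls(doc.get("name", path.stem), samples)


@dataclass
class PipelineConfig:
    """Tunable parameters of a pipeline run (YAML-loadable)."""

    target_units: int = 50000
    reps: int = 100
    species_target_units: int = 10000
    species_reps: int = 100
    prefix_len: int = 50
    max_ambiguous: int = 5
    min_fraction: float = 0.01
    min_bases: int = 20000
    eh_min: float = -0.35
    eh_max: float = 0.05
    eh_steps: int = 128
    temperature: float = 298.15
    basis_log_activities: Dict[str, float] = field(default_factory=dict)
    reducing_samples: Optional[List[str]] = None
    oxidizing_samples: Optional[List[str]] = None
    max_bases: Optional[int] = None
    rna_display_offset: float = 0.28

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)


@dataclass
class ResultBundle:
    samples: pd.DataFrame
    trend: pd.DataFrame
    dna_vs_protein: pd.DataFrame
    stage_counts: pd.DataFrame
    affinities: Optional[pd.DataFrame] = None
    quadrant_ok: Optional[bool] = None
    quadrant: Optional[pd.DataFrame] = None
    taxa: Optional[pd.DataFrame] = None

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        def dump(frame, name):
            frame.to_csv(out_dir / name, sep="\t", index=False, float_format=_FLOAT_FORMAT)
        dump(self.samples, "samples.tsv")
        dump(self.trend, "trend.tsv")
        dump(self.dna_vs_protein, "dna_vs_protein.tsv")
        dump(self.stage_counts, "stage_counts.tsv")
        if self.affinities is not None:
            dump(self.affinities, "affinity.tsv")
        if self.quadrant is not None:
            quadrant = self.quadrant.copy()
            quadrant.insert(0, "verdict_quadrant_1", self.quadrant_ok)
            dump(quadrant, "quadrant.tsv")
        if self.taxa is not None:
            dump(self.taxa, "taxa.tsv")


def _estimate_or_clamp(
    source: ReadSet, kind: str, target: int, reps: int, seed, label: str
):
    """Subsample with the target clamped to the pool size (logged)."""
    if kind == "protein":
        total = sum(
            sum(seq.count(a) for a in "ACDEFGHIKLMNPQRSTVWY") for seq in source.seqs
        )
    else:
        total = sum(
            sum(seq.count(b) for b in "ACGTU") for seq in source.seqs
        )
    eff = min(target, total)
    if eff < target:
        log.info("%s: subsample target reduced to pool size %d", label, eff)
    est, comps = subsample_zc(
        source, kind=kind, target_units=eff, reps=reps, seed=seed,
        return_compositions=True,
    )
    return est, comps


def run_dataset(
    manifest: DatasetManifest,
    config: Optional[PipelineConfig] = None,
    seed: int = 0,
    out_dir: Optional[str | Path] = None,
    do_subsample: bool = True,
    do_thermo: bool = True,
    do_taxa: bool = True,
) -> ResultBundle:
    """Run the pipeline over every sample in the manifest.

    Raises with a per-sample diagnostic if any sample fails a hard
    precondition (missing file, empty pool).  When ``out_dir`` is given
    all tables are written there, along with per-replicate subsample
    composition tables under ``replicates/``.
    """
    config = config or PipelineConfig()
    table = load_monomers()
    root = np.random.SeedSequence(seed)
    sample_seeds = root.spawn(len(manifest.samples))
    rows, stage_rows, taxa_rows = [], [], []
    pools: List[SamplePool] = []
    replicate_tables: Dict[str, pd.DataFrame] = {}

    for entry, sseed in zip(manifest.samples, sample_seeds):
        try:
            row, pool, stages, reps_tabs, taxa_part = _run_sample(
                entry, config, sseed, do_subsample, do_taxa, table
            )
        except Exception as exc:
            raise RuntimeError(f"sample {entry.label!r}: {exc}") from exc
        rows.append(row)
        pools.append(pool)
        stage_rows.extend(stages)
        replicate_tables.update(reps_tabs)
        taxa_rows.extend(taxa_part)

    samples = pd.DataFrame(rows)
    trend = samples[
        ["sample", "rank", "redox", "zc_dna", "zc_dna_sd",
         "zc_rna", "zc_rna_sd", "zc_protein", "zc_protein_sd"]
    ].copy()
    # display-only offset so DNA and RNA share an axis; stored values untouched
    trend["zc_rna_display"] = trend["zc_rna"] - config.rna_display_offset
    dna_vs_protein = samples[["sample", "zc_dna", "zc_protein"]].copy()
    stage_counts = pd.DataFrame(stage_rows)
    bundle = ResultBundle(
        samples=samples, trend=trend, dna_vs_protein=dna_vs_protein,
        stage_counts=stage_counts,
        taxa=pd.DataFrame(taxa_rows) if taxa_rows else None,
    )

    if do_thermo and len(pools) >= 2:
        bundle.affinities, bundle.quadrant_ok, bundle.quadrant = _run_thermo(
            manifest, config, pools, table
        )

    if out_dir is not None:
        bundle.write(out_dir)
        rep_dir = Path(out_dir) / "replicates"
        rep_dir.mkdir(exist_ok=True)
        for name, frame in replicate_tables.items():
            frame.to_csv(rep_dir / f"{name}.tsv", sep="\t", index=False,
                         float_format=_FLOAT_FORMAT)
    return bundle


def _run_sample(entry, config, sseed, do_subsample, do_taxa, table):
    if not Path(entry.reads).exists():
        raise FileNotFoundError(f"reads file {entry.reads} not found")
    reads = seqs.read_fasta(entry.reads, label=entry.label, max_bases=config.max_bases)
    if config.max_bases is not None:
        log.info("%s: capped input at %d bases", entry.label, config.max_bases)
    stages = [_stage(entry.label, "input", reads)]
    if entry.kind == "contigs":
        # contigs skip read-level cleaning, mirroring pipeline use on assemblies
        stages.append(_stage(entry.label, "length_filter", reads, note="skipped (contigs)"))
        stages.append(_stage(entry.label, "dereplicate", reads, note="skipped (contigs)"))
        cleaned = reads
    else:
        cleaned = seqs.length_filter(reads, max_ambiguous=config.max_ambiguous)
        stages.append(_stage(entry.label, "length_filter", cleaned))
        cleaned = seqs.dereplicate(cleaned, prefix_len=config.prefix_len)
        stages.append(_stage(entry.label, "dereplicate", cleaned))

    pool = seqs.pool_dsdna(cleaned, name=entry.label,
                           gradient_rank=entry.rank, redox=entry.redox)
    gc = seqs.gc_content(pool)
    zc_dna = seqs.zc_dsdna(pool, table)

    dna_seed, rna_seed, prot_seed, taxa_seed = sseed.spawn(4)
    reps_tabs = {}
    est_dna = est_rna = est_prot = None
    if do_subsample:
        est_dna, comp = _estimate_or_clamp(
            cleaned, "dna", config.target_units, config.reps, dna_seed, entry.label
        )
        reps_tabs[f"{entry.label}_dna"] = comp

    zc_rna = zc_prot = float("nan")
    if entry.cds is not None:
        cds = seqs.read_fasta(entry.cds, label=entry.label)
        if entry.strands is not None:
            strand_map = seqs.read_strand_table(entry.strands)
            strands = [strand_map[rid] for rid in cds.ids]
        else:
            strands = [seqs.strand_from_fgs_header(rid) for rid in cds.ids]
        oriented = seqs.orient_cds(cds, strands)
        zc_rna = seqs.zc_rna(seqs.rna_counts_from_cds(oriented), table)
        stages.append(_stage(entry.label, "cds", oriented))
        if do_subsample:
            est_rna, comp = _estimate_or_clamp(
                oriented, "rna", config.target_units, config.reps, rna_seed, entry.label
            )
            reps_tabs[f"{entry.label}_rna"] = comp
    if entry.proteins is not None:
        prots = seqs.read_fasta(entry.proteins, label=entry.label)
        pool.aa_counts = seqs.aa_counts_from_proteins(prots.seqs)
        zc_prot = seqs.zc_protein(pool.aa_counts, table)
        stages.append(_stage(entry.label, "proteins", prots))
        if do_subsample:
            est_prot, comp = _estimate_or_clamp(
                prots, "protein", config.target_units, config.reps, prot_seed, entry.label
            )
            reps_tabs[f"{entry.label}_protein"] = comp

    taxa_rows = []
    if do_taxa and entry.taxa is not None:
        assignments = seqs.read_taxon_assignments(entry.taxa)
        taxon_reads = seqs.taxon_read_sets(
            cleaned, assignments,
            min_fraction=config.min_fraction, min_bases=config.min_bases,
        )
        estimates = species_zc(
            taxon_reads, target_units=config.species_target_units,
            reps=config.species_reps,
            seed=int(taxa_seed.generate_state(1)[0] % (2**31)),
        )
        for taxon in sorted(estimates):
            est = estimates[taxon]
            taxa_rows.append(
                {"sample": entry.label, "taxon": taxon,
                 "n_reads": len(taxon_reads[taxon]),
                 "n_bases": taxon_reads[taxon].total_bases,
                 "zc_dna": est.mean, "zc_dna_sd": est.sd}
            )

    row = {
        "sample": entry.label, "rank": entry.rank, "redox": entry.redox,
        "n_reads": len(cleaned), "n_bases": cleaned.total_bases, "gc": gc,
        "zc_dna": est_dna.mean if est_dna else zc_dna,
        "zc_dna_sd": est_dna.sd if est_dna else 0.0,
        "zc_dna_pool": zc_dna,
        "zc_rna": est_rna.mean if est_rna else zc_rna,
        "zc_rna_sd": est_rna.sd if est_rna else 0.0,
        "zc_protein": est_prot.mean if est_prot else zc_prot,
        "zc_protein_sd": est_prot.sd if est_prot else 0.0,
    }
    return row, pool, stages, reps_tabs, taxa_rows


def _stage(label: str, stage: str, reads: ReadSet, note: str = "") -> Dict:
    return {"sample": label, "stage": stage, "n_reads": len(reads),
            "n_bases": reads.total_bases, "note": note}


def _run_thermo(manifest, config, pools, table):
    basis = default_basis(table, config.basis_log_activities)
    grid = default_eh_grid(config.eh_min, config.eh_max, config.eh_steps)
    dna_curves, protein_curves = [], []
    for pool in pools:
        comp, gibbs = average_monomer(pool, "dna", table)
        rxn = balance(comp, gibbs, basis, label=pool.name)
        dna_curves.append(affinity_curve(rxn, grid, config.temperature, kind="dna"))
        if pool.aa_counts:
            comp, gibbs = average_monomer(pool, "protein", table)
            rxn = balance(comp, gibbs, basis, label=pool.name)
            protein_curves.append(
                affinity_curve(rxn, grid, config.temperature, kind="protein")
            )
    dna_rel = relative_affinity(dna_curves)
    frames = []
    for abs_c, rel_c in zip(dna_curves, dna_rel):
        frames.append(pd.DataFrame(
            {"sample": abs_c.sample, "kind": "dna", "eh": abs_c.eh,
             "affinity": abs_c.loga, "relative_affinity": rel_c.loga}))
    verdict, endpoints = None, None
    if len(protein_curves) >= 2:
        protein_rel = relative_affinity(protein_curves)
        for abs_c, rel_c in zip(protein_curves, protein_rel):
            frames.append(pd.DataFrame(
                {"sample": abs_c.sample, "kind": "protein", "eh": abs_c.eh,
                 "affinity": abs_c.loga, "relative_affinity": rel_c.loga}))
        reducing, oxidizing = _designate(manifest, config)
        verdict, endpoints = quadrant_classify(dna_rel, protein_rel, reducing, oxidizing)
    return pd.concat(frames, ignore_index=True), verdict, endpoints


def _designate(manifest, config):
    """Most-reducing / most-oxidizing samples: config, redox labels, or rank ends."""
    if config.reducing_samples and config.oxidizing_samples:
        return list(config.reducing_samples), list(config.oxidizing_samples)
    reducing = [s.label for s in manifest.samples if s.redox == "reducing"]
    oxidizing = [s.label for s in manifest.samples if s.redox == "oxidizing"]
    if reducing and oxidizing:
        return reducing, oxidizing
    ordered = sorted(manifest.samples, key=lambda s: s.rank)
    return [ordered[0].label], [ordered[-1].label]
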