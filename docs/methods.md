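# Methods

## The carbon oxidation state metric

For a chemical formula C_c H_h N_n O_o S_s the average oxidation state of
carbon is Z_C = (−h + 3n + 2o + 2s)/c, obtained by assigning H +1, N −3,
O −2, S −2 and requiring the oxidation states of a neutral molecule to sum
to zero. The generalisation NOSC = (z − h + 3n + 2o + 2s − 5p)/c adds the
formal charge z and phosphorus (as +5); both extra terms vanish for the
molecules treated here, and for a nucleotide the phosphate and charge
contributions cancel so that NOSC equals the Z_C of the underlying
nucleoside. This is why the package computes nucleic-acid Z_C from
nucleoside compositions and can ignore the sugar-phosphate backbone: adding
phosphate is a condensation (dehydration) reaction and does not change the
carbon oxidation state.

Element counts are real numbers so that average per-monomer formulas (for
example C2.5H6NO2, the 50/50 Ala/Gly protein monomer) are ordinary values,
and Z_C of any weighted mixture is the carbon-weighted mean of the member
values — an identity the test suite checks by brute force.

## Sequence processing

The pipeline ingests processed reads or contigs (FASTA/FASTQ) together with
the outputs of external tools: CDS and protein FASTA from a gene caller
(strand read from FragGeneScan-style `_start_end_strand` headers or a
sidecar TSV) and read→taxon tables from a classifier. Adapter trimming,
rRNA calling, gene calling and classification are deliberately out of
scope; this package starts where those tools end.

Read-level cleaning, applied to read inputs and skipped for contigs:

- **Length/ambiguity filter.** One pass removing reads whose length falls
  outside mean ± 2 population standard deviations of the input set
  (boundary inclusive) or containing more than 5 non-ACGT characters. A
  second application of the filter can remove further reads (the cutoffs
  are recomputed), so the operation is intentionally single-pass;
  dereplication, by contrast, is exactly idempotent.
- **Dereplication.** Artificial duplicate reads are collapsed by identical
  leading prefix (default 50 bases, the common ADR convention; full
  sequence when shorter), first occurrence kept.

Base counts exclude all ambiguity codes. Double-stranded composition adds
the complement of every counted base, so each A or T contributes one A–T
pair and each G or C one G–C pair; this makes the pooled Z_C a function of
GC fraction alone, `(10+4f)/(20−f)`, and erases any strand GC skew (a
property the generator's skew knob verifies). mRNA composition uses
ribonucleosides with T read as U on re-oriented (all positive-sense) CDS;
proteins use free amino-acid formulas, equivalent to residues by
dehydration invariance.

Per-taxon pools keep taxa holding at least 1% of classified reads **and**
at least 20,000 bases, both thresholds configurable.

## Subsampling uncertainty

A subsample includes each sequence independently with probability
p = target/total (Bernoulli inclusion), the only reading of "a total of
50,000 bases on average" that is well defined over variable-length reads.
Defaults: 50,000 bases or amino acids, 100 replicates; 10,000 bases for
per-species estimates, whose error bars are correspondingly wider. The
mean and sample standard deviation (ddof = 1) over replicates are
reported; a replicate with zero included units is redrawn so the replicate
count stays fixed. All draws descend from one named seed through numpy
`SeedSequence` spawning (per sample, per molecule kind, per taxon in
sorted order), so results are independent of iteration order and
reproducible byte-for-byte. Subsampling is a measurement of within-sample
heterogeneity, not an unbiasedness device: the subsample mean converges on
the whole-pool value as the target grows, and the sd shrinks roughly as
1/sqrt(target).

## Thermodynamic model

Formation reactions of one average monomer — for DNA the average
nucleotide-monophosphate base pair (sum of two charge −2 NMP ions; water
lost on polymerisation is a per-monomer constant that cancels in relative
affinities), for proteins the average amino acid — are balanced from the
basis species H2O, HCO3⁻, H2PO4⁻, NH4⁺, HS⁻, H⁺ and e⁻ by solving the
7×7 element+charge linear system (residual must be < 1e-9). With nitrogen
supplied at −3 and sulfur at −2, the electron coefficient obeys
n_e = c(4 − NOSC): the exact mechanism linking carbon oxidation state to
redox sensitivity (a hand-balanced check: alanine takes 3 HCO3⁻ + NH4⁺ +
14 H⁺ + 12 e⁻ → Ala + 7 H2O).

Affinity is reported in dimensionless log units, A/(2.303RT) = log K −
log Q, with fixed basis log-activities (0, −3, −5, −7, −9, −7 respectively,
i.e. pH 7), unit product activity, 25 °C and 1 bar, and the electron
activity set by Eh: log a(e⁻) = −F·Eh/(2.303RT) ≈ −16.90·Eh/V. Each curve
is therefore affine in Eh with slope −16.90·n_e per volt. A kJ/mol export
multiplies by 2.303RT. The default Eh window is −0.35 V to +0.05 V in 128
steps — a span bracketing anoxic-to-suboxic aqueous environments at
neutral pH — and is configuration, not chemistry; the window endpoints
define where the quadrant classification is evaluated. The product
activity convention and temperature are deliberate simplifications: any
constant common to all samples cancels in relative affinities, which are
the reported quantity (per-Eh all-sample mean subtracted, zero-sum by
construction).

Standard Gibbs energies ship in `data/monomers.tsv` (per-row unit tags;
stored internally in J/mol). Amino-acid and nucleobase/sugar values follow
the published aqueous standard-state compilation lineage; nucleoside and
nucleotide-monophosphate values are additive condensation estimates
(base + sugar − H2O, then + HPO4²⁻ − H2O), flagged `estimate` in the
table's source column. These absolute values set only the intercepts of
the affinity curves; every structural property the package asserts —
balance residuals, the n_e identity, affine slopes, zero-sum relative
curves — is independent of them, and the qualitative endpoint ordering on
gradients is dominated by the electron term (≈ 5.9 log units per electron
at Eh = −0.35 V). The nucleotide monophosphates are taken as the fully
deprotonated −2 ions from the cited compilation; descriptions of them as
"+2 charged" in parts of the literature are treated as a sign slip, and
the table records the charge explicitly.

## Synthetic data

The generator emulates the statistical structure the analysis depends on,
nothing more. Bases are i.i.d. with P(G) = P(C) = gc/2 (no dinucleotide
structure — every downstream statistic is compositional); read lengths are
normal (default 150 ± 20, floor 30); each base is replaced by N with a
small probability; artificial duplicates (exact copies, or shared
50-base prefixes with regenerated tails) are appended at a binomial rate
with the injected count recorded as truth. Coding sequences are drawn
from an amino-acid usage table with codons uniform among synonyms under
the standard genetic code, half the genes emitted negative-sense to
exercise re-orientation; the usage table itself fixes the expected protein
and mRNA Z_C, which are recorded as truth.

Gradient defaults — five samples, GC 0.30→0.60, amino-acid usage tilted by
weights ∝ exp(α·Z_C) with α from −0.8 to +0.8, 1000 reads per sample,
ambiguous-base rate 0.002, duplicate rate 0.02, coding fraction 0.3 —
describe a coherent mixing-style gradient: GC spans the middle of the
natural 0.25–0.75 genome range and the α tilt moves per-residue protein
Z_C by roughly ±0.3, comparable to the spread between reduced
(hydrothermal) and oxidised (surface) proteomes. Reversing the GC
trajectory while keeping the protein tilt gives an OMZ-like inverted
gradient on which the quadrant classification correctly fails.

What the generator does **not** emulate: sequencing error and quality
profiles, genome-linked codon structure, taxon abundance distributions,
coverage biases, real mobile elements. Passing tests therefore show the
pipeline recovers known compositional signals and that the thermodynamic
machinery behaves as specified — not that any particular natural dataset
will show a given trend.

## Problem sizes and numerical choices

Tests and examples run five-sample gradients of 1000 reads × ~150 bases
per sample with subsample targets of 5,000 units and 50–100 replicates,
small enough to execute in seconds while leaving every pool an order of
magnitude larger than its subsample target. Production defaults remain
50,000-unit targets and 100 replicates. Balancing uses a dense LAPACK
solve with a 1e-9 residual guard; curves are stored on the configured Eh
grid; TSVs are written with a fixed `%.6g` float format so reruns are
byte-identical. Degenerate inputs raise informative errors: empty read
sets, pools without countable bases, subsample targets exceeding the pool
(the pipeline clamps to the pool size and logs instead), missing Gibbs
entries (named), rank-deficient bases, mismatched Eh grids.

## Known limitations

- No temperature or pressure extrapolation of Gibbs energies (25 °C, 1 bar
  only) and no ionisation-state speciation of amino-acid side chains; the
  per-monomer additive model is used for both DNA and proteins.
- Quadrant classification on real data depends on the chosen Eh window and
  on gradient-endpoint designation; it is a structural coherence check,
  not an estimate of in-situ energetics.
- Read weighting is uniform (no coverage weighting), matching the
  whole-metagenome focus; assembled contigs bypass read-level cleaning.
- The ADR prefix length (50) and the treatment of all non-ACGT characters
  as ambiguous are conventions, both configurable.
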