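# Methods

## Channel scheme

Single-base substitutions are classified on the pyrimidine strand: a record
whose reference allele is a purine is reverse-complemented (flanks swapped
and complemented) before lookup. The 96 channels are ordered by substitution
block (C>A, C>G, C>T, T>A, T>C, T>G) and, within a block, by 5′ then 3′
flank in alphabetical order — the standard catalog display convention, so
emitted profile tables are interoperable with other tools. Records whose
trinucleotide context cannot be resolved (flank off the contig end, or any
N base) are skipped and tallied, never imputed.

## Input handling

All three readers (VCF 4.x via pysam, headered TSV, multi-sample GDC-style
MAF via pandas) produce the same record model: 1-based positions,
single-base canonical ref/alt. Multi-allelic VCF ALT fields are split into
one record per alternate allele. Every reader maintains the accounting
invariant parsed = accepted + skipped, with per-reason skip tallies.
Identical variants within a sample (same chromosome, position, ref, alt) are
counted once; duplicates are tallied as skipped. This is an explicit
assumption: upstream callers emit unique somatic calls per sample, and
double-counting would distort profiles.

Chromosome names are normalized against the reference FASTA's contig names
(`chr` prefix added/stripped, MT ↔ chrM), since UCSC and 1000genomes-style
builds differ exactly there. Records whose ref allele disagrees with the
reference base are dropped with a logged warning rather than aborting the
run — tolerant behavior for heterogeneous cohorts. The VCF FILTER column is
ignored by default; `--pass-only` restricts to PASS rows. The genome build
label is recorded in the manifest only; context extraction always uses the
supplied FASTA.

## Signature refitting

The fit minimizes ‖S·x − m‖² subject to x ≥ 0 using scipy's Lawson–Hanson
active-set NNLS. Non-negativity is enforced even though "least squares"
alone would not require it: negative exposures have no physical meaning.
The fit operates on **raw count vectors**, so contributions are mutation
counts per signature; relative contributions (used for cohort analysis) are
derived afterwards. When all catalog signatures are fit, relative
contributions are invariant to this count-vs-frequency choice; RSS is
reported on the count scale and cosine similarity is scale-free. There is
no sparsity pruning or iterative signature removal: a single optimal fit is
reported, and the `--min-contribution` cutoff affects the displayed table
only, never the fit. Cosine similarity is computed with the denominator
√((a·a)(b·b)) and clamped to [0, 1], so identical profiles score exactly 1;
reconstructions with cosine > 0.9 are flagged adequate.

The tests cross-check the solver against an independent brute-force oracle:
a multi-stage refined grid search over the non-negative orthant (6 stages,
25 points per axis, window ±2 grid steps around the incumbent), which
resolves the optimal objective to ~1e-9 relative on instances of up to 6
channels and 3 signatures.

## Prevalence

Mutations per megabase over the surveyed territory. The study type sets the
territory: 3000 Mb for whole-genome, 30 Mb for whole-exome, both explicit,
documented defaults that can be overridden (`--territory-mb`), and required
for `custom`. Hypermutation is strictly greater than 12 mutations/Mb:
exactly 12.0 is not hypermutated.

## Cohort classification

Clustering uses the relative-contribution matrix (rows sum to 1), so burden
differences do not dominate pattern differences. The distance is
1 − Pearson correlation (range [0, 2], zero diagonal); constant
(zero-variance) vectors have no defined correlation and raise a named
error. Agglomeration is scipy hierarchical clustering with complete linkage
by default (average exposed via `--linkage`); merges are deterministic with
index-order tie-breaking. Dendrograms are exported as Newick with branch
lengths equal to merge-height differences.

PCA mean-centers columns without variance scaling (contributions share a
common scale already) and is computed only for cohorts of more than three
samples; smaller cohorts get a gated error (the pipeline records the gate in
the manifest instead of failing). Component signs are fixed by making the
largest-magnitude loading of each component positive, so coordinates are
reproducible across runs and sample orderings. Components 1–2 are plotted.

## Synthetic data generator

The generator emulates the study conditions the pipeline is designed for:
per-sample somatic SNV sets whose induced 96-channel profile follows a
chosen non-negative signature mixture. A pseudo-random single-contig
reference is drawn i.i.d. at a target GC fraction (default 0.41,
human-like); the build fails if any of the 32 pyrimidine-centered
trinucleotide contexts is absent. Channels are drawn i.i.d. from p = S·w;
each drawn channel is planted at a uniformly chosen, previously unused
genomic position whose normalized trinucleotide matches the channel's
context. A fair coin selects the forward-pyrimidine or forward-purine
position pool (falling back to the other when one is exhausted), so the
emitted VCF exercises reverse-complement normalization; the REF/ALT alleles
always agree with the reference strand at the chosen position. Positions
are never reused within a sample, mirroring somatic SNV uniqueness.

All randomness flows from a single master seed; per-sample seeds are
derived as `SeedSequence([master_seed, sample_index])` reduced mod 2³¹, so
cohorts are byte-reproducible.

What the generator does **not** emulate: real human genome composition
(repeats, CpG islands, chromatin-dependent mutation rates), germline
variation, sequencing error, caller artifacts, or inter-mutation clustering
(kataegis). Passing tests therefore demonstrate the correctness of the
channel accounting, the refitting mathematics and the pipeline plumbing —
not calling accuracy or biological validity of any particular catalog on
real tumors.

## Packaged catalog

The packaged 30-signature catalog is **synthetic**: each column is an
independent sparse Dirichlet(α = 0.1) draw over the 96 channels, rounded to
6 decimals with the largest entry adjusted so each column sums to exactly 1
(well within the 1e-3 column-sum tolerance). This reproduces the spiky,
mutually distinguishable shape of real SBS catalogs (the first five columns
have smallest singular value ≈ 0.26, comfortably conditioned for refitting)
while remaining deterministic, offline and redistributable.
`scripts/make_catalog_fixture.py` regenerates it. The companion cancer-type
association table is likewise a synthetic fixture that exercises the
association API. For real analyses, pass a real catalog TSV (either the
`Channel`-column dialect or the historic two-column
`Substitution Type`/`Trinucleotide` layout) via `--catalog`.

## Problem sizes and numerical choices

Test and acceptance runs use references of 40–100 kb and cohorts of up to
20 samples × 2000 mutations over 5 signatures — large enough that
multinomial sampling error on recovered mixture weights is well below the
0.05 mean-absolute-error bound we assert, and small enough for quick,
deterministic runs. Catalog columns must sum to 1 within 1e-3 (strict mode;
lenient mode defers to `validate_catalog`). Profile tables are written as
TSV with floats at 6 significant digits; plots are rendered with the Agg
backend without timestamps, so repeated runs produce identical tables
byte-for-byte.

## Known limitations

Only single-base-substitution 96-channel catalogs are supported (no
doublet, indel or extended-context channels, no transcription-strand bias).
De novo signature extraction (NMF) is out of scope — the package quantifies
known signatures. Excel input is not parsed; convert to TSV. Exposure
uncertainty (bootstrap confidence intervals) is not computed.
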