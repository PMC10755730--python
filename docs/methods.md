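# Methods

## Readout model

A cytosine's fate under deaminase treatment depends only on its modification
state and, optionally, its 5′ neighbor on the same strand. The
`DeaminationModel` holds a 3×4 table of deamination probabilities
(state ∈ {C, 5mC, 5hmC} × neighbor ∈ {A, C, G, T}); a deaminated cytosine is
emitted as T, a retained one as C. Deamination acts exactly once per
molecule — PCR resampling, adapters and paired-end structure are not
modeled, and base qualities are written as a constant Phred 40 and ignored
downstream. 5-formyl- and 5-carboxylcytosine are not simulated; their
contribution to the readout is negligible at genomic abundances.

The two shipped enzyme models are context-uniform (the engineered enzyme
shows no sequence-context bias; the 5′-neighbor axis is kept so that biased
variants can be expressed):

| enzyme   | C→T    | 5mC→T  | 5hmC→T |
|----------|--------|--------|--------|
| eA3A-v10 | 0.9992 | 0.9952 | 0.0016 |
| wtA3A    | 1.0000 | 0.9968 | 0.8071 |

## Synthetic genomes and planted truth

`build_reference` draws a first-order Markov sequence with a target G+C
fraction (default 0.42) and a CpG obs/exp ratio (default 0.25), giving the
CpG depletion characteristic of mammalian genomes (~1 CpG per 100 bp per
strand). `plant_modifications` assigns, independently per CpG cytosine on
each strand, 5mC with probability 0.75 and 5hmC with probability 0.10, and
5hmC at 2×10⁻⁴ of non-CpG cytosines. The defaults describe a tissue with
appreciable hydroxymethylation; they imply a planted CpG share of ≈96.5%,
consistent with the observation that genomic 5hmC is almost exclusively
CpG-bound. Planting is binary: a planted site is 5hmC on every molecule.
Real tissues show sub-unit site stoichiometries and regional 5hmC structure
(gene bodies, enhancers) that the generator does not emulate, so passing
tests demonstrate correctness of the statistics, not biological realism of
the landscape.

Spike-ins default to a 3 kb unmodified lambda-like contig and two 1.5 kb
uniformly modified amplicons (all-5mC, all-5hmC). The simulator covers every
contig at the same mean per-strand depth; the real protocol's ~0.1% spike-in
*mass* is reflected in the spike-ins' small length share, which is all that
matters downstream (only rates are estimated from them).

Read simulation draws, per contig and strand, Poisson(depth·L/read_len)
fixed-length single-end reads with uniform starts (≈ Poisson per-position
coverage, matching a ~10× per-strand design), applies the deamination table
position-wise, and records each read's origin in a truth sidecar. Identical
seeds give byte-identical FASTQ.

## Alignment and counting

The converted-space aligner replaces a production bisulfite-style mapper at
synthetic scale: reference and reads are collapsed C→T; both strands are
indexed (minus strand via reverse complement then C→T) with 2-bit-packed
20-mers; each read is anchored by an exact seed at its start (one rescue
seed one seed-length in) and scored by full-length mismatch count in
converted space, keeping hits within 2 mismatches. Equally good hits at
more than one locus mark the read non-unique; non-unique and unmatched reads
are excluded from counting. Uniqueness/mismatch defaults are this package's
own; they are not derived from any production aligner's settings. There is
no indel handling, no quality-aware filtering and no SAM/BAM emission;
externally produced per-site count tables can be imported instead (TSV with
columns contig, pos0, strand, context5p, context3p, N_C, N_T, N_other).

The pileup counts, per reference C on the plus strand (G on the minus
strand, with read bases projected onto plus orientation), reads showing
C (N_C), T (N_T) or anything else (N_other). Coordinates are 0-based
half-open everywhere, including BED/bedGraph outputs.

## Spike-in calibration

Conversion rates are pooled proportions ΣN_T/Σ(N_C+N_T) per class, not
per-site averages (the per-site median is kept as a diagnostic). The
caller's non-conversion error is

ε = max(1 − rate(unmodified), 1 − rate(all-5mC)),

the conservative choice: it is not stated which spike-in feeds the null in
the original analysis, and taking the larger residual guarantees that
incompletely converted 5mC is not promoted to 5hmC. With the default enzyme
this makes ε ≈ 0.005 (driven by 5mC), costing a little sensitivity at pure-C
sites in exchange for validity at methylated ones.

## Calling

For each site, p = P(X ≥ N_C) with X ~ Binomial(N_C + N_T, ε) (upper tail
including the observed count; N_other is excluded from the test).
Benjamini–Hochberg q-values are computed over sites with depth ≥ 5 only;
high-confidence sites satisfy depth ≥ 5 and q < 0.01. "q-value" is read as
BH — the standard, testable interpretation; a Storey-style estimate
(λ = 0.5) is available by flag. Calling is per strand with no CpG merging by
default; `merge_symmetric_cpg` optionally pools the two strands of a
palindromic CpG as a post-step. Ties in p receive identical q by
construction of the step-up procedure.

## Summaries

Binned signal is the mean site fraction in fixed-width tiling bins (default
10 kb). Replicate/method correlation is Pearson's r over bins non-empty in
both signals; empty bins are excluded pairwise, never zero-filled (zero
filling manufactures correlation). The default bin signal uses
high-confidence sites only; a raw-fraction mode (all covered sites) is
exposed and is the right choice for replicate correlation under binary
planting, where high-confidence site fractions are ≈1 everywhere and carry
no between-bin variance — the raw mean fraction tracks the planted-site
density that replicates share. Feature assignment resolves overlaps by an
explicit, config-ordered priority (promoter > UTR > exon > intron by
convention here; no external annotation tool's priorities are assumed);
unassigned sites are "intergenic". TSS metaprofiles are strand-oriented
(upstream negative).

## Kinetics

The measured quantity is the deaminated fraction I_D/(I_U + I_D); the rate
obeys rate·[E]·t = I_D/(I_U + I_D) and follows the Michaelis–Menten law
rate = k_cat[S]/(K_M + [S]). Fitting is by linear regression of the
double-reciprocal (Lineweaver–Burk) form — the linearization reading of
"linear regression of the Michaelis–Menten equation" — with Hanes–Woolf
([S]/rate vs [S]) behind a flag; the two agree exactly on noise-free data,
and a non-positive recovered k_cat flags the fit invalid. The rate
definition divides a dimensionless fraction by [E]·t; k_cat and K_M are
reported in the units conventionally printed (min⁻¹, μM) without attempting
to reconcile the dimensional bookkeeping, and efficiency is always exactly
k_cat/K_M of the same fit.

Only catalytic efficiencies are anchored for the shipped enzymes, so the
default (k_cat, K_M) pairs are this package's parameterization chosen once
under two constraints: each ratio equals the enzyme's efficiency exactly
(eA3A-v10: C 6.27, 5mC 3.90; wtA3A: C 90.82, 5mC 22.45, 5hmC 0.32
μM⁻¹ min⁻¹), and the noise-free deaminated fractions stay strictly inside
(0, 1) over the assay's substrate range at its [E] and t (0.1–2.5 μM at
40 nM enzyme for the engineered enzyme's C/5mC assays; 0.025–1.25 μM at 1 μM
enzyme for wtA3A/5hmC; t = 5 min), so that clamping never distorts the
linearization. eA3A-v10/5hmC has no kinetic entry: its activity on 5hmC is
too low for parameters to be measurable, and the package mirrors that.

## Problem sizes and numerical choices

The test suite and the acceptance script run the genome-scale checks at
desk scale as the package's own design: 100 kb replicate genomes (50 of
them) for false-discovery calibration, a 1 Mb genome at 10× per strand for
planted-site recovery and replicate correlation, 50–200 colonies × ~90
cytosines for conversion-rate round trips, and 10⁴ molecules per mixture
point. At these sizes every stochastic check has comfortable binomial
headroom against its threshold. Degenerate inputs are rejected loudly
(empty substrate, zero-depth spike-in class naming the class, zero-variance
correlation, end ≤ start intervals); sites with depth 0 after N_other
exclusion keep NaN fraction/p and can never be called; edge cytosines
without a 5′ neighbor use the state's mean probability across contexts, and
contexts at contig edges are "NA".

## Known limitations

No paired-end or duplicate modeling (the simulator makes no duplicates, so
deduplication is moot); no indels or quality filtering in the aligner; no
differential 5hmC between samples; no 5mC calling (C and 5mC are
indistinguishable by design of the readout); enrichment analyses against
external annotation databases are out of scope.
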