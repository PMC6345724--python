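# Methods

## Stacking free-energy model

The package treats base-pair stacking additively at the dinucleotide-step
level. A step XY (two consecutive bases on one strand, 5′→3′, together with
their paired bases) carries a stacking free energy ΔG_XY in kcal/mol; a
trinucleotide ABC contains exactly two steps, so

    ΔG_ABC = ΔG_AB + ΔG_BC.

This nearest-neighbour additivity is the standard assumption of DNA
thermodynamics; it ignores next-nearest-neighbour coupling and any
sequence-context dependence beyond the step itself. A central substitution
B → B′ changes both steps, and its effect is scored as

    ΔΔGs = ΔG_AB′C − ΔG_ABC   (mutated − wild type),

so ΔΔGs < 0 means the mutation strengthens stacking ("enhanced").

Because a step and its reverse complement describe the same stacked
base-pair dimer, the 16-key dinucleotide table holds 10 unique values and
every derived quantity is strand-invariant: ΔG(t) = ΔG(revcomp(t)) for all
64 trimers, and ΔΔGs is unchanged when a variant is reported on the other
strand. A consequence worth noting is that the extreme entries of the
difference matrix always come in reverse-complement pairs: the minimum
−1.09 kcal/mol is attained at CTA→CGA *and* TAG→TCG, the maximum +1.09 at
TCG→TAG *and* CGA→CTA. `matrix_extremes` therefore reports every tied key.

### Constants

The default set (`"protozanova"`) is the nicked-duplex experimental
measurement of Protozanova, Yakovchuk & Frank-Kamenetskii (J Mol Biol 342,
2004), at 37 °C, in kcal/mol:

| step | ΔG | step | ΔG |
|------|------|------|------|
| AA/TT | −1.11 | CC/GG | −1.44 |
| AC/GT | −1.81 | CG    | −0.91 |
| AG/CT | −1.06 | GA/TC | −1.43 |
| AT    | −1.34 | GC    | −2.17 |
| CA/TG | −0.55 | TA    | −0.19 |

Units are kcal/mol throughout; the constants are used as measured, with no
temperature or salt correction. Alternative sets load from a two-column
TSV (the loader fills reverse-complement partners and enforces symmetry to
1e-9). Ambiguity codes (N and the other IUPAC letters) are rejected
wherever an energy would be computed — no averaging rule exists for them —
and are soft-skipped (counted, excluded) in base-composition summaries.

Two structural properties of the default matrix, both asserted by the test
suite over every context: substitutions to G or C always yield a lower
ΔΔGs than substitutions to A or T in the same context, and the 192
non-identity |ΔΔGs| values split 31.25% / 37.5% / 31.25% across the bins
[0, 0.3), [0.3, 0.6) and ≥ 0.6 kcal/mol — nearly even, with the high bin
at ~30%.

## SNP annotation and cohort statistics

A variant is annotated from its wild-type trinucleotide context (variant
base central), either supplied directly (TSV) or extracted from a
reference FASTA at a 1-based VCF position; contig-edge positions and
ambiguous contexts are skipped with a warning, and a mismatch between the
stated and actual reference base is an error. |ΔΔGs| bins are left-closed
([0, 0.3), [0.3, 0.6), ≥ 0.6 kcal/mol), so a value exactly on an edge
falls in the upper bin; the edges are configurable. "Enhanced stacking"
means strictly ΔΔGs < 0; an exact zero (impossible for real substitutions
under the default constants, possible under custom tables) counts as not
enhanced. Identity entries are stored in the matrix (value 0) so the 64×4
grid is complete, but all statistics run over the 192 true substitutions.

Enrichment of enhanced-stacking variants inside TF binding sites is tested
with the exact hypergeometric upper tail P[X ≥ k], framing the full
annotated cohort as the population, enhanced variants as successes, and
the in-TFBS subset as the sample. Mutation types are the 12 ordered
ref→alt pairs on the reported strand (no transition/transversion
collapsing). Bin-distribution series can be compared with Student's t in
two modes — independent two-sample or paired by bin — because either
framing of such a comparison is defensible; neither mode is privileged. An
optional numeric significance filter (e.g. keep P ≤ 1e-8) applies to input
tables carrying a p-value column; it is not hard-coded.

## Affinity model

gcPBM-style data are fixed-length probes (K = 36 in the canonical design)
with positive fluorescence intensities; the response is ln(intensity). The
"1mer" feature set is the 4K one-hot encoding with slot order A, T, G, C
per position — deliberately not alphabetical, matching the convention of
the binding-affinity matrices this format follows; most toolkits default
to A, C, G, T, so the order is worth noticing when comparing weight
vectors. The "1mer+dgs" set appends the K−2 sliding-window stacking
energies (34 values for K = 36; the two terminal bases have no complete
window), giving 178 features.

The regressor is a linear ε-SVR (epsilon-insensitive loss). It is fit with
scikit-learn's `LinearSVR`, which solves the same primal problem as
libsvm's linear ε-SVR but scales far better at these dimensions. Numerical
choices: the response is mean-centred before the solve (the liblinear
intercept is regularized, so leaving ln-intensities near 7 uncentred both
biases and drastically slows the dual coordinate descent); the iteration
cap is 1000 with tolerance 1e-3, which reaches the PCC plateau on probe
sets of this size (verified against runs at 10× the cap, which change CV
PCC only in the fourth decimal); a zero-variance response degrades to a
constant predictor with a warning. Stacking columns are min–max scaled to
[0, 1] using statistics of the training rows only, putting kcal/mol values
on the indicator scale without test-fold leakage; the one-hot block is
left as-is. Scaling is toggleable.

Performance is estimated by nested cross-validation: a seeded, shuffled
outer 10-fold split; within each outer training fold an inner 5-fold CV
selects (C, ε) by mean inner PCC from the grid C ∈ {2⁻⁵, 2⁻³, …, 2⁵} ×
ε ∈ {0.01, 0.1, 0.5} (grid ties keep the first grid point, so selection is
deterministic); the winner is refit on the outer training fold and scored
by PCC on the held-out fold. No probe is ever predicted by a model that
saw it, which the tests assert from the fold bookkeeping kept in the
result object. The grid and inner depth are package defaults, configurable
per call. A degenerate (constant) prediction vector scores PCC 0 during
model selection rather than erroring; the public `pearson` function, by
contrast, raises on zero variance.

## Synthetic data

The generators produce every input the pipeline reads, as pure functions
of their spec (including the seed), so all fixtures are regenerated rather
than stored.

- **Random DNA**: i.i.d. bases with a GC-fraction dial.
- **gcPBM probes**: ln-intensity = intercept + w·x + N(0, σ), where x is
  the 1mer+dgs encoding. Default ground truth mimics a TF motif: an 8-bp
  core of strong per-position weights (sd 0.4) plus moderate weights on
  all stacking columns (sd 0.15); default n = 2000 probes of 36 bp with
  noise sd 0.1 on the ln scale, a size at which nested CV runs in about a
  minute per model on one CPU. The returned truth record allows exact
  parameter-recovery checks at σ = 0.
- **SNP cohorts**: mutation types drawn with the four transitions at a
  combined 70% (the preference observed in phenotype-associated cohorts)
  and transversions uniform on the rest; flanks uniform; a configurable
  fraction (default 0.4) flagged in-TFBS; optionally, flagged variants are
  redrawn with some probability from the high-|ΔΔGs| matrix entries to
  plant an enrichment signal. The redraw may change the mutation type —
  necessarily so, since G↔C substitutions have no high-|ΔΔGs| context at
  all under the default constants.
- **Reference + VCF**: random contigs with interior-only biallelic SNVs
  and a truth table of contexts, for exercising the extraction path.

What the generators do *not* emulate: linkage disequilibrium and the
genomic context distribution of real SNPs, microarray spatial artifacts,
probe replicates and background correction, and the empirical flank
distribution that makes transitions the top mutation types by mean |ΔΔGs|
in real GWAS cohorts (under uniform flanks, A↔C and T↔G transversions tie
the transitions by strand symmetry). Passing tests therefore demonstrate
correctness of the computations and power of the statistics under
idealized conditions, not real-data effect sizes; in particular the
published real-data cross-validation PCCs for Mad/Max/Myc require the
original gcPBM measurements and are out of scope here.

## Design notes and limitations

- Dinucleotide keys are read 5′→3′ on one strand and the duplex value is
  assigned to both the key and its reverse complement; this is what makes
  all downstream quantities strand-invariant.
- The sign convention (mutated − wild type) was chosen so that
  stacking-strengthening mutations are negative.
- Matrix TSV exports default to full precision (round-trip exact through
  the matching importers); the CLI writes presentation files at 2
  decimals.
- Coordinates: profile window i covers 0-based positions [i, i+3) and is
  attributed to central base i+1; VCF positions are 1-based.
- The stacking model is purely thermodynamic and sequence-local: no DNA
  shape features, no MD-derived structural quantities, no
  temperature/salt dependence, no quantum corrections.
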