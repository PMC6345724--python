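# tristack

Trinucleotide base-pair stacking free energies for regulatory genomics:
score the stacking effect of single-nucleotide substitutions and use
stacking profiles as features for transcription-factor (TF) binding-affinity
models.

Base-pair stacking is the dominant stabilizing interaction in duplex DNA. A
SNP changes the stacking of the two dinucleotide steps that flank it, so the
natural unit for scoring a substitution is the trinucleotide centred on the
variant base. `tristack` is for computational biologists who want to

- build the 64-entry trinucleotide stacking free-energy matrix and the
  64×4 central-substitution difference matrix from experimental
  dinucleotide constants,
- annotate SNP cohorts with ΔΔG<sub>s</sub>, |ΔΔG<sub>s</sub>| bins and
  enhanced-stacking flags, and test enrichment inside TF binding sites,
- train ε-SVR models of gcPBM probe intensities from one-hot sequence
  features augmented with the stacking-energy profile.

## The model

With ΔG<sub>XY</sub> the stacking free energy of the dinucleotide step XY
(kcal/mol, read 5′→3′; the bundled defaults are the nicked-duplex
measurements of Protozanova et al., ranging from −2.17 for GC to −0.19 for
TA), the trinucleotide energy is the sum of its two steps:

    ΔG_ABC = ΔG_AB + ΔG_BC

and a substitution of the central base B → B′ changes stacking by

    ΔΔGs(ABC → AB′C) = ΔG_AB′C − ΔG_ABC     (mutated − wild type)

so negative ΔΔG<sub>s</sub> means the mutation *enhances* stacking. Both
quantities are invariant under strand flip. For affinity modeling, a K-bp
probe is encoded as 4K one-hot indicators (slot order A, T, G, C) plus the
K−2 sliding-window stacking energies ("1mer+dgs", 178 features for K = 36);
a linear ε-SVR predicts ln(fluorescence intensity) and is evaluated by
nested 10-fold cross-validation with Pearson correlation (PCC).

## Worked example

```python
from tristack import (build_difference_matrix, build_trimer_matrix,
                      load_dinucleotide_table, matrix_extremes, trimer_energy)

table = load_dinucleotide_table("protozanova")
tm = build_trimer_matrix(table)
dm = build_difference_matrix(tm)
print(trimer_energy(table, "TAT"), trimer_energy(table, "TGT"))
print(dm[("CTA", "G")], dm[("TCG", "A")])
```

prints `-1.53 -2.36` — the MEIS1 binding-site trimer TAT and its A→G mutant
TGT, whose 0.83 kcal/mol stacking gain accompanies the increased MEIS1
binding affinity of that SNP — and `-1.09 1.09`, the extreme entries of the
difference matrix (CTA→CGA is the largest possible stacking gain, TCG→TAG
the largest loss; `matrix_extremes(dm)` confirms both, each tied with its
reverse complement). Running `examples/01_stacking_matrices.py` produces:

```
dinucleotide constants: protozanova, range -2.17 .. -0.19 kcal/mol
dG(TAT) = -1.53 kcal/mol  (weak stacking)
dG(TGT) = -2.36 kcal/mol  (the A->G mutant of TAT stacks much more strongly)
strongest-stacking trimers: GCC,GGC at -3.61
weakest-stacking trimers:   CTA,TAG at -1.25
largest stacking gain:  CTA->CGA, TAG->TCG (-1.09 kcal/mol)
largest stacking loss:  CGA->CTA, TCG->TAG (1.09 kcal/mol)
```

The other scripts in `examples/` walk through sequence profiles
(`02_sequence_profiles.py`), SNP-cohort annotation and TFBS enrichment
(`03_snp_enrichment.py`), and affinity-model cross-validation
(`04_affinity_model.py`, where the stacking-augmented model reaches mean
PCC 0.996 vs 0.971 for the sequence-only model on a stacking-loaded
synthetic probe set).

A thin CLI wraps the same functionality:

```bash
tristack matrix --extremes --out-dir matrices/
tristack simulate snps --n 1000 --seed 1 --out cohort.tsv
tristack annotate --snps cohort.tsv --out-prefix run
tristack train --gcpbm probes.tsv --features 1mer+dgs --seed 1 --out cv.json
```

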