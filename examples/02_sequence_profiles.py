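"""Sliding-window stacking profile and base composition of a binding site.

Scores every trinucleotide window of the MEIS1 binding-site sequence; the
profile has L-2 values because the two terminal bases lack a full window.
"""

from tristack import composition, load_dinucleotide_table, stacking_profile

table = load_dinucleotide_table()

site = "ACTATCGA"  # MEIS1 binding site; the 4th base carries an A->G SNP
prof = stacking_profile(site, table, sequence_id="MEIS1_site")
print(f"sequence {site} ({len(site)} bp) -> {len(prof)} scored windows")
for i, value in enumerate(prof.values):
    center = prof.offset + i
    print(f"  pos {center}: {site[center - 1 : center + 2]}  {value:6.2f} kcal/mol")

mutated = site[:3] + "G" + site[4:]
delta = (
    stacking_profile(mutated, table).values.sum() - prof.values.sum()
)
print(f"A->G substitution at pos 3 changes total stacking by {delta:.2f} "
      "kcal/mol (negative = stronger stacking)")

summary = composition([site, mutated])
print(f"pooled composition: {summary.at_count} A/T, {summary.gc_count} G/C "
      f"-> {summary.at_fraction:.2f}% AT")
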