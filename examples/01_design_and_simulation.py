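"""Build a common-garden design and simulate a synthetic cohort.

Each block plants one 12-sapling plot for every non-empty subset of the
maternal families, so genetic diversity (1-4 families) is balanced within
blocks.  Genotypes descend from genotyped mothers through a finite pollen
pool; herbivory is scored from 20 leaf-level damage classes per sapling.
"""

from herbdiv import (
    MatingDesign,
    apply_dropout,
    build_design,
    make_locus_panel,
    simulate_genotypes,
    simulate_herbivory,
)

mating = MatingDesign(n_mothers=4, pollen_donors_per_mother=3)
design = build_design(blocks=6, mating=mating, seed=0)
print(f"planted {len(design)} saplings in {design['plot'].nunique()} plots")
print("plots per diversity level:")
print(design.groupby("plot")["gd"].first().value_counts().sort_index().to_string())

# mortality and genotyping failure at the default calibrated rates
design = apply_dropout(design, seed=0)
print(f"\nalive: {int(design['alive'].sum())}, genotyped: {int(design['genotyped'].sum())}")

panel = make_locus_panel(n_loci=11, n_alleles=(6, 19), seed=0)
genotypes = simulate_genotypes(design, panel, mating, seed=0)
print(f"genotype table: {len(genotypes)} rows "
      f"({genotypes['individual_id'].nunique()} individuals x {len(panel)} loci)")

phenotypes = simulate_herbivory(design, seed=0)
print("\nper-sapling phenotypes:")
print(phenotypes.head().to_string(index=False))
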