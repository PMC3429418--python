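"""Verify maternity by Mendelian exclusion and screen loci for errors.

An offspring mismatches a candidate mother at a locus when they share no
allele there.  Two or more mismatches against every candidate excludes the
offspring; exactly one retains it but feeds a per-locus error screen that
flags markers responsible for an outsized share of single-mismatch events.
"""

from collections import Counter

from herbdiv import (
    MatingDesign,
    assign_maternity_all,
    build_design,
    locus_error_screen,
    make_locus_panel,
    simulate_genotypes,
)

mating = MatingDesign(n_mothers=4)
design = build_design(blocks=2, mating=mating, seed=3)
panel = make_locus_panel(n_loci=11, n_alleles=11, seed=3)

# inject a 10% genotyping error rate at one locus only
genotypes = simulate_genotypes(design, panel, mating, seed=3, error_rate={"L05": 0.10})

checks = assign_maternity_all(genotypes)
print("assignment statuses:", dict(Counter(c.status for c in checks)))

correct = sum(
    c.best_mother == fam
    for c, fam in zip(checks, design["family"])
    if c.best_mother is not None
)
print(f"correctly assigned: {correct}/{len(checks)}")

print("\nlocus error screen (share of single-mismatch events):")
for report in locus_error_screen(checks):
    flag = "  <-- flagged" if report.flagged else ""
    print(f"  {report.locus_id}: {report.mismatch_rate:.2f} ({report.n_events} events){flag}")
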