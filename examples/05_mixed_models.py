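"""Fit the herbivory regressions with the prescribed model structure.

Ectophage damage (logit of the per-sapling mean damage proportion) is
modelled with a linear mixed model - height, maternal family and one
diversity measure as fixed effects, plot nested in block as random
intercepts.  Leaf-miner counts use Poisson regression with plot-clustered
robust standard errors, including a height x diversity interaction.  GD
(number of maternal lineages) and GR (mean pairwise relatedness) enter in
separate models, never together.
"""

import pandas as pd

from herbdiv import MatingDesign, build_design, fit_herbivory_models, simulate_herbivory
from herbdiv.stats import prepare_analysis_table, model_summary_frame

mating = MatingDesign(n_mothers=4)
design = build_design(blocks=6, mating=mating, seed=21)
pheno = simulate_herbivory(design, seed=21)
maternity = pd.DataFrame(
    {
        "offspring_id": design["sapling_id"],
        "best_mother": design["family"],
        "mismatches": 0,
        "status": "assigned",
    }
)
plot_summary = design.groupby("plot")["gd"].first().rename("gd").reset_index()

data = prepare_analysis_table(pheno, maternity, design, plot_summary)
fits = fit_herbivory_models(data)

frame = model_summary_frame(fits)
cols = ["model", "term", "coef", "se", "stat", "df", "p_value"]
pd.set_option("display.float_format", lambda v: f"{v:.4f}")
print(frame[cols].to_string(index=False))
print("\nrandom structures:", {k: f.random_structure for k, f in fits.items()})
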