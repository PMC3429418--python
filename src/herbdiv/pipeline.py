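"""End-to-end pipeline: simulate -> QC -> relatedness -> partition -> stats.

A run is fully reproducible from its :class:`PipelineConfig` (one root
seed, named substreams per stage).  Every stage writes its CSV outputs and
the run ends with a manifest recording the configuration hash, package
version, seed and the count of saplings surviving each filter (planted ->
alive -> genotyped -> maternally assigned -> analyzable).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import herbdiv.io as hio
from herbdiv._version import __version__ as _version
from herbdiv.design import MatingDesign, build_design
from herbdiv.partition import partition_all, partition_anova, partition_table, partition_tests
from herbdiv.qc import assign_maternity_all, locus_error_screen, maternity_table
from herbdiv.relatedness import (
    estimate_allele_frequencies,
    plot_summaries,
    relatedness_pairs,
    within_plot_pairs,
)
from herbdiv.simulate import (
    DEATH_RATE_DEFAULT,
    FAIL_RATE_DEFAULT,
    HerbivoryEffectSpec,
    apply_dropout,
    make_locus_panel,
    simulate_genotypes,
    simulate_herbivory,
)
from herbdiv.stats import fit_herbivory_models, kruskal_gr_by_gd, prepare_analysis_table, model_summary_frame

__all__ = ["PipelineConfig", "run", "make_fixture"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Serializable description of one full pipeline run."""

    seed: int = 0
    blocks: int = 6
    n_mothers: int = 4
    pollen_donors_per_mother: int = 3
    n_loci: int = 11
    n_alleles: int = 11
    equifrequent_alleles: bool = False
    death_rate: float = DEATH_RATE_DEFAULT
    fail_rate: float = FAIL_RATE_DEFAULT
    genotyping_error_rate: float = 0.0
    effects: HerbivoryEffectSpec = field(default_factory=HerbivoryEffectSpec)
    test_directions: dict = field(
        default_factory=lambda: {"NGDE": 1, "CE": 1, "SE": -1}
    )
    genepop_export: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        fx = raw.pop("effects", None)
        cfg = cls(**raw) if fx is None else cls(effects=HerbivoryEffectSpec(**fx), **raw)
        return cfg

    @property
    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def make_fixture(scale: str = "small") -> PipelineConfig:
    """Standard configurations: ``"small"`` (2 blocks x 2 mothers, 3 plots
    per block, 72 saplings; seconds to run) or ``"full"`` (the full
    6-block x 15-plot x 12-sapling design, 1080 saplings)."""
    if scale == "small":
        return PipelineConfig(
            blocks=2,
            n_mothers=2,
            effects=HerbivoryEffectSpec(
                family_means_monoculture={"MT1": 5.5, "MT2": 8.3},
                height_log_means={"MT1": 4.80, "MT2": 4.86},
            ),
        )
    if scale == "full":
        return PipelineConfig()
    raise ValueError(f"unknown fixture scale: {scale!r}")


def run(config: PipelineConfig, outdir) -> dict:
    """Execute the full pipeline and write all outputs under ``outdir``.

    Returns a dict of in-memory artifacts (design, genotypes, phenotypes,
    maternity, locus error reports, relatedness, plot summaries, partition
    results and test tables, per-term model summary, manifest).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    mating = MatingDesign(
        n_mothers=config.n_mothers,
        pollen_donors_per_mother=config.pollen_donors_per_mother,
    )

    design = build_design(config.blocks, mating, seed)
    n_planted = len(design)
    design = apply_dropout(design, config.death_rate, config.fail_rate, seed)
    n_alive = int(design["alive"].sum())
    n_genotyped = int(design["genotyped"].sum())
    logger.info("planted=%d alive=%d genotyped=%d", n_planted, n_alive, n_genotyped)

    panel = make_locus_panel(
        config.n_loci, config.n_alleles, seed, equifrequent=config.equifrequent_alleles
    )
    genotypes = simulate_genotypes(
        design, panel, mating, seed, error_rate=config.genotyping_error_rate
    )
    # ungenotyped saplings contribute no usable genotype downstream
    genotyped_ids = set(design.loc[design["genotyped"], "sapling_id"])
    usable = genotypes[
        (genotypes["role"] == "mother") | genotypes["individual_id"].isin(genotyped_ids)
    ].reset_index(drop=True)

    phenotypes = simulate_herbivory(design, config.effects, seed)

    checks = assign_maternity_all(usable)
    maternity = maternity_table(checks)
    errors = locus_error_screen(checks)
    n_assigned = int(maternity["status"].isin(["assigned", "flagged_one_mismatch"]).sum())
    logger.info("maternally assigned=%d", n_assigned)

    freqs = estimate_allele_frequencies(usable)
    analyzable_ids = set(
        maternity.loc[
            maternity["status"].isin(["assigned", "flagged_one_mismatch"]), "offspring_id"
        ]
    ) & genotyped_ids
    alive_ids = set(design.loc[design["alive"], "sapling_id"])
    analyzable_ids &= alive_ids
    pairs = within_plot_pairs(design, analyzable_ids)
    rel = relatedness_pairs(usable, panel=freqs, pairs=pairs)
    summary = plot_summaries(rel, maternity, design)

    results_ecto = partition_all(phenotypes, maternity, design, "ecto_damage")
    results_miner = partition_all(phenotypes, maternity, design, "mine_count")
    tests = []
    for guild, results in (("ecto", results_ecto), ("miner", results_miner)):
        if len(results) >= 2:
            for scope in ("grand", "by_gd"):
                try:
                    for inf in partition_tests(results, scope, config.test_directions):
                        tests.append((guild, inf.scope, inf.effect, inf.mean, inf.t_statistic, inf.df, inf.p_value))
                except ValueError:
                    logger.warning("%s/%s: too few mixtures for t-tests", guild, scope)
    tests_df = pd.DataFrame(
        tests, columns=["guild", "scope", "effect", "mean", "t", "df", "p_value"]
    )
    anova_frames = []
    for guild, results in (("ecto", results_ecto), ("miner", results_miner)):
        try:
            adf = partition_anova(results)
            adf.insert(0, "guild", guild)
            anova_frames.append(adf)
        except ValueError:
            logger.info("%s: single GD level; across-GD ANOVA skipped", guild)
    anova_df = pd.concat(anova_frames, ignore_index=True) if anova_frames else pd.DataFrame()

    analysis = prepare_analysis_table(phenotypes, maternity, design, summary)
    fits = fit_herbivory_models(analysis)
    model_summary = model_summary_frame(fits)
    try:
        k_stat, k_df, k_p = kruskal_gr_by_gd(summary)
        kruskal = {"K": k_stat, "df": k_df, "p_value": k_p}
    except ValueError:
        kruskal = None

    hio.write_design(design, out / "design.csv")
    hio.write_genotypes(usable, out / "genotypes.csv")
    hio.write_phenotypes(phenotypes, out / "phenotypes.csv")
    maternity.to_csv(out / "maternity.csv", index=False)
    pd.DataFrame(
        [(e.locus_id, e.mismatch_rate, e.n_events, e.flagged) for e in errors],
        columns=["locus", "mismatch_rate", "n_events", "flagged"],
    ).to_csv(out / "locus_errors.csv", index=False)
    rel.to_csv(out / "relatedness.csv", index=False)
    summary.to_csv(out / "plot_summary.csv", index=False)
    pd.concat(
        [
            partition_table(results_ecto).assign(guild="ecto"),
            partition_table(results_miner).assign(guild="miner"),
        ],
        ignore_index=True,
    ).to_csv(out / "partition.csv", index=False)
    tests_df.to_csv(out / "partition_tests.csv", index=False)
    anova_df.to_csv(out / "partition_anova.csv", index=False)
    model_summary.to_csv(out / "model_summary.csv", index=False)
    if config.genepop_export:
        hio.export_genepop(usable, design, out / "genotypes.genepop.txt")
    config.to_yaml(out / "config.yaml")

    manifest = {
        "config_hash": config.config_hash,
        "herbdiv_version": _version,
        "seed": seed,
        "counts": {
            "planted": n_planted,
            "alive": n_alive,
            "genotyped": n_genotyped,
            "maternally_assigned": n_assigned,
            "analyzable": len(analyzable_ids),
            "mixtures_partitioned_ecto": len(results_ecto),
            "mixtures_partitioned_miner": len(results_miner),
        },
        "kruskal_gr_by_gd": kruskal,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "design": design,
        "genotypes": usable,
        "phenotypes": phenotypes,
        "maternity": maternity,
        "locus_errors": errors,
        "relatedness": rel,
        "plot_summary": summary,
        "partition_ecto": results_ecto,
        "partition_miner": results_miner,
        "partition_tests": tests_df,
        "partition_anova": anova_df,
        "model_summary": model_summary,
        "manifest": manifest,
    }
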