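"""Synthetic cohorts: genotypes, dropout and herbivory phenotypes.

Generates data with the statistical structure the downstream analysis
assumes: maternal half-sib families produced through a finite pollen-donor
pool (so offspring are a full-sib/half-sib mixture), codominant multiallelic
markers transmitted Mendelian-fashion, mortality and genotyping-failure
dropout, and per-sapling herbivory scores built from 20 leaf-level damage
draws discretized into the field scoring classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from herbdiv._rng import substream
from herbdiv.design import MatingDesign, plot_families

__all__ = [
    "LocusModel",
    "HerbivoryEffectSpec",
    "make_locus_panel",
    "simulate_genotypes",
    "simulate_dyads",
    "apply_dropout",
    "simulate_herbivory",
    "classify_damage",
    "DAMAGE_CLASS_LABELS",
    "DAMAGE_CLASS_MIDPOINTS",
    "DEATH_RATE_DEFAULT",
    "FAIL_RATE_DEFAULT",
    "GENOTYPE_COLUMNS",
]

#: Defaults calibrated to 25/1080 dead and 53/1055 unusable genotypes among
#: survivors, so the expected analyzable count in the full design is 1002.
DEATH_RATE_DEFAULT = 25 / 1080
FAIL_RATE_DEFAULT = 53 / 1055

#: Column contract for long-format genotype tables (``genotypes.csv``).
GENOTYPE_COLUMNS = ["individual_id", "role", "family", "locus", "allele_1", "allele_2"]

#: Leaf-damage scoring classes (% leaf area) and their midpoint scores.
#: The open top class ">76" is scored at the midpoint of 76-100.
DAMAGE_CLASS_LABELS = ["0", "1-5", "6-15", "16-25", "26-50", "51-75", ">76"]
DAMAGE_CLASS_MIDPOINTS = np.array([0.0, 3.0, 10.5, 20.5, 38.0, 63.0, 88.0])
_CLASS_UPPER_EDGES = np.array([5.0, 15.0, 25.0, 50.0, 75.0])


@dataclass(frozen=True)
class LocusModel:
    """Allele-frequency model of one codominant marker locus.

    Alleles are integer codes; frequencies are strictly positive and sum
    to 1.  The default panel mimics a microsatellite kit: 11 loci with
    about 11 alleles each (configurable in the 6-19 range).
    """

    locus_id: str
    alleles: tuple[int, ...]
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", freqs)
        if len(self.alleles) != freqs.size:
            raise ValueError("alleles and frequencies must have equal length")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError("duplicate allele codes")
        if np.any(freqs <= 0):
            raise ValueError("allele frequencies must be strictly positive")
        if abs(freqs.sum() - 1.0) > 1e-12:
            raise ValueError("allele frequencies must sum to 1")

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    def frequency_of(self, allele: int) -> float:
        try:
            return float(self.frequencies[self.alleles.index(allele)])
        except ValueError:
            raise KeyError(f"allele {allele} unknown at locus {self.locus_id}") from None


@dataclass(frozen=True)
class HerbivoryEffectSpec:
    """Effect sizes and dispersions of the herbivory generative model.

    Ectophage damage: per leaf, a damage proportion is drawn logit-normally
    with location = logit(family monoculture mean) + gd_slope * GD_std
    + height_slope_ecto * H_std + block + plot effects, plus leaf noise
    (all on the logit scale), then discretized into the field classes and
    scored by class midpoint; the sapling value is the 20-leaf mean.
    Miner counts are Poisson with log-mean = miner_intercept
    + height_slope_miner * H_std.

    Defaults: family monoculture means span 5.5-8.3 % leaf area; the height
    slopes are 0.05 (logit scale, ectophages) and 0.31 (log scale, miners);
    the diversity slope is 0.06 per standardized GD unit.
    """

    family_means_monoculture: dict[str, float] = field(
        default_factory=lambda: {"MT1": 5.5, "MT2": 6.5, "MT3": 7.5, "MT4": 8.3}
    )
    gd_slope: float = 0.06
    height_slope_ecto: float = 0.05
    height_slope_miner: float = 0.31
    block_sd: float = 0.15
    plot_sd: float = 0.15
    leaf_sd: float = 0.5
    miner_intercept: float = 0.0
    height_log_means: dict[str, float] = field(
        default_factory=lambda: {"MT1": 4.80, "MT2": 4.86, "MT3": 4.70, "MT4": 4.76}
    )
    height_log_sd: float = 0.25

    def __post_init__(self) -> None:
        for name in ("block_sd", "plot_sd", "leaf_sd", "height_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for fam, mean in self.family_means_monoculture.items():
            if not 0.0 < mean < 100.0:
                raise ValueError(f"monoculture mean for {fam} must be in (0, 100)")


def make_locus_panel(
    n_loci: int = 11,
    n_alleles: int | tuple[int, int] = 11,
    seed: int = 0,
    equifrequent: bool = False,
    dirichlet_alpha: float = 1.0,
) -> list[LocusModel]:
    """Build a marker panel.

    ``n_alleles`` may be a fixed count (default 11, the panel mean in the
    emulated kit) or an inclusive ``(low, high)`` range (e.g. ``(6, 19)``)
    from which per-locus counts are drawn uniformly.  Frequencies are
    symmetric-Dirichlet draws unless ``equifrequent``.
    """
    rng = substream(seed, "locus-panel")
    panel = []
    for i in range(n_loci):
        if isinstance(n_alleles, tuple):
            lo, hi = n_alleles
            k = int(rng.integers(lo, hi + 1))
        else:
            k = int(n_alleles)
        if k < 2:
            raise ValueError("each locus needs at least 2 alleles")
        if equifrequent:
            freqs = np.full(k, 1.0 / k)
        else:
            freqs = rng.dirichlet(np.full(k, dirichlet_alpha))
            # keep frequencies bounded away from 0 so every allele is observable
            freqs = np.clip(freqs, 1e-4, None)
            freqs = freqs / freqs.sum()
        panel.append(LocusModel(f"L{i + 1:02d}", tuple(range(1, k + 1)), freqs))
    return panel


def _draw_genotypes(rng: np.random.Generator, loci: list[LocusModel], n: int) -> np.ndarray:
    """n independent multilocus genotypes; shape (n, n_loci, 2) of allele codes."""
    out = np.empty((n, len(loci), 2), dtype=np.int64)
    for j, locus in enumerate(loci):
        codes = np.asarray(locus.alleles)
        out[:, j, :] = codes[rng.choice(locus.n_alleles, size=(n, 2), p=locus.frequencies)]
    return out


def _transmit(rng: np.random.Generator, parents: np.ndarray) -> np.ndarray:
    """One gamete per parent genotype: uniform choice of the two alleles per locus."""
    n, n_loci, _ = parents.shape
    pick = rng.integers(0, 2, size=(n, n_loci))
    return np.take_along_axis(parents, pick[:, :, None], axis=2)[:, :, 0]


def _genotype_frame(ids, role, families, loci, geno) -> pd.DataFrame:
    n, n_loci, _ = geno.shape
    return pd.DataFrame(
        {
            "individual_id": np.repeat(ids, n_loci),
            "role": np.repeat(role, n * n_loci),
            "family": np.repeat(families, n_loci),
            "locus": np.tile([l.locus_id for l in loci], n),
            "allele_1": geno[:, :, 0].ravel().astype(float),
            "allele_2": geno[:, :, 1].ravel().astype(float),
        }
    )


def simulate_genotypes(
    design: pd.DataFrame,
    loci: list[LocusModel],
    mating: MatingDesign,
    seed: int,
    error_rate: float | dict[str, float] = 0.0,
    failure_rate: float = 0.0,
) -> pd.DataFrame:
    """Simulate mother and offspring genotypes for a planted design.

    Mothers are independent draws from the locus allele frequencies.  Each
    mother has a pool of pollen donors with Dirichlet(1) usage weights; each
    offspring receives one maternal allele (uniform over the mother's two)
    and one allele from its assigned donor, at every locus.  Afterwards an
    optional per-locus genotyping error (one allele replaced by a random
    population draw; scalar rate or per-locus dict) and a per-individual
    whole-genotype failure rate are applied.

    Returns a long table with columns ``GENOTYPE_COLUMNS``; mothers appear
    with ``role="mother"`` and ``individual_id`` equal to the family name.
    Missing allele calls are NaN.
    """
    for locus in loci:
        if locus.n_alleles < 2:
            raise ValueError(f"locus {locus.locus_id} has < 2 alleles")
    rng = substream(seed, "genotypes")
    fams = mating.family_names
    offspring = design[["sapling_id", "family"]].reset_index(drop=True)
    n_off = len(offspring)
    n_loci = len(loci)

    mother_geno = _draw_genotypes(rng, loci, len(fams))
    donors = {f: _draw_genotypes(rng, loci, mating.pollen_donors_per_mother) for f in fams}
    weights = {f: rng.dirichlet(np.ones(mating.pollen_donors_per_mother)) for f in fams}

    off_geno = np.empty((n_off, n_loci, 2), dtype=np.int64)
    fam_index = {f: i for i, f in enumerate(fams)}
    for f in fams:
        mask = (offspring["family"] == f).to_numpy()
        k = int(mask.sum())
        if k == 0:
            continue
        mother = np.broadcast_to(mother_geno[fam_index[f]], (k, n_loci, 2))
        donor_idx = rng.choice(mating.pollen_donors_per_mother, size=k, p=weights[f])
        donor = donors[f][donor_idx]
        off_geno[mask, :, 0] = _transmit(rng, mother)
        off_geno[mask, :, 1] = _transmit(rng, donor)

    frame = pd.concat(
        [
            _genotype_frame(np.array(fams), "mother", np.array(fams), loci, mother_geno),
            _genotype_frame(
                offspring["sapling_id"].to_numpy(),
                "offspring",
                offspring["family"].to_numpy(),
                loci,
                off_geno,
            ),
        ],
        ignore_index=True,
    )

    # genotyping error: replace one random allele call with a population draw
    if np.isscalar(error_rate):
        rates = {l.locus_id: float(error_rate) for l in loci}
    else:
        rates = {l.locus_id: float(error_rate.get(l.locus_id, 0.0)) for l in loci}
    if any(r > 0 for r in rates.values()):
        off_mask = frame["role"] == "offspring"
        for locus in loci:
            rate = rates[locus.locus_id]
            if rate <= 0:
                continue
            rows = frame.index[off_mask & (frame["locus"] == locus.locus_id)]
            hit = rows[rng.random(len(rows)) < rate]
            if len(hit) == 0:
                continue
            which = rng.integers(0, 2, size=len(hit))
            new = np.asarray(locus.alleles)[
                rng.choice(locus.n_alleles, size=len(hit), p=locus.frequencies)
            ]
            col1 = frame.columns.get_loc("allele_1")
            col2 = frame.columns.get_loc("allele_2")
            for r, w, a in zip(hit, which, new):
                frame.iat[r, col1 if w == 0 else col2] = float(a)

    if failure_rate > 0:
        ids = offspring["sapling_id"].to_numpy()
        failed = set(ids[rng.random(n_off) < failure_rate])
        if failed:
            bad = frame["individual_id"].isin(failed)
            frame.loc[bad, ["allele_1", "allele_2"]] = np.nan

    return frame


def simulate_dyads(
    kind: str,
    n_dyads: int,
    loci: list[LocusModel],
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate genotype pairs of known pedigree relationship.

    ``kind`` is ``"full-sib"`` (shared mother and father), ``"half-sib"``
    (shared mother, independent fathers) or ``"unrelated"``.  Returns two
    arrays of shape (n_dyads, n_loci, 2) of allele codes, one per dyad
    member.  Used for estimator-calibration checks.
    """
    rng = substream(seed, f"dyads-{kind}")
    if kind == "unrelated":
        return _draw_genotypes(rng, loci, n_dyads), _draw_genotypes(rng, loci, n_dyads)
    mothers = _draw_genotypes(rng, loci, n_dyads)
    fathers1 = _draw_genotypes(rng, loci, n_dyads)
    if kind == "full-sib":
        fathers2 = fathers1
    elif kind == "half-sib":
        fathers2 = _draw_genotypes(rng, loci, n_dyads)
    else:
        raise ValueError(f"unknown dyad kind: {kind!r}")
    g1 = np.stack([_transmit(rng, mothers), _transmit(rng, fathers1)], axis=2)
    g2 = np.stack([_transmit(rng, mothers), _transmit(rng, fathers2)], axis=2)
    return g1, g2


def apply_dropout(
    design: pd.DataFrame,
    death_rate: float = DEATH_RATE_DEFAULT,
    fail_rate: float = FAIL_RATE_DEFAULT,
    seed: int = 0,
) -> pd.DataFrame:
    """Flag mortality and genotyping failure on a design table.

    Each sapling dies independently with ``death_rate``; each survivor's
    genotype fails with ``fail_rate``.  Dead saplings are never genotyped.
    Returns a copy with updated ``alive`` / ``genotyped`` columns.
    """
    if not (0 <= death_rate <= 1 and 0 <= fail_rate <= 1):
        raise ValueError("rates must be in [0, 1]")
    rng = substream(seed, "dropout")
    out = design.copy()
    n = len(out)
    alive = rng.random(n) >= death_rate
    genotyped = alive & (rng.random(n) >= fail_rate)
    out["alive"] = alive
    out["genotyped"] = genotyped
    return out


def classify_damage(percent):
    """Map % leaf area damaged to its scoring class and midpoint score.

    Classes: 0, 1-5, 6-15, 16-25, 26-50, 51-75, >76 (% of leaf area); the
    score is the class midpoint (0, 3, 10.5, 20.5, 38, 63, 88).  Accepts a
    scalar or array; returns ``(label, score)`` or ``(labels, scores)``.
    """
    arr = np.asarray(percent, dtype=float)
    if np.any((arr < 0) | (arr > 100) | ~np.isfinite(arr)):
        raise ValueError("damage percentage must be within [0, 100]")
    idx = np.where(arr == 0.0, 0, np.searchsorted(_CLASS_UPPER_EDGES, arr, side="left") + 1)
    if np.isscalar(percent) or arr.ndim == 0:
        i = int(idx)
        return DAMAGE_CLASS_LABELS[i], float(DAMAGE_CLASS_MIDPOINTS[i])
    return np.asarray(DAMAGE_CLASS_LABELS, dtype=object)[idx], DAMAGE_CLASS_MIDPOINTS[idx]


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def simulate_herbivory(
    design: pd.DataFrame,
    fx: HerbivoryEffectSpec = HerbivoryEffectSpec(),
    seed: int = 0,
    n_leaves: int = 20,
) -> pd.DataFrame:
    """Simulate heights, ectophage damage and miner counts per sapling.

    Heights are family-specific lognormal.  Plot-level genetic diversity
    (GD = number of planted families) and height are standardized over the
    simulated saplings before entering the linear predictors.  See
    :class:`HerbivoryEffectSpec` for the damage model.

    Returns a phenotype table: sapling_id, height, ecto_damage (mean % leaf
    area over ``n_leaves`` midpoint-scored leaves), mine_count (per
    ``n_leaves`` leaves).
    """
    rng = substream(seed, "herbivory")
    df = design.reset_index(drop=True)
    n = len(df)

    present = set(df["family"])
    missing = sorted(present - set(fx.height_log_means)) or sorted(
        present - set(fx.family_means_monoculture)
    )
    if missing:
        raise ValueError(f"no effect model for families: {missing}")
    mu_h = df["family"].map(fx.height_log_means)
    height = np.exp(rng.normal(mu_h.to_numpy(dtype=float), fx.height_log_sd))

    gd = df["gd"].to_numpy(dtype=float)
    gd_std = _standardize_or_zero(gd)
    h_std = _standardize_or_zero(height)

    blocks = df["block"].unique()
    plots = df["plot"].unique()
    block_eff = dict(zip(blocks, rng.normal(0.0, fx.block_sd, size=len(blocks))))
    plot_eff = dict(zip(plots, rng.normal(0.0, fx.plot_sd, size=len(plots))))

    base = df["family"].map(lambda f: _logit(fx.family_means_monoculture[f] / 100.0))
    eta = (
        base.to_numpy(dtype=float)
        + fx.gd_slope * gd_std
        + fx.height_slope_ecto * h_std
        + df["block"].map(block_eff).to_numpy(dtype=float)
        + df["plot"].map(plot_eff).to_numpy(dtype=float)
    )
    if not np.all(np.isfinite(eta)):
        raise FloatingPointError("non-finite linear predictor in damage model")

    leaf_eta = eta[:, None] + rng.normal(0.0, fx.leaf_sd, size=(n, n_leaves))
    leaf_pct = 100.0 / (1.0 + np.exp(-leaf_eta))
    _, leaf_scores = classify_damage(leaf_pct)
    ecto = leaf_scores.mean(axis=1)

    log_mu = fx.miner_intercept + fx.height_slope_miner * h_std
    if not np.all(np.isfinite(log_mu)):
        raise FloatingPointError("non-finite linear predictor in miner model")
    mines = rng.poisson(np.exp(log_mu))

    return pd.DataFrame(
        {
            "sapling_id": df["sapling_id"],
            "height": height,
            "ecto_damage": ecto,
            "mine_count": mines,
        }
    )


def _standardize_or_zero(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def plot_gd_table(design: pd.DataFrame) -> pd.DataFrame:
    """Per-plot design GD (planted family count); thin wrapper over the design."""
    return plot_families(design)[["plot", "block", "gd"]]
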