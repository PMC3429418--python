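"""Additive partition of mixture herbivory into diversity-effect components.

For a mixture of n families in a block, each family i contributes an
observed response C_i (its damage at its 1/n share of the plot) and a
same-block monoculture reference M_i.  Observed relative forage is
RF_Oi = C_i / M_i, with null expectation RF_Ei = 1/n, and deviation
dRC_i = RF_Oi - 1/n.  The net genetic diversity effect

    NGDE = sum_i C_i - (1/n) * sum_i M_i

splits exactly into a complementarity effect CE = n * mean(dRC) * mean(M)
(a uniform change in relative consumption across families) and a selection
effect SE = n * cov(dRC, M) (population covariance: families' intrinsic
susceptibility covarying with their deviation in mixture), so
NGDE = CE + SE holds as an algebraic identity.  Positive NGDE indicates
associational susceptibility; negative, associational resistance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MixtureObservation",
    "PartitionResult",
    "PartitionInference",
    "relative_forage",
    "partition_mixture",
    "partition_all",
    "partition_tests",
    "partition_anova",
    "partition_table",
]

logger = logging.getLogger(__name__)

#: Alternative-hypothesis directions for the one-sided tests, following the
#: observed pattern (associational susceptibility: positive NGDE and CE,
#: negative SE).  Overridable per call.
DEFAULT_DIRECTIONS = {"NGDE": +1, "CE": +1, "SE": -1}


@dataclass(frozen=True)
class MixtureObservation:
    """One mixture plot with its same-block monoculture references.

    ``C`` holds each family's observed response at its 1/n plot share;
    ``M`` the family's monoculture response in the same block, in the same
    units (mean % leaf area, or mines per 20 leaves).
    """

    block_id: str
    plot_id: str
    families: tuple[str, ...]
    C: np.ndarray
    M: np.ndarray

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        M = np.asarray(self.M, dtype=float)
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "M", M)
        if len(self.families) < 2:
            raise ValueError("a mixture needs at least 2 families")
        if C.shape != M.shape or C.shape != (len(self.families),):
            raise ValueError("C and M must align with the family list")
        if np.any(C < 0) or np.any(M < 0):
            raise ValueError("responses must be non-negative")

    @property
    def n(self) -> int:
        return len(self.families)


@dataclass(frozen=True)
class PartitionResult:
    block_id: str
    plot_id: str
    n: int
    families: tuple[str, ...]
    ngde: float
    ce: float
    se: float
    rf_obs: np.ndarray
    delta_rc: np.ndarray


@dataclass(frozen=True)
class PartitionInference:
    effect: str
    scope: str
    mean: float
    t_statistic: float
    df: int
    p_value: float
    direction: int


def relative_forage(C_i: float, M_i: float) -> float:
    """Observed relative forage RF_Oi = C_i / M_i (undefined when M_i = 0)."""
    if M_i <= 0:
        raise ZeroDivisionError("relative forage undefined for monoculture response 0")
    return C_i / M_i


def partition_mixture(obs: MixtureObservation) -> PartitionResult:
    """Partition one mixture into NGDE, CE and SE.

    Requires every M_i > 0.  Uses the population covariance (denominator n)
    so the additivity NGDE = CE + SE is exact.
    """
    if np.any(obs.M <= 0):
        raise ZeroDivisionError(f"plot {obs.plot_id}: some monoculture response is 0")
    n = obs.n
    rf_obs = obs.C / obs.M
    delta_rc = rf_obs - 1.0 / n
    ngde = float(obs.C.sum() - obs.M.sum() / n)
    ce = float(n * delta_rc.mean() * obs.M.mean())
    # population covariance keeps the partition exactly additive
    se = float(n * np.mean((delta_rc - delta_rc.mean()) * (obs.M - obs.M.mean())))
    return PartitionResult(obs.block_id, obs.plot_id, n, obs.families, ngde, ce, se, rf_obs, delta_rc)


def partition_all(
    responses: pd.DataFrame,
    maternity: pd.DataFrame,
    design: pd.DataFrame,
    response: str = "ecto_damage",
) -> list[PartitionResult]:
    """Partition every mixture plot of a cohort, block by block.

    Saplings count as analyzable when alive, genotyped and maternally
    assigned (single-mismatch retentions included); families are the
    assigned maternal lineages.  For each mixture, C_i is the family's mean
    per-sapling response in the plot divided by the number of families
    present (its design share), and M_i is the family's mean per-sapling
    response in its same-block monoculture, so that without diversity
    effects RF_Oi has expectation 1/n and NGDE is centred on zero.
    Mixtures with a missing or zero monoculture reference, or a family with
    no analyzable sapling, are skipped and logged.
    """
    retained = maternity[maternity["status"].isin(["assigned", "flagged_one_mismatch"])]
    lineage = dict(zip(retained["offspring_id"], retained["best_mother"]))
    df = design.merge(responses, on="sapling_id", how="left")
    df = df[df["alive"] & df["genotyped"] & df["sapling_id"].isin(lineage)].copy()
    df["lineage"] = df["sapling_id"].map(lineage)
    if df[response].isna().any():
        raise ValueError("analyzable saplings with missing response values")

    results: list[PartitionResult] = []
    for block_id, bdf in df.groupby("block", sort=False):
        mono: dict[str, float] = {}
        for plot_id, pdf in bdf.groupby("plot", sort=False):
            planted = set(design.loc[design["plot"] == plot_id, "family"])
            if len(planted) == 1:
                (fam,) = planted
                mono[fam] = float(pdf[response].mean())
        for plot_id, pdf in bdf.groupby("plot", sort=False):
            planted = tuple(sorted(set(design.loc[design["plot"] == plot_id, "family"])))
            n = len(planted)
            if n == 1:
                continue
            fam_means = pdf.groupby("lineage")[response].mean()
            if any(f not in fam_means.index for f in planted):
                logger.warning("plot %s: family without analyzable sapling; skipped", plot_id)
                continue
            if any(f not in mono for f in planted):
                logger.warning("plot %s: missing monoculture reference; skipped", plot_id)
                continue
            M = np.array([mono[f] for f in planted])
            if np.any(M <= 0):
                logger.warning("plot %s: zero monoculture response; partition undefined", plot_id)
                continue
            C = np.array([fam_means[f] / n for f in planted])
            results.append(
                partition_mixture(MixtureObservation(str(block_id), str(plot_id), planted, C, M))
            )
    return results


def _effect_values(results: list[PartitionResult], effect: str) -> np.ndarray:
    attr = effect.lower()
    return np.array([getattr(res, attr) for res in results])


def partition_tests(
    results: list[PartitionResult],
    scope: str = "grand",
    directions: dict[str, int] = DEFAULT_DIRECTIONS,
) -> list[PartitionInference]:
    """One-sample, one-sided t-tests of NGDE, CE and SE against zero.

    ``scope`` is ``"grand"`` (all mixtures pooled; df = n_mixtures - 1) or
    ``"by_gd"`` (one test per diversity level).  ``directions`` gives the
    alternative-hypothesis sign per effect (+1: mean > 0, -1: mean < 0).
    """
    groups: dict[str, list[PartitionResult]]
    if scope == "grand":
        groups = {"grand": results}
    elif scope == "by_gd":
        groups = {}
        for res in results:
            groups.setdefault(f"GD={res.n}", []).append(res)
    else:
        raise ValueError(f"unknown scope: {scope!r}")

    out: list[PartitionInference] = []
    for label, group in groups.items():
        if len(group) < 2:
            raise ValueError(f"scope {label}: need >= 2 mixtures for a t-test")
        for effect in ("NGDE", "CE", "SE"):
            x = _effect_values(group, effect)
            n = x.size
            sd = x.std(ddof=1)
            direction = directions.get(effect, +1)
            if sd == 0:
                if x.mean() != 0:
                    raise ZeroDivisionError(f"{effect} has zero variance in scope {label}")
                t, p = 0.0, 0.5  # exactly-null limit
            else:
                t = x.mean() / (sd / np.sqrt(n))
                p = sps.t.sf(t, df=n - 1) if direction > 0 else sps.t.cdf(t, df=n - 1)
            out.append(PartitionInference(effect, label, float(x.mean()), float(t), n - 1, float(p), direction))
    return out


def partition_anova(results: list[PartitionResult]) -> pd.DataFrame:
    """One-way ANOVA of each effect across diversity (GD) levels."""
    levels: dict[int, list[PartitionResult]] = {}
    for res in results:
        levels.setdefault(res.n, []).append(res)
    usable = {n: grp for n, grp in levels.items() if len(grp) >= 2}
    if len(usable) < 2:
        raise ValueError("need >= 2 GD levels with >= 2 mixtures each")
    rows = []
    for effect in ("NGDE", "CE", "SE"):
        samples = [_effect_values(grp, effect) for grp in usable.values()]
        f, p = sps.f_oneway(*samples)
        rows.append((effect, float(f), float(p), len(usable)))
    return pd.DataFrame(rows, columns=["effect", "F", "p_value", "n_levels"])


def partition_table(results: list[PartitionResult]) -> pd.DataFrame:
    """Flatten results to the ``partition.csv`` contract (one row per mixture)."""
    rows = []
    for res in results:
        rows.append(
            {
                "block": res.block_id,
                "plot": res.plot_id,
                "n": res.n,
                "families": ";".join(res.families),
                "NGDE": res.ngde,
                "CE": res.ce,
                "SE": res.se,
                "RF_obs": ";".join(f"{v:.6g}" for v in res.rf_obs),
                "dRC": ";".join(f"{v:.6g}" for v in res.delta_rc),
            }
        )
    return pd.DataFrame(rows)
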