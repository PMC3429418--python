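"""Dyadic maximum-likelihood relatedness from codominant markers.

A non-inbred pair of diploids shares 0, 1 or 2 alleles identical by descent
(IBD) with probabilities (k0, k1, k2); relatedness is r = k1/2 + k2 (0.5
expected for full sibs, 0.25 for half sibs, 0 for unrelated pairs).  For
each dyad the likelihood of the observed genotype pair is, per locus,

    L(k) = k0 * P0 + k1 * P1 + k2 * P2,

where Pm is the probability of the genotype pair given m IBD alleles,
computed from population allele frequencies; the product over co-typed loci
is maximized over the probability simplex.  Pairwise estimates aggregate to
plot-level genetic relatedness (GR, the mean over distinct within-plot
pairs) alongside genetic diversity (GD, the number of maternal lineages).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from herbdiv.simulate import LocusModel

__all__ = [
    "IBDModeCoefficients",
    "DyadMLResult",
    "estimate_allele_frequencies",
    "ibd_mode_probabilities",
    "dyad_locus_likelihood",
    "dyadml",
    "relatedness_pairs",
    "plot_summaries",
    "grid_search_dyadml",
]

_LOG_FLOOR = 1e-300


@dataclass(frozen=True)
class IBDModeCoefficients:
    """IBD-mode probabilities (k0, k1, k2) of a non-inbred dyad."""

    k0: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        ks = (self.k0, self.k1, self.k2)
        if any(k < -1e-12 or k > 1 + 1e-12 for k in ks):
            raise ValueError("IBD coefficients must lie in [0, 1]")
        if abs(sum(ks) - 1.0) > 1e-9:
            raise ValueError("IBD coefficients must sum to 1")

    @property
    def r(self) -> float:
        """Relatedness r = k1/2 + k2."""
        return self.k1 / 2.0 + self.k2


@dataclass(frozen=True)
class DyadMLResult:
    k: IBDModeCoefficients
    r: float
    loglik: float
    loci_used: int
    low_confidence: bool = False


def estimate_allele_frequencies(genotypes: pd.DataFrame) -> list[LocusModel]:
    """Estimate per-locus allele frequencies by counting over all typed calls.

    Both mothers and offspring contribute.  A monomorphic locus triggers a
    warning (it carries no relatedness information) and is returned with a
    single allele at frequency 1; downstream it contributes a constant
    factor to every dyad likelihood.
    """
    panel: list[LocusModel] = []
    for locus, grp in genotypes.groupby("locus", sort=True):
        calls = pd.concat([grp["allele_1"], grp["allele_2"]]).dropna()
        if calls.empty:
            raise ValueError(f"locus {locus}: no typed individuals")
        counts = calls.astype(int).value_counts().sort_index()
        freqs = counts.to_numpy(dtype=float) / counts.sum()
        if len(counts) == 1:
            warnings.warn(f"locus {locus} is monomorphic: uninformative for relatedness")
            panel.append(_MonomorphicLocus(str(locus), (int(counts.index[0]),), freqs))
        else:
            panel.append(LocusModel(str(locus), tuple(int(a) for a in counts.index), freqs))
    return panel


class _MonomorphicLocus(LocusModel):
    """LocusModel permitting a single allele (frequency 1)."""

    def __post_init__(self) -> None:  # relax the >= 2 alleles expectation
        object.__setattr__(self, "frequencies", np.asarray(self.frequencies, dtype=float))


def _genotype_prob(a: int, b: int, locus: LocusModel) -> float:
    pa, pb = locus.frequency_of(a), locus.frequency_of(b)
    return pa * pa if a == b else 2.0 * pa * pb


def ibd_mode_probabilities(g1, g2, locus: LocusModel) -> tuple[float, float, float]:
    """(P0, P1, P2): probability of the unordered genotype pair given m IBD alleles.

    P0 treats the four genes as independent population draws.  P1 copies one
    gene of the second individual IBD from a uniformly chosen gene of the
    first, the other being an independent draw.  P2 copies both, so P2 is
    zero unless the genotypes coincide.
    """
    a, b = int(g1[0]), int(g1[1])
    c, d = int(g2[0]), int(g2[1])
    p1g = _genotype_prob(a, b, locus)
    p0 = p1g * _genotype_prob(c, d, locus)

    def trans(shared: int) -> float:
        # P(second genotype {c,d} | one gene IBD-copied from `shared`)
        if c == d:
            return locus.frequency_of(c) if shared == c else 0.0
        if shared == c:
            return locus.frequency_of(d)
        if shared == d:
            return locus.frequency_of(c)
        return 0.0

    p1 = p1g * 0.5 * (trans(a) + trans(b))
    p2 = p1g if sorted((a, b)) == sorted((c, d)) else 0.0
    return p0, p1, p2


def dyad_locus_likelihood(g1, g2, locus: LocusModel, k: IBDModeCoefficients) -> float:
    """Single-locus dyad likelihood k0*P0 + k1*P1 + k2*P2."""
    p0, p1, p2 = ibd_mode_probabilities(g1, g2, locus)
    return k.k0 * p0 + k.k1 * p1 + k.k2 * p2


def _mode_prob_matrix(g1: np.ndarray, g2: np.ndarray, panel: list[LocusModel]) -> np.ndarray:
    """(L_used, 3) matrix of (P0, P1, P2) over co-typed polymorphic loci."""
    rows = []
    for j, locus in enumerate(panel):
        pair1, pair2 = g1[j], g2[j]
        if np.any(pd.isna(pair1)) or np.any(pd.isna(pair2)):
            continue
        if locus.n_alleles < 2:
            continue  # monomorphic: constant factor, no information
        rows.append(ibd_mode_probabilities(pair1, pair2, locus))
    return np.asarray(rows, dtype=float).reshape(-1, 3)


def _simplex_grid(step: float) -> np.ndarray:
    n = int(round(1.0 / step))
    pts = []
    for i in range(n + 1):
        for j in range(n + 1 - i):
            k1, k2 = i * step, j * step
            pts.append((1.0 - k1 - k2, k1, k2))
    return np.asarray(pts)


_GRID_CACHE: dict[float, np.ndarray] = {}


def _loglik(P: np.ndarray, k: np.ndarray) -> float:
    return float(np.log(np.maximum(P @ k, _LOG_FLOOR)).sum())


def grid_search_dyadml(P: np.ndarray, step: float = 0.01) -> tuple[np.ndarray, float]:
    """Exhaustive simplex grid search; reference oracle for the optimizer."""
    grid = _GRID_CACHE.setdefault(step, _simplex_grid(step))
    ll = np.log(np.maximum(grid @ P.T, _LOG_FLOOR)).sum(axis=1)
    r = grid[:, 1] / 2 + grid[:, 2]
    best = np.lexsort((r, -ll))[0]  # ties broken toward smaller r
    return grid[best], float(ll[best])


def dyadml(
    g1,
    g2,
    panel: list[LocusModel],
    coarse_step: float = 0.05,
    min_informative_loci: int = 3,
) -> DyadMLResult:
    """Maximum-likelihood IBD-mode coefficients and relatedness for one dyad.

    ``g1`` and ``g2`` are (n_loci, 2) arrays of allele codes aligned with
    ``panel``; missing calls are NaN and the pair likelihood runs over
    co-typed polymorphic loci only.  The likelihood is maximized by a coarse
    simplex grid (step ``coarse_step``) followed by local SLSQP refinement;
    ties are broken toward smaller r.  No triangle constraint
    (k1^2 >= 4*k0*k2) is imposed.  Pairs with fewer than
    ``min_informative_loci`` co-typed loci are flagged low-confidence;
    zero co-typed loci raises.
    """
    P = _mode_prob_matrix(np.asarray(g1, dtype=float), np.asarray(g2, dtype=float), panel)
    if P.shape[0] == 0:
        raise ValueError("no co-typed informative loci for this dyad")
    k_best, ll_best = grid_search_dyadml(P, coarse_step)

    def neg_ll(x: np.ndarray) -> float:
        k = np.array([1.0 - x[0] - x[1], x[0], x[1]])
        return -_loglik(P, k)

    res = minimize(
        neg_ll,
        x0=np.array([k_best[1], k_best[2]]),
        method="SLSQP",
        bounds=[(0.0, 1.0), (0.0, 1.0)],
        constraints=[{"type": "ineq", "fun": lambda x: 1.0 - x[0] - x[1]}],
        options={"ftol": 1e-10, "maxiter": 200},
    )
    if res.success and -res.fun > ll_best + 1e-12:
        k1, k2 = np.clip(res.x, 0.0, 1.0)
        if k1 + k2 > 1.0:
            s = k1 + k2
            k1, k2 = k1 / s, k2 / s
        k_best = np.array([1.0 - k1 - k2, k1, k2])
        ll_best = _loglik(P, k_best)

    # the optimum must dominate the simplex vertices
    for vertex in np.eye(3):
        if _loglik(P, vertex) > ll_best + 1e-8:
            k_best, ll_best = vertex, _loglik(P, vertex)

    k = IBDModeCoefficients(*np.clip(k_best, 0.0, 1.0) / np.clip(k_best, 0.0, 1.0).sum())
    return DyadMLResult(
        k=k,
        r=k.r,
        loglik=ll_best,
        loci_used=int(P.shape[0]),
        low_confidence=P.shape[0] < min_informative_loci,
    )


def _genotype_arrays(
    genotypes: pd.DataFrame, panel: list[LocusModel], include_mothers: bool
) -> dict[str, np.ndarray]:
    order = {l.locus_id: j for j, l in enumerate(panel)}
    sub = genotypes if include_mothers else genotypes[genotypes["role"] == "offspring"]
    out: dict[str, np.ndarray] = {}
    for ind, grp in sub.groupby("individual_id", sort=False):
        arr = np.full((len(panel), 2), np.nan)
        idx = grp["locus"].map(order).to_numpy()
        arr[idx, 0] = grp["allele_1"].to_numpy(dtype=float)
        arr[idx, 1] = grp["allele_2"].to_numpy(dtype=float)
        out[str(ind)] = arr
    return out


def relatedness_pairs(
    genotypes: pd.DataFrame,
    panel: list[LocusModel] | None = None,
    pairs: list[tuple[str, str]] | None = None,
    include_mothers: bool = False,
) -> pd.DataFrame:
    """Dyadic ML relatedness for a set of individual pairs.

    With ``pairs=None`` every distinct pair of (offspring) individuals is
    estimated — quadratic in cohort size, so pass an explicit pair list
    (e.g. within-plot pairs) for large cohorts.  Allele frequencies default
    to counting over the full genotype table, mothers included.  Pairs with
    no co-typed locus are reported with NaN estimates.

    Returns a table: id1, id2, r, k0, k1, k2, loci_used, loglik,
    low_confidence.
    """
    if panel is None:
        panel = estimate_allele_frequencies(genotypes)
    genos = _genotype_arrays(genotypes, panel, include_mothers)
    if pairs is None:
        ids = list(genos)
        pairs = list(combinations(ids, 2))
    records = []
    for id1, id2 in pairs:
        try:
            res = dyadml(genos[id1], genos[id2], panel)
            records.append(
                (id1, id2, res.r, res.k.k0, res.k.k1, res.k.k2, res.loci_used, res.loglik, res.low_confidence)
            )
        except ValueError:
            records.append((id1, id2, np.nan, np.nan, np.nan, np.nan, 0, np.nan, True))
    return pd.DataFrame(
        records,
        columns=["id1", "id2", "r", "k0", "k1", "k2", "loci_used", "loglik", "low_confidence"],
    )


def within_plot_pairs(design: pd.DataFrame, analyzable_ids: set[str]) -> list[tuple[str, str]]:
    """All distinct within-plot pairs among analyzable saplings."""
    pairs: list[tuple[str, str]] = []
    for _, sub in design.groupby("plot", sort=False):
        ids = [s for s in sub["sapling_id"] if s in analyzable_ids]
        pairs.extend(combinations(ids, 2))
    return pairs


def plot_summaries(
    relmatrix: pd.DataFrame,
    maternity: pd.DataFrame,
    design: pd.DataFrame,
) -> pd.DataFrame:
    """Per-plot genetic diversity (GD) and genetic relatedness (GR).

    Analyzable saplings are alive, genotyped and maternally assigned
    (single-mismatch retentions included).  GD counts distinct assigned
    maternal lineages; GR is the mean pairwise r among within-plot pairs
    present in ``relmatrix`` and is NaN when fewer than 2 analyzable
    saplings (or no estimated pair) exist.
    """
    retained = maternity[maternity["status"].isin(["assigned", "flagged_one_mismatch"])]
    lineage = dict(zip(retained["offspring_id"], retained["best_mother"]))
    ok = design["alive"] & design["genotyped"] & design["sapling_id"].isin(lineage)
    analyzable = design[ok]

    pair_r: dict[tuple[str, str], float] = {}
    for id1, id2, r in zip(relmatrix["id1"], relmatrix["id2"], relmatrix["r"]):
        pair_r[(id1, id2)] = r
        pair_r[(id2, id1)] = r

    records = []
    for plot_id, sub in design.groupby("plot", sort=False):
        ids = analyzable.loc[analyzable["plot"] == plot_id, "sapling_id"].tolist()
        gd = len({lineage[i] for i in ids})
        rs = [
            pair_r[(i, j)]
            for i, j in combinations(ids, 2)
            if (i, j) in pair_r and np.isfinite(pair_r[(i, j)])
        ]
        gr = float(np.mean(rs)) if rs else np.nan
        records.append((plot_id, sub["block"].iloc[0], gd, gr, len(ids)))
    return pd.DataFrame(records, columns=["plot", "block", "gd", "gr", "n_saplings"])
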