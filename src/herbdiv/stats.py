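"""Transforms and mixed-model scaffolding for the herbivory regressions.

This module owns what the analysis prescribes — the logit transform for
percentage damage, centring/scaling of continuous predictors, the model
structures (plot nested in block as random intercepts; GD and GR entered
in separate models), and the backward simplification of interaction terms —
while delegating estimation to statsmodels: linear mixed models for
(logit-transformed) ectophage damage and sapling height, and Poisson
regression with plot-clustered robust covariance for leaf-miner counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

__all__ = [
    "ModelSpec",
    "FitSummary",
    "logit_transform",
    "inverse_logit",
    "standardize",
    "fit_model",
    "simplify_model",
    "fit_herbivory_models",
    "fit_height",
    "kruskal_gr_by_gd",
    "prepare_analysis_table",
]


def logit_transform(p, eps: float | None = None):
    """log((p + eps) / (1 - p + eps)) for proportions in [0, 1].

    With ``eps=None`` the adjustment is half the smallest nonzero observed
    proportion — a standard boundary correction that leaves the transform
    symmetric (0.5 maps to 0) and defined at 0 and 1.  Pass ``eps=0`` for
    the exact logit of interior data.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    if eps is None:
        nonzero = arr[arr > 0]
        if nonzero.size == 0:
            raise ValueError("cannot choose eps: no nonzero proportions observed")
        eps = float(nonzero.min()) / 2.0
    if eps == 0 and (np.any(arr == 0) or np.any(arr == 1)):
        raise ValueError("eps=0 undefined at the boundary values 0 and 1")
    out = np.log((arr + eps) / (1.0 - arr + eps))
    return float(out) if np.isscalar(p) else out


def inverse_logit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def standardize(x) -> np.ndarray:
    """Centre to mean 0 and scale to sample SD 1 (ddof=1)."""
    arr = np.asarray(x, dtype=float)
    if arr.size < 2 or np.unique(arr).size < 2:
        raise ValueError("standardize needs >= 2 distinct values")
    return (arr - arr.mean()) / arr.std(ddof=1)


@dataclass(frozen=True)
class ModelSpec:
    """Structure of one herbivory regression.

    ``fixed`` are main-effect column names (categorical columns are handled
    by the formula machinery); ``interactions`` are tuples of those names.
    GD and GR must not co-occur (they enter separate models).  ``random``
    is ``"plot_in_block"`` (random intercepts for block and plot nested in
    block) or ``"none"``; Poisson models use plot-clustered robust
    covariance in place of explicit random intercepts.
    """

    response: str
    fixed: tuple[str, ...]
    interactions: tuple[tuple[str, ...], ...] = ()
    family: str = "gaussian"
    random: str = "plot_in_block"

    def __post_init__(self) -> None:
        if "GD" in self.fixed and "GR" in self.fixed:
            raise ValueError("GD and GR are alternative diversity measures; use separate models")
        if self.family not in ("gaussian", "poisson"):
            raise ValueError(f"unknown family: {self.family!r}")
        for terms in self.interactions:
            for t in terms:
                if t not in self.fixed:
                    raise ValueError(f"interaction term {t} lacks its main effect")

    @property
    def formula(self) -> str:
        terms = list(self.fixed) + [":".join(t) for t in self.interactions]
        return f"{self.response} ~ " + " + ".join(terms) if terms else f"{self.response} ~ 1"


@dataclass
class FitSummary:
    """Term-level summary of one fitted model.

    ``table`` columns: term, coef, se, stat (Wald chi2), df, p_value, r2
    (likelihood-ratio R2 of adding the term last; NaN where not computed).
    Multi-level categorical terms report NaN coef/se, as is conventional.
    """

    spec: ModelSpec
    table: pd.DataFrame
    loglik: float
    nobs: int
    converged: bool = True
    random_structure: str = "plot_in_block"
    flags: list[str] = field(default_factory=list)


def _fit_formula(spec: ModelSpec, data: pd.DataFrame, formula: str | None = None):
    """Fit one formula under the spec's family/random structure.

    Returns (results, random_structure_used, flags).
    """
    formula = formula or spec.formula
    flags: list[str] = []
    if spec.family == "poisson":
        if spec.random == "plot_in_block":
            model = smf.glm(formula, data, family=sm.families.Poisson())
            res = model.fit(cov_type="cluster", cov_kwds={"groups": data["plot"]})
            return res, "cluster_by_plot", flags
        res = smf.glm(formula, data, family=sm.families.Poisson()).fit()
        return res, "none", flags

    if spec.random == "none":
        return smf.ols(formula, data).fit(), "none", flags
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(
                formula, data, groups=data["block"], re_formula="1",
                vc_formula={"plot": "0 + C(plot)"},
            )
            res = model.fit(reml=False)
            if res.converged:
                return res, "plot_in_block", flags
        except Exception:
            pass
        flags.append("random_effects_fallback_block_only")
        try:
            res = smf.mixedlm(formula, data, groups=data["block"], re_formula="1").fit(reml=False)
            if res.converged:
                return res, "block_only", flags
        except Exception:
            pass
    flags.append("random_effects_dropped")
    return smf.ols(formula, data).fit(), "none", flags


def _term_table(res, random_structure: str) -> pd.DataFrame:
    """Wald chi-square per model term from the fitted covariance."""
    design_info = res.model.data.design_info
    params = np.asarray(res.fe_params if hasattr(res, "fe_params") else res.params)
    names = list(design_info.column_names)
    cov = pd.DataFrame(np.asarray(res.cov_params()), index=None)
    cov = cov.iloc[: len(names), : len(names)].to_numpy()
    rows = []
    for term, slc in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = np.arange(len(names))[slc]
        beta = params[idx]
        V = cov[np.ix_(idx, idx)]
        try:
            stat = float(beta @ np.linalg.solve(V, beta))
        except np.linalg.LinAlgError:
            stat = np.nan
        df = len(idx)
        p = float(sps.chi2.sf(stat, df)) if np.isfinite(stat) else np.nan
        if df == 1:
            coef, se = float(beta[0]), float(np.sqrt(V[0, 0]))
        else:
            coef, se = np.nan, np.nan
        rows.append((term, coef, se, stat, df, p, np.nan))
    return pd.DataFrame(rows, columns=["term", "coef", "se", "stat", "df", "p_value", "r2"])


def _loglik(res) -> float:
    return float(res.llf)


def fit_model(spec: ModelSpec, data: pd.DataFrame, compute_r2: bool = False) -> FitSummary:
    """Fit one model spec and summarize it per term.

    ``compute_r2`` additionally refits the model without each term (and the
    intercept-only null) to attach likelihood-ratio R2 values,
    1 - exp(-2 * (ll_with - ll_without) / n); linear mixed models use ML
    (not REML) likelihoods so these comparisons are valid.
    """
    res, random_used, flags = _fit_formula(spec, data)
    table = _term_table(res, random_used)
    summary = FitSummary(
        spec=spec,
        table=table,
        loglik=_loglik(res),
        nobs=int(res.model.endog.shape[0]),
        converged=getattr(res, "converged", True),
        random_structure=random_used,
        flags=flags,
    )
    if compute_r2:
        n = summary.nobs
        for i, term in enumerate(table["term"]):
            reduced = _drop_term_formula(spec, term)
            try:
                res_red, _, _ = _fit_formula(spec, data, formula=reduced)
                lr = 2.0 * (summary.loglik - _loglik(res_red))
                summary.table.loc[i, "r2"] = float(1.0 - np.exp(-max(lr, 0.0) / n))
            except Exception:
                summary.flags.append(f"r2_failed:{term}")
    return summary


def _drop_term_formula(spec: ModelSpec, term: str) -> str:
    all_terms = list(spec.fixed) + [":".join(t) for t in spec.interactions]
    kept = [t for t in all_terms if t != term]
    return f"{spec.response} ~ " + (" + ".join(kept) if kept else "1")


def simplify_model(
    spec: ModelSpec, data: pd.DataFrame, alpha: float = 0.05
) -> tuple[ModelSpec, FitSummary]:
    """Backward-eliminate non-significant interactions, highest order first.

    Repeatedly refits, dropping the least significant interaction of the
    highest remaining order whenever its p-value exceeds ``alpha``; main
    effects are never dropped.  A non-convergent refit retains the term and
    flags it.  Terminates after at most one pass per interaction.
    """
    current = spec
    for _ in range(len(spec.interactions) + 1):
        summary = fit_model(current, data)
        if not current.interactions:
            return current, summary
        inter_names = {":".join(t): t for t in current.interactions}
        max_order = max(len(t) for t in current.interactions)
        rows = summary.table[
            summary.table["term"].isin(
                [nm for nm, t in inter_names.items() if len(t) == max_order]
            )
        ]
        if not summary.converged:
            summary.flags.append("simplification_stopped_nonconvergent")
            return current, summary
        worst = rows.loc[rows["p_value"].idxmax()]
        if worst["p_value"] <= alpha or not np.isfinite(worst["p_value"]):
            return current, summary
        dropped = inter_names[worst["term"]]
        current = replace(
            current,
            interactions=tuple(t for t in current.interactions if t != dropped),
        )
    return current, fit_model(current, data)


def prepare_analysis_table(
    responses: pd.DataFrame,
    maternity: pd.DataFrame,
    design: pd.DataFrame,
    plot_summary: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the per-sapling regression table.

    Keeps analyzable saplings (alive, genotyped, maternally assigned) and
    returns columns: y_ecto (logit-transformed damage proportion),
    mine_count, height_sq, H / GD / GR (standardized), MT (assigned
    lineage), block, plot.
    """
    retained = maternity[maternity["status"].isin(["assigned", "flagged_one_mismatch"])]
    lineage = dict(zip(retained["offspring_id"], retained["best_mother"]))
    df = design.merge(responses, on="sapling_id", how="left")
    df = df[df["alive"] & df["genotyped"] & df["sapling_id"].isin(lineage)].copy()
    df["MT"] = df["sapling_id"].map(lineage)
    summary_cols = ["plot", "gd", "gr"] if "gr" in plot_summary.columns else ["plot", "gd"]
    df = df.merge(plot_summary[summary_cols], on="plot", how="left", suffixes=("", "_obs"))
    out = pd.DataFrame(
        {
            "sapling_id": df["sapling_id"],
            "block": df["block"],
            "plot": df["plot"],
            "MT": df["MT"],
            "y_ecto": logit_transform(df["ecto_damage"].to_numpy() / 100.0),
            "mine_count": df["mine_count"].to_numpy(),
            "height_sq": df["height"].to_numpy() ** 2,
            "H": standardize(df["height"]),
            "GD": standardize(df["gd_obs"] if "gd_obs" in df.columns else df["gd"]),
        }
    )
    if "gr" in df.columns:
        out["GR"] = standardize(df["gr"])
    return out.reset_index(drop=True)


def fit_herbivory_models(data: pd.DataFrame, compute_r2: bool = False) -> dict[str, FitSummary]:
    """Fit the four herbivory model families.

    For each diversity measure (GD, GR, entered separately): a linear mixed
    model of logit ectophage damage on H + MT + measure, and a Poisson
    model of miner counts on H + MT + measure + H x measure, both with the
    plot-in-block error structure.  Keys: ``"{measure}_{guild}"``.
    """
    out: dict[str, FitSummary] = {}
    for measure in ("GD", "GR"):
        if measure not in data.columns:
            continue
        ecto = ModelSpec("y_ecto", ("H", "MT", measure), family="gaussian")
        miner = ModelSpec(
            "mine_count",
            ("H", "MT", measure),
            interactions=(("H", measure),),
            family="poisson",
        )
        out[f"{measure}_ecto"] = fit_model(ecto, data, compute_r2=compute_r2)
        out[f"{measure}_miner"] = fit_model(miner, data, compute_r2=compute_r2)
    return out


def fit_height(data: pd.DataFrame, measure: str = "GD") -> FitSummary:
    """Linear mixed model of squared height on MT and one diversity measure."""
    spec = ModelSpec("height_sq", ("MT", measure), family="gaussian")
    return fit_model(spec, data)


def kruskal_gr_by_gd(plot_summary: pd.DataFrame) -> tuple[float, int, float]:
    """Kruskal-Wallis test of plot genetic relatedness across GD levels."""
    groups = [
        grp["gr"].dropna().to_numpy()
        for _, grp in plot_summary.groupby("gd")
        if grp["gr"].notna().sum() > 0
    ]
    if len(groups) < 2:
        raise ValueError("need >= 2 GD levels with GR values")
    stat, p = sps.kruskal(*groups)
    return float(stat), len(groups) - 1, float(p)


def model_summary_frame(fits: dict[str, FitSummary]) -> pd.DataFrame:
    """Flatten fit summaries to the ``model_summary.csv`` contract."""
    rows = []
    for key, summary in fits.items():
        measure, guild = key.split("_", 1)
        for _, row in summary.table.iterrows():
            rows.append(
                {
                    "model": key,
                    "measure": measure,
                    "guild": guild,
                    "term": row["term"],
                    "coef": row["coef"],
                    "se": row["se"],
                    "stat": row["stat"],
                    "df": row["df"],
                    "p_value": row["p_value"],
                    "r2": row["r2"],
                    "random_structure": summary.random_structure,
                    "converged": summary.converged,
                }
            )
    return pd.DataFrame(rows)
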