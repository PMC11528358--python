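"""Mixed-model summaries of simulation output and the protective effect.

Three Gaussian linear mixed models summarize per-individual accumulated
infection cost, each with the same random-intercept structure (group-year,
individual ID, and group-year x simulation number):

- model 1: ``cost ~ age`` — the total age effect, including whatever part
  of it travels through age-related differences in social centrality;
- model 2: ``cost ~ age + degree + strength + closeness`` (each centrality
  z-scored within group-year and binned into five ordered categories) — the
  age effect net of social position;
- model 3: ``cost ~ age * (degree + strength + closeness)`` — how the cost
  of occupying each social category changes with age.

The **protective effect of social ageing** is the model-1 age coefficient
minus the model-2 age coefficient: negative values mean that age-related
declines in social centrality absorb part of the age trend in infection
cost, i.e. that social ageing buffers infection risk.  Model 3 yields
age-specific contrasts: the predicted change in cost from moving between
two centrality categories at a young (8 y) versus an old (18 y) age.

Because the focus is description of simulation output rather than
hypothesis testing, effect sizes (with SEs) are reported, not p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "CATEGORY_LABELS",
    "ProtectiveEffectReport",
    "zscore_bin",
    "build_frame",
    "fit_models",
    "protective_effect",
    "cost_to_infections",
    "age_contrast",
    "summarize_experiment",
]

#: Ordered centrality categories from within-group-year z-scores.
CATEGORY_LABELS = ("very_low", "low", "average", "high", "very_high")
#: Bin edges on the z scale; intervals are closed on the left
#: ([-1.5, -0.5) is "low", [0.5, 1.5) is "high", ...).
CATEGORY_EDGES = (-np.inf, -1.5, -0.5, 0.5, 1.5, np.inf)

_METRICS = ("degree", "strength", "closeness")


@dataclass(frozen=True)
class ModelFit:
    """Fixed-effect table (and diagnostics) for one mixed model."""

    model: int
    params: pd.Series
    bse: pd.Series
    converged: bool
    singular: bool
    n_obs: int

    def coef(self, name: str) -> float:
        return float(self.params[name])

    def se(self, name: str) -> float:
        return float(self.bse[name])


@dataclass(frozen=True)
class ProtectiveEffectReport:
    """Protective-effect summary for one parameterization."""

    param_id: str
    beta_age_m1: float
    se_m1: float
    beta_age_m2: float
    se_m2: float
    protective_effect: float
    # metric -> (contrast at age_young, contrast at age_old); each contrast is
    # the predicted cost change moving high -> average at that age
    model3_contrasts: dict[str, tuple[float, float]]


def bin_z(z: pd.Series | np.ndarray) -> pd.Series:
    """Map z-scores to the five ordered centrality categories.

    Intervals are closed on the left, so z = -1.5 is "low", z = 0.5 is
    "high", and the five bins partition the whole line with no gaps.
    """
    binned = pd.cut(pd.Series(np.asarray(z, dtype=float)),
                    bins=CATEGORY_EDGES, labels=CATEGORY_LABELS, right=False)
    return binned.astype(pd.CategoricalDtype(CATEGORY_LABELS, ordered=True))


def zscore_bin(values: pd.Series, group: pd.Series) -> pd.Series:
    """Within-group z-score then 5-category bin (see :func:`bin_z`).

    Raises if any group has zero variance (binning would be undefined).
    """
    g = values.groupby(group)
    sd = g.transform("std")
    bad = sd.isna() | (sd == 0)
    if bad.any():
        culprit = group[bad].iloc[0]
        raise ValueError(f"zero within-group variance in group-year {culprit!r}")
    z = (values - g.transform("mean")) / sd
    out = bin_z(z)
    out.index = values.index
    return out


def build_frame(results: pd.DataFrame, centralities: pd.DataFrame) -> pd.DataFrame:
    """Join per-individual simulation costs with per-draw centralities and
    add the three binned centrality categories.

    ``results`` needs columns (group_year, draw, id, age, cost) — typically
    :func:`socage.epi.results_table` restricted to one parameterization —
    and ``centralities`` the output of :func:`socage.centrality.centrality_table`.
    z-scoring is within group-year, pooling individuals and draws.
    """
    merged = results.merge(
        centralities[["group_year", "draw", "id", "strength", "closeness", "degree"]],
        on=["group_year", "draw", "id"],
        how="left",
        validate="many_to_one",
    )
    if merged[["strength", "closeness", "degree"]].isna().any().any():
        missing = merged.loc[merged["strength"].isna(), ["group_year", "draw", "id"]].iloc[0]
        raise KeyError(f"no centrality record for {tuple(missing)}")
    for m in _METRICS:
        merged[f"{m}_cat"] = zscore_bin(merged[m].astype(float), merged["group_year"])
    merged["sim"] = merged["group_year"].astype(str) + ":" + merged["draw"].astype(str)
    return merged


def _categorical_terms(frame: pd.DataFrame, interaction: bool) -> list[str]:
    terms = []
    for m in _METRICS:
        col = f"{m}_cat"
        observed = [c for c in CATEGORY_LABELS if (frame[col] == c).any()]
        if "average" not in observed:
            raise ValueError(f"reference category 'average' absent for {m}")
        levels = "', '".join(["average"] + [c for c in observed if c != "average"])
        term = f"C({col}, levels=['{levels}'])"
        terms.append(term)
        if interaction:
            terms.append(f"age:{term}")
    return terms


def fit_models(frame: pd.DataFrame, which: int) -> ModelFit:
    """Fit mixed model 1, 2 or 3 on an analysis frame.

    Random intercepts: group-year (grouping factor), individual ID and
    group-year x simulation number (variance components within group-year;
    both are nested in group-year here, which makes the crossed structure
    exactly representable).  The reference level for every centrality
    factor is "average", so the model-3 "high" coefficients read directly
    as high-vs-average contrasts.  Non-convergence and singular variance
    components are reported on the fit, not raised.
    """
    if which not in (1, 2, 3):
        raise ValueError("which must be 1, 2 or 3")
    if which == 1:
        fixed = "age"
    else:
        terms = _categorical_terms(frame, interaction=(which == 3))
        fixed = " + ".join(["age"] + terms)
    formula = f"cost ~ {fixed}"
    vc = {"individual": "0 + C(id)", "simulation": "0 + C(sim)"}
    model = smf.mixedlm(formula, frame, groups=frame["group_year"], re_formula="1", vc_formula=vc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = model.fit(method="lbfgs", maxiter=200)
    fe = fit.fe_params
    singular = bool(
        np.any(np.asarray(fit.vcs if hasattr(fit, "vcs") else []) <= 1e-10)
        or fit.cov_re.values.min() <= 1e-10
    )
    if not fit.converged:
        warnings.warn(f"model {which} did not fully converge; estimates retained")
    return ModelFit(
        model=which,
        params=fe,
        bse=fit.bse_fe,
        converged=bool(fit.converged),
        singular=singular,
        n_obs=len(frame),
    )


def protective_effect(beta_m1: float, beta_m2: float) -> float:
    """Model-1 age coefficient minus model-2 age coefficient.

    Negative values indicate that age-related centrality differences buffer
    infection cost (a protective effect of social ageing).
    """
    return beta_m1 - beta_m2


def cost_to_infections(cost_units: float, di: int = 5, ci: float = 1.0) -> float:
    """Convert cost units to baseline-infection equivalents (one baseline
    infection costs di * ci units)."""
    denom = di * ci
    if denom == 0:
        raise ZeroDivisionError("di * ci must be non-zero")
    return cost_units / denom


def _coef_names(fit: ModelFit, metric: str, cat: str) -> tuple[str, str]:
    main = inter = None
    for name in fit.params.index:
        if f"{metric}_cat" in name and name.endswith(f"[T.{cat}]"):
            if name.startswith("age:"):
                inter = name
            else:
                main = name
    if main is None:
        raise KeyError(f"category {cat!r} absent from model-{fit.model} fit for {metric}")
    return main, inter


def age_contrast(
    fit: ModelFit,
    metric: str,
    from_cat: str = "high",
    to_cat: str = "average",
    age_young: float = 8.0,
    age_old: float = 18.0,
) -> tuple[float, float]:
    """Predicted cost change moving ``from_cat`` -> ``to_cat`` at two ages.

    Computed from model-3 fixed effects: with "average" as reference, the
    predicted cost difference (to_cat - from_cat) at age a is
    ``(beta_to + a * beta_age:to) - (beta_from + a * beta_age:from)`` where
    reference-category terms are zero.  Negative values mean the move
    lowers infection cost.  Returns (young, old).
    """
    if fit.model != 3:
        raise ValueError("age contrasts require a model-3 fit")

    def predicted(cat: str, age: float) -> float:
        if cat == "average":
            return 0.0
        main, inter = _coef_names(fit, metric, cat)
        val = fit.coef(main)
        if inter is not None:
            val += age * fit.coef(inter)
        return val

    return tuple(
        predicted(to_cat, a) - predicted(from_cat, a) for a in (age_young, age_old)
    )


def summarize_experiment(
    results: pd.DataFrame,
    centralities: pd.DataFrame,
    contrasts: bool = True,
) -> list[ProtectiveEffectReport]:
    """Fit models 1-3 separately for every parameterization present in
    ``results`` and assemble protective-effect reports."""
    reports = []
    for param_id, sub in results.groupby("param_id", sort=True):
        frame = build_frame(sub.drop(columns=["param_id"]), centralities)
        m1 = fit_models(frame, 1)
        m2 = fit_models(frame, 2)
        c3: dict[str, tuple[float, float]] = {}
        if contrasts:
            m3 = fit_models(frame, 3)
            for metric in _METRICS:
                try:
                    c3[metric] = age_contrast(m3, metric)
                except KeyError:
                    c3[metric] = (np.nan, np.nan)
        reports.append(
            ProtectiveEffectReport(
                param_id=str(param_id),
                beta_age_m1=m1.coef("age"),
                se_m1=m1.se("age"),
                beta_age_m2=m2.coef("age"),
                se_m2=m2.se("age"),
                protective_effect=protective_effect(m1.coef("age"), m2.coef("age")),
                model3_contrasts=c3,
            )
        )
    return reports


def report_table(reports: list[ProtectiveEffectReport]) -> pd.DataFrame:
    """Flatten reports to one row per parameterization."""
    rows = []
    for r in reports:
        row = {
            "param_id": r.param_id,
            "beta_age_m1": r.beta_age_m1,
            "se_m1": r.se_m1,
            "beta_age_m2": r.beta_age_m2,
            "se_m2": r.se_m2,
            "protective_effect": r.protective_effect,
        }
        for m, (young, old) in r.model3_contrasts.items():
            row[f"{m}_high_to_avg_young"] = young
            row[f"{m}_high_to_avg_old"] = old
        rows.append(row)
    return pd.DataFrame(rows)
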