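"""Statistical analysis of the implantation campaign.

The design sweep is analysed with the campaign's standard battery: Spearman rank
correlations between ring dimensions and outcomes, one-way ANOVA with Tukey
HSD post-hoc comparisons across categories and diameters, backward-elimination
multivariate regression of each outcome on the basic design parameters
(horizontal dimension H, vertical dimension V, implantation diameter D) with
VIF screening, and an adjusted-R^2 variance-contribution decomposition
(LMG-style averaging over predictor orderings) whose residual share is
attributed to the detailed implant design.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["OUTCOMES", "PREDICTORS", "spearman_matrix", "anova_tukey",
           "backward_regression", "contribution_decomposition",
           "ContributionReport", "RegressionResult"]

OUTCOMES = ("delta_k_mean", "delta_axial_length", "delta_cct",
            "max_contact_pressure")
PREDICTORS = ("horizontal", "vertical", "diameter")


# ---------------------------------------------------------------------------
# Spearman correlations
# ---------------------------------------------------------------------------

def spearman_matrix(table: pd.DataFrame,
                    predictors=("horizontal", "vertical"),
                    outcomes=OUTCOMES) -> pd.DataFrame:
    """Spearman rho and two-sided p between design parameters and outcomes.

    Average-rank ties; two-sided p via the t approximation (scipy).  A
    constant column yields NaN rho, reported as such.
    """
    if len(table) < 10:
        raise ValueError("need at least 10 configurations")
    rows = []
    for out in outcomes:
        for pred in predictors:
            x, y = table[pred].to_numpy(), table[out].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rho, p = np.nan, np.nan
            else:
                rho, p = sps.spearmanr(x, y)
            rows.append({"outcome": out, "predictor": pred,
                         "rho": rho, "p_value": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ANOVA + Tukey HSD
# ---------------------------------------------------------------------------

def anova_tukey(table: pd.DataFrame, factor: str, outcome: str,
                within: str | None = None) -> pd.DataFrame:
    """One-way ANOVA per grouping with Tukey HSD pairwise adjusted p-values.

    ``within`` optionally stratifies the comparison (e.g. diameters compared
    within each ring category, the structure of the campaign's diameter
    comparison).  Degenerate strata (a level with < 2 observations, or zero
    variance everywhere) are flagged in the output.
    """
    strata = [(None, table)] if within is None else list(table.groupby(within))
    rows = []
    for name, sub in strata:
        levels = sub[factor].unique()
        if len(levels) < 2:
            raise ValueError(f"factor {factor!r} needs >= 2 levels in stratum {name!r}")
        counts = sub.groupby(factor)[outcome].count()
        if (counts < 2).any():
            raise ValueError(f"empty/singleton cell in stratum {name!r}: "
                             f"{counts[counts < 2].index.tolist()}")
        groups = [g[outcome].to_numpy() for _, g in sub.groupby(factor)]
        if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
            rows.append({"stratum": name, "level_1": None, "level_2": None,
                         "F": np.nan, "anova_p": np.nan, "tukey_p": np.nan,
                         "degenerate": True})
            continue
        F, p = sps.f_oneway(*groups)
        tk = pairwise_tukeyhsd(sub[outcome].to_numpy(),
                               sub[factor].astype(str).to_numpy())
        pairs = list(itertools.combinations(tk.groupsunique, 2))
        for (g1, g2), p_adj in zip(pairs, tk.pvalues):
            rows.append({"stratum": name, "level_1": g1, "level_2": g2,
                         "F": F, "anova_p": p, "tukey_p": float(p_adj),
                         "degenerate": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# backward-elimination regression with VIF
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    outcome: str
    kept: list
    params: pd.Series
    pvalues: pd.Series
    r2_adj: float
    vif: dict
    excluded_by_vif: list = field(default_factory=list)
    model: object = None


def _vif(table: pd.DataFrame, predictors) -> dict:
    """Variance inflation factors via auxiliary regressions 1/(1 - R_j^2)."""
    out = {}
    for j in predictors:
        others = [p for p in predictors if p != j]
        if not others:
            out[j] = 1.0
            continue
        X = sm.add_constant(table[others])
        r2 = sm.OLS(table[j], X).fit().rsquared
        out[j] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return out


def backward_regression(table: pd.DataFrame, outcome: str,
                        predictors=PREDICTORS, vif_threshold: float = 10.0,
                        alpha: float = 0.05) -> RegressionResult:
    """OLS with VIF pre-screening and backward elimination at p <= alpha."""
    preds = [p for p in predictors if np.ptp(table[p].to_numpy()) > 0]
    if not preds:
        raise ValueError("all predictors constant")
    vif = _vif(table, preds)
    excluded = []
    while len(preds) > 1 and max(vif[p] for p in preds) > vif_threshold:
        worst = max(preds, key=lambda p: vif[p])
        preds.remove(worst)
        excluded.append(worst)
        vif = {**vif, **_vif(table, preds)}
    fit = None
    while preds:
        X = sm.add_constant(table[list(preds)])
        fit = sm.OLS(table[outcome], X).fit()
        pv = fit.pvalues.drop("const")
        if pv.max() <= alpha:
            break
        preds.remove(pv.idxmax())
    if not preds:
        fit = sm.OLS(table[outcome], np.ones(len(table))).fit()
    return RegressionResult(outcome=outcome, kept=list(preds),
                            params=fit.params, pvalues=fit.pvalues,
                            r2_adj=float(fit.rsquared_adj), vif=vif,
                            excluded_by_vif=excluded, model=fit)


# ---------------------------------------------------------------------------
# variance-contribution decomposition
# ---------------------------------------------------------------------------

@dataclass
class ContributionReport:
    outcome: str
    shares: dict  # predictor -> share in [0, 1]; key "design" = residual
    r2_adj_full: float

    def as_series(self) -> pd.Series:
        return pd.Series(self.shares, name=self.outcome)


def _r2_adj(table, outcome, preds) -> float:
    if not preds:
        return 0.0
    X = sm.add_constant(table[list(preds)])
    return float(sm.OLS(table[outcome], X).fit().rsquared_adj)


def contribution_decomposition(table: pd.DataFrame, outcome: str,
                               predictors=PREDICTORS) -> ContributionReport:
    """Share of outcome variance attributed to each design parameter.

    Adjusted-R^2 increments are averaged over all predictor orderings
    (LMG-style, order-invariant); negative increments are clipped at zero.
    The unexplained share 1 - R^2_adj(full) is attributed to the detailed
    implant design ("design"); shares are renormalized to sum to one.
    """
    preds = [p for p in predictors if np.ptp(table[p].to_numpy()) > 0]
    increments = {p: [] for p in preds}
    for order in itertools.permutations(preds):
        r_prev = 0.0
        for k, p in enumerate(order):
            r_now = _r2_adj(table, outcome, order[:k + 1])
            increments[p].append(max(0.0, r_now - r_prev))
            r_prev = max(r_prev, r_now)
    raw = {p: float(np.mean(v)) for p, v in increments.items()}
    r2_full = max(0.0, _r2_adj(table, outcome, preds))
    total_pred = sum(raw.values())
    if total_pred > 0:
        raw = {p: v * r2_full / total_pred for p, v in raw.items()}
    shares = dict(raw)
    shares["design"] = 1.0 - r2_full
    total = sum(shares.values())
    shares = {k: v / total for k, v in shares.items()}
    return ContributionReport(outcome=outcome, shares=shares,
                              r2_adj_full=r2_full)
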