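"""Survival association: Cox risk scores, four-group KM stratification and
an exact small-n Spearman permutation test.

The Cox model maximizes the Breslow partial likelihood by Newton–Raphson
(score-norm tolerance 1e-8), which keeps the numerics fully specified and
testable against a grid-search oracle; ties share their risk-set
denominator. Risk scores are the plain linear predictor over signature
genes, ``sum_i expression_i * Coef_i``, dichotomized at the cohort mean.
Patients discordant between the two signatures (lepidic-high & acinar-low,
or the reverse) form the two contrast groups compared by Kaplan–Meier and
log-rank.

For n <= 9 paired observations without ties the Spearman p-value is exact:
all n! rank permutations are enumerated and those with |rho| at least the
observed value are counted (two-sided).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .errors import ConvergenceError, EmptyResultError, MissingGeneError, SeparationError

CONTRAST_LEPIDIC = "lepidic-high/acinar-low"
CONTRAST_ACINAR = "acinar-high/lepidic-low"


@dataclass
class CoxModel:
    coef: pd.Series
    se: pd.Series
    z: pd.Series
    p: pd.Series
    loglik: float
    converged: bool
    n_iter: int
    n: int
    n_events: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.coef, "se": self.se,
                             "z": self.z, "p": self.p})


def _breslow_loglik_parts(beta, X, order, event_sorted, tie_first):
    """Log partial likelihood, score and information under Breslow ties."""
    lp = X @ beta
    elp = np.exp(lp)
    # reverse cumulative sums over time-ascending order give risk-set sums
    Xs = X[order]
    elps = elp[order]
    s0 = np.cumsum(elps[::-1])[::-1]
    s1 = np.cumsum((Xs * elps[:, None])[::-1], axis=0)[::-1]
    s2 = np.cumsum((Xs[:, :, None] * Xs[:, None, :] * elps[:, None, None])[::-1],
                   axis=0)[::-1]
    ev = np.where(event_sorted)[0]
    denom_idx = tie_first[ev]
    s0e, s1e, s2e = s0[denom_idx], s1[denom_idx], s2[denom_idx]
    ll = float(np.sum(Xs[ev] @ beta) - np.sum(np.log(s0e)))
    xbar = s1e / s0e[:, None]
    score = Xs[ev].sum(axis=0) - xbar.sum(axis=0)
    info = (s2e / s0e[:, None, None]
            - xbar[:, :, None] * xbar[:, None, :]).sum(axis=0)
    return ll, score, info


def cox_fit(data: pd.DataFrame, covariates: list[str], time_col: str = "time",
            event_col: str = "event", tol: float = 1e-8,
            max_iter: int = 50) -> CoxModel:
    """Fit a proportional-hazards model by Newton–Raphson.

    Raises on zero events, constant covariates, non-convergence within
    ``max_iter`` iterations, and detected monotone likelihood (separation).
    """
    covariates = list(covariates)
    X = data[covariates].to_numpy(dtype=float)
    time = data[time_col].to_numpy(dtype=float)
    event = data[event_col].to_numpy() == 1
    if event.sum() == 0:
        raise EmptyResultError("no events in the data")
    const = [c for c, v in zip(covariates, X.std(axis=0)) if v == 0]
    if const:
        raise ValueError(f"constant covariates: {const}")

    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    event_sorted = event[order]
    # first index of each tied time block (shared Breslow denominator)
    tie_first = np.zeros(len(t_sorted), dtype=int)
    for i in range(1, len(t_sorted)):
        tie_first[i] = tie_first[i - 1] if t_sorted[i] == t_sorted[i - 1] else i

    beta = np.zeros(len(covariates))
    ll, score, info = _breslow_loglik_parts(beta, X, order, event_sorted, tie_first)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if np.linalg.norm(score) < tol:
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        new_beta = beta + step
        new_ll, new_score, new_info = _breslow_loglik_parts(
            new_beta, X, order, event_sorted, tie_first)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = _breslow_loglik_parts(
                new_beta, X, order, event_sorted, tie_first)
            halvings += 1
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        if np.abs(beta).max() > 30:
            raise SeparationError(
                "monotone partial likelihood: coefficient diverging "
                f"(|beta| > 30 for {covariates[int(np.abs(beta).argmax())]!r})")
    converged = np.linalg.norm(score) < tol
    if not converged:
        raise ConvergenceError(
            f"Newton-Raphson did not converge in {max_iter} iterations "
            f"(score norm {np.linalg.norm(score):.3g})")
    if np.abs(beta).max() > 15:
        # the gradient also vanishes as beta -> inf under monotone likelihood,
        # so a huge "converged" coefficient means separation, not a fit
        raise SeparationError(
            "monotone partial likelihood: "
            f"{covariates[int(np.abs(beta).argmax())]!r} perfectly orders the events")
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    idx = pd.Index(covariates)
    return CoxModel(coef=pd.Series(beta, idx), se=pd.Series(se, idx),
                    z=pd.Series(z, idx), p=pd.Series(p, idx), loglik=ll,
                    converged=True, n_iter=n_iter, n=len(data),
                    n_events=int(event.sum()))


def screen_confounders(data: pd.DataFrame,
                       candidates: tuple[str, ...] = ("age", "sex", "smoking"),
                       alpha: float = 0.05) -> list[str]:
    """Univariate Cox screen: retain candidates with Wald p < alpha."""
    retained = []
    for cand in candidates:
        model = cox_fit(data, [cand])
        if model.p[cand] < alpha:
            retained.append(cand)
    return retained


def risk_score(model: CoxModel | pd.Series, expression: pd.DataFrame,
               genes: list[str] | None = None) -> pd.Series:
    """Linear risk score: sum over genes of expression x Coef."""
    coef = model.coef if isinstance(model, CoxModel) else model
    if genes is not None:
        coef = coef[list(genes)]
    missing = [g for g in coef.index if g not in expression.columns]
    if missing:
        raise MissingGeneError(f"expression is missing model gene(s) {missing[:5]}")
    return (expression[coef.index] @ coef).rename("risk_score")


def stratify_four_groups(lepidic_scores: pd.Series,
                         acinar_scores: pd.Series) -> pd.DataFrame:
    """Mean-cutoff dichotomization of both risk scores.

    "High" means strictly greater than the cohort mean of that score. The
    contrast groups are the discordant cells of the 2x2; concordant
    patients carry an empty group label and are excluded from KM.
    """
    df = pd.DataFrame({"lepidic_score": lepidic_scores,
                       "acinar_score": acinar_scores}).dropna()
    df["lepidic_high"] = df["lepidic_score"] > df["lepidic_score"].mean()
    df["acinar_high"] = df["acinar_score"] > df["acinar_score"].mean()
    group = pd.Series("", index=df.index, name="group")
    group[df["lepidic_high"] & ~df["acinar_high"]] = CONTRAST_LEPIDIC
    group[df["acinar_high"] & ~df["lepidic_high"]] = CONTRAST_ACINAR
    df["group"] = group
    for label in (CONTRAST_LEPIDIC, CONTRAST_ACINAR):
        if (group == label).sum() == 0:
            warnings.warn(f"contrast group {label!r} is empty; KM comparison "
                          "will be skipped", stacklevel=2)
    return df


def km_estimate(times, events, groups=None) -> dict[str, pd.DataFrame]:
    """Product-limit survival curves per group.

    Returns, per group, a step-function table with columns ``survival``
    (indexed by time) and the censoring times for tick marks.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    groups = np.asarray(["all"] * len(times)) if groups is None else np.asarray(groups)
    out = {}
    for g in pd.unique(groups):
        mask = groups == g
        if mask.sum() == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        curve = kmf.survival_function_.copy()
        curve.columns = ["survival"]
        out[str(g)] = {"curve": curve,
                       "censor_times": sorted(times[mask][events[mask] == 0])}
    return out


def logrank_test(times, events, groups) -> dict:
    """Standard two-group log-rank test (1 df)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) != 2 or (counts == 0).any():
        raise ValueError(f"log-rank needs exactly two non-empty groups, got {labels}")
    res = multivariate_logrank_test(times, groups, events)
    return {"statistic": float(res.test_statistic), "p": float(res.p_value), "df": 1}


def spearman_exact(x, y) -> dict:
    """Spearman rho with an exact two-sided permutation p for small n.

    For n <= 9 with no ties in either vector, the p-value enumerates all n!
    rank permutations and counts |rho_perm| >= |rho_observed|. Otherwise the
    usual t-approximation is used and the method flag says so.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rho undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    no_ties = len(np.unique(x)) == n and len(np.unique(y)) == n
    if n <= 9 and no_ties:
        base = np.arange(1, n + 1)
        perms = np.array(list(itertools.permutations(base)), dtype=float)
        d2 = ((perms - base) ** 2).sum(axis=1)
        rho_perm = 1.0 - 6.0 * d2 / (n * (n * n - 1))
        count = int(np.sum(np.abs(rho_perm) >= abs(rho) - 1e-12))
        return {"rho": rho, "p": count / math.factorial(n), "n": n,
                "method": "exact"}
    res = stats.spearmanr(x, y)
    return {"rho": rho, "p": float(res.pvalue), "n": n, "method": "approximate"}


def risk_stratification_pipeline(data: pd.DataFrame, lepidic_genes: list[str],
                                 acinar_genes: list[str],
                                 candidates: tuple[str, ...] = ("age", "sex", "smoking")
                                 ) -> dict:
    """Confounder screen -> two multivariate Cox fits -> four-group KM.

    One multivariate model per signature (its genes plus the retained
    confounders); each patient's risk scores use the gene coefficients
    only. The discordant risk groups are compared by KM and log-rank when
    both are populated.
    """
    retained = screen_confounders(data, candidates)
    models, scores = {}, {}
    for name, genes in (("lepidic", lepidic_genes), ("acinar", acinar_genes)):
        model = cox_fit(data, list(genes) + retained)
        models[name] = model
        scores[name] = risk_score(model, data, genes=list(genes))
    strata = stratify_four_groups(scores["lepidic"], scores["acinar"])
    result = {"confounders": retained, "models": models, "strata": strata,
              "km": None, "logrank": None}
    contrast = strata[strata["group"] != ""]
    if contrast["group"].nunique() == 2:
        sub = data.loc[contrast.index]
        result["km"] = km_estimate(sub["time"], sub["event"], contrast["group"])
        result["logrank"] = logrank_test(sub["time"], sub["event"], contrast["group"])
    return result
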