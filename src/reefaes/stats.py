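"""Feature screening, regression, importance shares and habitat tests.

The analysis chain applied to predicted aesthetic ratings:

1. collinearity screen - among any feature pair with |Pearson r| above
   0.7, keep the one more correlated with the rating;
2. backward stepwise OLS (features scaled, response unscaled) deleting
   the least significant feature until all retained p <= 0.05;
3. LMG relative importance - each retained feature's sequential R^2
   increment averaged over all orderings, normalized to percent;
4. habitat comparisons with mixed models (habitat fixed effect, site
   random intercept; Gaussian, Gamma-log or Poisson family), tested by
   likelihood ratio against the null without habitat, followed by
   Tukey all-pair contrasts with a compact letter display;
5. a binomial GLMM with photo random intercept testing whether any
   respondent socio-cultural attribute shifts pairwise choices.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .glmm import fit_glmm, fit_lmm, likelihood_ratio_test
from .synthgen import ATTRIBUTE_NAMES, PreferenceRecord, records_to_frame

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionResult",
    "HabitatTestResult",
    "correlation_filter",
    "backward_stepwise",
    "importance_shares",
    "fit_habitat_model",
    "tukey_posthoc",
    "respondent_effects",
]


# ---------------------------------------------------------------------------
# collinearity screen


def correlation_filter(
    features: pd.DataFrame,
    target: pd.Series,
    threshold: float = 0.7,
) -> tuple[list[str], list[dict]]:
    """Iteratively remove one member of each over-correlated feature pair.

    While any pair exceeds ``|r| > threshold``, the most correlated
    offending pair is examined and the member with the weaker absolute
    correlation to the target is dropped (ties keep the alphabetically
    first name).  Returns the retained features and a removal log.
    """
    if features.shape[1] < 2:
        raise ValueError("need at least 2 features")
    retained = sorted(features.columns)
    log: list[dict] = []
    for col in list(retained):
        if features[col].std() == 0:
            logger.warning("dropping constant feature %r (undefined correlation)", col)
            retained.remove(col)
            log.append({"removed": col, "kept": None, "reason": "constant"})
    while len(retained) >= 2:
        corr = features[retained].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        a = corr.stack().idxmax()
        r_pair = float(corr.loc[a[0], a[1]])
        if r_pair <= threshold:
            break
        f1, f2 = sorted(a)
        r1 = abs(float(features[f1].corr(target)))
        r2 = abs(float(features[f2].corr(target)))
        drop, keep = (f2, f1) if r1 >= r2 else (f1, f2)
        retained.remove(drop)
        log.append(
            {
                "removed": drop,
                "kept": keep,
                "pair_r": r_pair,
                "removed_target_r": r2 if drop == f2 else r1,
                "kept_target_r": r1 if keep == f1 else r2,
            }
        )
    return retained, log


# ---------------------------------------------------------------------------
# stepwise OLS and importance decomposition


@dataclass
class RegressionResult:
    """Retained features with scaled coefficients and importance shares."""

    retained: tuple[str, ...]
    coefficients: pd.Series
    std_errors: pd.Series
    p_values: pd.Series
    r_squared: float
    importance: pd.Series  # percent per retained feature, sums to 100
    importance_method: str = "lmg"

    def __post_init__(self) -> None:
        if len(self.importance) and abs(self.importance.sum() - 100.0) > 0.1:
            raise ValueError("importance shares must sum to 100")

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.coefficients,
                "std_error": self.std_errors,
                "p_value": self.p_values,
                "importance_pct": self.importance,
            }
        )


def _scale(df: pd.DataFrame) -> pd.DataFrame:
    return (df - df.mean()) / df.std(ddof=0)


def backward_stepwise(
    features: pd.DataFrame,
    response: pd.Series,
    alpha: float = 0.05,
    importance_method: str = "lmg",
) -> RegressionResult:
    """Backward deletion OLS: drop the least significant feature while
    any p-value exceeds ``alpha``.

    Features are scaled to zero mean / unit variance; the response is
    left unscaled.  Ties in the worst p-value are broken by canonical
    (alphabetical) feature order for determinism.
    """
    retained = sorted(features.columns)
    x_all = _scale(features[retained])
    while retained:
        x = sm.add_constant(x_all[retained])
        fit = sm.OLS(np.asarray(response, dtype=float), x).fit()
        pvals = fit.pvalues.drop("const")
        worst_p = pvals.max()
        if worst_p <= alpha:
            break
        # alphabetically first among the (tied) worst
        worst = sorted(pvals.index[pvals == worst_p])[0]
        retained.remove(worst)
    if not retained:
        logger.warning("no feature survived backward deletion at alpha=%g", alpha)
        empty = pd.Series(dtype=float)
        return RegressionResult((), empty, empty, empty, float("nan"), empty,
                                importance_method)
    x = sm.add_constant(x_all[retained])
    fit = sm.OLS(np.asarray(response, dtype=float), x).fit()
    shares = importance_shares(
        features[retained], response, method=importance_method
    )
    return RegressionResult(
        retained=tuple(retained),
        coefficients=fit.params.drop("const"),
        std_errors=fit.bse.drop("const"),
        p_values=fit.pvalues.drop("const"),
        r_squared=float(fit.rsquared),
        importance=shares,
        importance_method=importance_method,
    )


def _subset_r2(x: np.ndarray, y: np.ndarray, cols: tuple[int, ...]) -> float:
    if not cols:
        return 0.0
    xs = x[:, cols]
    xs = np.column_stack([np.ones(len(xs)), xs])
    coef, *_ = np.linalg.lstsq(xs, y, rcond=None)
    resid = y - xs @ coef
    sst = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(np.sum(resid**2)) / sst


def importance_shares(
    features: pd.DataFrame,
    response: pd.Series,
    method: str = "lmg",
) -> pd.Series:
    """Percent of explained variance attributed to each feature.

    ``lmg`` averages each feature's sequential R^2 increment over all
    orderings of entry (computed exactly via the subset-weight
    identity); ``squared_coef`` uses squared standardized coefficients.
    Shares are normalized to sum to 100.
    """
    names = list(features.columns)
    k = len(names)
    if k == 0:
        return pd.Series(dtype=float)
    if k > 10:
        raise ValueError(
            f"{k} features: exact LMG enumerates 2^k subsets; "
            "reduce the feature set or sample orderings externally"
        )
    x = _scale(features).to_numpy(dtype=float)
    y = np.asarray(response, dtype=float)
    if method == "lmg":
        r2_cache: dict[tuple[int, ...], float] = {}
        for r in range(k + 1):
            for s in itertools.combinations(range(k), r):
                r2_cache[s] = _subset_r2(x, y, s)
        raw = np.zeros(k)
        for i in range(k):
            others = [j for j in range(k) if j != i]
            for r in range(k):
                w = math.factorial(r) * math.factorial(k - r - 1) / math.factorial(k)
                for s in itertools.combinations(others, r):
                    s_with = tuple(sorted(s + (i,)))
                    raw[i] += w * (r2_cache[s_with] - r2_cache[s])
    elif method == "squared_coef":
        xs = np.column_stack([np.ones(len(x)), x])
        coef, *_ = np.linalg.lstsq(xs, y, rcond=None)
        raw = coef[1:] ** 2
    else:
        raise ValueError(f"unknown importance method {method!r}")
    total = raw.sum()
    if total <= 0:
        raise ValueError("response variance is not explained by any feature")
    return pd.Series(100.0 * raw / total, index=names)


# ---------------------------------------------------------------------------
# habitat mixed models


@dataclass
class HabitatTestResult:
    """Habitat fixed-effect test with Tukey letters."""

    response: str
    family: str
    chi2: float
    df: int
    p: float
    letters: dict[str, str]
    contrasts: pd.DataFrame
    group_estimates: dict[str, float]  # linear-predictor scale
    singular: bool = False
    notes: list[str] = field(default_factory=list)
    # internal: treatment-coded effects and their covariance for post-hoc
    _levels: tuple[str, ...] = ()
    _effects: np.ndarray | None = None
    _cov_effects: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")


_FAMILY_ALIASES = {
    "gaussian": "gaussian",
    "gaussian-lmm": "gaussian",
    "lmm": "gaussian",
    "gamma": "gamma",
    "gamma-log": "gamma",
    "gamma-log-glmm": "gamma",
    "poisson": "poisson",
    "poisson-glmm": "poisson",
    "binomial": "binomial",
    "binomial-glmm": "binomial",
}


def _habitat_design(data: pd.DataFrame) -> tuple[np.ndarray, tuple[str, ...]]:
    levels = tuple(sorted(data["habitat"].unique()))
    dummies = np.column_stack(
        [np.ones(len(data))]
        + [(data["habitat"] == lv).to_numpy(dtype=float) for lv in levels[1:]]
    )
    return dummies, levels


def fit_habitat_model(
    data: pd.DataFrame,
    family: str = "gaussian",
    response_name: str = "value",
    alpha: float = 0.05,
    posthoc: bool = True,
) -> HabitatTestResult:
    """Mixed model of ``value ~ habitat + (1 | site_id)`` with an LRT
    against the null model lacking the habitat term.

    ``data`` needs columns value / habitat / site_id, with at least two
    sites per habitat.  Family choices: gaussian (LMM), gamma (log
    link), poisson.  Gamma responses equal to zero are nudged to a tiny
    positive value (logged in ``notes``) since the Gamma support
    excludes zero.
    """
    fam = _FAMILY_ALIASES.get(family.lower())
    if fam is None:
        raise ValueError(f"unknown family {family!r}")
    data = data.copy()
    per_habitat = data.groupby("habitat")["site_id"].nunique()
    if (per_habitat < 2).any():
        bad = per_habitat[per_habitat < 2].index.tolist()
        raise ValueError(f"need >= 2 sites per habitat; offending: {bad}")
    notes: list[str] = []
    values = data["value"].to_numpy(dtype=float)
    if fam == "gamma" and (values <= 0).any():
        nudge = max(values[values > 0].min() * 1e-6, 1e-12) if (values > 0).any() else 1e-12
        n_bad = int((values <= 0).sum())
        values = np.where(values <= 0, nudge, values)
        notes.append(f"nudged {n_bad} non-positive values to {nudge:g} for Gamma fit")
    x_full, levels = _habitat_design(data)
    x_null = x_full[:, :1]
    df_test = x_full.shape[1] - 1
    groups = data["site_id"].to_numpy()

    if fam == "gaussian":
        full_ml = fit_lmm(values, x_full, groups, reml=False)
        null_ml = fit_lmm(values, x_null, groups, reml=False)
        chi2, df, p = likelihood_ratio_test(full_ml.loglik, null_ml.loglik, df_test)
        # parameter estimates and their covariance from the REML refit
        est = fit_lmm(values, x_full, groups, reml=True)
        beta = est.beta
        cov = est.cov_beta
        singular = est.singular
    else:
        full = fit_glmm(values, x_full, groups, fam)
        null = fit_glmm(values, x_null, groups, fam, compute_cov=False)
        chi2, df, p = likelihood_ratio_test(full.loglik, null.loglik, df_test)
        beta = full.beta
        cov = full.cov_beta
        singular = full.singular
    if singular:
        notes.append("random-intercept variance estimated at (near) zero")

    estimates = {levels[0]: float(beta[0])}
    for j, lv in enumerate(levels[1:], start=1):
        estimates[lv] = float(beta[0] + beta[j])

    result = HabitatTestResult(
        response=response_name,
        family=fam,
        chi2=chi2,
        df=df,
        p=p,
        letters={},
        contrasts=pd.DataFrame(),
        group_estimates=estimates,
        singular=singular,
        notes=notes,
        _levels=levels,
        _effects=beta[1:],
        _cov_effects=None if cov is None else cov[1:, 1:],
    )
    if posthoc:
        tukey_posthoc(result, alpha=alpha)
    return result


def _maxmod_adjust(z_obs: float, corr: np.ndarray) -> float:
    """P(max_k |Z_k| > |z|) for jointly normal contrast statistics."""
    if not np.isfinite(z_obs):
        return 0.0
    a = abs(z_obs)
    if a == 0.0:
        return 1.0
    mvn = sps.multivariate_normal(mean=np.zeros(corr.shape[0]), cov=corr,
                                  allow_singular=True)
    inside = float(mvn.cdf(np.full(corr.shape[0], a),
                           lower_limit=np.full(corr.shape[0], -a)))
    return float(min(1.0, max(0.0, 1.0 - inside)))


def tukey_posthoc(result: HabitatTestResult, alpha: float = 0.05) -> HabitatTestResult:
    """All-pair habitat contrasts with family-wise adjusted p-values and a
    compact letter display (groups sharing a letter are not separable)."""
    levels = result._levels
    eff = result._effects
    cov = result._cov_effects
    if eff is None or cov is None:
        raise ValueError("fit lacks the effect covariance needed for contrasts")
    n_eff = len(eff)
    pairs = list(itertools.combinations(range(len(levels)), 2))
    cvecs = []
    for i, j in pairs:
        c = np.zeros(n_eff)
        if i > 0:
            c[i - 1] -= 1.0
        if j > 0:
            c[j - 1] += 1.0
        cvecs.append(c)
    cmat = np.array(cvecs)
    var = cmat @ cov @ cmat.T
    se = np.sqrt(np.maximum(np.diag(var), 0.0))
    diffs = cmat @ eff
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, diffs / se, np.where(diffs == 0, 0.0, np.inf))
    denom = np.outer(se, se)
    corr = np.divide(var, denom, out=np.eye(len(pairs)), where=denom > 0)
    np.fill_diagonal(corr, 1.0)
    p_raw = 2.0 * sps.norm.sf(np.abs(z))
    p_adj = np.array([_maxmod_adjust(zi, corr) for zi in z])

    rows = []
    for (i, j), d, s, zi, pr, pa in zip(pairs, diffs, se, z, p_raw, p_adj):
        rows.append(
            {
                "contrast": f"{levels[j]} - {levels[i]}",
                "estimate": float(d),
                "se": float(s),
                "z": float(zi),
                "p_raw": float(pr),
                "p_adj": float(pa),
            }
        )
    result.contrasts = pd.DataFrame(rows)

    # compact letter display via maximal cliques of the "not separable" graph
    nsd = {frozenset((levels[i], levels[j])) for (i, j), pa in zip(pairs, p_adj) if pa >= alpha}
    order = sorted(levels, key=lambda lv: -result.group_estimates[lv])
    cliques: list[set[str]] = []
    for size in range(len(order), 0, -1):
        for combo in itertools.combinations(order, size):
            if all(frozenset((x, y)) in nsd for x, y in itertools.combinations(combo, 2)):
                cs = set(combo)
                if not any(cs <= c for c in cliques):
                    cliques.append(cs)
    covered: set[str] = set()
    final: list[set[str]] = []
    for c in cliques:
        if not c <= covered:
            final.append(c)
            covered |= c
    letters = {lv: "" for lv in levels}
    for letter, clique in zip("abcdefgh", final):
        for lv in order:
            if lv in clique:
                letters[lv] += letter
    result.letters = letters
    return result


# ---------------------------------------------------------------------------
# respondent socio-cultural effects


def respondent_effects(
    records: Sequence[PreferenceRecord] | pd.DataFrame,
    attributes: Sequence[str] = ATTRIBUTE_NAMES,
) -> pd.DataFrame:
    """Binomial GLMM testing socio-cultural effects on pairwise choices.

    Response: whether the first-presented photo won; random intercept
    per first photo; fixed effects are dummy blocks per attribute.
    Per-attribute chi-square tests are Wald tests on the dummy block
    from a single fit (the standard analysis-of-deviance table for
    mixed models).  Attributes with a single observed level are dropped
    with a warning.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(list(records))
    attributes = [a for a in attributes]
    if not attributes:
        raise ValueError("no respondent attributes supplied")
    missing = [a for a in attributes if a not in df.columns]
    if missing:
        raise ValueError(f"records lack attribute columns: {missing}")
    usable = []
    for a in attributes:
        if df[a].nunique() < 2:
            logger.warning("attribute %r has a single level; dropped", a)
        else:
            usable.append(a)
    if not usable:
        raise ValueError("no attribute with >= 2 levels to test")

    y = (df["winner"] == df["photo_a"]).to_numpy(dtype=float)
    cols = [np.ones(len(df))]
    names = ["intercept"]
    blocks: dict[str, list[int]] = {}
    for a in usable:
        levels = sorted(df[a].astype(str).unique())
        idxs = []
        for lv in levels[1:]:
            cols.append((df[a].astype(str) == lv).to_numpy(dtype=float))
            names.append(f"{a}[{lv}]")
            idxs.append(len(names) - 1)
        blocks[a] = idxs
    x = np.column_stack(cols)
    fit = fit_glmm(y, x, df["photo_a"].to_numpy(), "binomial", beta_names=tuple(names))

    rows = []
    for a in usable:
        chi2, dfree, p = fit.wald_block_test(blocks[a])
        rows.append({"attribute": a, "chi2": chi2, "df": dfree, "p": p})
    return pd.DataFrame(rows)
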