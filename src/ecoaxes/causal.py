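"""Invariance-based causal screening and interventional variable importance.

Sites are split into two environments (forest sites of the northern
continents versus everything else); a covariate subset is a candidate set of
causal predictors when the regression of the axis score on that subset has
residuals whose distribution is invariant across environments. The test uses
sample splitting (fit on one half, residuals evaluated on the other) and
combines a two-sample location test with a variance-equality test by
Bonferroni. Exhaustive search over all 511 non-empty subsets of the nine
covariates yields the accepted sets and their intersection (invariant causal
prediction). Interventional importance measures how much the expected
prediction moves under joint interventions that set one covariate (or a
group) while the rest follow their empirical product marginal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .flux_io import SiteMeta
from .synthetic import CLIMATE_COVARIATES, STRUCTURE_COVARIATES

FOREST_PFTS = frozenset({"DBF", "DNF", "EBF", "ENF", "MF"})
NORTHERN_CONTINENTS = frozenset({"North America", "Europe", "Asia"})

#: ISO country prefix of FLUXNET site codes -> continent
COUNTRY_CONTINENT = {
    "US": "North America", "CA": "North America", "MX": "North America",
    "CR": "North America", "PA": "North America", "GL": "North America",
    "BR": "South America", "AR": "South America", "CL": "South America",
    "PE": "South America", "CO": "South America", "GF": "South America",
    "EC": "South America", "UY": "South America",
    "DE": "Europe", "FR": "Europe", "IT": "Europe", "ES": "Europe",
    "PT": "Europe", "NL": "Europe", "BE": "Europe", "CH": "Europe",
    "AT": "Europe", "CZ": "Europe", "PL": "Europe", "HU": "Europe",
    "SK": "Europe", "SE": "Europe", "FI": "Europe", "NO": "Europe",
    "DK": "Europe", "IE": "Europe", "UK": "Europe", "GB": "Europe",
    "GR": "Europe", "RO": "Europe", "EE": "Europe", "IS": "Europe",
    "RU": "Asia", "CN": "Asia", "JP": "Asia", "KR": "Asia", "MN": "Asia",
    "KZ": "Asia", "IN": "Asia", "TH": "Asia", "VN": "Asia", "MY": "Asia",
    "ID": "Asia", "IL": "Asia", "SA": "Asia",
    "AU": "Oceania", "NZ": "Oceania", "PG": "Oceania",
    "ZA": "Africa", "BW": "Africa", "ZM": "Africa", "GH": "Africa",
    "SD": "Africa", "SN": "Africa", "CG": "Africa", "TZ": "Africa",
    "ML": "Africa", "NE": "Africa", "BF": "Africa", "MA": "Africa",
}


@dataclass
class EnvironmentAssignment:
    """Per-site environment label (E1/E2) and the scheme that produced it."""

    labels: pd.Series                 # site_id -> "E1" | "E2"
    scheme: str = "forest_by_continent"
    forest_pfts: frozenset = FOREST_PFTS
    northern_continents: frozenset = NORTHERN_CONTINENTS


def continent_of(site_id: str) -> str:
    prefix = site_id.split("-")[0].upper()
    try:
        return COUNTRY_CONTINENT[prefix]
    except KeyError:
        raise KeyError(prefix) from None


def assign_environments(metas: list[SiteMeta],
                        scheme: str = "forest_by_continent") -> EnvironmentAssignment:
    """Assign each site to E1 or E2.

    E1 = forest PFT (DBF, DNF, EBF, ENF, MF) on a northern continent (North
    America, Europe, Asia); E2 = everything else (all southern-continent
    sites, and northern non-forest sites). Unmappable country codes raise an
    error listing them.
    """
    labels = {}
    unmapped = []
    for m in metas:
        try:
            cont = continent_of(m.site_id)
        except KeyError as err:
            unmapped.append(str(err.args[0]))
            continue
        forest = m.pft in FOREST_PFTS
        labels[m.site_id] = ("E1" if forest and cont in NORTHERN_CONTINENTS
                             else "E2")
    if unmapped:
        raise ValueError(f"unmappable country codes: {sorted(set(unmapped))}")
    return EnvironmentAssignment(labels=pd.Series(labels, name="env"),
                                 scheme=scheme)


@dataclass
class InvarianceResult:
    """Outcome of the exhaustive invariance search over covariate subsets."""

    pvalues: dict                     # frozenset of names -> p-value
    accepted: list                    # accepted subsets (frozensets) at alpha
    intersection: frozenset
    alpha: float
    regressor: str
    no_invariant_subset: bool = False
    environments_degenerate: bool = False
    diagnostics: dict = field(default_factory=dict)


def _fit_regressor(Xtr, ytr, regressor: str, seed: int, n_trees: int):
    if regressor == "tree-ensemble":
        model = RandomForestRegressor(n_estimators=n_trees, random_state=seed,
                                      n_jobs=1)
        model.fit(Xtr, ytr)
        return model.predict
    if regressor == "smooth-additive":
        # additive cubic-spline model: per-covariate B-spline expansion with
        # linear extrapolation beyond the training range, lightly ridged
        from sklearn.linear_model import Ridge
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import SplineTransformer

        model = make_pipeline(
            SplineTransformer(degree=3, n_knots=5, extrapolation="linear"),
            Ridge(alpha=1e-3),
        )
        model.fit(np.asarray(Xtr, dtype=float), ytr)
        return lambda Xte: model.predict(np.asarray(Xte, dtype=float))
    raise ValueError(f"unknown regressor {regressor!r}")


def invariance_pvalue(X_subset: pd.DataFrame | None, y, env,
                      regressor: str = "tree-ensemble", seed: int = 0,
                      n_trees: int = 100, min_per_env: int = 15,
                      train_frac: float = 0.8) -> float:
    """Invariance p-value of one covariate subset across two environments.

    The regressor is fitted on a random ``train_frac`` share of the pooled
    data (stratified by environment); held-out residuals are compared across
    environments by a Welch two-sample t test (location) and a
    Brown-Forsythe test (variance), Bonferroni-combined:
    p = min(1, 2 min(p_loc, p_var)). An empty subset tests the
    intercept-only model.

    The asymmetric default split keeps the regressor's estimation error —
    which concentrates in environment-specific covariate regions and is
    shared across held-out points — small relative to the two-sample
    standard error, so the test holds its level when environments shift the
    covariate distribution.
    """
    y = np.asarray(y, dtype=float)
    env = np.asarray(env)
    ulev = np.unique(env)
    if len(ulev) < 2:
        return 1.0
    for lev in ulev:
        if (env == lev).sum() < min_per_env:
            raise ValueError(f"environment {lev!r} has fewer than {min_per_env} sites")
    rng = np.random.default_rng(seed)
    n = len(y)
    # stratified train/test split
    test_mask = np.zeros(n, dtype=bool)
    for lev in ulev:
        idx = np.flatnonzero(env == lev)
        idx = idx[rng.permutation(len(idx))]
        n_test = max(int(round(len(idx) * (1.0 - train_frac))), 5)
        test_mask[idx[:n_test]] = True
    if X_subset is None or (hasattr(X_subset, "shape") and X_subset.shape[1] == 0):
        resid = y[test_mask] - y[~test_mask].mean()
    else:
        Xv = np.asarray(X_subset, dtype=float)
        predict = _fit_regressor(Xv[~test_mask], y[~test_mask], regressor,
                                 seed, n_trees)
        resid = y[test_mask] - np.asarray(predict(Xv[test_mask]), dtype=float)
    env_te = env[test_mask]
    r1 = resid[env_te == ulev[0]]
    r2 = resid[env_te == ulev[1]]
    p_loc = stats.ttest_ind(r1, r2, equal_var=False).pvalue
    p_var = stats.levene(r1, r2, center="median").pvalue
    return float(min(1.0, 2.0 * min(p_loc, p_var)))


def icp_search(X: pd.DataFrame, y, env, alpha: float = 0.05,
               regressor: str = "tree-ensemble", seed: int = 0,
               n_trees: int = 100) -> InvarianceResult:
    """Invariant causal prediction over all non-empty covariate subsets.

    Subsets with invariance p-value > alpha are accepted; the intersection of
    accepted subsets is the ICP estimate of (a subset of) the causal
    predictors. With a single environment every subset is vacuously accepted
    and the result is flagged degenerate; with no accepted subset the
    ``no_invariant_subset`` flag is raised (a hint that the environment may
    act directly on the response).
    """
    env = np.asarray(env)
    cols = list(X.columns)
    result = InvarianceResult(pvalues={}, accepted=[], intersection=frozenset(),
                              alpha=alpha, regressor=regressor)
    if len(np.unique(env)) < 2:
        all_sets = [frozenset(c) for r in range(1, len(cols) + 1)
                    for c in combinations(cols, r)]
        result.pvalues = {s: 1.0 for s in all_sets}
        result.accepted = all_sets
        result.intersection = frozenset()
        result.environments_degenerate = True
        return result
    rng = np.random.default_rng(seed)
    for r in range(1, len(cols) + 1):
        for combo in combinations(cols, r):
            s = frozenset(combo)
            p = invariance_pvalue(X[list(combo)], y, env, regressor=regressor,
                                  seed=int(rng.integers(2**31 - 1)),
                                  n_trees=n_trees)
            result.pvalues[s] = p
            if p > alpha:
                result.accepted.append(s)
    if result.accepted:
        inter = set(result.accepted[0])
        for s in result.accepted[1:]:
            inter &= s
        result.intersection = frozenset(inter)
    else:
        result.no_invariant_subset = True
    return result


GROUPS = {"structure": tuple(STRUCTURE_COVARIATES),
          "climate": tuple(CLIMATE_COVARIATES)}


def causal_importance(model, X: pd.DataFrame, variables_or_groups,
                      seed: int = 0, n_marginal: int = 200) -> pd.Series:
    """Interventional variable (or group) importance of a fitted model.

    For a target set S, the interventional mean m(x_S) is the average
    prediction with the covariates in S clamped to x_S while the remaining
    covariates are drawn from their empirical *product* marginal
    (independently permuted columns). The importance of S is the variance of
    m over the empirical grid of x_S values, normalized so that the nine
    single-variable importances sum to 1.
    """
    Xv = X.dropna()
    base = Xv.to_numpy(dtype=float)
    n = len(base)
    rng = np.random.default_rng(seed)
    # empirical product marginal: independently permuted columns
    m = min(n_marginal, n)
    marg = np.column_stack([base[rng.permutation(n)[:m], j]
                            for j in range(base.shape[1])])

    def resolve(item):
        if isinstance(item, str) and item in GROUPS:
            names = GROUPS[item]
        elif isinstance(item, str):
            names = (item,)
        else:
            names = tuple(item)
        for nm in names:
            if nm not in Xv.columns:
                raise ValueError(f"unknown covariate or group {item!r}")
        return [Xv.columns.get_loc(nm) for nm in names]

    def raw_variance(cols):
        mvals = np.empty(n)
        for i in range(n):
            work = marg.copy()
            work[:, cols] = base[i, cols]
            mvals[i] = model.predict(work).mean()
        return float(np.var(mvals))

    singles = {c: raw_variance([j]) for c, j in
               ((c, Xv.columns.get_loc(c)) for c in Xv.columns)}
    denom = sum(singles.values()) or 1.0

    out = {}
    for item in variables_or_groups:
        key = item if isinstance(item, str) else "+".join(item)
        cols = resolve(item)
        if isinstance(item, str) and item in singles:
            out[key] = singles[item] / denom
        else:
            out[key] = raw_variance(cols) / denom
    return pd.Series(out, name="causal_importance")
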