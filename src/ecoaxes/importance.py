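"""Predictive attribution of axis scores to climate and structure covariates.

A random-forest regression links the nine site covariates (four vegetation
structure: LAI_max, AGB, H_c, N%; five climate: T_air, VPD, SW_in, P, CSWI)
to each significant principal-component score. Importance is the percentage
increase in out-of-bag mean squared error under per-tree permutation of one
covariate (the %IncMSE convention of classical random-forest software),
partial dependence is restricted to the convex hull of the training values,
and group differences across plant functional types or climate classes are
quantified by one-way ANOVA effect size (eta squared) with Tukey HSD compact
letter display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import Delaunay, QhullError
from sklearn.ensemble import RandomForestRegressor
from sklearn.ensemble._forest import _generate_sample_indices
from statsmodels.stats.multicomp import pairwise_tukeyhsd

COVARIATE_GROUPS = {
    "LAI_max": "structure", "AGB": "structure", "H_c": "structure",
    "N_pct": "structure",
    "T_air": "climate", "VPD": "climate", "SW_in": "climate", "P": "climate",
    "CSWI": "climate",
}


@dataclass
class ImportanceResult:
    """Per-covariate %IncMSE with the fitted forest and its OOB quality."""

    importance: pd.Series            # percent increase in OOB MSE
    groups: pd.Series                # covariate -> {structure, climate}
    oob_r2: float
    model: RandomForestRegressor = field(repr=False, default=None)
    feature_names: list = field(default_factory=list)

    def ranking(self) -> list:
        return list(self.importance.sort_values(ascending=False).index)


def fit_rf_importance(X: pd.DataFrame, y, n_trees: int = 1000,
                      seed: int = 0, min_rows: int = 30) -> ImportanceResult:
    """Random-forest %IncMSE importance of each covariate for ``y``.

    Complete-case rows only. For every tree, the out-of-bag samples are
    identified from the tree's bootstrap RNG; the importance of covariate j
    is the mean over trees of the relative increase in OOB MSE when column j
    is permuted (x100). Deterministic given ``seed``.
    """
    df = X.copy()
    df["_y"] = np.asarray(y, dtype=float)
    df = df.dropna()
    if len(df) < min_rows:
        raise ValueError(f"need >= {min_rows} complete-case rows, got {len(df)}")
    yv = df.pop("_y").to_numpy()
    if np.std(yv) == 0:
        raise ValueError("constant response: importance undefined")
    Xv = df.to_numpy(dtype=float)
    n, p = Xv.shape

    rf = RandomForestRegressor(n_estimators=n_trees, oob_score=True,
                               random_state=seed, n_jobs=1)
    rf.fit(Xv, yv)

    rng = np.random.default_rng(seed)
    inc = np.zeros((len(rf.estimators_), p))
    valid = np.zeros(len(rf.estimators_), dtype=bool)
    for t, tree in enumerate(rf.estimators_):
        # re-derive the tree's bootstrap sample to identify its OOB rows
        sampled = _generate_sample_indices(tree.random_state, n, n, None)
        oob = np.setdiff1d(np.arange(n), sampled, assume_unique=False)
        if len(oob) < 2:
            continue
        Xo = Xv[oob]
        mse0 = np.mean((yv[oob] - tree.predict(Xo)) ** 2)
        if mse0 <= 0:
            continue
        valid[t] = True
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = Xo[rng.permutation(len(oob)), j]
            msej = np.mean((yv[oob] - tree.predict(Xp)) ** 2)
            inc[t, j] = 100.0 * (msej - mse0) / mse0
    if not valid.any():
        raise ValueError("no tree had usable out-of-bag samples")
    imp = pd.Series(inc[valid].mean(axis=0), index=df.columns, name="pct_inc_mse")
    groups = pd.Series({c: COVARIATE_GROUPS.get(c, "other") for c in df.columns})
    return ImportanceResult(importance=imp, groups=groups,
                            oob_r2=float(rf.oob_score_), model=rf,
                            feature_names=list(df.columns))


@dataclass
class PartialDependence:
    """PD curve (1-D) or surface (2-D) with a convex-hull validity mask."""

    features: tuple
    grid: list                       # one array per feature
    values: np.ndarray               # PD response; NaN where masked (2-D)
    in_hull: np.ndarray              # boolean mask over the grid


def partial_dependence_hull(model, X: pd.DataFrame, covariates,
                            grid_size: int = 30) -> PartialDependence:
    """Partial dependence averaged over the empirical covariate distribution.

    One-dimensional grids span the 5th-95th percentile of the training
    values; two-dimensional grid points outside the convex hull of the
    training pairs are masked (NaN) to avoid extrapolation.
    """
    if isinstance(covariates, str):
        covariates = (covariates,)
    covariates = tuple(covariates)
    for c in covariates:
        if c not in X.columns:
            raise ValueError(f"unknown covariate {c!r}")
    if len(covariates) not in (1, 2):
        raise ValueError("partial dependence supports 1 or 2 covariates")
    Xv = X.dropna()
    cols = [Xv.columns.get_loc(c) for c in covariates]
    base = Xv.to_numpy(dtype=float)
    grids = [np.linspace(*np.quantile(base[:, j], [0.05, 0.95]), grid_size)
             for j in cols]

    if len(covariates) == 1:
        vals = np.empty(grid_size)
        work = base.copy()
        for i, g in enumerate(grids[0]):
            work[:, cols[0]] = g
            vals[i] = model.predict(work).mean()
        return PartialDependence(covariates, grids, vals,
                                 np.ones(grid_size, dtype=bool))

    gx, gy = np.meshgrid(grids[0], grids[1], indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    train_pairs = base[:, cols]
    try:
        hull = Delaunay(train_pairs)
        inside = hull.find_simplex(pts) >= 0
    except QhullError:
        inside = np.ones(len(pts), dtype=bool)
    vals = np.full(len(pts), np.nan)
    work = base.copy()
    for i, (a, b) in enumerate(pts):
        if not inside[i]:
            continue
        work[:, cols[0]] = a
        work[:, cols[1]] = b
        vals[i] = model.predict(work).mean()
    shape = (grid_size, grid_size)
    return PartialDependence(covariates, grids, vals.reshape(shape),
                             inside.reshape(shape))


@dataclass
class AnovaResult:
    """One-way ANOVA effect size with Tukey HSD compact letter display."""

    eta_squared: float
    letters: dict                    # group -> letter string
    group_means: pd.Series
    group_n: pd.Series
    f_pvalue: float
    alpha: float


def _compact_letter_display(groups: list, different: set) -> dict:
    """Insert-absorb compact letter display.

    ``different`` holds unordered pairs that differ significantly; groups
    sharing no letter differ. Groups are processed in mean order (the caller
    passes them sorted) so letters read from the largest mean down.
    """
    letter_sets: list[set] = [set(groups)]
    for a, b in different:
        for s in [s for s in letter_sets if a in s and b in s]:
            letter_sets.remove(s)
            sa, sb = s - {a}, s - {b}
            for cand in (sa, sb):
                if cand and not any(cand <= other for other in letter_sets):
                    letter_sets.append(cand)
    # absorb: drop sets contained in another
    letter_sets = [s for s in letter_sets
                   if not any(s < other for other in letter_sets)]
    letter_sets.sort(key=lambda s: min(groups.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for i, s in enumerate(letter_sets):
        for g in groups:
            if g in s:
                out[g] += alphabet[i % len(alphabet)]
    return out


def anova_tukey(values, groups, alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA (eta squared) and all-pairs Tukey HSD letters.

    eta^2 = SS_between / SS_total; groups that do not share a letter differ
    at the given level.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float),
                       "g": np.asarray(groups)}).dropna()
    labels = df["g"].unique().tolist()
    if len(labels) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    counts = df.groupby("g")["y"].count()
    if (counts < 2).any():
        raise ValueError("every group needs >= 2 members")
    grand = df["y"].mean()
    ss_total = float(((df["y"] - grand) ** 2).sum())
    means = df.groupby("g")["y"].mean()
    ss_between = float((counts * (means - grand) ** 2).sum())
    eta2 = ss_between / ss_total if ss_total > 0 else 0.0
    samples = [df.loc[df["g"] == g, "y"].to_numpy() for g in labels]
    f_p = float(stats.f_oneway(*samples).pvalue) if ss_total > 0 else 1.0

    ordered = list(means.sort_values(ascending=False).index)
    different: set = set()
    if ss_total > 0 and df.groupby("g")["y"].var(ddof=1).sum() > 0:
        tk = pairwise_tukeyhsd(df["y"], df["g"], alpha=alpha)
        res = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        for _, row in res.iterrows():
            if bool(row["reject"]):
                different.add(frozenset((row["group1"], row["group2"])))
    letters = _compact_letter_display(ordered, {tuple(d) for d in different})
    return AnovaResult(eta_squared=eta2, letters=letters,
                       group_means=means, group_n=counts,
                       f_pvalue=f_p, alpha=alpha)
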