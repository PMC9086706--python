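"""Cohort statistics: group comparisons, ROC, NRI, stepwise, matching,
variable clustering and covariate-adjusted medians.

Test-selection logic mirrors the source study's battery: per-group
Shapiro-Wilk normality at alpha = 0.05 routes a continuous variable to
ANOVA / t-test (all groups normal) or Kruskal-Wallis / Mann-Whitney U
(otherwise); categorical variables go to Fisher's exact test when any
expected cell count is below 5 (2x2 tables), else to chi-square with
Yates correction.  Discrimination uses the C-statistic with DeLong
confidence intervals and a Youden-J optimal cutoff; incremental value
uses the category-free (continuous) net reclassification improvement
with a permutation p-value; dependence screening uses MIC (see
lawmap.mic); similarity uses average-linkage clustering on 1 - MIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist, squareform

from .mic import MICResult, mic

ALPHA_NORMALITY = 0.05
ALPHA_PAIRWISE = 0.05


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# group comparisons


@dataclass(frozen=True)
class ComparisonResult:
    variable: str
    groups: tuple
    family: str  # "parametric" | "nonparametric" | "categorical"
    test_name: str
    statistic: float
    p_value: float
    summaries: dict  # group -> summary dict matching the family's style
    pairwise_p: dict  # (group_a, group_b) -> p
    pairwise_flags: dict  # (group_a, group_b) -> bool (p < 0.05)

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "groups": list(self.groups),
            "family": self.family,
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "summaries": {g: dict(s) for g, s in self.summaries.items()},
            "pairwise_p": {f"{a}|{b}": p for (a, b), p in self.pairwise_p.items()},
            "pairwise_flags": {f"{a}|{b}": bool(v) for (a, b), v in self.pairwise_flags.items()},
        }


def _is_binary(values: np.ndarray) -> bool:
    u = np.unique(values)
    return len(u) <= 2 and np.all(np.isin(u, [0, 1]))


def _two_sample_continuous(a, b, parametric: bool):
    if parametric:
        res = sstats.ttest_ind(a, b, equal_var=True)
        return "t-test", float(res.statistic), float(res.pvalue)
    res = sstats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return "Mann-Whitney U", float(res.statistic), float(res.pvalue)


def _omnibus_continuous(samples, parametric: bool):
    if len(samples) == 2:
        return _two_sample_continuous(samples[0], samples[1], parametric)
    if parametric:
        res = sstats.f_oneway(*samples)
        return "one-way ANOVA", float(res.statistic), float(res.pvalue)
    res = sstats.kruskal(*samples)
    return "Kruskal-Wallis", float(res.statistic), float(res.pvalue)


def _categorical_test(table: np.ndarray):
    expected = sstats.contingency.expected_freq(table)
    if table.shape == (2, 2) and (expected < 5).any():
        _, p = sstats.fisher_exact(table)
        return "Fisher exact", float("nan"), float(p)
    chi2, p, _, _ = sstats.chi2_contingency(table, correction=True)
    return "chi-square (Yates)", float(chi2), float(p)


def compare_groups(
    cohort: pd.DataFrame,
    variable: str,
    groups=None,
    group_col: str = "group",
    categorical: bool | None = None,
    force_family: str | None = None,
) -> ComparisonResult:
    """Compare `variable` across groups with the study's test-selection rule.

    Normality is assessed per group by Shapiro-Wilk at alpha = 0.05; any
    failing group routes the variable down the non-parametric path.  The
    routing is a pure function of the data; `force_family` ("parametric"
    or "nonparametric") overrides it for sensitivity analyses.
    """
    if groups is None:
        groups = tuple(pd.unique(cohort[group_col]))
    groups = tuple(groups)
    if len(groups) < 2:
        raise StatsError("need at least two groups")
    samples = []
    for g in groups:
        vals = pd.to_numeric(
            cohort.loc[cohort[group_col] == g, variable], errors="coerce"
        ).dropna().to_numpy(dtype=float)
        if len(vals) == 0:
            raise StatsError(f"group {g!r} has no observations for {variable!r}")
        if len(vals) < 3:
            raise StatsError(f"group {g!r} has fewer than 3 observations for {variable!r}")
        samples.append(vals)
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        raise StatsError(f"{variable!r} is constant across all groups")

    if categorical is None:
        categorical = _is_binary(pooled)

    if categorical:
        table = np.array(
            [[(s == 1).sum(), (s == 0).sum()] for s in samples], dtype=float
        )
        test_name, statistic, p = _categorical_test(table)
        summaries = {
            g: {"count": int((s == 1).sum()), "n": len(s), "percent": 100.0 * (s == 1).mean()}
            for g, s in zip(groups, samples)
        }
        family = "categorical"
        pairwise = {}
        for ia in range(len(groups)):
            for ib in range(ia + 1, len(groups)):
                sub = table[[ia, ib]]
                _, _, pp = _categorical_test(sub)
                pairwise[(groups[ia], groups[ib])] = pp
    else:
        if force_family is not None:
            if force_family not in ("parametric", "nonparametric"):
                raise StatsError(f"unknown family {force_family!r}")
            normal = force_family == "parametric"
        else:
            normal = all(
                sstats.shapiro(s).pvalue > ALPHA_NORMALITY for s in samples
            )
        test_name, statistic, p = _omnibus_continuous(samples, normal)
        if normal:
            summaries = {
                g: {"mean": float(s.mean()), "sd": float(s.std(ddof=1)), "n": len(s)}
                for g, s in zip(groups, samples)
            }
            family = "parametric"
        else:
            summaries = {
                g: {
                    "median": float(np.median(s)),
                    "q1": float(np.percentile(s, 25)),
                    "q3": float(np.percentile(s, 75)),
                    "n": len(s),
                }
                for g, s in zip(groups, samples)
            }
            family = "nonparametric"
        pairwise = {}
        for ia in range(len(groups)):
            for ib in range(ia + 1, len(groups)):
                _, _, pp = _two_sample_continuous(samples[ia], samples[ib], normal)
                pairwise[(groups[ia], groups[ib])] = pp

    flags = {k: v < ALPHA_PAIRWISE for k, v in pairwise.items()}
    return ComparisonResult(
        variable=variable,
        groups=groups,
        family=family,
        test_name=test_name,
        statistic=statistic,
        p_value=p,
        summaries=summaries,
        pairwise_p=pairwise,
        pairwise_flags=flags,
    )


# ---------------------------------------------------------------------------
# ROC / C-statistic


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci95: tuple[float, float]
    se: float
    optimal_cutoff: float
    sensitivity: float
    specificity: float
    n_events: int
    n_nonevents: int

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ci95": list(self.ci95),
            "se": self.se,
            "optimal_cutoff": self.optimal_cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n_events": self.n_events,
            "n_nonevents": self.n_nonevents,
        }


def roc_analysis(scores, labels) -> ROCResult:
    """C-statistic with DeLong 95% CI and the Youden-optimal cutoff.

    AUC is the Mann-Whitney U statistic over event/nonevent pairs with
    ties counted 1/2; the cutoff maximizes Youden's J over observed
    thresholds (predict event when score >= cutoff), ties broken toward
    higher specificity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise StatsError("scores and labels must align")
    if not np.isin(labels, [0, 1]).all():
        raise StatsError("labels must be binary 0/1")
    x = scores[labels == 1]
    y = scores[labels == 0]
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise StatsError("both classes must be present")

    # DeLong structural components via midranks
    allv = np.concatenate([x, y])
    r_all = sstats.rankdata(allv)
    r_x = sstats.rankdata(x)
    r_y = sstats.rankdata(y)
    v10 = (r_all[:m] - r_x) / n  # placement of each event among nonevents
    v01 = 1.0 - (r_all[m:] - r_y) / m
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    lo = max(0.0, auc - 1.959963984540054 * se)
    hi = min(1.0, auc + 1.959963984540054 * se)

    thresholds = np.unique(scores)
    sens = np.array([(x >= t).mean() for t in thresholds])
    spec = np.array([(y < t).mean() for t in thresholds])
    j = sens + spec - 1.0
    best_j = j.max()
    candidates = np.flatnonzero(j >= best_j - 1e-12)
    pick = candidates[np.argmax(spec[candidates])]
    return ROCResult(
        auc=auc,
        ci95=(lo, hi),
        se=se,
        optimal_cutoff=float(thresholds[pick]),
        sensitivity=float(sens[pick]),
        specificity=float(spec[pick]),
        n_events=m,
        n_nonevents=n,
    )


# ---------------------------------------------------------------------------
# continuous (category-free) NRI


@dataclass(frozen=True)
class NRIResult:
    nri_events: float
    nri_nonevents: float
    nri_total: float
    p_value: float
    degenerate: bool
    n_permutations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "nri_events": self.nri_events,
            "nri_nonevents": self.nri_nonevents,
            "nri_total": self.nri_total,
            "p_value": self.p_value,
            "degenerate": self.degenerate,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def continuous_nri(
    old_score, new_score, labels, n_permutations: int = 2000, seed: int = 0
) -> NRIResult:
    """Category-free NRI of new vs old risk scores with a permutation p.

    nri_events = P(up|event) - P(down|event); nri_nonevents =
    P(down|nonevent) - P(up|nonevent); total is their sum (in [-2, 2]).
    The null distribution permutes event labels (seeded, 2000 reps).
    """
    old = np.asarray(old_score, dtype=float)
    new = np.asarray(new_score, dtype=float)
    lab = np.asarray(labels).astype(int)
    if not (old.shape == new.shape == lab.shape):
        raise StatsError("old, new and labels must align")
    if not np.isin(lab, [0, 1]).all():
        raise StatsError("labels must be binary 0/1")
    ev = lab == 1
    if ev.all() or not ev.any():
        raise StatsError("both classes must be present")
    up = (new > old).astype(float)
    down = (new < old).astype(float)
    if not (up.any() or down.any()):
        return NRIResult(0.0, 0.0, 0.0, 1.0, True, n_permutations, seed)
    delta = up - down
    n_ev = int(ev.sum())
    n_ne = int((~ev).sum())
    nri_e = float(delta[ev].mean())
    nri_ne = float(-delta[~ev].mean())
    total = nri_e + nri_ne

    rng = np.random.default_rng(seed)
    perm = np.argsort(rng.random((n_permutations, len(lab))), axis=1)
    d_perm = delta[perm]
    null = d_perm[:, :n_ev].mean(axis=1) - d_perm[:, n_ev:].mean(axis=1)
    p = float((1 + np.count_nonzero(np.abs(null) >= abs(total) - 1e-12)) / (n_permutations + 1))
    return NRIResult(nri_e, nri_ne, total, p, False, n_permutations, seed)


def incremental_nri(
    base, added, labels, n_permutations: int = 2000, seed: int = 0
) -> NRIResult:
    """NRI of adding a marker to a base marker via logistic risk models.

    Category-free NRI is defined on the risk scale, so both scores are
    converted to fitted event probabilities: old = logit(label ~ base),
    new = logit(label ~ base + added), then compared subject-wise.
    """
    from sklearn.linear_model import LogisticRegression

    base = np.asarray(base, dtype=float)
    added = np.asarray(added, dtype=float)
    lab = np.asarray(labels).astype(int)
    # C=inf => unpenalised maximum likelihood
    old_model = LogisticRegression(C=np.inf, max_iter=5000)
    new_model = LogisticRegression(C=np.inf, max_iter=5000)
    old = old_model.fit(base[:, None], lab).predict_proba(base[:, None])[:, 1]
    x2 = np.column_stack([base, added])
    new = new_model.fit(x2, lab).predict_proba(x2)[:, 1]
    return continuous_nri(old, new, lab, n_permutations=n_permutations, seed=seed)


# ---------------------------------------------------------------------------
# forward stepwise selection


@dataclass(frozen=True)
class StepwiseResult:
    selected: tuple  # names in entry order
    entry_p: dict  # name -> p at entry
    coefficients: dict  # final-model name -> coef
    p_values: dict  # final-model name -> p
    dropped_collinear: tuple

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "entry_p": dict(self.entry_p),
            "coefficients": dict(self.coefficients),
            "p_values": dict(self.p_values),
            "dropped_collinear": list(self.dropped_collinear),
        }


def forward_stepwise(
    response, candidates: pd.DataFrame, entry_alpha: float = 0.05,
    condition_limit: float = 1e8,
) -> StepwiseResult:
    """Greedy forward selection on a linear model (entry when p < 0.05)."""
    import statsmodels.api as sm

    y = np.asarray(response, dtype=float)
    candidates = candidates.copy()
    names = list(candidates.columns)
    if len(y) <= len(names) + 5:
        raise StatsError(
            f"need n > candidates + 5 (n={len(y)}, candidates={len(names)})"
        )
    selected: list[str] = []
    entry_p: dict[str, float] = {}
    dropped: list[str] = []
    remaining = list(names)
    while remaining:
        best_name, best_p = None, None
        for name in list(remaining):
            cols = selected + [name]
            x = candidates[cols].to_numpy(dtype=float)
            xs = (x - x.mean(axis=0)) / np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
            if np.linalg.cond(np.column_stack([np.ones(len(xs)), xs])) > condition_limit:
                warnings.warn(f"dropping collinear candidate {name!r}")
                dropped.append(name)
                remaining.remove(name)
                continue
            fit = sm.OLS(y, sm.add_constant(x)).fit()
            p = float(fit.pvalues[-1])
            if best_p is None or p < best_p:
                best_name, best_p = name, p
        if best_name is None or best_p >= entry_alpha:
            break
        selected.append(best_name)
        entry_p[best_name] = best_p
        remaining.remove(best_name)
    if selected:
        x = candidates[selected].to_numpy(dtype=float)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        coefs = {"const": float(fit.params[0])}
        pvals = {"const": float(fit.pvalues[0])}
        for k, name in enumerate(selected):
            coefs[name] = float(fit.params[k + 1])
            pvals[name] = float(fit.pvalues[k + 1])
    else:
        coefs, pvals = {}, {}
    return StepwiseResult(
        selected=tuple(selected),
        entry_p=entry_p,
        coefficients=coefs,
        p_values=pvals,
        dropped_collinear=tuple(dropped),
    )


# ---------------------------------------------------------------------------
# 1:1 matching


@dataclass(frozen=True)
class MatchResult:
    pairs: tuple  # of (case_index, pool_index) labels from the input frames
    distances: tuple
    metric: str
    smd_before: dict
    smd_after: dict

    def to_dict(self) -> dict:
        return {
            "pairs": [list(p) for p in self.pairs],
            "distances": list(self.distances),
            "metric": self.metric,
            "smd_before": dict(self.smd_before),
            "smd_after": dict(self.smd_after),
        }


def _smd(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1) if len(a) > 1 else 0.0, b.var(ddof=1) if len(b) > 1 else 0.0
    denom = np.sqrt((va + vb) / 2.0)
    if denom == 0:
        return 0.0
    return float(abs(a.mean() - b.mean()) / denom)


def match_cohorts(cases: pd.DataFrame, pool: pd.DataFrame, covariates) -> MatchResult:
    """Greedy 1:1 nearest-neighbour matching without replacement.

    Distance is Mahalanobis over the stated covariates (covariance from
    the stacked cases+pool); a singular covariance falls back to
    SD-normalized Euclidean with a warning.
    """
    covariates = list(covariates)
    if len(pool) < len(cases):
        raise StatsError(f"pool ({len(pool)}) smaller than cases ({len(cases)})")
    xc = cases[covariates].to_numpy(dtype=float)
    xp = pool[covariates].to_numpy(dtype=float)
    stacked = np.vstack([xc, xp])
    cov = np.cov(stacked, rowvar=False)
    cov = np.atleast_2d(cov)
    metric = "mahalanobis"
    try:
        vi = np.linalg.inv(cov)
        if not np.all(np.isfinite(vi)) or np.linalg.cond(cov) > 1e12:
            raise np.linalg.LinAlgError
        d = cdist(xc, xp, metric="mahalanobis", VI=vi)
    except np.linalg.LinAlgError:
        warnings.warn("singular covariance; falling back to normalized Euclidean")
        metric = "normalized-euclidean"
        sd = stacked.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        d = cdist(xc / sd, xp / sd, metric="euclidean")

    used = np.zeros(len(pool), dtype=bool)
    pairs = []
    dists = []
    for i in range(len(cases)):
        row = np.where(used, np.inf, d[i])
        j = int(np.argmin(row))
        used[j] = True
        pairs.append((cases.index[i], pool.index[j]))
        dists.append(float(row[j]))
    matched_pool = pool.loc[[j for _, j in pairs]]
    smd_before = {
        c: _smd(cases[c].to_numpy(dtype=float), pool[c].to_numpy(dtype=float))
        for c in covariates
    }
    smd_after = {
        c: _smd(cases[c].to_numpy(dtype=float), matched_pool[c].to_numpy(dtype=float))
        for c in covariates
    }
    return MatchResult(
        pairs=tuple(pairs),
        distances=tuple(dists),
        metric=metric,
        smd_before=smd_before,
        smd_after=smd_after,
    )


# ---------------------------------------------------------------------------
# variable clustering on MIC proximity


@dataclass(frozen=True)
class ClusterTree:
    variables: tuple
    proximity: np.ndarray  # MIC matrix
    linkage: np.ndarray  # scipy linkage matrix (average on 1 - MIC)
    merges: tuple  # ((members_a, members_b, height), ...)

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "proximity": self.proximity.tolist(),
            "linkage_method": "average",
            "distance": "1 - MIC",
            "merges": [
                {"left": list(a), "right": list(b), "height": h} for a, b, h in self.merges
            ],
        }


def variable_cluster(cohort: pd.DataFrame, variables) -> ClusterTree:
    """Average-linkage clustering of variables on 1 - MIC proximity."""
    variables = list(variables)
    if len(variables) < 3:
        raise StatsError("need at least 3 variables to cluster")
    sub = cohort[variables].dropna()
    if len(sub) < 25:
        raise StatsError(f"need >= 25 complete cases, got {len(sub)}")
    k = len(variables)
    prox = np.eye(k)
    for ia in range(k):
        for ib in range(ia + 1, k):
            r = mic(sub[variables[ia]].to_numpy(), sub[variables[ib]].to_numpy())
            prox[ia, ib] = prox[ib, ia] = r.mic
    dist = 1.0 - prox
    np.fill_diagonal(dist, 0.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    members: list[tuple] = [(v,) for v in variables]
    merges = []
    for left, right, height, _ in z:
        a, b = members[int(left)], members[int(right)]
        merges.append((a, b, float(height)))
        members.append(a + b)
    return ClusterTree(
        variables=tuple(variables), proximity=prox, linkage=z, merges=tuple(merges)
    )


# ---------------------------------------------------------------------------
# covariate-adjusted medians


@dataclass(frozen=True)
class AdjustedMedians:
    variable: str
    covariates: tuple
    method: str
    per_group: dict  # group -> {"median", "q1", "q3", "n"}

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "covariates": list(self.covariates),
            "method": self.method,
            "per_group": {g: dict(s) for g, s in self.per_group.items()},
        }


def adjusted_medians(
    cohort: pd.DataFrame, variable: str, covariates, group_col: str = "group"
) -> AdjustedMedians:
    """Per-group median [IQR] after pooled linear residualization.

    The variable is regressed on the covariates pooled across groups;
    the per-group summaries are computed on residual + grand mean.  With
    an empty covariate list this equals the unadjusted summaries exactly.
    """
    covariates = list(covariates)
    sub = cohort[[group_col, variable] + covariates].dropna()
    y = sub[variable].to_numpy(dtype=float)
    if covariates:
        x = sub[covariates].to_numpy(dtype=float)
        design = np.column_stack([np.ones(len(x)), x])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise StatsError("rank-deficient covariate design")
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        adj = y - design @ beta + y.mean()
    else:
        adj = y
    per_group = {}
    for g, grp_idx in sub.groupby(group_col).groups.items():
        vals = adj[sub.index.get_indexer(grp_idx)]
        per_group[g] = {
            "median": float(np.median(vals)),
            "q1": float(np.percentile(vals, 25)),
            "q3": float(np.percentile(vals, 75)),
            "n": int(len(vals)),
        }
    return AdjustedMedians(
        variable=variable,
        covariates=tuple(covariates),
        method="pooled-linear-residualization+grand-mean",
        per_group=per_group,
    )
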