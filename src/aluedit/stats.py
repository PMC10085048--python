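"""Cohort statistics: group comparisons, FDR control, meaningful-site calls,
covariate/interaction regression, rank correlation and ROC marker evaluation.

Test selection follows a normality gate: the unpaired two-sided Student's
t-test (or one-way ANOVA + Tukey HSD for >2 groups) is used only when every
group passes the Shapiro-Wilk test (p >= 0.05) AND every group has n >= 30;
otherwise the two-sided Mann-Whitney U test (or Kruskal-Wallis + Dunn's
post-test) is used.  The conjunction is the conservative reading of the
two conditions.  Multiple testing is controlled by Benjamini-Hochberg,
one family per analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .annotations import CohortDesign

__all__ = [
    "GroupComparison",
    "MeaningfulSiteCall",
    "RocResult",
    "compare_two_groups",
    "compare_multi_groups",
    "dunn_posthoc",
    "bh_adjust",
    "meaningful_sites",
    "covariate_regression",
    "correlate",
    "interaction_model",
    "roc_auc",
]

NORMALITY_ALPHA = 0.05
PARAMETRIC_MIN_N = 30


@dataclass
class GroupComparison:
    """One statistical comparison between groups of per-sample values.

    ``direction`` is the sign of (second group mean - first group mean):
    with ``pair=(control, patient)`` an ``up`` arrow means elevated values
    in patients.
    """

    variable: str
    groups: tuple[str, ...]
    test_used: str
    statistic: float
    p_value: float
    means: tuple[float, ...]
    sems: tuple[float, ...]
    ns: tuple[int, ...]
    direction: str
    adjusted_p: float | None = None

    def to_row(self) -> dict:
        row = {
            "variable": self.variable,
            "groups": "|".join(self.groups),
            "test": self.test_used,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "adjusted_p": np.nan if self.adjusted_p is None else self.adjusted_p,
            "direction": self.direction,
        }
        for g, m, s, n in zip(self.groups, self.means, self.sems, self.ns):
            row[f"mean_{g}"] = m
            row[f"sem_{g}"] = s
            row[f"n_{g}"] = n
        return row


@dataclass
class MeaningfulSiteCall:
    """Per-site differential-editing call: meaningful iff the mean editing-level
    difference is >= the threshold AND the BH-adjusted p is below the FDR cutoff."""

    site: str
    gene: str
    mean_diff_pct: float
    p_value: float
    adjusted_p: float
    meaningful: bool
    comparison: GroupComparison = field(repr=False, default=None)


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_case: int
    n_control: int


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")


def _shapiro_p(x: np.ndarray) -> float:
    # constant samples are maximally non-normal for gating purposes
    if np.ptp(x) == 0:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.shapiro(x).pvalue)


def _normal_gate(groups: Sequence[np.ndarray]) -> bool:
    return all(g.size >= PARAMETRIC_MIN_N for g in groups) and all(
        _shapiro_p(g) >= NORMALITY_ALPHA for g in groups
    )


def _extract(values, design: CohortDesign, group: str) -> np.ndarray:
    v = pd.Series(values, dtype=float)
    samples = [s for s in design.samples_in(group) if s in v.index]
    x = v.loc[samples].dropna().to_numpy()
    return x


def _direction(mean_first: float, mean_second: float) -> str:
    if mean_second > mean_first:
        return "up"
    if mean_second < mean_first:
        return "down"
    return "none"


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact for min(n) <= 8 and no ties, otherwise
    normal approximation with mid-rank tie correction."""
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_two_groups(
    values,
    design: CohortDesign,
    pair: tuple[str, str],
    variable: str = "",
) -> GroupComparison:
    """Compare per-sample values between two cohort groups.

    ``values`` is a mapping/Series keyed by sample ID.  Both groups need
    >= 3 non-missing values.  Reports mean, SEM and n per group; the test
    is chosen by the normality/N gate documented in the module docstring.
    """
    g1, g2 = pair
    for g in pair:
        if g not in design.groups:
            raise ValueError(f"group {g!r} absent from the cohort design")
    x = _extract(values, design, g1)
    y = _extract(values, design, g2)
    if x.size < 3 or y.size < 3:
        raise ValueError(
            f"need >= 3 non-missing values per group (got {x.size}, {y.size})"
        )
    if _normal_gate([x, y]):
        res = sps.ttest_ind(x, y, equal_var=True)
        test, stat, p = "t", float(res.statistic), float(res.pvalue)
    else:
        stat, p = _mannwhitney(x, y)
        test = "mann_whitney"
    return GroupComparison(
        variable=variable,
        groups=(g1, g2),
        test_used=test,
        statistic=stat,
        p_value=p,
        means=(float(x.mean()), float(y.mean())),
        sems=(_sem(x), _sem(y)),
        ns=(int(x.size), int(y.size)),
        direction=_direction(x.mean(), y.mean()),
    )


def dunn_posthoc(
    samples: Mapping[str, np.ndarray], adjust: str = "bh"
) -> list[GroupComparison]:
    """Dunn's rank-based post-test for all group pairs after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with the
    tie correction T = sum(t^3 - t) / (12 (N - 1)); two-sided normal p-values
    adjusted by BH (default) or Bonferroni.
    """
    if adjust not in ("bh", "bonferroni"):
        raise ValueError("adjust must be 'bh' or 'bonferroni'")
    labels = list(samples)
    data = [np.asarray(samples[k], dtype=float) for k in labels]
    pooled = np.concatenate(data)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    offsets = np.cumsum([0] + [d.size for d in data])
    mean_ranks = [
        ranks[offsets[i] : offsets[i + 1]].mean() for i in range(len(data))
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    comparisons = []
    pvals = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            se = np.sqrt(base_var * (1.0 / data[i].size + 1.0 / data[j].size))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            p = float(2.0 * sps.norm.sf(abs(z)))
            comparisons.append(
                GroupComparison(
                    variable="",
                    groups=(labels[i], labels[j]),
                    test_used="dunn",
                    statistic=float(z),
                    p_value=p,
                    means=(float(data[i].mean()), float(data[j].mean())),
                    sems=(_sem(data[i]), _sem(data[j])),
                    ns=(int(data[i].size), int(data[j].size)),
                    direction=_direction(data[i].mean(), data[j].mean()),
                )
            )
            pvals.append(p)
    if pvals:
        if adjust == "bh":
            adj = bh_adjust(pvals)
        else:
            adj = np.minimum(np.asarray(pvals) * len(pvals), 1.0)
        for comparison, a in zip(comparisons, adj):
            comparison.adjusted_p = float(a)
    return comparisons


def compare_multi_groups(
    values,
    design: CohortDesign,
    groups: Sequence[str] | None = None,
    variable: str = "",
) -> tuple[GroupComparison, list[GroupComparison]]:
    """Omnibus comparison of >= 3 groups plus pairwise post-hoc results.

    Uses Kruskal-Wallis + Dunn (BH-adjusted) unless the normality/N gate
    passes, in which case one-way ANOVA + Tukey HSD.  With exactly two
    groups an error directs the caller to :func:`compare_two_groups`.
    """
    groups = list(groups) if groups is not None else design.groups
    if len(groups) < 3:
        raise ValueError("fewer than 3 groups: use compare_two_groups")
    data = {g: _extract(values, design, g) for g in groups}
    for g, x in data.items():
        if x.size < 3:
            raise ValueError(f"group {g!r} has < 3 non-missing values")
    arrays = list(data.values())
    means = tuple(float(x.mean()) for x in arrays)
    sems = tuple(_sem(x) for x in arrays)
    ns = tuple(int(x.size) for x in arrays)

    if _normal_gate(arrays):
        f, p = sps.f_oneway(*arrays)
        omnibus = GroupComparison(
            variable, tuple(groups), "anova", float(f), float(p),
            means, sems, ns, "none",
        )
        stacked = np.concatenate(arrays)
        labels = np.concatenate([[g] * x.size for g, x in data.items()])
        tukey = sm.stats.multicomp.pairwise_tukeyhsd(stacked, labels)
        pairwise = []
        for row in tukey.summary().data[1:]:
            a, b = str(row[0]), str(row[1])
            pairwise.append(
                GroupComparison(
                    variable, (a, b), "tukey_hsd", float(row[2]), float(row[3]),
                    (float(data[a].mean()), float(data[b].mean())),
                    (_sem(data[a]), _sem(data[b])),
                    (data[a].size, data[b].size),
                    _direction(data[a].mean(), data[b].mean()),
                    adjusted_p=float(row[3]),
                )
            )
    else:
        h, p = sps.kruskal(*arrays)
        omnibus = GroupComparison(
            variable, tuple(groups), "kruskal_wallis", float(h), float(p),
            means, sems, ns, "none",
        )
        pairwise = dunn_posthoc(data)
        for comparison in pairwise:
            comparison.variable = variable
    return omnibus, pairwise


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def meaningful_sites(
    site_table: pd.DataFrame,
    design: CohortDesign,
    pair: tuple[str, str],
    diff_threshold_pct: float = 5.0,
    q: float = 0.05,
) -> tuple[list[MeaningfulSiteCall], list[str]]:
    """Differential-editing calls over a long-format per-(sample, site) table.

    Only observations with ``included`` (coverage >= 10) enter.  Each site
    is compared between the two groups; BH is applied across sites; a site
    is *meaningful* iff |patient mean - control mean| >= ``diff_threshold_pct``
    AND adjusted p < ``q``.  Sites with < 3 included samples in either group
    are excluded and reported in the second return value.
    """
    required = {"sample", "site", "level_pct", "included"}
    if not required.issubset(site_table.columns):
        raise ValueError(f"site table must have columns {sorted(required)}")
    usable = site_table[site_table["included"].astype(bool)]
    gene_of = {}
    if "gene" in site_table.columns:
        gene_of = site_table.drop_duplicates("site").set_index("site")["gene"].to_dict()

    sort_cols = [c for c in ("chrom", "pos") if c in site_table.columns] or ["site"]
    site_order = (
        site_table.drop_duplicates("site").sort_values(sort_cols)["site"].tolist()
    )

    kept: list[tuple[str, GroupComparison, float]] = []
    excluded: list[str] = []
    for site in site_order:
        sub = usable[usable["site"] == site]
        values = sub.set_index("sample")["level_pct"]
        values = values[~values.index.duplicated()]
        n1 = sum(s in values.index for s in design.samples_in(pair[0]))
        n2 = sum(s in values.index for s in design.samples_in(pair[1]))
        if n1 < 3 or n2 < 3:
            excluded.append(site)
            continue
        comparison = compare_two_groups(values, design, pair, variable=site)
        diff = comparison.means[1] - comparison.means[0]
        kept.append((site, comparison, diff))

    calls: list[MeaningfulSiteCall] = []
    if kept:
        adj = bh_adjust([c.p_value for _, c, _ in kept])
        for (site, comparison, diff), a in zip(kept, adj):
            comparison.adjusted_p = float(a)
            calls.append(
                MeaningfulSiteCall(
                    site=site,
                    gene=str(gene_of.get(site, "")),
                    mean_diff_pct=float(diff),
                    p_value=comparison.p_value,
                    adjusted_p=float(a),
                    meaningful=bool(abs(diff) >= diff_threshold_pct and a < q),
                    comparison=comparison,
                )
            )
    return calls, excluded


def _design_matrix(frame: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    X = sm.add_constant(frame[list(columns)].astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify offending columns by greedy removal
        bad = []
        keep = list(X.columns)
        for col in list(X.columns[1:]):
            trial = [c for c in keep if c != col]
            if np.linalg.matrix_rank(X[trial].to_numpy()) == rank:
                bad.append(col)
                keep = trial
        raise ValueError(f"collinear design; offending column(s): {bad}")
    return X


def covariate_regression(
    response,
    design: CohortDesign,
    group_pair: tuple[str, str],
    min_covariate_fraction: float = 0.8,
) -> pd.DataFrame:
    """OLS of the response on a group indicator plus age and sex.

    Restricted to the two groups of ``group_pair``; samples with missing
    covariates are dropped listwise (with a logged count), provided at
    least ``min_covariate_fraction`` of samples have complete covariates.
    Sex is encoded as a single indicator.  Returns a coefficient table
    (term, coef, stderr, t, p); the ``group`` row is the adjusted effect.
    """
    v = pd.Series(response, dtype=float)
    meta = design.covariates()
    meta = meta[meta["group"].isin(group_pair)]
    frame = meta.join(v.rename("y"), how="inner").dropna(subset=["y"])
    complete = frame.dropna(subset=["age", "sex"])
    if len(complete) < min_covariate_fraction * len(frame):
        raise ValueError(
            f"age/sex available for only {len(complete)}/{len(frame)} samples "
            f"(< {min_covariate_fraction:.0%})"
        )
    n_dropped = len(frame) - len(complete)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} sample(s) dropped listwise for missing covariates",
            stacklevel=2,
        )
    frame = complete
    sex_levels = sorted(frame["sex"].astype(str).unique())
    frame = frame.assign(
        group_ind=(frame["group"] == group_pair[1]).astype(float),
        sex_ind=(frame["sex"].astype(str) == sex_levels[-1]).astype(float)
        if len(sex_levels) > 1
        else 0.0,
        age=frame["age"].astype(float),
    )
    predictors = ["group_ind", "age"] + (["sex_ind"] if len(sex_levels) > 1 else [])
    X = _design_matrix(frame, predictors)
    with np.errstate(divide="ignore"):  # constant response: R^2 degenerates
        fit = sm.OLS(frame["y"].to_numpy(), X).fit()
    out = pd.DataFrame(
        {
            "term": ["intercept", "group", "age"] + (["sex"] if "sex_ind" in X else []),
            "coef": fit.params.to_numpy(),
            "stderr": fit.bse.to_numpy(),
            "t": fit.tvalues.to_numpy(),
            "p_value": fit.pvalues.to_numpy(),
        }
    )
    with np.errstate(divide="ignore"):
        r2 = float(fit.rsquared)
    out.attrs["r_squared"] = r2 if np.isfinite(r2) else 0.0
    out.attrs["n"] = int(fit.nobs)
    return out


def correlate(x, y, method: str = "spearman") -> tuple[float, float]:
    """Rank (or Pearson) correlation with mid-rank ties and two-sided p.

    Requires >= 4 complete pairs; a constant vector yields (NaN, NaN) with
    a warning.
    """
    xs = pd.Series(x, dtype=float).reset_index(drop=True)
    ys = pd.Series(y, dtype=float).reset_index(drop=True)
    if isinstance(x, (pd.Series,)) and isinstance(y, (pd.Series,)):
        joined = pd.concat([pd.Series(x, dtype=float), pd.Series(y, dtype=float)], axis=1)
        joined = joined.dropna()
        xs, ys = joined.iloc[:, 0], joined.iloc[:, 1]
    else:
        ok = ~(xs.isna() | ys.isna())
        xs, ys = xs[ok], ys[ok]
    if len(xs) < 4:
        raise ValueError("need >= 4 paired observations")
    if np.ptp(xs.to_numpy()) == 0 or np.ptp(ys.to_numpy()) == 0:
        warnings.warn("constant vector; correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    if method == "spearman":
        rho, p = sps.spearmanr(xs, ys)
    elif method == "pearson":
        rho, p = sps.pearsonr(xs, ys)
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")
    return float(rho), float(p)


def interaction_model(aei, adar1_expr, isg_score) -> pd.DataFrame:
    """OLS of AEI on standardized ADAR1, ISG and their interaction.

    Tests whether interferon signalling modulates the ADAR1-editing
    relationship; the ``adar1:isg`` row carries the interaction coefficient
    and its p-value.  Requires >= 10 complete (AEI, ADAR1, ISG) triples.
    """
    frame = pd.DataFrame(
        {
            "aei": pd.Series(aei, dtype=float),
            "adar1": pd.Series(adar1_expr, dtype=float),
            "isg": pd.Series(isg_score, dtype=float),
        }
    ).dropna()
    if len(frame) < 10:
        raise ValueError(f"need >= 10 complete triples, got {len(frame)}")
    z = lambda s: (s - s.mean()) / s.std(ddof=1)
    frame = frame.assign(adar1_z=z(frame["adar1"]), isg_z=z(frame["isg"]))
    frame["inter"] = frame["adar1_z"] * frame["isg_z"]
    X = _design_matrix(frame, ["adar1_z", "isg_z", "inter"])
    fit = sm.OLS(frame["aei"].to_numpy(), X).fit()
    out = pd.DataFrame(
        {
            "term": ["intercept", "adar1", "isg", "adar1:isg"],
            "coef": fit.params.to_numpy(),
            "stderr": fit.bse.to_numpy(),
            "t": fit.tvalues.to_numpy(),
            "p_value": fit.pvalues.to_numpy(),
        }
    )
    out.attrs["n"] = int(fit.nobs)
    return out


def roc_auc(values, labels, positive) -> RocResult:
    """Rank-based AUC of a marker for case/control separation.

    AUC = P(case > control) + 0.5 P(tie), computed from the Mann-Whitney U
    statistic (U / (n1 n0)).  The confidence interval is the Hanley-McNeil
    normal interval on the rank statistic, clipped to [0, 1].
    """
    v = np.asarray(pd.Series(values, dtype=float))
    lab = np.asarray(list(labels))
    ok = ~np.isnan(v)
    v, lab = v[ok], lab[ok]
    classes = set(lab.tolist())
    if positive not in classes or len(classes) < 2:
        raise ValueError("both case and control labels must be present")
    case = v[lab == positive]
    ctrl = v[lab != positive]
    n1, n0 = case.size, ctrl.size
    ranks = sps.rankdata(np.concatenate([case, ctrl]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    auc = float(u / (n1 * n0))
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)
    ) / (n1 * n0)
    se = float(np.sqrt(max(var, 0.0)))
    lo = float(np.clip(auc - 1.959963984540054 * se, 0.0, 1.0))
    hi = float(np.clip(auc + 1.959963984540054 * se, 0.0, 1.0))
    return RocResult(auc=auc, ci_low=lo, ci_high=hi, n_case=n1, n_control=n0)
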