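"""Tissue-by-site editing-profile matrices and their clustering.

Per-(tissue, site) values are pooled editing percentages — summed edited
counts over summed coverage across the tissue's samples, never a mean of
ratios — masked where pooled coverage falls below the inclusion floor.
Tissues are clustered hierarchically in a reduced principal-component
space (components retaining >= 90% of variance by default, standardized
site columns, Euclidean distance, average linkage); all three choices are
configuration, since no single canonical parameterization exists for
"PCA-based hierarchical clustering".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .indices import centralization

__all__ = [
    "ProfileMatrix",
    "TissueClustering",
    "build_profile",
    "filter_profile",
    "cluster_tissues",
    "contribution_profile",
]


class ProfileMatrix:
    """Tissues x sites pooled editing percentages with an availability mask."""

    def __init__(
        self,
        values: pd.DataFrame,
        edited: pd.DataFrame,
        coverage: pd.DataFrame,
        min_reads: int,
    ):
        self.values = values          # percent, NaN where masked
        self.edited = edited          # pooled edited counts
        self.coverage = coverage      # pooled informative reads
        self.min_reads = min_reads

    @property
    def tissues(self) -> list[str]:
        return list(self.values.index)

    @property
    def sites(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """True where a cell is available (pooled coverage >= min_reads)."""
        return self.coverage >= self.min_reads

    def subset_sites(self, sites: Sequence[str]) -> "ProfileMatrix":
        sites = list(sites)
        return ProfileMatrix(
            self.values[sites], self.edited[sites], self.coverage[sites], self.min_reads
        )


@dataclass
class TissueClustering:
    """Hierarchical clustering of tissues in PC space."""

    tissues: list[str]
    linkage: np.ndarray
    newick: str
    embedding: pd.DataFrame           # tissues x (PC1, PC2)
    n_components: int
    explained_variance_ratio: np.ndarray

    def top_split(self) -> tuple[frozenset, frozenset]:
        """The two tissue sets produced by cutting the tree at its top merge."""
        assignment = hierarchy.fcluster(self.linkage, t=2, criterion="maxclust")
        a = frozenset(t for t, c in zip(self.tissues, assignment) if c == 1)
        b = frozenset(t for t, c in zip(self.tissues, assignment) if c == 2)
        return a, b


def build_profile(
    site_tables: pd.DataFrame | Sequence[pd.DataFrame],
    tissues: Mapping[str, str],
    min_reads: int = 10,
) -> ProfileMatrix:
    """Pool per-sample site tables into a tissue x site profile matrix.

    ``site_tables`` is a long-format table (or list of per-sample tables)
    with columns sample, site, edited, coverage.  Cells are pooled by
    summed counts; cells with pooled coverage < ``min_reads`` are masked.
    Pooling is permutation-invariant over samples.
    """
    if not isinstance(site_tables, pd.DataFrame):
        site_tables = pd.concat(list(site_tables), ignore_index=True)
    required = {"sample", "site", "edited", "coverage"}
    if not required.issubset(site_tables.columns):
        raise ValueError(f"site tables must have columns {sorted(required)}")
    long = site_tables.copy()
    long["tissue"] = long["sample"].map(dict(tissues))
    if long["tissue"].isna().any():
        missing = long.loc[long["tissue"].isna(), "sample"].unique()[:3]
        raise ValueError(f"no tissue assignment for sample(s) {list(missing)}")
    if len(set(tissues.values())) < 2:
        raise ValueError("need >= 2 tissues")

    sort_cols = [c for c in ("chrom", "pos") if c in long.columns] or ["site"]
    site_order = long.drop_duplicates("site").sort_values(sort_cols)["site"].tolist()
    pooled = (
        long.groupby(["tissue", "site"], sort=True)[["edited", "coverage"]]
        .sum()
        .reset_index()
    )
    edited = pooled.pivot(index="tissue", columns="site", values="edited").fillna(0.0)
    coverage = pooled.pivot(index="tissue", columns="site", values="coverage").fillna(0.0)
    edited = edited.reindex(columns=site_order)
    coverage = coverage.reindex(columns=site_order)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = 100.0 * edited / coverage
    values = values.where(coverage >= min_reads)
    return ProfileMatrix(values, edited, coverage, min_reads)


def filter_profile(
    matrix: ProfileMatrix,
    min_level_pct: float = 5.0,
    min_tissues: int = 5,
    strict: bool = False,
) -> ProfileMatrix:
    """Apply the profile inclusion cutoffs.

    Default reading: a site is retained if it is available (unmasked) in at
    least ``min_tissues`` tissues AND reaches >= ``min_level_pct`` editing in
    at least one tissue.  ``strict=True`` switches to the alternative
    reading: >= ``min_level_pct`` editing in >= ``min_tissues`` tissues.
    """
    available = matrix.mask.sum(axis=0)
    high = (matrix.values >= min_level_pct).sum(axis=0)
    if strict:
        keep = high >= min_tissues
    else:
        keep = (available >= min_tissues) & (high >= 1)
    return matrix.subset_sites([s for s in matrix.sites if keep[s]])


def cluster_tissues(
    matrix: ProfileMatrix, variance_retained: float = 0.9
) -> TissueClustering:
    """PCA-reduced hierarchical clustering of tissue editing profiles.

    Masked cells are imputed with the site's cross-tissue mean, site columns
    are standardized, principal components retaining >= ``variance_retained``
    of the variance are kept, and tissues are merged by average linkage on
    Euclidean distances in PC space.  Tissue rows are processed in sorted
    name order so the result is independent of input ordering; all-identical
    rows yield a single flat cluster rather than an error.
    """
    values = matrix.values.sort_index()
    tissues = list(values.index)
    if len(tissues) < 3:
        raise ValueError("need >= 3 tissues to cluster")
    x = values.to_numpy(dtype=float)
    # drop sites with no data anywhere, impute the rest with column means
    keep = ~np.all(np.isnan(x), axis=0)
    x = x[:, keep]
    if x.shape[1] < 2:
        raise ValueError("need >= 2 sites with data after filtering")
    col_mean = np.nanmean(x, axis=0)
    nan_at = np.isnan(x)
    x[nan_at] = np.take(col_mean, np.nonzero(nan_at)[1])
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd

    n_comp_max = min(z.shape)
    pca = PCA(n_components=n_comp_max, svd_solver="full")
    with np.errstate(invalid="ignore"):  # zero total variance is a valid input
        scores = pca.fit_transform(z)
        evr = pca.explained_variance_ratio_
    if evr.sum() == 0 or np.isnan(evr).all():
        n_keep = 1
    else:
        n_keep = int(np.searchsorted(np.cumsum(evr), variance_retained) + 1)
        n_keep = min(max(n_keep, 1), n_comp_max)
    reduced = scores[:, :n_keep]

    linkage = hierarchy.linkage(reduced, method="average", metric="euclidean")
    newick = _to_newick(linkage, tissues)
    embedding = pd.DataFrame(
        scores[:, : min(2, scores.shape[1])],
        index=tissues,
        columns=[f"PC{i+1}" for i in range(min(2, scores.shape[1]))],
    )
    return TissueClustering(
        tissues=tissues,
        linkage=linkage,
        newick=newick,
        embedding=embedding,
        n_components=n_keep,
        explained_variance_ratio=evr,
    )


def _to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage as Newick, ordering children by smallest leaf name."""
    tree = hierarchy.to_tree(linkage)

    def min_leaf(node):
        if node.is_leaf():
            return labels[node.id]
        return min(min_leaf(node.left), min_leaf(node.right))

    def render(node, parent_dist):
        length = parent_dist - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.10g}"
        children = sorted((node.left, node.right), key=min_leaf)
        inner = ",".join(render(c, node.dist) for c in children)
        return f"({inner}):{length:.10g}"

    return render(tree, tree.dist) + ";"


def contribution_profile(activity: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Per-site fractions of total editing activity for each tissue.

    ``activity`` holds per-site edited counts per tissue (rows tissues).
    Rows sum to 1 exactly; a zero-activity tissue yields an all-NA row with
    a warning.  The top-``k`` share of a row is its :func:`centralization`.
    """
    totals = activity.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"zero-activity tissue(s): {list(activity.index[zero])}", stacklevel=2
        )
    out = activity.div(totals.where(~zero), axis=0)
    return out
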