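"""Community-structure statistics: dissimilarities, ordination, clustering,
correlation and group tests.

All computations act on per-sample relative abundances.  Principal
coordinate analysis is classical metric scaling (Gower double-centering +
eigendecomposition); negative eigenvalues, which appear for non-Euclidean
dissimilarities such as Bray-Curtis, are reported but excluded from the
coordinates.  Hierarchical clustering uses Ward's minimum-variance
criterion in the Ward.D2 convention (Lance-Williams update on squared
dissimilarities), with a Ward.D compatibility variant.  Dunnett's
many-to-one comparison is implemented by Monte-Carlo sampling of the
max-|t| null under the comparisons' exact correlation structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import scipy.stats as sstats

from .tables import TaxonTable


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("shape mismatch with ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix not symmetric")
        if (v < -1e-12).any():
            raise ValueError("negative distances")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("nonzero diagonal")
        object.__setattr__(self, "values", v)

    def condensed(self) -> np.ndarray:
        return ssd.squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))


def _relabund_rows(table: TaxonTable) -> tuple[list[str], np.ndarray]:
    # samples as rows (observations), taxa as columns
    return table.sample_ids, table.relabund.to_numpy().T


def bray_curtis(table: TaxonTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity 1 - 2*sum(min(u,v)) / (sum(u)+sum(v)) on
    per-sample relative abundances; every sample needs at least one read."""
    if table.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    if (table.sample_totals() == 0).any():
        empty = [s for s in table.sample_ids if table.sample_totals()[s] == 0]
        raise ValueError(f"samples with zero reads: {empty}")
    ids, X = _relabund_rows(table)
    d = ssd.squareform(ssd.pdist(X, metric="braycurtis"))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(tuple(ids), d)


def euclidean(table: TaxonTable) -> DistanceMatrix:
    """Euclidean distance between per-sample relative abundance vectors."""
    if table.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    ids, X = _relabund_rows(table)
    d = ssd.squareform(ssd.pdist(X, metric="euclidean"))
    return DistanceMatrix(tuple(ids), d)


# ---------------------------------------------------------------------------
# Ordination

@dataclass(frozen=True)
class PcoaResult:
    ids: tuple[str, ...]
    coordinates: np.ndarray  # samples x positive axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # per positive axis

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=list(self.ids), columns=cols)


def pcoa(d: DistanceMatrix) -> PcoaResult:
    """Classical metric scaling of a dissimilarity matrix.

    B = -0.5 * J D^2 J is eigendecomposed; coordinates are eigenvectors
    scaled by sqrt(eigenvalue) for strictly positive eigenvalues, and the
    proportion explained is relative to the sum of positive eigenvalues.
    For an exactly Euclidean-embeddable input the pairwise coordinate
    distances reproduce the input.
    """
    n = len(d.ids)
    if n < 2:
        raise ValueError("need >= 2 samples")
    D2 = d.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-12 if n else 0.0
    pos = eigval > tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    total_pos = eigval[pos].sum()
    prop = eigval[pos] / total_pos if total_pos > 0 else eigval[pos]
    return PcoaResult(d.ids, coords, eigval, prop)


# ---------------------------------------------------------------------------
# Clustering

@dataclass(frozen=True)
class ClusterResult:
    ids: tuple[str, ...]
    linkage: np.ndarray  # scipy linkage matrix; heights non-decreasing
    labels: np.ndarray  # cluster label (1..k) per id

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with branch lengths from merge
        heights (each node sits at half its merge height)."""
        tree = sch.to_tree(self.linkage)

        def rec(node, parent_height: float) -> str:
            height = node.dist / 2.0
            bl = parent_height - height
            if node.is_leaf():
                return f"{self.ids[node.id]}:{parent_height:.10g}"
            left = rec(node.left, height)
            right = rec(node.right, height)
            return f"({left},{right}):{bl:.10g}"

        return rec(tree, tree.dist / 2.0).rsplit(":", 1)[0] + ";"


def ward_cluster(d: DistanceMatrix, k: int, variant: str = "D2") -> ClusterResult:
    """Agglomerative Ward clustering of a dissimilarity matrix, cut at k.

    ``variant`` "D2" (default) applies the Lance-Williams Ward update to
    squared dissimilarities (the behaviour of hclust ward.D2 and of
    scipy); "D" applies it to the dissimilarities as given (hclust
    ward.D).
    """
    n = len(d.ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    cond = d.condensed()
    if variant == "D2":
        Z = sch.linkage(cond, method="ward")
    elif variant == "D":
        # scipy's update on sqrt(d) is the plain-Ward recurrence on d;
        # squaring the heights restores the ward.D height scale
        Z = sch.linkage(np.sqrt(cond), method="ward")
        Z = Z.copy()
        Z[:, 2] = Z[:, 2] ** 2
    else:
        raise ValueError(f"unknown Ward variant {variant!r}")
    labels = sch.fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(d.ids, Z, labels)


# ---------------------------------------------------------------------------
# Correlation and group tests

def pearson_matrix(
    table: TaxonTable, taxa: list[str] | None = None, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation of taxon relative abundances across
    samples, with two-sided p-values from the t transform (n-2 df) and a
    significance mask at ``alpha``.

    Zero-variance taxa yield NaN (undefined correlation), never 0.
    """
    if taxa is None:
        taxa = table.taxa
    X = table.relabund.loc[taxa].to_numpy()  # taxa x samples
    n = X.shape[1]
    if n < 3:
        raise ValueError("need >= 3 samples")
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ Xc.T) / np.outer(norms, norms)
    r[norms == 0, :] = np.nan
    r[:, norms == 0] = np.nan
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * sstats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) == 1.0] = 0.0
    p[np.isnan(r)] = np.nan
    np.fill_diagonal(p, 0.0)
    rdf = pd.DataFrame(r, index=taxa, columns=taxa)
    pdf = pd.DataFrame(p, index=taxa, columns=taxa)
    return rdf, pdf, pdf < alpha


def correlation_display_order(r: pd.DataFrame) -> list[str]:
    """Row/column order for displaying a correlation matrix: hierarchical
    clustering (average linkage) of 1 - |r|."""
    dist = 1.0 - r.abs().fillna(0.0).to_numpy()
    np.fill_diagonal(dist, 0.0)
    Z = sch.linkage(ssd.squareform(dist, checks=False), method="average")
    order = sch.leaves_list(Z)
    return [r.index[i] for i in order]


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, Satterthwaite df,
    two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 values")
    res = sstats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def dunnett(
    groups: list, control_index: int = 0, mc_draws: int = 100_000, seed: int = 0
) -> np.ndarray:
    """Dunnett's many-to-one comparisons against a control group.

    Per-comparison t statistics use the pooled variance across all groups
    (df = N - k).  Family-wise adjusted p-values are
    P(max_j |T_j| >= |t_i|) under the null, where (T_1..T_m) is
    multivariate t with the comparisons' correlation structure
    rho_ij = lambda_i * lambda_j, lambda_i = sqrt(n_i / (n_i + n_0));
    the probability is evaluated by Monte Carlo with ``mc_draws`` samples,
    deterministic given ``seed``.  Returns adjusted p per non-control
    group, in input order.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs >= 2 values")
    if not 0 <= control_index < len(arrays):
        raise ValueError("invalid control index")
    control = arrays[control_index]
    others = [a for i, a in enumerate(arrays) if i != control_index]
    ns = np.array([len(a) for a in arrays])
    N, k = ns.sum(), len(arrays)
    df = N - k
    s2 = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df
    n0 = len(control)
    t_obs = np.array(
        [
            (a.mean() - control.mean()) / np.sqrt(s2 * (1 / len(a) + 1 / n0))
            for a in others
        ]
    )
    lam = np.array([np.sqrt(len(a) / (len(a) + n0)) for a in others])
    R = np.outer(lam, lam)
    np.fill_diagonal(R, 1.0)
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(R)
    Z = rng.standard_normal((mc_draws, len(others))) @ L.T
    W = np.sqrt(rng.chisquare(df, size=mc_draws) / df)
    maxabs = np.abs(Z / W[:, None]).max(axis=1)
    return np.array([float((maxabs >= abs(t)).mean()) for t in t_obs])
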