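"""Population-level comparisons of fitted hydrotime parameters.

Covers the downstream statistics of a multi-population germination study:

* heteroscedastic (Welch) one-way ANOVA across populations with
  Games–Howell pairwise comparisons summarized as a compact letter display;
* ordinary linear regressions of fitted parameters on environmental or
  geographic variables;
* PCA of standardized variables (correlation matrix), so eigenvalues sum
  to the number of variables;
* UPGMA (average-linkage) hierarchical clustering on Euclidean distances,
  with categorical site descriptors entering via one-hot encoding, and the
  dendrogram serialized as Newick.

The heteroscedastic ANOVA is Welch's, with Games–Howell letters — the
closest standard procedure with a citable definition for an "ANOVA with
heterogeneity of variances".
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "AnovaResult",
    "EnvRegression",
    "PCAResult",
    "ClusteringResult",
    "welch_anova",
    "regress_env",
    "pca_env",
    "hcluster_average",
    "compact_letter_display",
]


@dataclass(frozen=True)
class AnovaResult:
    """Welch ANOVA outcome with Games–Howell compact letters.

    Groups sharing a letter are not significantly different at the chosen
    alpha.  ``pairwise`` holds the Games–Howell table (None when letters
    were not requested).
    """

    F: float
    df_num: float
    df_den: float
    p: float
    letters: dict[str, str] | None
    pairwise: pd.DataFrame | None
    alpha: float = 0.05


def compact_letter_display(
    groups: Sequence[str],
    not_different: Mapping[tuple[str, str], bool],
    order: Sequence[str] | None = None,
) -> dict[str, str]:
    """Assign compact letters from pairwise non-significance indicators.

    Letters correspond to maximal cliques of the graph whose edges join
    pairs that are *not* significantly different, so two groups share a
    letter iff their pairwise test does not reject.  Cliques are lettered
    in the order of their first member in ``order`` (default: input order).
    """
    import networkx as nx

    graph = nx.Graph()
    graph.add_nodes_from(groups)
    for (a, b), nd in not_different.items():
        if nd:
            graph.add_edge(a, b)
    rank = {g: i for i, g in enumerate(order if order is not None else groups)}
    cliques = sorted(
        (sorted(c, key=rank.get) for c in nx.find_cliques(graph)),
        key=lambda c: (rank[c[0]], len(c)),
    )
    letters: dict[str, list[str]] = {g: [] for g in groups}
    for letter, clique in zip(string.ascii_lowercase, cliques):
        for g in clique:
            letters[g].append(letter)
    if len(cliques) > len(string.ascii_lowercase):
        raise ValueError("more than 26 letter groups; display not supported")
    return {g: "".join(sorted(ls)) for g, ls in letters.items()}


def welch_anova(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    letters: bool = True,
) -> AnovaResult:
    """Welch's heteroscedastic one-way ANOVA across labelled groups.

    Parameters
    ----------
    groups : mapping of label -> values
        Per-population parameter values; every group needs ≥ 2 values and
        positive variance.
    letters : bool
        Also run Games–Howell pairwise comparisons and derive the compact
        letter display (skippable to save time in simulation loops).
    """
    import pingouin as pg

    if len(groups) < 2:
        raise ValueError("need ≥ 2 groups")
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
        if arr.std(ddof=1) == 0:
            raise ValueError(f"group {name!r} has zero variance")

    long = pd.DataFrame(
        [(name, v) for name, vals in groups.items() for v in np.asarray(vals, float)],
        columns=["group", "value"],
    )
    aov = pg.welch_anova(data=long, dv="value", between="group")
    F = float(aov["F"].iloc[0])
    pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
    p = float(aov[pcol].iloc[0])
    df_num = float(aov["ddof1"].iloc[0])
    df_den = float(aov["ddof2"].iloc[0])
    if np.isnan(p) and F == 0.0:  # all group means equal: no evidence at all
        p = 1.0

    letter_map = None
    pairwise = None
    if letters:
        pairwise = pg.pairwise_gameshowell(data=long, dv="value", between="group")
        nd = {
            (str(row["A"]), str(row["B"])): bool(row["pval"] > alpha)
            for _, row in pairwise.iterrows()
        }
        means = {name: float(np.mean(vals)) for name, vals in groups.items()}
        order = sorted(groups, key=means.get)
        letter_map = compact_letter_display(list(groups), nd, order=order)
    return AnovaResult(
        F=F, df_num=df_num, df_den=df_den, p=p,
        letters=letter_map, pairwise=pairwise, alpha=alpha,
    )


@dataclass(frozen=True)
class EnvRegression:
    """OLS fit of a hydrotime parameter on an environmental variable."""

    slope: float
    intercept: float
    r2: float
    p: float
    n: int


def regress_env(x: Sequence[float], y: Sequence[float]) -> EnvRegression:
    """Ordinary least-squares regression of parameter ``y`` on variable ``x``.

    Needs ≥ 3 paired observations and a non-constant ``x``.  ``r2`` is the
    coefficient of determination of the fitted line (equal to the squared
    Pearson correlation for simple OLS).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need ≥ 3 populations with both values")
    if np.unique(x).size < 2:
        raise ValueError("x is constant; regression undefined")
    res = stats.linregress(x, y)
    return EnvRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue) ** 2,
        p=float(res.pvalue),
        n=int(x.size),
    )


@dataclass(frozen=True)
class PCAResult:
    """Correlation-matrix PCA: loadings, eigenvalues, variance shares, scores."""

    loadings: pd.DataFrame  # variables × components (unit eigenvectors)
    eigenvalues: np.ndarray  # descending; sums to the number of variables
    proportion: np.ndarray  # fraction of total variance per component
    scores: pd.DataFrame  # observations × components


def pca_env(matrix: pd.DataFrame) -> PCAResult:
    """PCA of standardized variables (i.e. on the correlation matrix).

    Requires ≥ 2 variables, ≥ 3 rows, no missing values and no constant
    columns.  Eigenvalues sum to the number of variables; ``proportion``
    sums to 1.
    """
    df = pd.DataFrame(matrix).astype(float)
    if df.shape[1] < 2 or df.shape[0] < 3:
        raise ValueError("need ≥ 2 variables and ≥ 3 rows for PCA")
    if df.isna().any().any():
        cells = [
            f"({idx}, {col})"
            for col in df.columns
            for idx in df.index[df[col].isna()]
        ]
        raise ValueError("missing values in cells: " + ", ".join(cells))
    sd = df.std(ddof=1)
    constant = list(sd.index[sd == 0])
    if constant:
        raise ValueError(f"constant variables cannot be standardized: {constant}")
    z = (df - df.mean()) / sd
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    idx = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[idx], 0.0, None)
    eigvecs = eigvecs[:, idx]
    comps = [f"PC{i+1}" for i in range(len(eigvals))]
    loadings = pd.DataFrame(eigvecs, index=df.columns, columns=comps)
    scores = pd.DataFrame(z.to_numpy() @ eigvecs, index=df.index, columns=comps)
    return PCAResult(
        loadings=loadings,
        eigenvalues=eigvals,
        proportion=eigvals / eigvals.sum(),
        scores=scores,
    )


@dataclass(frozen=True)
class ClusteringResult:
    """UPGMA dendrogram: scipy linkage matrix, leaf labels, Newick string."""

    linkage: np.ndarray
    labels: tuple[str, ...]
    newick: str

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def _to_newick(node, labels: Sequence[str], parent_height: float) -> str:
    length = parent_height - (0.0 if node.is_leaf() else node.dist)
    if node.is_leaf():
        return f"{labels[node.id]}:{length:.10g}"
    left = _to_newick(node.left, labels, node.dist)
    right = _to_newick(node.right, labels, node.dist)
    return f"({left},{right}):{length:.10g}"


def hcluster_average(
    matrix: pd.DataFrame,
    categorical: pd.DataFrame | None = None,
    standardize: bool = True,
) -> ClusteringResult:
    """Average-linkage (UPGMA) clustering on Euclidean distances.

    Numeric variables are z-standardized by default (``standardize=False``
    clusters on raw coordinates).  Optional categorical site descriptors
    (e.g. soil type, floristic physiognomic type) enter as unit-range
    one-hot indicator columns.  Branch lengths in the Newick output are
    height differences between merges, so root-to-leaf distance equals the
    leaf's last merge height (ultrametric).
    """
    df = pd.DataFrame(matrix).astype(float)
    if df.shape[0] < 2:
        raise ValueError("need ≥ 2 rows to cluster")
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate population labels: {dupes}")
    if standardize:
        sd = df.std(ddof=1)
        keep = sd > 0
        df = (df.loc[:, keep] - df.loc[:, keep].mean()) / sd[keep]
    if categorical is not None:
        cat = pd.DataFrame(categorical).reindex(df.index)
        onehot = pd.get_dummies(cat, dtype=float)
        df = pd.concat([df, onehot], axis=1)
    data = df.to_numpy()
    link = hierarchy.linkage(data, method="average", metric="euclidean")
    labels = tuple(str(v) for v in df.index)
    root = hierarchy.to_tree(link)
    newick = f"({_to_newick(root.left, labels, root.dist)},{_to_newick(root.right, labels, root.dist)});"
    return ClusteringResult(linkage=link, labels=labels, newick=newick)
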