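"""Clustering and PCA of condition fitness vectors.

Each condition is summarized as a vector over mutants (one entry per
single substitution).  Hierarchical clustering uses Euclidean distance
and Ward's method on absolute fitness vectors; PCA operates on
difference-fitness vectors (treatment minus control) with stop
substitutions excluded.  Both analyses take the complete-case matrix:
a mutant with a missing observation in any condition is removed
entirely before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from sklearn.decomposition import PCA

from .fitness import FitnessLandscape
from .landscape import DifferenceMap
from .variants import STOP, token_position

#: Conditions whose pairwise merge height is below this are reported in
#: the same flat cluster.
DEFAULT_CLUSTER_CUTOFF = 6.0


@dataclass
class ConditionMatrix:
    """Conditions (rows) x mutants (columns) fitness matrix."""

    values: pd.DataFrame
    complete_case: bool
    stops_excluded: bool

    @property
    def conditions(self) -> list[str]:
        return list(self.values.index)

    @property
    def mutants(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class LinkageTree:
    """Ward linkage over condition vectors.

    ``merges`` is the scipy linkage matrix: each row
    (cluster_a, cluster_b, height, size) records one agglomeration;
    heights are non-decreasing.
    """

    merges: np.ndarray
    labels: list[str]
    method: str = "ward"
    metric: str = "euclidean"


@dataclass
class PCAResult:
    """Principal components of a centered condition matrix.

    ``scores`` are condition coordinates, ``loadings`` the per-mutant
    component weights.  Component signs follow the convention that the
    largest-magnitude loading of each component is positive.
    """

    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame
    loadings: pd.DataFrame
    mean: pd.Series

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def build_condition_matrix(
    inputs: Mapping[str, FitnessLandscape | DifferenceMap] | Sequence,
    exclude_stops: bool = False,
    complete_case: bool = True,
) -> ConditionMatrix:
    """Assemble one row per condition over a shared mutant axis.

    Mutants with a missing observation in any condition are dropped
    when ``complete_case``; stop substitutions are dropped when
    ``exclude_stops``.
    """
    if not isinstance(inputs, Mapping):
        inputs = {
            getattr(x, "condition", None) or f"{x.treatment}-{x.control}": x
            for x in inputs
        }
    if len(inputs) < 2:
        raise ValueError("at least two conditions are required")
    rows = {name: obj.to_series() for name, obj in inputs.items()}
    mat = pd.DataFrame(rows).T
    mat.index.name = "condition"
    if exclude_stops:
        mat = mat.loc[:, [c for c in mat.columns if not c.endswith(STOP)]]
    if complete_case:
        mat = mat.dropna(axis=1, how="any")
        if mat.shape[1] < 2:
            raise ValueError("fewer than 2 complete-case mutants remain")
    return ConditionMatrix(
        values=mat, complete_case=complete_case, stops_excluded=exclude_stops
    )


def ward_cluster(matrix: ConditionMatrix) -> LinkageTree:
    """Agglomerative Ward linkage over Euclidean distances.

    At every step the pair of clusters whose merge least increases the
    total within-cluster variance is joined; ties break by lowest
    cluster index.
    """
    if matrix.values.isna().any().any():
        raise ValueError(
            "matrix contains missing values; build it with complete_case=True"
        )
    if matrix.values.shape[0] < 2:
        raise ValueError("at least two condition vectors are required")
    Z = sch.linkage(matrix.values.to_numpy(), method="ward")
    return LinkageTree(merges=Z, labels=matrix.conditions)


def flat_clusters(
    tree: LinkageTree, height_cutoff: float = DEFAULT_CLUSTER_CUTOFF
) -> pd.Series:
    """Cut the dendrogram: conditions joined below ``height_cutoff``
    share a cluster id."""
    assign = sch.fcluster(tree.merges, t=height_cutoff, criterion="distance")
    return pd.Series(assign, index=pd.Index(tree.labels, name="condition"), name="cluster")


def tree_to_newick(tree: LinkageTree) -> str:
    """Newick rendering with branch lengths derived from merge heights."""
    root = sch.to_tree(tree.merges)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{tree.labels[node.id]}:{length:g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return render(root, root.dist).rsplit(":", 1)[0] + ";"


def write_linkage(tree: LinkageTree, path: str | Path) -> None:
    """Merge table as TSV (cluster_a, cluster_b, height, size)."""
    df = pd.DataFrame(
        tree.merges, columns=["cluster_a", "cluster_b", "height", "size"]
    )
    df.to_csv(path, sep="\t", index=False)


def pca_difference(matrix: ConditionMatrix, n_components: int | None = None) -> PCAResult:
    """PCA of difference-fitness vectors (conditions as observations).

    The matrix is column-centered; no variance scaling or whitening is
    applied.  Signs are fixed so each component's largest-magnitude
    loading is positive.
    """
    if matrix.values.isna().any().any():
        raise ValueError(
            "matrix contains missing values; build it with complete_case=True"
        )
    X = matrix.values.to_numpy()
    if X.shape[0] < 2:
        raise ValueError("at least two condition vectors are required")
    pca = PCA(n_components=n_components, whiten=False, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # mutants x components
    # sign convention: largest-|loading| entry of each component positive
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    comp_names = [f"PC{k + 1}" for k in range(loadings.shape[1])]
    return PCAResult(
        explained_variance_ratio=pca.explained_variance_ratio_,
        scores=pd.DataFrame(scores, index=matrix.values.index, columns=comp_names),
        loadings=pd.DataFrame(
            loadings, index=matrix.values.columns, columns=comp_names
        ),
        mean=pd.Series(pca.mean_, index=matrix.values.columns),
    )


def loading_percent_of_max(result: PCAResult, component: int) -> pd.Series:
    """Loadings as a percentage of the component's maximum-magnitude
    loading: values in [-100, 100], rendered with a +-75 display clip."""
    name = f"PC{component}"
    if name not in result.loadings.columns:
        raise IndexError(f"component {component} out of range")
    col = result.loadings[name]
    peak = col.abs().max()
    if peak == 0:
        raise ValueError(f"all loadings of {name} are zero")
    return 100.0 * col / peak


def position_mean_loading(result: PCAResult, component: int) -> pd.Series:
    """Unweighted mean loading over the substitutions at each position."""
    name = f"PC{component}"
    if name not in result.loadings.columns:
        raise IndexError(f"component {component} out of range")
    col = result.loadings[name]
    positions = [token_position(tok) for tok in col.index]
    out = col.groupby(positions).mean()
    out.index.name = "position"
    return out


def write_pca(result: PCAResult, out_dir: str | Path, prefix: str = "pca") -> None:
    out_dir = Path(out_dir)
    result.scores.to_csv(out_dir / f"{prefix}_scores.tsv", sep="\t")
    result.loadings.rename_axis("mutant").to_csv(
        out_dir / f"{prefix}_loadings.tsv", sep="\t"
    )
    pd.Series(
        result.explained_variance_ratio,
        index=result.scores.columns,
        name="explained_variance_ratio",
    ).rename_axis("component").to_csv(
        out_dir / f"{prefix}_explained_variance.tsv", sep="\t"
    )
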