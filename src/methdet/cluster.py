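"""Unsupervised hierarchical clustering of samples on a gene panel.

Samples are clustered on median-centered panel values with euclidean
distance and centroid linkage. Missing entries are excluded pairwise: the
distance between two profiles (or centroids) is computed over their shared
observed genes and rescaled by sqrt(total/observed dimensions). Centroid
linkage is agglomerated directly from cluster centroids (recomputed as
missing-aware means of the member samples), which can produce height
inversions; these are permitted and counted, matching the method rather
than substituting a monotone linkage. The top split of the tree defines two
branches whose relapse/non-relapse composition is reported.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .preprocess import MethylationMatrix
from .synthetic import CONTROL, RELAPSE


@dataclass
class ClusterReport:
    linkage: np.ndarray  # (n-1) x 4, scipy convention
    samples: List[str]  # leaf order = lexicographic sample ids
    branch_assignment: pd.Series  # sample -> {"left", "right"}
    concordance: pd.DataFrame  # branch x label counts
    inversions: int
    centered: pd.DataFrame  # gene x sample median-centered values


def _pairwise_distance(a: np.ndarray, b: np.ndarray, p_total: int) -> float:
    mask = ~np.isnan(a) & ~np.isnan(b)
    m = int(mask.sum())
    if m == 0:
        return float("inf")
    d2 = float(((a[mask] - b[mask]) ** 2).sum())
    return np.sqrt(d2 * p_total / m)


def centroid_linkage(X: np.ndarray) -> Tuple[np.ndarray, int]:
    """Direct O(n^3) centroid-linkage agglomeration of the rows of X.

    NaN entries are ignored when computing centroids (missing-aware means)
    and distances (pairwise-complete, rescaled). Returns a scipy-style
    linkage matrix and the number of height inversions. Ties are broken by
    the smallest (i, j) cluster-id pair, making the result invariant to
    input permutations once rows are sorted by sample id.
    """
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    members = {i: [i] for i in range(n)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        centroids = {i: X[i].astype(float) for i in range(n)}
    active = list(range(n))
    Z = np.zeros((n - 1, 4))
    inversions = 0
    last_height = -np.inf
    cache: dict = {}

    def dist(i: int, j: int) -> float:
        key = (i, j) if i < j else (j, i)
        if key not in cache:
            cache[key] = _pairwise_distance(centroids[i], centroids[j], p)
        return cache[key]

    for step in range(n - 1):
        best = None
        act = sorted(active)
        for ai in range(len(act)):
            for aj in range(ai + 1, len(act)):
                i, j = act[ai], act[aj]
                d = dist(i, j)
                if best is None or d < best[0] - 1e-12:
                    best = (d, i, j)
        d, i, j = best
        if d < last_height - 1e-12:
            inversions += 1
        last_height = d
        new = n + step
        members[new] = members[i] + members[j]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            centroids[new] = np.nanmean(X[members[new]], axis=0)
        Z[step] = (i, j, d, len(members[new]))
        active.remove(i)
        active.remove(j)
        for key in [k for k in cache if i in k or j in k]:
            del cache[key]
        active.append(new)
    return Z, inversions


def _leaves(Z: np.ndarray, node: int, n: int) -> List[int]:
    if node < n:
        return [node]
    row = Z[node - n]
    return _leaves(Z, int(row[0]), n) + _leaves(Z, int(row[1]), n)


def cluster_and_concordance(
    matrix: MethylationMatrix,
    labels: pd.Series,
    panel: Sequence[str],
) -> ClusterReport:
    """Cluster samples on the panel genes and report branch-outcome counts.

    Values are median-centered per gene ("deviation from the median");
    all-missing samples are excluded with a warning. The "left" branch of
    the top split is the one containing the lexicographically smallest
    sample id.
    """
    if len(panel) == 0:
        raise ValueError("panel must be non-empty")
    missing = [g for g in panel if g not in matrix.values.index]
    if missing:
        raise KeyError(f"panel genes absent from matrix: {missing}")
    common = sorted(s for s in matrix.samples if s in labels.index)
    values = matrix.values.loc[list(panel), common]
    all_missing = values.isna().all(axis=0)
    if all_missing.any():
        dropped = values.columns[all_missing].tolist()
        warnings.warn(f"samples with no observed panel value excluded: {dropped}")
        values = values.loc[:, ~all_missing]
    if values.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    centered = values.sub(values.median(axis=1, skipna=True), axis=0)
    samples = list(centered.columns)
    X = centered.to_numpy().T  # samples x genes
    Z, inversions = centroid_linkage(X)

    n = len(samples)
    left_ids = _leaves(Z, int(Z[-1, 0]), n)
    right_ids = _leaves(Z, int(Z[-1, 1]), n)
    if min(left_ids) > min(right_ids):
        left_ids, right_ids = right_ids, left_ids
    assignment = pd.Series(index=pd.Index(samples, name="sample_id"), dtype=object)
    assignment.iloc[left_ids] = "left"
    assignment.iloc[right_ids] = "right"
    lbl = labels.loc[samples]
    concordance = (
        pd.crosstab(assignment, lbl)
        .reindex(index=["left", "right"], columns=[RELAPSE, CONTROL])
        .fillna(0)
        .astype(int)
    )
    concordance.index.name = "branch"
    return ClusterReport(
        linkage=Z,
        samples=samples,
        branch_assignment=assignment,
        concordance=concordance,
        inversions=inversions,
        centered=centered,
    )


def majority_purity(report: ClusterReport) -> float:
    """Fraction of samples on the majority branch of their outcome group,
    maximized over the two label-to-branch assignments (the published tree
    put 13/19 relapsing cases on one branch and 18/19 non-relapsing on the
    other, purity 31/38)."""
    c = report.concordance
    n = int(c.to_numpy().sum())
    a = c.loc["left", RELAPSE] + c.loc["right", CONTROL]
    b = c.loc["left", CONTROL] + c.loc["right", RELAPSE]
    return float(max(a, b) / n)


def to_newick(report: ClusterReport) -> str:
    """Newick export of the sample dendrogram (non-negative branch lengths;
    inversions are clamped to zero-length edges)."""
    Z = report.linkage
    n = len(report.samples)

    def height(node: int) -> float:
        return 0.0 if node < n else float(Z[node - n, 2])

    def render(node: int, parent_h: float) -> str:
        length = max(parent_h - height(node), 0.0)
        if node < n:
            return f"{report.samples[node]}:{length:.6g}"
        row = Z[node - n]
        left = render(int(row[0]), height(node))
        right = render(int(row[1]), height(node))
        return f"({left},{right}):{length:.6g}"

    root = 2 * n - 2
    row = Z[-1]
    h = float(row[2])
    return f"({render(int(row[0]), h)},{render(int(row[1]), h)});"
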