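"""Alpha diversity, weighted UniFrac beta diversity, jackknife rarefaction,
principal coordinate analysis, and the paired-design beta comparison.

Weighted UniFrac is computed from its definition over a rooted tree with
branch lengths: for each branch b, the compositions' mass descending
through b is compared, and

    raw(A, B)        = sum_b len(b) * |A_b - B_b|
    normalized(A, B) = raw / sum_j depth(j) * (A_j + B_j)

with depth(j) the root-to-leaf path length of leaf j; the normalized
variant is bounded in [0, 1]. Trees are handled as scikit-bio TreeNode
objects (newick I/O included).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode

from .tables import AbundanceTable, PairedDesign, TableError

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "read_tree",
    "shannon",
    "weighted_unifrac",
    "beta_distance_matrix",
    "jackknife_beta",
    "pcoa",
    "within_vs_between_beta_test",
    "alpha_compare",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample distances with a zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise TableError("distance matrix shape does not match sample ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise TableError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise TableError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise TableError("distances must be non-negative")

    def get(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def write(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", float_format="%.17g")


@dataclass
class OrdinationResult:
    """Classical-scaling embedding of a distance matrix.

    ``coordinates``: samples x k positions on the retained axes.
    ``eigenvalues``: full spectrum in descending order (negative values —
    non-Euclidean distortion — are reported but excluded from coordinates).
    ``proportion_explained``: per retained axis, relative to the positive
    part of the spectrum.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def read_tree(path: str | Path) -> TreeNode:
    """Read a rooted newick tree with branch lengths."""
    return TreeNode.read(str(path), format="newick")


# -- alpha ---------------------------------------------------------------------


def shannon(abundance, base: float = 2.0) -> float:
    """Shannon diversity H = -sum p_i log_base p_i of one specimen.

    The vector is renormalized to proportions first; zero entries
    contribute nothing. Base 2 (bits) by default.
    """
    x = np.asarray(abundance, dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("cannot compute diversity of an all-zero specimen")
    p = x[x > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


# -- weighted UniFrac ----------------------------------------------------------


def _tree_arrays(
    tree: TreeNode, taxon_ids: list[str]
) -> tuple[list, np.ndarray, np.ndarray, dict[str, int]]:
    """Postorder traversal scaffolding shared by all UniFrac calls.

    Returns (postorder nodes excluding root, branch lengths, leaf depths
    aligned to taxon_ids, taxon -> leaf position map).
    """
    leaves = {leaf.name: leaf for leaf in tree.tips()}
    missing = [t for t in taxon_ids if t not in leaves]
    if missing:
        raise TableError(f"taxa absent from the tree: {missing}")
    pos = {t: i for i, t in enumerate(taxon_ids)}
    nodes = [nd for nd in tree.postorder(include_self=False)]
    lengths = np.array([nd.length if nd.length is not None else 0.0 for nd in nodes])
    if np.any(lengths < 0) or not np.all(np.isfinite(lengths)):
        raise TableError("branch lengths must be finite and non-negative")
    # root-to-leaf depth per taxon
    depths = np.zeros(len(taxon_ids))
    for t in taxon_ids:
        nd, d = leaves[t], 0.0
        while nd.parent is not None:
            d += nd.length if nd.length is not None else 0.0
            nd = nd.parent
        depths[pos[t]] = d
    return nodes, lengths, depths, pos


def _branch_mass(
    nodes: list, pos: dict[str, int], P: np.ndarray
) -> np.ndarray:
    """Mass descending through each branch for every sample column of P.

    P: (n_taxa, n_samples) proportions aligned with ``pos``. Returns
    (n_branches, n_samples).
    """
    acc: dict[int, np.ndarray] = {}
    out = np.zeros((len(nodes), P.shape[1]))
    for i, nd in enumerate(nodes):
        if nd.is_tip():
            mass = P[pos[nd.name]] if nd.name in pos else np.zeros(P.shape[1])
        else:
            mass = np.zeros(P.shape[1])
            for child in nd.children:
                mass = mass + acc[id(child)]
        acc[id(nd)] = mass
        out[i] = mass
    return out


def weighted_unifrac(
    sample_a,
    sample_b,
    tree: TreeNode,
    taxon_ids: list[str],
    normalized: bool = True,
) -> float:
    """Weighted UniFrac between two proportion vectors over the tree's leaves."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    nodes, lengths, depths, pos = _tree_arrays(tree, taxon_ids)
    mass = _branch_mass(nodes, pos, np.column_stack([a, b]))
    raw = float((lengths * np.abs(mass[:, 0] - mass[:, 1])).sum())
    if not normalized:
        return raw
    denom = float((depths * (a + b)).sum())
    if denom == 0:
        return 0.0
    return raw / denom


def beta_distance_matrix(
    table: AbundanceTable, tree: TreeNode, normalized: bool = True
) -> DistanceMatrix:
    """All pairwise weighted UniFrac distances between a table's specimens."""
    if table.mode != "proportions":
        raise TableError("beta diversity expects a proportions table")
    nodes, lengths, depths, pos = _tree_arrays(tree, table.taxon_ids)
    mass = _branch_mass(nodes, pos, table.values)  # (branches, samples)
    S = len(table.sample_ids)
    D = np.zeros((S, S))
    leaf_depth_mass = depths @ table.values  # (samples,)
    for i in range(S):
        diffs = np.abs(mass[:, i][:, None] - mass[:, i + 1 :])
        raw = lengths @ diffs
        if normalized:
            denom = leaf_depth_mass[i] + leaf_depth_mass[i + 1 :]
            with np.errstate(invalid="ignore", divide="ignore"):
                row = np.where(denom > 0, raw / denom, 0.0)
        else:
            row = raw
        D[i, i + 1 :] = row
        D[i + 1 :, i] = row
    return DistanceMatrix(list(table.sample_ids), D)


# -- jackknife rarefaction -----------------------------------------------------


def jackknife_beta(
    counts: AbundanceTable,
    tree: TreeNode,
    fraction: float = 0.01,
    reps: int = 10,
    seed: int | None = None,
    normalized: bool = True,
) -> tuple[DistanceMatrix, list[DistanceMatrix]]:
    """Jackknife-rarefied beta diversity.

    Each rep subsamples every specimen without replacement down to
    floor(fraction * specimen total) reads, renormalizes, and recomputes
    the weighted UniFrac matrix; the reported matrix is the element-wise
    mean over reps. fraction=1.0 degenerates to the full-data matrix.
    """
    if counts.mode != "counts":
        raise TableError("jackknife_beta expects a counts table")
    if not (0 < fraction <= 1):
        raise TableError("fraction must be in (0, 1]")
    c = counts.values
    if not np.allclose(c, np.round(c)):
        raise TableError("jackknife_beta needs integer read counts")
    c = np.round(c).astype(np.int64)
    totals = c.sum(axis=0)
    depths = np.floor(fraction * totals).astype(np.int64)
    empty = np.flatnonzero(depths == 0)
    if empty.size:
        raise TableError(
            f"subsample size 0 for sample {counts.sample_ids[empty[0]]!r}; "
            "increase fraction"
        )
    rng = np.random.default_rng(seed)
    per_rep: list[DistanceMatrix] = []
    for _ in range(reps):
        sub = np.empty_like(c)
        for j in range(c.shape[1]):
            sub[:, j] = rng.multivariate_hypergeometric(c[:, j], depths[j])
        prop = AbundanceTable(
            counts.taxon_ids,
            counts.sample_ids,
            sub / sub.sum(axis=0),
            mode="proportions",
        )
        per_rep.append(beta_distance_matrix(prop, tree, normalized=normalized))
    # mean via deviations from the first rep: exact when all reps coincide
    # (the fraction=1.0 degenerate case) and numerically tighter in general
    base = per_rep[0].values
    dev = np.mean([dm.values - base for dm in per_rep], axis=0)
    mean = DistanceMatrix(list(counts.sample_ids), base + dev)
    return mean, per_rep


# -- ordination ----------------------------------------------------------------


def pcoa(D: DistanceMatrix, k: int = 3) -> OrdinationResult:
    """Principal coordinate analysis (classical / Gower scaling).

    Double-centers -0.5 * D^2, eigendecomposes, and scales eigenvectors by
    the square roots of positive eigenvalues. Negative eigenvalues are
    reported in the spectrum but excluded from the embedding (no
    Cailliez/Lingoes correction).
    """
    S = len(D.sample_ids)
    if not (0 < k < S):
        raise ValueError(f"k must be in [1, {S - 1}]")
    d2 = D.values**2
    J = np.eye(S) - np.ones((S, S)) / S
    B = -0.5 * J @ d2 @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(1e-12 * max(abs(vals[0]), 1.0), 0.0)
    n_keep = min(k, int(pos.sum()))
    coords = vecs[:, :n_keep] * np.sqrt(vals[:n_keep])
    pos_sum = vals[pos].sum()
    prop = vals[:n_keep] / pos_sum if pos_sum > 0 else np.zeros(n_keep)
    frame = pd.DataFrame(
        coords if n_keep else np.zeros((S, 0)),
        index=D.sample_ids,
        columns=[f"PC{i + 1}" for i in range(n_keep)],
    )
    if n_keep < k:  # degenerate spectra still honour the requested width
        for i in range(n_keep, k):
            frame[f"PC{i + 1}"] = 0.0
        prop = np.concatenate([prop, np.zeros(k - n_keep)])
    return OrdinationResult(
        coordinates=frame, eigenvalues=vals, proportion_explained=prop
    )


# -- paired-design comparisons -------------------------------------------------


def within_vs_between_beta_test(
    D: DistanceMatrix, design: PairedDesign
) -> tuple[np.ndarray, np.ndarray, float]:
    """Are same-subject pre/post specimens closer than unrelated specimens?

    within  = n same-subject pre-vs-post distances;
    between = all n(n-1)/2 pre-vs-pre distances across distinct subjects.
    One-sided Wilcoxon rank-sum of within < between.
    """
    subs = design.subjects
    within = np.array(
        [D.get(design.pre_sample[s], design.post_sample[s]) for s in subs]
    )
    between = np.array(
        [
            D.get(design.pre_sample[subs[i]], design.pre_sample[subs[j]])
            for i in range(len(subs))
            for j in range(i + 1, len(subs))
        ]
    )
    res = stats.mannwhitneyu(within, between, alternative="less", method="auto")
    return within, between, float(res.pvalue)


def alpha_compare(pre_alphas, post_alphas) -> float:
    """Two-sided Wilcoxon signed-rank p for paired alpha diversities.

    All-zero differences (identical vectors) return p = 1 by convention.
    """
    pre = np.asarray(pre_alphas, dtype=float)
    post = np.asarray(post_alphas, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1 or pre.size < 2:
        raise ValueError("need paired 1-D vectors with n >= 2")
    diffs = post - pre
    if np.all(diffs == 0):
        return 1.0
    res = stats.wilcoxon(post, pre, alternative="two-sided", method="auto")
    return float(res.pvalue)
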