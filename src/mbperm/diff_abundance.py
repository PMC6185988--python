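"""Permutation-based differential abundance for paired pre/post designs.

The test statistic for each taxon is a two-group t-like quantity

    t = (mean(post) - mean(pre)) / sqrt((var(post) + var(pre)) / n)

with n the number of subjects and var the unbiased (ddof-1) sample
variance. Significance is assessed without distributional assumptions:

* **Label permutation** — the pre/post status of all 2n specimens is
  randomly reassigned (group sizes held at n), the statistic recomputed,
  and the empirical p-value taken as the fraction of permuted statistics
  at least as extreme as the observed one in the observed direction:
  P(t_perm >= t_obs) when t_obs > 0, else P(t_perm <= t_obs). This
  sign-selected one-sided rule doubles the nominal level under a
  symmetric null (p <= alpha occurs at rate ~2*alpha).
* **Paired sign-flip** — each subject's pre and post values are swapped
  or not, giving 2^n arrangements which are enumerated exhaustively for
  moderate n (the identity arrangement always counts, so exhaustive
  p >= 2^-n); Monte-Carlo flips are used beyond ``exhaustive_threshold``.

Effect size is the log2 fold change of mean relative abundances,
log2(mean(post)/mean(pre)), with +/-inf when one group mean is zero
(taxa absent from one condition entirely).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .tables import AbundanceTable, PairedDesign, validate_paired_design

__all__ = [
    "DiffAbundanceResult",
    "t_statistic",
    "log2_fold_change",
    "permutation_test_labels",
    "paired_permutation_test",
    "compute_diff_abundance",
    "rank_and_report",
    "format_report",
]

PairedRule = Literal["signed_one_sided", "two_sided_abs"]


# -- the statistic -------------------------------------------------------------


def _t_rows(pre: np.ndarray, post: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Row-wise t over (..., n) arrays of paired group values.

    Degenerate convention: both variances zero and equal means -> 0;
    zero variances with a mean gap -> signed infinity. NaN never escapes.
    """
    n = pre.shape[-1]
    diff = post.mean(axis=-1) - pre.mean(axis=-1)
    v = (post.var(axis=-1, ddof=ddof) + pre.var(axis=-1, ddof=ddof)) / n
    denom = np.sqrt(np.maximum(v, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    zero_denom = denom == 0
    if np.any(zero_denom):
        t = np.where(zero_denom & (diff == 0), 0.0, t)
        t = np.where(zero_denom & (diff > 0), np.inf, t)
        t = np.where(zero_denom & (diff < 0), -np.inf, t)
    return t


def t_statistic(pre, post, ddof: int = 1) -> float:
    """t for one taxon from its n pre and n post abundances."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1-D vectors of equal length")
    if pre.size < 2:
        raise ValueError("need at least 2 subjects")
    return float(_t_rows(pre, post, ddof=ddof))


def log2_fold_change(pre_mean: float, post_mean: float) -> float:
    """log2(post_mean / pre_mean); +/-inf when exactly one mean is zero."""
    if pre_mean < 0 or post_mean < 0:
        raise ValueError("means must be non-negative")
    if pre_mean == 0 and post_mean == 0:
        raise ValueError("fold change undefined when both means are zero")
    if pre_mean == 0:
        return float("inf")
    if post_mean == 0:
        return float("-inf")
    return float(np.log2(post_mean / pre_mean))


# -- empirical p machinery -----------------------------------------------------


def _empirical_p(
    t_obs: np.ndarray,
    t_perm: np.ndarray,
    rule: PairedRule = "signed_one_sided",
    add_one: bool = False,
) -> np.ndarray:
    """Sign-selected (or two-sided) empirical p from a permuted-t matrix.

    t_obs: (T,), t_perm: (M, T). Comparisons use extended-real ordering,
    so +inf >= +inf counts and finite values never reach +inf. Permuted
    statistics within a small relative tolerance of the observed one count
    as ties: different vectorization paths can leave last-ulp differences
    between arithmetically identical relabellings.
    """
    t_obs = np.atleast_1d(np.asarray(t_obs, dtype=float))
    gamma = np.where(np.isfinite(t_obs), 1e-7 * (1.0 + np.abs(t_obs)), 0.0)
    if rule == "signed_one_sided":
        upper = (t_perm >= t_obs - gamma).sum(axis=0)
        lower = (t_perm <= t_obs + gamma).sum(axis=0)
        r = np.where(t_obs > 0, upper, lower)
    elif rule == "two_sided_abs":
        r = (np.abs(t_perm) >= np.abs(t_obs) - gamma).sum(axis=0)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    m = t_perm.shape[0]
    if add_one:
        return (r + 1) / (m + 1)
    return r / m


def _paired_matrices(
    table: AbundanceTable, design: PairedDesign
) -> tuple[np.ndarray, np.ndarray]:
    validate_paired_design(table, design)
    pre = table.select_samples(design.pre_ids())
    post = table.select_samples(design.post_ids())
    return pre, post


def permutation_test_labels(
    table: AbundanceTable,
    design: PairedDesign,
    B: int = 100_000,
    seed: int | None = None,
    *,
    exhaustive: bool = False,
    ddof: int = 1,
    add_one: bool = False,
) -> pd.Series:
    """Unpaired label-permutation empirical p per taxon.

    All 2n specimens are pooled; each permutation relabels n of them as
    "post" and n as "pre" (uniformly, with replacement across the B draws).
    With ``exhaustive=True`` all C(2n, n) label assignments are enumerated
    instead — the exact reference used to validate the Monte-Carlo path.
    """
    pre, post = _paired_matrices(table, design)
    n = design.n
    X = np.concatenate([pre, post], axis=1)  # (T, 2n)
    # t_obs must go through the exact same arithmetic as the permuted t's:
    # otherwise a permutation that reproduces the observed labeling can
    # differ in the last ulp and slip out of the >= / <= counts
    identity = np.zeros((1, 2 * n), dtype=bool)
    identity[0, n:] = True
    t_obs = _t_for_masks(X, identity, n, ddof=ddof)[0]

    if exhaustive:
        assign = np.array(
            [list(c) for c in combinations(range(2 * n), n)], dtype=np.intp
        )  # rows: indices labelled "post"
        masks = np.zeros((assign.shape[0], 2 * n), dtype=bool)
        np.put_along_axis(masks, assign, True, axis=1)
    else:
        if B < 1:
            raise ValueError("B must be >= 1")
        rng = np.random.default_rng(seed)
        order = np.argsort(rng.random((B, 2 * n)), axis=1)
        masks = np.zeros((B, 2 * n), dtype=bool)
        np.put_along_axis(masks, order[:, :n], True, axis=1)

    t_perm = _t_for_masks(X, masks, n, ddof=ddof)
    p = _empirical_p(t_obs, t_perm, "signed_one_sided", add_one=add_one)
    return pd.Series(p, index=table.taxon_ids, name="p_unpaired")


def _t_for_masks(
    X: np.ndarray, masks: np.ndarray, n: int, ddof: int = 1, chunk: int = 4096
) -> np.ndarray:
    """t for each relabelling mask (True = labelled post) over all taxa.

    X: (T, 2n); masks: (M, 2n) boolean with n True each; returns (M, T).
    Chunked so B=100,000 permutations stay within a modest memory budget.
    """
    m_total = masks.shape[0]
    T = X.shape[0]
    # t is invariant under a per-taxon location shift; centering keeps the
    # sums-of-squares variance identity numerically stable (a constant taxon
    # yields exactly zero residuals, hence exactly t = 0 in every permutation)
    X = X - X.mean(axis=1, keepdims=True)
    out = np.empty((m_total, T))
    for start in range(0, m_total, chunk):
        mk = masks[start : start + chunk].astype(float)  # (m, 2n)
        # sums over the two label groups for every taxon and permutation
        s_post = mk @ X.T  # (m, T)
        s_all = X.sum(axis=1)  # (T,)
        s_pre = s_all - s_post
        q_post = mk @ (X.T**2)
        q_all = (X**2).sum(axis=1)
        q_pre = q_all - q_post
        mean_post, mean_pre = s_post / n, s_pre / n
        dd = n - ddof
        var_post = np.maximum(q_post - n * mean_post**2, 0.0) / dd
        var_pre = np.maximum(q_pre - n * mean_pre**2, 0.0) / dd
        diff = mean_post - mean_pre
        denom = np.sqrt((var_post + var_pre) / n)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / denom
        zero = denom == 0
        if np.any(zero):
            t = np.where(zero & (diff == 0), 0.0, t)
            t = np.where(zero & (diff > 0), np.inf, t)
            t = np.where(zero & (diff < 0), -np.inf, t)
        out[start : start + chunk] = t
    return out


def paired_permutation_test(
    table: AbundanceTable,
    design: PairedDesign,
    exhaustive_threshold: int = 20,
    B: int = 10_000,
    seed: int | None = None,
    *,
    rule: PairedRule = "signed_one_sided",
    ddof: int = 1,
    add_one: bool = False,
) -> tuple[pd.Series, int, bool]:
    """Paired sign-flip empirical p per taxon.

    For n <= ``exhaustive_threshold`` all 2^n within-subject pre/post swaps
    (including the identity) are enumerated, making p an exact multiple of
    2^-n with p >= 2^-n. Larger n falls back to B random flips.

    Returns (p series, number of arrangements used, exhaustive flag).
    """
    pre, post = _paired_matrices(table, design)
    n = design.n
    t_obs = _t_rows(pre, post, ddof=ddof)

    if n <= exhaustive_threshold:
        m = 1 << n
        bits = (np.arange(m)[:, None] >> np.arange(n)[None, :]) & 1
        flips = bits.astype(bool)  # (2^n, n): True = swap that subject
        exhaustive = True
    else:
        if B < 1:
            raise ValueError("B must be >= 1")
        rng = np.random.default_rng(seed)
        flips = rng.random((B, n)) < 0.5
        m = B
        exhaustive = False

    # swap pre/post per subject per arrangement: (M, T, n)
    f = flips[:, None, :]
    preP = np.where(f, post[None, :, :], pre[None, :, :])
    postP = np.where(f, pre[None, :, :], post[None, :, :])
    t_perm = _t_rows(preP, postP, ddof=ddof)  # (M, T)
    if exhaustive:
        t_obs = t_perm[0]  # identity arrangement: identical arithmetic path

    p = _empirical_p(t_obs, t_perm, rule, add_one=add_one)
    return pd.Series(p, index=table.taxon_ids, name="p_paired"), m, exhaustive


# -- assembled per-taxon results ----------------------------------------------


@dataclass
class DiffAbundanceResult:
    """Per-taxon differential abundance summary.

    ``frame`` columns: t_obs, log2fc, p_unpaired, p_paired; plus the
    permutation bookkeeping shared by all taxa.
    """

    frame: pd.DataFrame
    n_subjects: int
    n_permutations_unpaired: int
    n_permutations_paired: int
    exhaustive_paired: bool
    paired_rule: PairedRule = "signed_one_sided"


def compute_diff_abundance(
    table: AbundanceTable,
    design: PairedDesign,
    B: int = 100_000,
    seed: int | None = None,
    *,
    exhaustive_threshold: int = 20,
    B_paired: int | None = None,
    paired_rule: PairedRule = "signed_one_sided",
    ddof: int = 1,
    add_one: bool = False,
) -> DiffAbundanceResult:
    """Run both permutation tests and the fold change for every taxon.

    The table must be proportions; taxa absent everywhere must already be
    dropped (their statistics are undefined).
    """
    if table.mode != "proportions":
        raise ValueError("differential abundance expects a proportions table")
    if np.any(table.values.sum(axis=1) == 0):
        raise ValueError("drop all-zero taxa before testing (drop_absent_taxa)")
    pre, post = _paired_matrices(table, design)
    t_obs = _t_rows(pre, post, ddof=ddof)
    pre_mean, post_mean = pre.mean(axis=1), post.mean(axis=1)
    lfc = np.array(
        [log2_fold_change(a, b) for a, b in zip(pre_mean, post_mean)]
    )
    p_unpaired = permutation_test_labels(
        table, design, B=B, seed=seed, ddof=ddof, add_one=add_one
    )
    p_paired, m_paired, exhaustive = paired_permutation_test(
        table,
        design,
        exhaustive_threshold=exhaustive_threshold,
        B=B_paired if B_paired is not None else B,
        seed=None if seed is None else seed + 1,
        rule=paired_rule,
        ddof=ddof,
        add_one=add_one,
    )
    frame = pd.DataFrame(
        {
            "t_obs": t_obs,
            "log2fc": lfc,
            "pre_mean": pre_mean,
            "post_mean": post_mean,
            "p_unpaired": p_unpaired.to_numpy(),
            "p_paired": p_paired.to_numpy(),
        },
        index=pd.Index(table.taxon_ids, name="taxon"),
    )
    return DiffAbundanceResult(
        frame=frame,
        n_subjects=design.n,
        n_permutations_unpaired=B,
        n_permutations_paired=m_paired,
        exhaustive_paired=exhaustive,
        paired_rule=paired_rule,
    )


def rank_and_report(result: DiffAbundanceResult) -> pd.DataFrame:
    """Sort taxa for reporting: ascending empirical p from the label
    permutation, ties broken by |log2 fold change| descending, then name."""
    df = result.frame.copy()
    df["_abs_lfc"] = np.abs(df["log2fc"])
    df = df.sort_values(
        by=["p_unpaired", "_abs_lfc", "taxon"],
        ascending=[True, False, True],
        key=lambda s: s if s.name != "taxon" else s.str.lower(),
    )
    df = df.drop(columns="_abs_lfc")
    df["n_permutations"] = result.n_permutations_unpaired
    df["exhaustive_paired"] = result.exhaustive_paired
    return df


def format_report(report: pd.DataFrame) -> pd.DataFrame:
    """Human-facing rendering: infinite fold changes printed literally as
    "Inf"/"-Inf", numbers rounded to report precision."""
    out = report.reset_index()[["taxon", "log2fc", "p_unpaired", "p_paired"]].copy()
    out["log2fc"] = [
        "Inf" if v == np.inf else "-Inf" if v == -np.inf else f"{v:.2f}"
        for v in out["log2fc"]
    ]
    out["p_unpaired"] = out["p_unpaired"].map(lambda p: f"{p:.3g}")
    out["p_paired"] = out["p_paired"].map(lambda p: f"{p:.3g}")
    return out


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t")
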