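"""Host-factor association battery for per-subject abundance changes.

For a chosen taxon, the per-subject change in relative abundance
(post - pre) is screened against host covariates:

* numeric covariates (PrEP duration, age, TFV-DP) — Spearman rank
  correlation with a two-sided p;
* multi-level categoricals (race) — Kruskal-Wallis;
* binary covariates (any drug use, drug abuse, rectal douching) —
  Wilcoxon rank-sum.

Missing covariate values (an explicit level, e.g. "declined to answer")
are excluded pairwise from each test, and the n actually used is
reported. With the tiny cohorts these studies have, p-values default to
exact/permutation enumeration rather than asymptotic approximations.
"""

from __future__ import annotations

from itertools import combinations, permutations
from math import comb, factorial

import numpy as np
import pandas as pd
from scipy import stats

from .tables import AbundanceTable, HostCovariates, PairedDesign, validate_paired_design

__all__ = ["abundance_change_per_subject", "association_battery"]

NUMERIC = ["prep_duration_weeks", "age", "tfv_dp"]
CATEGORICAL = ["race"]
BINARY = ["any_drug_use", "drug_abuse", "rectal_douching"]

#: at most this many subjects -> enumerate the exact permutation null
EXACT_N_MAX = 10


def abundance_change_per_subject(
    table: AbundanceTable, design: PairedDesign, taxon: str
) -> pd.Series:
    """Per-subject post-minus-pre proportion change for one taxon."""
    if table.mode != "proportions":
        raise ValueError("abundance changes are defined on proportions")
    validate_paired_design(table, design)
    row = table.values[table.taxon_index(taxon)]
    idx = {s: i for i, s in enumerate(table.sample_ids)}
    deltas = {
        subj: row[idx[design.post_sample[subj]]] - row[idx[design.pre_sample[subj]]]
        for subj in design.subjects
    }
    return pd.Series(deltas, name=taxon)


def _spearman(x: np.ndarray, y: np.ndarray, exact: bool, rng) -> tuple[float, float]:
    """Spearman rho with an exact pairing-enumeration p for small n.

    Midranks handle ties; the exact null enumerates all n! pairings of the
    two rank vectors (vectorized), two-sided on |rho|.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    cx, cy = rx - rx.mean(), ry - ry.mean()
    denom = np.sqrt((cx**2).sum() * (cy**2).sum())
    if denom == 0:  # a constant covariate carries no ordering information
        return float("nan"), float("nan")
    rho = float(cx @ cy / denom)
    n = len(x)
    if not exact or n > EXACT_N_MAX:
        return rho, float(stats.spearmanr(x, y).pvalue)
    perms = np.array(list(permutations(range(n))))
    rho_all = (cy[perms] @ cx) / denom
    p = float(np.mean(np.abs(rho_all) >= abs(rho) - 1e-12))
    return rho, p


def _n_independent_perms(sizes: list[int]) -> float:
    total = sum(sizes)
    c = factorial(total)
    for s in sizes:
        c //= factorial(s)
    return c


def _kruskal_h(ranks: np.ndarray, sizes: list[int], tie_denom: float) -> float:
    """Tie-corrected Kruskal-Wallis H from pooled midranks split by sizes."""
    n = len(ranks)
    h, start = 0.0, 0
    for size in sizes:
        s = ranks[start : start + size].sum()
        h += s * s / size
        start += size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    return h / tie_denom


def _kruskal(groups: list[np.ndarray], exact: bool, rng) -> tuple[float, float]:
    """Kruskal-Wallis across levels; exact enumeration of all distinct
    label assignments for small cohorts (singleton levels allowed)."""
    stat = float(stats.kruskal(*groups).statistic)
    sizes = [len(g) for g in groups]
    total = sum(sizes)
    n_exact = _n_independent_perms(sizes)
    if not exact or total > EXACT_N_MAX or n_exact > 20_000:
        return stat, float(stats.kruskal(*groups).pvalue)
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_denom = 1.0 - ((counts**3 - counts).sum() / (total**3 - total) or 0.0)
    if tie_denom == 0:  # all values identical: no ordering information
        return stat, 1.0
    h_obs = _kruskal_h(ranks, sizes, tie_denom)

    def assignments(indices: tuple[int, ...], sizes_left: list[int]):
        if len(sizes_left) == 1:
            yield indices
            return
        k = sizes_left[0]
        pool = set(indices)
        for chosen in combinations(sorted(pool), k):
            rest = tuple(sorted(pool - set(chosen)))
            for tail in assignments(rest, sizes_left[1:]):
                yield chosen + tail

    count = hits = 0
    for order in assignments(tuple(range(total)), sizes):
        h = _kruskal_h(ranks[list(order)], sizes, tie_denom)
        hits += h >= h_obs - 1e-12
        count += 1
    return stat, hits / count


def _ranksum(a: np.ndarray, b: np.ndarray, exact: bool, rng) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum; exact tail of |U - mu| for small n."""
    u = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
    if not exact or len(a) + len(b) > EXACT_N_MAX:
        p = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue
        return float(u), float(p)
    mu = len(a) * len(b) / 2
    res = stats.permutation_test(
        (a, b),
        lambda x, y, axis=-1: np.abs(
            stats.mannwhitneyu(x, y, alternative="two-sided", axis=axis).statistic - mu
        ),
        permutation_type="independent",
        alternative="greater",
        vectorized=True,
        n_resamples=int(comb(len(a) + len(b), len(a))) + 1,
        rng=rng,
    )
    return float(u), float(res.pvalue)


def association_battery(
    delta: pd.Series,
    covariates: HostCovariates,
    exact: bool = True,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run the full covariate screen against one taxon's deltas.

    Returns one row per covariate: test name, statistic, p, n_used, and a
    ``testable`` flag (False with fewer than 3 usable subjects — the row
    is kept, never silently dropped).
    """
    rng = np.random.default_rng(seed)
    rows = []
    subjects = delta.index

    def row(covariate, test, stat, p, n_used, testable=True, note=""):
        rows.append(
            {
                "covariate": covariate,
                "test": test,
                "statistic": stat,
                "p": p,
                "n_used": n_used,
                "testable": testable,
                "note": note,
            }
        )

    for cov in NUMERIC:
        x = covariates.numeric(cov).reindex(subjects)
        mask = x.notna() & delta.notna()
        n_used = int(mask.sum())
        if n_used < 3:
            row(cov, "spearman", np.nan, np.nan, n_used, False, "fewer than 3 subjects")
            continue
        rho, p = _spearman(
            x[mask].to_numpy(float), delta[mask].to_numpy(float), exact, rng
        )
        row(cov, "spearman", rho, p, n_used)

    for cov in CATEGORICAL:
        levels = covariates.categorical(cov).reindex(subjects)
        mask = levels.notna() & delta.notna()
        n_used = int(mask.sum())
        groups = [
            delta[mask][levels[mask] == lv].to_numpy(float)
            for lv in pd.unique(levels[mask].dropna())
        ]
        if n_used < 3 or len(groups) < 2:
            row(cov, "kruskal-wallis", np.nan, np.nan, n_used, False,
                "fewer than 3 subjects or a single level")
            continue
        stat, p = _kruskal(groups, exact, rng)
        row(cov, "kruskal-wallis", stat, p, n_used)

    for cov in BINARY:
        levels = covariates.categorical(cov).reindex(subjects)
        mask = levels.notna() & delta.notna()
        n_used = int(mask.sum())
        vals = levels[mask]
        a = delta[mask][vals == "yes"].to_numpy(float)
        b = delta[mask][vals == "no"].to_numpy(float)
        if n_used < 3 or len(a) == 0 or len(b) == 0:
            row(cov, "rank-sum", np.nan, np.nan, n_used, False,
                "fewer than 3 subjects or an empty group")
            continue
        stat, p = _ranksum(a, b, exact, rng)
        row(cov, "rank-sum", stat, p, n_used)

    return pd.DataFrame(rows)
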