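"""Synthetic paired pre/post compositional studies with known ground truth.

The generator emulates the statistical structure of a small paired
rectal-swab 16S study: per-subject baseline compositions drawn from a
skewed Dirichlet (one dominant family around 35% plus a long tail),
log-normal subject-level jitter shared by a subject's pre and post
specimens (the source of within-pair similarity), multiplicative spikes
of chosen log2 fold change applied to the post composition followed by
renormalization (compositional closure intentionally included), and
multinomial read sampling at a fixed sequencing depth.

Defaults describe the emulated study: 8 subjects, 30 taxa, 50,000 reads
per specimen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import (
    MISSING,
    AbundanceTable,
    HostCovariates,
    PairedDesign,
    TaxonomyMap,
    write_abundance_table,
    write_metadata,
    write_taxonomy,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "default_concentration",
    "generate_paired_counts",
    "generate_tree",
    "generate_covariates",
    "generate_taxonomy",
    "write_fixture_bundle",
]


def default_concentration(n_taxa: int, total: float = 25.0) -> np.ndarray:
    """Skewed baseline Dirichlet parameters: one dominant taxon at ~35% of
    the community, the rest following a power-law rank-abundance tail
    (share of rank k proportional to 1/k), as in skewed gut profiles.
    ``total`` sets the concentration mass and hence between-subject
    variability."""
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    tail = 1.0 / np.arange(1, n_taxa)
    p = np.concatenate([[0.35], 0.65 * tail / tail.sum()])
    return total * p


@dataclass
class SimulationConfig:
    """Knobs of the paired-study generator.

    spikes: list of (taxon index, true log2 fold change) applied to the
    post composition. subject_effect_sd: SD of the shared log-abundance
    jitter per subject (0 disables it). depth: multinomial reads per
    specimen.
    """

    n_subjects: int = 8
    n_taxa: int = 30
    concentration: np.ndarray | None = None
    spikes: tuple[tuple[int, float], ...] = ()
    subject_effect_sd: float = 0.6
    depth: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.subject_effect_sd < 0:
            raise ValueError("subject_effect_sd must be >= 0")
        if self.concentration is None:
            self.concentration = default_concentration(self.n_taxa)
        else:
            self.concentration = np.asarray(self.concentration, dtype=float)
            if self.concentration.shape != (self.n_taxa,):
                raise ValueError("concentration must have length n_taxa")
            if np.any(self.concentration <= 0):
                raise ValueError("concentration entries must be positive")
        idx = [i for i, _ in self.spikes]
        if len(set(idx)) != len(idx):
            raise ValueError("spiked taxon indices must be distinct")
        if any(i < 0 or i >= self.n_taxa for i in idx):
            raise ValueError("spiked taxon index out of range")

    def spike_vector(self) -> np.ndarray:
        v = np.zeros(self.n_taxa)
        for i, delta in self.spikes:
            v[i] = delta
        return v


@dataclass
class SimulationTruth:
    """Ground truth of one simulated study: per-taxon spiked log2 fold
    change (0 for null taxa) and the realized expected pre/post mean
    proportions (means over subjects of the noise-free compositions)."""

    taxon_ids: list[str]
    true_log2fc: np.ndarray
    expected_pre_mean: np.ndarray
    expected_post_mean: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "true_log2fc": self.true_log2fc,
                "expected_pre_mean": self.expected_pre_mean,
                "expected_post_mean": self.expected_post_mean,
            },
            index=pd.Index(self.taxon_ids, name="taxon_id"),
        )


def _taxon_ids(n: int) -> list[str]:
    return [f"T{i:03d}" for i in range(n)]


def generate_paired_counts(
    config: SimulationConfig,
) -> tuple[AbundanceTable, PairedDesign, SimulationTruth]:
    """Simulate paired pre/post read-count tables with known truth.

    For each subject: baseline ~ Dirichlet(concentration); per-taxon
    log-abundance jitter Normal(0, subject_effect_sd) shared by the pair;
    pre composition = renormalized jittered baseline; post composition =
    the same with spiked taxa multiplied by 2^delta, renormalized; read
    counts ~ Multinomial(depth). Identical seeds give identical output.
    """
    rng = np.random.default_rng(config.seed)
    K, n = config.n_taxa, config.n_subjects
    taxa = _taxon_ids(K)
    mult = np.exp2(config.spike_vector())
    if not np.all(np.isfinite(mult)):
        raise ValueError("spike log2 fold change produces non-finite weight")

    pre_comp = np.empty((K, n))
    post_comp = np.empty((K, n))
    for s in range(n):
        base = rng.dirichlet(config.concentration)
        jitter = (
            np.exp(rng.normal(0.0, config.subject_effect_sd, size=K))
            if config.subject_effect_sd > 0
            else 1.0
        )
        w = base * jitter
        pre = w / w.sum()
        post_w = w * mult
        post = post_w / post_w.sum()
        pre_comp[:, s], post_comp[:, s] = pre, post

    counts = np.empty((K, 2 * n), dtype=float)
    for s in range(n):
        counts[:, s] = rng.multinomial(config.depth, pre_comp[:, s])
        counts[:, n + s] = rng.multinomial(config.depth, post_comp[:, s])

    subjects = [f"S{i + 1:02d}" for i in range(n)]
    sample_ids = [f"{s}_pre" for s in subjects] + [f"{s}_post" for s in subjects]
    table = AbundanceTable(taxa, sample_ids, counts, mode="counts")
    design = PairedDesign.from_pairs(
        {s: (f"{s}_pre", f"{s}_post") for s in subjects}
    )
    truth = SimulationTruth(
        taxon_ids=taxa,
        true_log2fc=config.spike_vector(),
        expected_pre_mean=pre_comp.mean(axis=1),
        expected_post_mean=post_comp.mean(axis=1),
    )
    return table, design, truth


# -- random tree ---------------------------------------------------------------


def generate_tree(
    n_leaves: int, seed: int | None = None, taxon_ids: list[str] | None = None
) -> str:
    """Random rooted bifurcating newick tree with exponential branch lengths.

    Built by repeatedly joining two uniformly chosen subtrees; every branch
    gets an independent Exp(1) length (strictly positive).
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    if taxon_ids is None:
        taxon_ids = _taxon_ids(n_leaves)
    if len(taxon_ids) != n_leaves:
        raise ValueError("taxon_ids length must equal n_leaves")
    rng = np.random.default_rng(seed)

    def length() -> float:
        # bounded away from zero so UniFrac denominators stay well posed
        return float(rng.exponential(1.0) + 1e-3)

    nodes = [f"{t}:{length():.6f}" for t in taxon_ids]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{length():.6f}"
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [merged]
    return f"({nodes[0]},{nodes[1]});"


# -- covariates ----------------------------------------------------------------

RACES = ("White", "Black", "Asian", "Multiple")
NUMERIC_COVARIATES = ("prep_duration_weeks", "age", "tfv_dp")


def generate_covariates(
    n_subjects: int,
    seed: int | None = None,
    induce: tuple[str, np.ndarray, float] | None = None,
) -> HostCovariates:
    """Host covariates sampled independently of the microbiome by default.

    Scales follow the emulated cohort: PrEP duration in {48, 60, 72}
    weeks, ages 20-55, TFV-DP 900-2100 fmol/punch, mostly-yes drug use,
    occasional "missing" douching answers. ``induce`` =
    (numeric covariate name, per-subject abundance deltas, strength in
    (0, 1]) replaces that covariate by a monotone function of the deltas
    blended with noise — strength 1 forces Spearman rho = 1.
    """
    rng = np.random.default_rng(seed)
    subjects = [f"S{i + 1:02d}" for i in range(n_subjects)]
    data = pd.DataFrame(
        {
            "prep_duration_weeks": rng.choice([48, 60, 72], size=n_subjects),
            "age": rng.integers(20, 56, size=n_subjects),
            "race": rng.choice(RACES, p=[0.5, 0.125, 0.125, 0.25], size=n_subjects),
            "tfv_dp": np.round(rng.uniform(900, 2100, size=n_subjects), 0),
            "any_drug_use": rng.choice(["yes", "no"], p=[0.75, 0.25], size=n_subjects),
            "drug_abuse": rng.choice(["yes", "no"], p=[0.4, 0.6], size=n_subjects),
            "rectal_douching": rng.choice(
                ["yes", "no", MISSING], p=[0.75, 0.125, 0.125], size=n_subjects
            ),
        },
        index=pd.Index(subjects, name="subject_id"),
    )
    if induce is not None:
        name, deltas, strength = induce
        if name not in NUMERIC_COVARIATES:
            raise ValueError(f"can only induce a numeric covariate, not {name!r}")
        if not (0 < strength <= 1):
            raise ValueError("strength must be in (0, 1]")
        deltas = np.asarray(deltas, dtype=float)
        if deltas.shape != (n_subjects,):
            raise ValueError("deltas must have one value per subject")
        z = (deltas - deltas.mean()) / (deltas.std() or 1.0)
        noise = rng.normal(size=n_subjects)
        signal = strength * z + (1.0 - strength) * noise
        lo, hi = {"prep_duration_weeks": (48, 72), "age": (20, 56), "tfv_dp": (900, 2100)}[name]
        ranks = np.argsort(np.argsort(signal))
        data[name] = lo + (hi - lo) * ranks / max(n_subjects - 1, 1)
    return HostCovariates(data)


def generate_taxonomy(
    taxon_ids: list[str], seed: int | None = None, genera_per_family: int = 3
) -> TaxonomyMap:
    """Assign each taxon its own genus and group genera into families."""
    lineages = {}
    for i, t in enumerate(taxon_ids):
        fam = f"Family{i // genera_per_family + 1:02d}"
        lineages[t] = (fam, f"Genus{i + 1:03d}", "")
    return TaxonomyMap(lineages)


# -- bundle --------------------------------------------------------------------


def write_fixture_bundle(
    outdir: str | Path,
    table: AbundanceTable,
    design: PairedDesign,
    covariates: HostCovariates,
    taxonomy: TaxonomyMap,
    tree_newick: str,
    truth: SimulationTruth,
) -> dict[str, Path]:
    """Write a complete simulated study as plain-text files.

    Layout: abundance.tsv, metadata.tsv, taxonomy.tsv, tree.nwk, truth.tsv.
    """
    if list(covariates.subjects) != list(design.subjects):
        raise ValueError("covariate subjects do not match the design")
    missing = [t for t in table.taxon_ids if t not in taxonomy]
    if missing:
        raise ValueError(f"taxonomy does not cover taxa: {missing}")
    if truth.taxon_ids != table.taxon_ids:
        raise ValueError("truth taxa do not match the table")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": outdir / "abundance.tsv",
        "metadata": outdir / "metadata.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "tree": outdir / "tree.nwk",
        "truth": outdir / "truth.tsv",
    }
    write_abundance_table(table, paths["abundance"])
    write_metadata(design, covariates, paths["metadata"])
    write_taxonomy(taxonomy, paths["taxonomy"])
    paths["tree"].write_text(tree_newick + ("\n" if not tree_newick.endswith("\n") else ""))
    truth.to_frame().to_csv(paths["truth"], sep="\t", float_format="%.17g")
    return paths
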