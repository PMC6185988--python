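"""Taxon-by-sample abundance tables: data model, I/O, normalization, rollup.

The analysis substrate is a matrix of non-negative abundances (raw read
counts or per-specimen proportions) with taxa as rows and specimens as
columns, plus the paired pre/post study design and per-subject host
covariates. Everything downstream (permutation tests, diversity,
host-factor screens) consumes these containers.

Canonical internal form for compositional analysis is proportions in
[0, 1]; percentages are a rendering concern only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "TaxonomyMap",
    "PairedDesign",
    "HostCovariates",
    "read_abundance_table",
    "write_abundance_table",
    "read_taxonomy",
    "read_metadata",
    "write_metadata",
    "normalize_to_proportions",
    "aggregate_to_rank",
    "profile_rmse",
    "validate_paired_design",
    "drop_absent_taxa",
]

PROPORTION_TOL = 1e-9

#: covariates measured per subject; order matters for TSV layout
COVARIATE_COLUMNS = [
    "prep_duration_weeks",
    "age",
    "race",
    "tfv_dp",
    "any_drug_use",
    "drug_abuse",
    "rectal_douching",
]

MISSING = "missing"


class TableError(ValueError):
    """Raised when an abundance table or design violates its invariants."""


@dataclass
class AbundanceTable:
    """Taxon-by-sample matrix of non-negative abundances.

    Parameters
    ----------
    taxon_ids : list of str
        Row labels, unique.
    sample_ids : list of str
        Column labels, unique.
    values : ndarray of shape (n_taxa, n_samples)
        Non-negative abundances.
    mode : {"counts", "proportions"}
        Proportions require each sample column to sum to 1 within 1e-9.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    mode: str = "counts"

    def __post_init__(self) -> None:
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise TableError("values must be a 2-D matrix")
        if self.values.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise TableError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if self.mode not in ("counts", "proportions"):
            raise TableError(f"unknown mode {self.mode!r}")
        for name, ids in (("taxon", self.taxon_ids), ("sample", self.sample_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise TableError(f"duplicate {name} ids: {sorted(dupes)}")
        if not np.all(np.isfinite(self.values)):
            raise TableError("values contain non-finite entries")
        if np.any(self.values < 0):
            bad = np.argwhere(self.values < 0)[0]
            raise TableError(
                f"negative abundance for taxon {self.taxon_ids[bad[0]]!r} "
                f"in sample {self.sample_ids[bad[1]]!r}"
            )
        if self.mode == "proportions" and self.values.shape[1] > 0:
            sums = self.values.sum(axis=0)
            bad = np.flatnonzero(np.abs(sums - 1.0) > PROPORTION_TOL)
            if bad.size:
                raise TableError(
                    f"sample {self.sample_ids[bad[0]]!r} proportions sum to "
                    f"{sums[bad[0]]:.12g}, expected 1"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def taxon_index(self, taxon_id: str) -> int:
        try:
            return self.taxon_ids.index(taxon_id)
        except ValueError:
            raise TableError(f"unknown taxon {taxon_id!r}") from None

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise TableError(f"unknown sample {sample_id!r}") from None

    def sample_vector(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_index(sample_id)]

    def sample_series(self, sample_id: str) -> pd.Series:
        return pd.Series(self.sample_vector(sample_id), index=self.taxon_ids)

    def select_samples(self, sample_ids: Iterable[str]) -> np.ndarray:
        idx = [self.sample_index(s) for s in sample_ids]
        return self.values[:, idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxon_ids, columns=self.sample_ids)

    def __eq__(self, other: object) -> bool:  # value equality, used in round trips
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return (
            self.taxon_ids == other.taxon_ids
            and self.sample_ids == other.sample_ids
            and self.mode == other.mode
            and np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True)
class TaxonomyMap:
    """taxon_id -> (family, genus, species) lineage assignments."""

    lineages: Mapping[str, tuple[str, str, str]]

    def family(self, taxon_id: str) -> str:
        return self.lineages[taxon_id][0]

    def genus(self, taxon_id: str) -> str:
        return self.lineages[taxon_id][1]

    def label(self, taxon_id: str, rank: str) -> str:
        if rank == "family":
            return self.family(taxon_id)
        if rank == "genus":
            return self.genus(taxon_id)
        raise TableError(f"unsupported rank {rank!r}; use 'family' or 'genus'")

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.lineages


@dataclass(frozen=True)
class PairedDesign:
    """Subject -> (pre specimen, post specimen) mapping.

    Defines both the label-permutation groups (all 2n specimens) and the
    sign-flip units (one flip per subject) of the paired test.
    """

    subjects: tuple[str, ...]
    pre_sample: Mapping[str, str]
    post_sample: Mapping[str, str]

    @classmethod
    def from_pairs(cls, pairs: Mapping[str, tuple[str, str]]) -> "PairedDesign":
        subjects = tuple(pairs)
        return cls(
            subjects=subjects,
            pre_sample={s: pairs[s][0] for s in subjects},
            post_sample={s: pairs[s][1] for s in subjects},
        )

    @property
    def n(self) -> int:
        return len(self.subjects)

    def pre_ids(self) -> list[str]:
        return [self.pre_sample[s] for s in self.subjects]

    def post_ids(self) -> list[str]:
        return [self.post_sample[s] for s in self.subjects]

    def all_sample_ids(self) -> list[str]:
        return self.pre_ids() + self.post_ids()


@dataclass(frozen=True)
class HostCovariates:
    """Per-subject host factors screened against abundance changes.

    Numeric fields: PrEP duration (weeks), age (years), TFV-DP adherence
    marker (fmol/punch). Categorical: race. Binary with explicit missing
    level: any drug use, drug abuse, rectal douching.
    """

    data: pd.DataFrame  # index = subject ids, columns = COVARIATE_COLUMNS

    def __post_init__(self) -> None:
        missing_cols = [c for c in COVARIATE_COLUMNS if c not in self.data.columns]
        if missing_cols:
            raise TableError(f"covariate table missing columns: {missing_cols}")
        tfv = pd.to_numeric(self.data["tfv_dp"], errors="coerce")
        if (tfv.dropna() < 0).any():
            raise TableError("tfv_dp must be non-negative")
        dur = pd.to_numeric(self.data["prep_duration_weeks"], errors="coerce")
        if (dur.dropna() <= 0).any():
            raise TableError("prep_duration_weeks must be positive")

    @property
    def subjects(self) -> list[str]:
        return list(self.data.index)

    def numeric(self, name: str) -> pd.Series:
        return pd.to_numeric(self.data[name], errors="coerce")

    def categorical(self, name: str) -> pd.Series:
        s = self.data[name].astype(str)
        return s.mask(s.str.lower().isin(["nan", "", MISSING]), other=pd.NA)


# -- file I/O ------------------------------------------------------------------


def read_abundance_table(path: str | Path, mode: str = "counts") -> AbundanceTable:
    """Read a tab-delimited taxon-by-sample table.

    First column holds taxon ids, the header row holds sample ids.
    Validation (duplicates, negatives, proportion sums) is delegated to the
    :class:`AbundanceTable` constructor.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str},
                     float_precision="round_trip")
    if df.shape[1] < 1:
        raise TableError(f"{path}: no columns found")
    taxon_col = df.columns[0]
    taxa = df[taxon_col].astype(str).tolist()
    samples = [str(c) for c in df.columns[1:]]
    values = df.drop(columns=[taxon_col]).to_numpy(dtype=float)
    return AbundanceTable(taxa, samples, values, mode=mode)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    """Write a table as TSV at full repr precision (round-trip safe)."""
    df = table.to_frame()
    df.index.name = "taxon_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"taxon_id", "family", "genus", "species"}
    if not required.issubset(df.columns):
        raise TableError(f"taxonomy file must have columns {sorted(required)}")
    return TaxonomyMap(
        {r.taxon_id: (r.family, r.genus, r.species) for r in df.itertuples()}
    )


def write_taxonomy(taxonomy: TaxonomyMap, path: str | Path) -> None:
    rows = [
        {"taxon_id": t, "family": f, "genus": g, "species": s}
        for t, (f, g, s) in taxonomy.lineages.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> tuple[PairedDesign, HostCovariates]:
    """Read subject metadata: pairing columns plus host covariates."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"subject_id", "pre_sample", "post_sample"}
    if not required.issubset(df.columns):
        raise TableError(f"metadata file must have columns {sorted(required)}")
    df = df.set_index("subject_id")
    design = PairedDesign.from_pairs(
        {s: (df.loc[s, "pre_sample"], df.loc[s, "post_sample"]) for s in df.index}
    )
    cov = df.drop(columns=["pre_sample", "post_sample"])
    for col in COVARIATE_COLUMNS:
        if col not in cov.columns:
            cov[col] = MISSING
    covariates = HostCovariates(cov[COVARIATE_COLUMNS].copy())
    return design, covariates


def write_metadata(
    design: PairedDesign, covariates: HostCovariates, path: str | Path
) -> None:
    df = covariates.data.copy()
    df.insert(0, "pre_sample", [design.pre_sample[s] for s in df.index])
    df.insert(1, "post_sample", [design.post_sample[s] for s in df.index])
    df.index.name = "subject_id"
    df.to_csv(path, sep="\t")


# -- transforms ----------------------------------------------------------------


def normalize_to_proportions(table: AbundanceTable) -> AbundanceTable:
    """Convert a counts table to per-specimen relative abundances."""
    if table.mode != "counts":
        raise TableError("normalize_to_proportions expects a counts table")
    totals = table.values.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise TableError(
            f"sample {table.sample_ids[zero[0]]!r} has zero total count; "
            "cannot normalize"
        )
    return AbundanceTable(
        table.taxon_ids,
        table.sample_ids,
        table.values / totals,
        mode="proportions",
    )


def aggregate_to_rank(
    table: AbundanceTable, taxonomy: TaxonomyMap, rank: str
) -> AbundanceTable:
    """Sum taxa into family- or genus-level rows; column totals are conserved."""
    unmapped = [t for t in table.taxon_ids if t not in taxonomy]
    if unmapped:
        raise TableError(f"taxa missing from taxonomy map: {unmapped}")
    labels = [taxonomy.label(t, rank) for t in table.taxon_ids]
    df = table.to_frame()
    df.index = pd.Index(labels, name=rank)
    # stable order: first appearance of each rank label
    agg = df.groupby(level=0, sort=False).sum()
    return AbundanceTable(
        list(agg.index), table.sample_ids, agg.to_numpy(), mode=table.mode
    )


def drop_absent_taxa(table: AbundanceTable) -> tuple[AbundanceTable, list[str]]:
    """Remove taxa with zero abundance in every sample.

    Their fold change and t statistic are undefined, so they are excluded
    before differential-abundance analysis. Returns the filtered table and
    the ids that were dropped.
    """
    keep = table.values.sum(axis=1) > 0
    dropped = [t for t, k in zip(table.taxon_ids, keep) if not k]
    if not dropped:
        return table, []
    out = AbundanceTable(
        [t for t, k in zip(table.taxon_ids, keep) if k],
        table.sample_ids,
        table.values[keep],
        mode=table.mode,
    )
    return out, dropped


def profile_rmse(a: Mapping[str, float] | pd.Series, b: Mapping[str, float] | pd.Series) -> float:
    """Root-mean-square difference between two labelled proportion profiles.

    Profiles (e.g. family compositions of the same specimen measured by two
    sequencing technologies) are aligned on the union of their labels with
    zero fill, then compared as sqrt(mean of squared differences).
    """
    sa, sb = pd.Series(dict(a), dtype=float), pd.Series(dict(b), dtype=float)
    labels = sa.index.union(sb.index)
    va = sa.reindex(labels, fill_value=0.0).to_numpy()
    vb = sb.reindex(labels, fill_value=0.0).to_numpy()
    return float(math.sqrt(np.mean((va - vb) ** 2)))


def validate_paired_design(table: AbundanceTable, design: PairedDesign) -> PairedDesign:
    """Check a design against a table; returns the design iff consistent."""
    if design.n < 2:
        raise TableError("paired design needs at least 2 subjects")
    seen: dict[str, str] = {}
    for subject in design.subjects:
        for role, mapping in (("pre", design.pre_sample), ("post", design.post_sample)):
            if subject not in mapping:
                raise TableError(f"subject {subject!r} lacks a {role} specimen")
            sid = mapping[subject]
            if sid not in table.sample_ids:
                raise TableError(
                    f"subject {subject!r}: {role} sample {sid!r} not in table"
                )
            if sid in seen:
                raise TableError(
                    f"sample {sid!r} referenced by both {seen[sid]} and "
                    f"{subject}/{role}"
                )
            seen[sid] = f"{subject}/{role}"
    return design


def _duplicates(ids: list[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for i in ids:
        if i in seen:
            dupes.add(i)
        seen.add(i)
    return dupes
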