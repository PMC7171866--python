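"""OTU/ASV count tables, sample metadata, and the standard preprocessing steps.

The count table is the central container of the package: an integer matrix of
sequence reads, samples (stations) by taxa, from which every downstream metric
derives relative abundances.  Preprocessing follows common amplicon practice:
rarefaction to an even depth by subsampling reads without replacement,
removal of low-count taxa, and classification of taxa into regional
abundance (abundant / intermediate / rare) and occupancy range
(cosmopolitan / intermediate / restricted) classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import output_header, spawn_rngs

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file violates the expected tabular format."""


class EmptyTableError(ValueError):
    """Raised when an operation would leave a table with no samples or taxa."""


@dataclass
class OtuTable:
    """Integer read counts for taxa observed across samples.

    Parameters
    ----------
    sample_ids:
        Ordered, unique station/sample identifiers (rows of ``counts``).
    taxon_ids:
        Ordered, unique taxon identifiers (columns of ``counts``).
    counts:
        Non-negative integer matrix of shape ``(n_samples, n_taxa)``.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise FormatError("counts must be integers (read counts)")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )
        if self.counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise FormatError("label counts do not match matrix dimensions")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise FormatError("duplicate taxon ids")

    # -- basic views --------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def taxon_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def relative_abundances(self) -> np.ndarray:
        """Row-normalised counts; every sample must have reads."""
        totals = self.sample_totals()
        if (totals == 0).any():
            bad = self.sample_ids[int(np.argmax(totals == 0))]
            raise EmptyTableError(f"sample {bad!r} has zero total reads")
        return self.counts / totals[:, None]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    def select_samples(self, keep: list[str]) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in keep]
        return OtuTable(keep, list(self.taxon_ids), self.counts[idx])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_otu_table(path, orientation: str = "taxa-as-rows") -> OtuTable:
    """Read a tab-delimited count table.

    ``orientation`` declares the on-disk layout; the returned table is always
    samples x taxa.  Duplicate labels, negative or non-numeric cells raise
    :class:`FormatError` naming the offending entry.
    """
    if orientation not in ("taxa-as-rows", "samples-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise FormatError(f"duplicate row or column labels in {path}")
    body = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, row in enumerate(df.index):
            cell = df.iat[i, j]
            try:
                value = float(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-numeric value {cell!r} at row {row!r}, column {col!r}"
                ) from None
            if value < 0:
                raise FormatError(f"negative count {cell!r} at row {row!r}, column {col!r}")
            if value != round(value):
                raise FormatError(f"non-integer count {cell!r} at row {row!r}, column {col!r}")
            body[i, j] = int(round(value))
    if orientation == "taxa-as-rows":
        return OtuTable(list(df.columns), list(df.index), body.T)
    return OtuTable(list(df.index), list(df.columns), body)


def write_otu_table(table: OtuTable, path, orientation: str = "taxa-as-rows",
                    seed=None, params: dict | None = None) -> None:
    """Write a table as TSV with a header comment recording provenance."""
    df = table.to_dataframe()
    if orientation == "taxa-as-rows":
        df = df.T
    with open(path, "w") as fh:
        fh.write(output_header(seed, params) + "\n")
        df.to_csv(fh, sep="\t", index_label="id")


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

@dataclass
class SampleMetadata:
    """Per-station context: coordinates, cruise order, environment, groups.

    ``data`` is indexed by sample id and must contain ``latitude``,
    ``longitude`` and ``cruise_order`` columns.  ``env_vars`` and
    ``group_vars`` name the continuous environmental and categorical
    geographic columns respectively.
    """

    data: pd.DataFrame
    env_vars: list[str] = field(default_factory=list)
    group_vars: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"latitude", "longitude", "cruise_order"}
        missing = required - set(self.data.columns)
        if missing:
            raise FormatError(f"metadata missing columns: {sorted(missing)}")
        lat, lon = self.data["latitude"], self.data["longitude"]
        if ((lat < -90) | (lat > 90)).any():
            raise FormatError("latitude outside [-90, 90]")
        if ((lon < -180) | (lon > 180)).any():
            raise FormatError("longitude outside [-180, 180]")
        order = np.sort(self.data["cruise_order"].to_numpy())
        if not np.array_equal(order, np.arange(1, len(self.data) + 1)):
            raise FormatError("cruise_order must be a permutation of 1..n")
        if self.data.index.has_duplicates:
            raise FormatError("duplicate sample ids in metadata")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    def aligned_to(self, sample_ids: list[str]) -> "SampleMetadata":
        missing = set(sample_ids) - set(self.sample_ids)
        if missing:
            raise FormatError(f"metadata missing samples: {sorted(missing)}")
        sub = self.data.loc[sample_ids].copy()
        # renumber cruise order within the retained subset, preserving rank
        sub["cruise_order"] = sub["cruise_order"].rank(method="first").astype(int)
        return SampleMetadata(sub, list(self.env_vars), list(self.group_vars))

    def cruise_sorted_ids(self) -> list[str]:
        return [str(s) for s in self.data.sort_values("cruise_order").index]


def read_metadata(path, env_vars: list[str] | None = None,
                  group_vars: list[str] | None = None) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if env_vars is None:
        known = {"temperature", "salinity", "conductivity", "fluorescence", "oxygen"}
        env_vars = [c for c in df.columns if c in known]
    if group_vars is None:
        group_vars = [c for c in df.columns if df[c].dtype == object]
    return SampleMetadata(df, env_vars, group_vars)


def write_metadata(meta: SampleMetadata, path, seed=None, params=None) -> None:
    with open(path, "w") as fh:
        fh.write(output_header(seed, params) + "\n")
        meta.data.to_csv(fh, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def rarefy(table: OtuTable, depth: int, seed: int | None = None) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped (logged at
    WARNING); taxa left with zero reads across all retained samples are
    removed.  Deterministic given ``seed``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    totals = table.sample_totals()
    keep = totals >= depth
    if not keep.any():
        raise EmptyTableError(f"no sample reaches rarefaction depth {depth}")
    for sid, tot in zip(table.sample_ids, totals):
        if tot < depth:
            logger.warning("dropping sample %s: %d < depth %d reads", sid, tot, depth)
    rngs = spawn_rngs(seed, table.n_samples)
    rows = []
    kept_ids = []
    for i in range(table.n_samples):
        if not keep[i]:
            continue
        row = table.counts[i]
        if totals[i] == depth:
            rows.append(row.copy())
        else:
            rows.append(rngs[i].multivariate_hypergeometric(row, depth))
        kept_ids.append(table.sample_ids[i])
    counts = np.array(rows, dtype=np.int64)
    nonzero = counts.sum(axis=0) > 0
    return OtuTable(kept_ids, [t for t, nz in zip(table.taxon_ids, nonzero) if nz],
                    counts[:, nonzero])


def filter_low_abundance(table: OtuTable, min_total_reads: int) -> OtuTable:
    """Keep taxa whose summed count across samples is strictly > threshold."""
    if min_total_reads < 0:
        raise ValueError("min_total_reads must be >= 0")
    keep = table.taxon_totals() > min_total_reads
    if not keep.any():
        raise EmptyTableError(f"no taxon exceeds {min_total_reads} total reads")
    return OtuTable(list(table.sample_ids),
                    [t for t, k in zip(table.taxon_ids, keep) if k],
                    table.counts[:, keep])


def classify_taxa(table: OtuTable, abundant_pct: float = 0.1, rare_pct: float = 0.001,
                  cosmo_pct: float = 80.0, restricted_pct: float = 20.0) -> pd.DataFrame:
    """Classify taxa by regional mean abundance and by occupancy.

    Mean relative abundance is the mean over samples of the within-sample
    relative abundance, expressed in percent; occupancy is the percentage of
    samples where the taxon has a non-zero count.  Threshold comparisons are
    strict: equality at a threshold falls in the intermediate class.
    """
    if not rare_pct < abundant_pct:
        raise ValueError("rare_pct must be below abundant_pct")
    if not restricted_pct < cosmo_pct:
        raise ValueError("restricted_pct must be below cosmo_pct")
    rel = table.relative_abundances()
    # round to 12 decimals so exact-threshold cases are not tipped over the
    # strict comparison by accumulated floating-point error
    mean_pct = np.round(rel.mean(axis=0) * 100.0, 12)
    occ_pct = np.round((table.counts > 0).mean(axis=0) * 100.0, 12)
    regional = np.where(mean_pct > abundant_pct, "abundant",
                        np.where(mean_pct < rare_pct, "rare", "intermediate"))
    rng_class = np.where(occ_pct > cosmo_pct, "cosmopolitan",
                         np.where(occ_pct < restricted_pct, "restricted", "intermediate"))
    return pd.DataFrame(
        {
            "mean_relative_abundance_pct": mean_pct,
            "occupancy_pct": occ_pct,
            "regional_class": regional,
            "range_class": rng_class,
        },
        index=pd.Index(table.taxon_ids, name="taxon"),
    )
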