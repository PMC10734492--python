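"""Count-table container, filtering, rarefaction, taxonomic aggregation and
the log relative-abundance transform.

The pipeline routes one input table into three branches with different
normalizations:

* diversity branch  — rarefied counts (equal sequencing effort per sample);
* abundance branch  — unrarefied filtered counts, log10 relative abundance;
* network branch    — absolute counts with the rare-taxon network filter,
  no rarefaction and no transform (compositional correlation estimation
  handles the closure itself).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "CountTable",
    "FilterParams",
    "TransformParams",
    "EmptyTableError",
    "filter_taxa",
    "filter_for_network",
    "rarefy",
    "aggregate_taxa",
    "log_relative_abundance",
    "parse_lineage",
]

#: GREENGENES-style rank order of a 7-rank lineage string.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIX = dict(zip(RANKS, ("k__", "p__", "c__", "o__", "f__", "g__", "s__")))


class EmptyTableError(ValueError):
    """Raised when a filter would silently remove every taxon."""


def parse_lineage(lineage: str) -> dict[str, str]:
    """Split a ``k__...; p__...; ...`` lineage into named ranks.

    Missing or unnamed ranks (``g__`` with nothing after the prefix) map to
    the empty string.
    """
    out = {r: "" for r in RANKS}
    for tok in str(lineage).split(";"):
        tok = tok.strip()
        for rank, pref in _RANK_PREFIX.items():
            if tok.startswith(pref):
                out[rank] = tok[len(pref):].strip()
    return out


@dataclass
class CountTable:
    """Samples x taxa matrix of non-negative integer counts.

    Parameters
    ----------
    counts
        DataFrame with sample identifiers as the index and taxon identifiers
        as columns; entries are non-negative integers.
    lineages
        Series mapping each taxon identifier to its 7-rank lineage string.
    """

    counts: pd.DataFrame
    lineages: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64, copy=False)
        self.lineages = pd.Series(self.lineages, dtype=object)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("count table contains negative entries")
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate taxon identifiers")
        missing = self.counts.columns.difference(self.lineages.index)
        if len(missing):
            raise ValueError(f"taxa missing a lineage: {list(missing)[:5]}")
        self.lineages = self.lineages.reindex(self.counts.columns)

    # -- basic views -------------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            bad = list(totals.index[totals == 0])
            raise ValueError(f"zero-total samples: {bad[:5]}")
        return self.counts.div(totals, axis=0)

    def select_taxa(self, taxa) -> "CountTable":
        return CountTable(self.counts.loc[:, list(taxa)], self.lineages.loc[list(taxa)])

    def select_samples(self, samples) -> "CountTable":
        return CountTable(self.counts.loc[list(samples)], self.lineages)

    # -- TSV round trip (taxa as rows, samples as columns) -----------------
    def to_tsv(self, path) -> None:
        out = self.counts.T.copy()
        out.insert(0, "lineage", self.lineages.reindex(out.index).to_numpy())
        out.index.name = "taxon"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CountTable":
        raw = pd.read_csv(path, sep="\t", index_col=0)
        if "lineage" not in raw.columns:
            raise ValueError("count TSV must carry a 'lineage' column")
        lineages = raw["lineage"]
        counts = raw.drop(columns="lineage").T
        return cls(counts, lineages)


@dataclass
class FilterParams:
    """Thresholds for the taxon filters.

    ``min_total_count`` removes taxa whose grand total is <= the threshold
    (420 by default, i.e. two reads per sample over 210 samples);
    ``min_prevalence_fraction`` removes taxa seen in fewer than that fraction
    of samples; ``min_mean_reads_per_sample`` applies only on the network
    branch; ``rarefaction_depth`` is the common per-sample read depth for the
    diversity branch.
    """

    min_total_count: int = 420
    min_prevalence_fraction: float = 0.10
    min_mean_reads_per_sample: float = 2.0
    rarefaction_depth: int = 10_000

    def __post_init__(self) -> None:
        if self.min_total_count < 0 or self.min_mean_reads_per_sample < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0.0 <= self.min_prevalence_fraction <= 1.0:
            raise ValueError("prevalence fraction must lie in [0, 1]")
        if self.rarefaction_depth <= 0:
            raise ValueError("rarefaction depth must be positive")


@dataclass
class TransformParams:
    """Scaling for the log relative-abundance transform.

    ``average_sequences_per_sample`` is the constant the relative abundance
    is multiplied by before ``log10(x + 1)``; when None it is recomputed as
    the mean library size of the table being transformed.
    """

    average_sequences_per_sample: float | None = None
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.average_sequences_per_sample is not None and self.average_sequences_per_sample <= 0:
            raise ValueError("average_sequences_per_sample must be positive")


def _check_nonempty(keep: pd.Index, what: str) -> None:
    if len(keep) == 0:
        raise EmptyTableError(f"{what} removed every taxon from the table")


def filter_taxa(table: CountTable, params: FilterParams | None = None) -> CountTable:
    """Apply the abundance/diversity-branch taxon filters.

    A taxon is retained iff its grand total exceeds ``min_total_count``
    (strictly: a total equal to the threshold is removed) and it is non-zero
    in at least ``ceil(min_prevalence_fraction * n_samples)`` samples.
    Total-count filtering runs first, then prevalence.
    """
    params = params or FilterParams()
    totals = table.counts.sum(axis=0)
    keep = totals.index[totals > params.min_total_count]
    _check_nonempty(keep, "total-count filter")
    sub = table.counts.loc[:, keep]
    min_n = math.ceil(params.min_prevalence_fraction * table.n_samples)
    prevalence = (sub > 0).sum(axis=0)
    keep = prevalence.index[prevalence >= min_n]
    _check_nonempty(keep, "prevalence filter")
    return table.select_taxa(keep)


def filter_for_network(table: CountTable, params: FilterParams | None = None) -> CountTable:
    """Network-branch filter on absolute counts.

    Retains taxa with total count >= ``min_total_count`` and a mean of at
    least ``min_mean_reads_per_sample`` reads per sample (the two criteria
    coincide at 420 total = 2 reads x 210 samples). Counts are kept absolute:
    this branch feeds compositional correlation estimation directly.
    """
    params = params or FilterParams()
    totals = table.counts.sum(axis=0)
    mean_reads = totals / table.n_samples
    keep = totals.index[
        (totals >= params.min_total_count)
        & (mean_reads >= params.min_mean_reads_per_sample)
    ]
    _check_nonempty(keep, "network filter")
    return table.select_taxa(keep)


def rarefy(
    table: CountTable, depth: int, seed: int | np.random.Generator = 0
) -> tuple[CountTable, list[str]]:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped. Returns the
    rarefied table and the list of dropped sample identifiers. Drawing is
    multivariate hypergeometric (exact without-replacement semantics), so a
    sample with exactly ``depth`` reads is returned unchanged.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    totals = table.library_sizes()
    dropped = [s for s, t in totals.items() if t < depth]
    kept = [s for s in table.samples if s not in set(dropped)]
    if not kept:
        raise EmptyTableError(f"all {table.n_samples} samples fall below depth {depth}")
    mat = table.counts.loc[kept].to_numpy()
    out = np.empty_like(mat)
    for i in range(mat.shape[0]):
        out[i] = rng.multivariate_hypergeometric(mat[i], depth, method="marginals")
    rare = pd.DataFrame(out, index=kept, columns=table.counts.columns)
    return CountTable(rare, table.lineages), dropped


def _aggregate_label(ranks: dict[str, str], level: str) -> str:
    """Display label for an aggregated taxon, in the reporting style that
    marks an unnamed genus under a named family explicitly."""
    name = ranks[level]
    if name:
        return name
    if level == "genus" and ranks["family"]:
        return f"Family {ranks['family']}—unknown genus"
    # fall back to the deepest named rank above the requested level
    idx = RANKS.index(level)
    for r in reversed(RANKS[:idx]):
        if ranks[r]:
            return f"{r} {ranks[r]}—unknown {level}"
    return f"unknown {level}"


def aggregate_taxa(table: CountTable, level: str) -> CountTable:
    """Sum counts over all features sharing the lineage prefix down to
    ``level`` (one of phylum/class/order/family/genus).

    Per-sample totals are conserved. The aggregated lineage string is
    truncated at ``level``; display labels mark unnamed genera under a named
    family as "Family <name>—unknown genus".
    """
    if level not in RANKS[1:6]:
        raise ValueError(f"unknown taxonomic level: {level!r}")
    depth = RANKS.index(level) + 1
    keys: dict[str, tuple] = {}
    for taxon, lin in table.lineages.items():
        ranks = parse_lineage(lin)
        keys[taxon] = tuple(ranks[r] for r in RANKS[:depth])
    groups: dict[tuple, list[str]] = {}
    for taxon, key in keys.items():
        groups.setdefault(key, []).append(taxon)

    cols, lins, labels = [], [], []
    for key, members in groups.items():
        ranks = dict(zip(RANKS, list(key) + [""] * (len(RANKS) - len(key))))
        label = _aggregate_label(ranks, level)
        if label in labels:  # disambiguate same-named groups under distinct prefixes
            label = f"{label} ({';'.join(key[:-1])})"
        labels.append(label)
        cols.append(table.counts[members].sum(axis=1))
        lins.append("; ".join(p + v for p, v in zip(
            ("k__", "p__", "c__", "o__", "f__", "g__", "s__"), key)))
    agg = pd.concat(cols, axis=1)
    agg.columns = labels
    return CountTable(agg, pd.Series(lins, index=labels))


def log_relative_abundance(
    table: CountTable, params: TransformParams | None = None
) -> pd.DataFrame:
    """log10(relative abundance x average sequences per sample + 1).

    A zero count maps to exactly 0; the transform is strictly monotone in
    the count for a fixed sample total. The scaling constant defaults to the
    mean library size of the table being transformed.
    """
    params = params or TransformParams()
    totals = table.counts.sum(axis=1)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"zero-total samples cannot be transformed: {bad[:5]}")
    avg = params.average_sequences_per_sample
    if avg is None:
        avg = float(totals.mean())
    rel = table.counts.div(totals, axis=0)
    return np.log10(rel * avg + params.pseudocount)
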