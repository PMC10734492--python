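"""Per-taxon abundance-change testing between timepoints.

The paired t-test runs on log10 relative abundances (which satisfy the
test's distributional assumptions far better than raw proportions), while
the reported percent change is computed on the raw group-mean relative
abundances — a linear scale a reader can interpret directly. Benjamini-
Hochberg step-up adjustment controls the false discovery rate across the
taxa of one taxonomic level within one group (a pooled mode is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .diversity import paired_ttest
from .preprocess import (
    CountTable,
    TransformParams,
    aggregate_taxa,
    log_relative_abundance,
    parse_lineage,
)

__all__ = [
    "TaxonTestResult",
    "WeightStratification",
    "percent_change",
    "bh_adjust",
    "test_taxa",
    "abundance_report",
    "stratify_by_weight_return",
]


@dataclass
class TaxonTestResult:
    """One taxon's change between timepoints within one group."""

    taxon: str
    phylum: str
    level: str
    percent_change: float | None
    p_raw: float
    q_bh: float
    significant: bool


@dataclass
class WeightStratification:
    """Per-subject flag: returned to within ``threshold_kg`` of
    pre-pregnancy weight by 6 months (inclusive boundary)."""

    within: pd.Series  # bool per subject
    threshold_kg: float
    n_excluded: int


def percent_change(mean_1m: float, mean_6m: float, digits: int | None = 2) -> float | None:
    """100 x (m6 - m1) / m1; None when the baseline mean is zero."""
    if mean_1m == 0:
        return None
    pc = 100.0 * (mean_6m - mean_1m) / mean_1m
    return round(pc, digits) if digits is not None else pc


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in the input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def _sort_key(row: dict) -> tuple:
    # reporting convention: phyla alphabetical; within a phylum families
    # ("Family ..." labels) before genera; alphabetical within each block
    label = row["taxon"]
    is_family = label.startswith("Family ") or label.endswith("_unknown")
    return (row["phylum"], 0 if is_family else 1, label)


def test_taxa(
    table: CountTable,
    metadata: pd.DataFrame,
    group: str,
    level: str = "genus",
    alpha: float = 0.05,
    transform_params: TransformParams | None = None,
    mode: str = "ratio_of_means",
) -> pd.DataFrame:
    """Paired differential-abundance test of every taxon at one level.

    ``table`` is the unrarefied filtered table (any aggregation level; it
    is re-aggregated to ``level``); ``metadata`` must carry subject_id,
    timepoint and weight_group indexed by sample. Returns one row per taxon
    with percent change, raw p, BH-adjusted q, and a significance flag,
    sorted by (phylum, families-then-genera, name).
    """
    agg = aggregate_taxa(table, level)
    common = [s for s in agg.samples if s in metadata.index]
    meta = metadata.loc[common]
    mask = meta["weight_group"] == group
    sub = agg.select_samples(list(meta.index[mask]))
    meta = meta.loc[mask]
    logvals = log_relative_abundance(sub, transform_params)
    rel = sub.relative_abundance()

    m1 = meta.index[meta["timepoint"] == "1m"]
    m6 = meta.index[meta["timepoint"] == "6m"]
    subj1 = meta.loc[m1, "subject_id"]
    subj6 = meta.loc[m6, "subject_id"]
    if set(subj1) != set(subj6):
        raise ValueError("paired design incomplete: subjects missing a timepoint")

    rows = []
    for taxon in sub.taxa:
        v1 = pd.Series(logvals.loc[m1, taxon].to_numpy(), index=subj1.to_numpy())
        v6 = pd.Series(logvals.loc[m6, taxon].to_numpy(), index=subj6.to_numpy())
        try:
            _, p = paired_ttest(v1, v6)
        except ValueError:
            p = 1.0  # constant taxon carries no evidence of change
        if mode == "ratio_of_means":
            pc = percent_change(
                float(rel.loc[m1, taxon].mean()), float(rel.loc[m6, taxon].mean())
            )
        elif mode == "mean_of_ratios":
            r1 = pd.Series(rel.loc[m1, taxon].to_numpy(), index=subj1.to_numpy())
            r6 = pd.Series(rel.loc[m6, taxon].to_numpy(), index=subj6.to_numpy())
            ratios = (r6 / r1.reindex(r6.index)).replace([np.inf, -np.inf], np.nan)
            pc = round(float((ratios.dropna() - 1.0).mean() * 100.0), 2)
        else:
            raise ValueError(f"unknown percent-change mode {mode!r}")
        phylum = parse_lineage(sub.lineages[taxon])["phylum"]
        rows.append(
            {"taxon": taxon, "phylum": phylum, "level": level,
             "percent_change": pc, "p_raw": p}
        )
    rows.sort(key=_sort_key)
    frame = pd.DataFrame(rows)
    frame["q_bh"] = bh_adjust(frame["p_raw"])
    frame["significant"] = frame["q_bh"] < alpha
    return frame


def abundance_report(
    table: CountTable,
    metadata: pd.DataFrame,
    group: str,
    levels: tuple[str, ...] = ("phylum", "class", "order", "family", "genus"),
    alpha: float = 0.05,
    pooled: bool = False,
    transform_params: TransformParams | None = None,
) -> pd.DataFrame:
    """Run :func:`test_taxa` at several taxonomic levels and stack the
    results (the reporting shape of a significant-taxa table).

    With ``pooled=True`` the BH family spans all levels at once instead of
    one family per level.
    """
    frames = [
        test_taxa(table, metadata, group, level, alpha, transform_params)
        for level in levels
    ]
    out = pd.concat(frames, ignore_index=True)
    if pooled:
        out["q_bh"] = bh_adjust(out["p_raw"])
        out["significant"] = out["q_bh"] < alpha
    return out


def stratify_by_weight_return(
    metadata: pd.DataFrame, threshold_kg: float = 5.0
) -> WeightStratification:
    """Flag subjects who returned to within ``threshold_kg`` (inclusive) of
    their pre-pregnancy weight by 6 months.

    Subjects missing either weight are excluded (counted, with a warning in
    the returned object rather than an exception).
    """
    six = metadata[metadata["timepoint"] == "6m"]
    flags = {}
    excluded = 0
    for _, row in six.iterrows():
        w6 = row.get("weight_kg")
        pre = row.get("pre_pregnancy_weight_kg")
        if pd.isna(w6) or pd.isna(pre):
            excluded += 1
            continue
        flags[row["subject_id"]] = bool(abs(w6 - pre) <= threshold_kg)
    return WeightStratification(
        within=pd.Series(flags, dtype=bool),
        threshold_kg=threshold_kg,
        n_excluded=excluded,
    )
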