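"""End-to-end orchestration: simulate or ingest a cohort, preprocess it
into the three analysis branches, and emit networks, diversity, abundance
and descriptive tables as a reproducible report bundle."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from . import abundance as ab
from . import diversity as dv
from . import network as nw
from .preprocess import (
    CountTable,
    FilterParams,
    TransformParams,
    filter_for_network,
    filter_taxa,
    rarefy,
)
from .sparcc import SparccParams
from .synthetic_data import GROUPS, TIMEPOINTS, SyntheticConfig, generate_study

__all__ = ["PipelineConfig", "PipelineError", "run", "describe_cohort"]

log = logging.getLogger("micronet")


class PipelineError(RuntimeError):
    """A stage failed; the stage name prefixes the message."""


@dataclass
class PipelineConfig:
    """Everything one run needs.

    Exactly one of ``synthetic`` (a :class:`SyntheticConfig`) or
    ``input_paths`` (dict with counts/metadata/tree TSV+newick paths) must
    be given. Sub-configurations cover the filters, the correlation
    estimator, the network comparison and the diversity/abundance settings.
    """

    synthetic: SyntheticConfig | None = None
    input_paths: dict | None = None
    filter_params: FilterParams = field(default_factory=FilterParams)
    transform_params: TransformParams = field(default_factory=TransformParams)
    sparcc_params: SparccParams = field(default_factory=SparccParams)
    network_alpha: float = 0.05
    n_subsample: int | None = 40
    n_network_replicates: int = 250
    permanova_permutations: int = 999
    shannon_base: float = 2.0
    abundance_levels: tuple[str, ...] = ("phylum", "class", "order", "family", "genus")
    pooled_bh: bool = False
    seed: int = 0
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.input_paths is None):
            raise ValueError(
                "exactly one of synthetic config or input paths must be set"
            )

    @classmethod
    def fast(cls, seed: int = 0, **kwargs) -> "PipelineConfig":
        """Reduced-replicate preset for quick runs; the planted structure is
        unchanged, only resampling resolution is lowered."""
        kwargs.setdefault("synthetic", SyntheticConfig(seed=seed))
        kwargs.setdefault(
            "sparcc_params",
            SparccParams(n_estimation_iterations=10, n_bootstraps=50, seed=seed),
        )
        kwargs.setdefault("n_network_replicates", 25)
        kwargs.setdefault("permanova_permutations", 499)
        return cls(seed=seed, **kwargs)

    @classmethod
    def paper_scale(cls, seed: int = 0, **kwargs) -> "PipelineConfig":
        """Full-resolution preset (250 network replicates, 1000 permutation
        replicates per p-value)."""
        kwargs.setdefault("synthetic", SyntheticConfig(seed=seed))
        kwargs.setdefault("sparcc_params", SparccParams(n_bootstraps=1000, seed=seed))
        return cls(seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# cohort descriptives


def _letter_display(cells: list[str], nsd_pairs: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display: cells sharing a letter are not significantly
    different. Letters are maximal cliques of the not-significantly-
    different graph; no letters when a single clique covers everything."""
    g = nx.Graph()
    g.add_nodes_from(cells)
    g.add_edges_from(nsd_pairs)
    cliques = sorted(nx.find_cliques(g), key=lambda c: sorted(cells.index(x) for x in c))
    if len(cliques) == 1:
        return {c: "" for c in cells}
    letters = {c: [] for c in cells}
    for k, clique in enumerate(cliques):
        lab = chr(ord("A") + k)
        for c in clique:
            letters[c].append(lab)
    return {c: ",".join(sorted(v)) for c, v in letters.items()}


def describe_cohort(metadata: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Means +/- SD per group x timepoint for numeric variables, with a
    letter annotation marking significant pairwise differences (paired
    within a group across timepoints, unpaired between groups), plus counts
    and percentages for non-numeric variables."""
    cells = [(g, t) for g in GROUPS for t in TIMEPOINTS]
    cell_names = [f"{g} {t}" for g, t in cells]
    num_cols = [
        c for c in metadata.columns
        if pd.api.types.is_numeric_dtype(metadata[c]) and c != "subject_id"
    ]
    rows = []
    for col in num_cols:
        vals: dict[str, pd.Series] = {}
        for (g, t), name in zip(cells, cell_names):
            m = metadata[(metadata["weight_group"] == g) & (metadata["timepoint"] == t)]
            vals[name] = pd.Series(m[col].to_numpy(), index=m["subject_id"].to_numpy())
        # pairwise tests on the 4 cells
        nsd: set[tuple[str, str]] = set()
        testable = all(v.std(ddof=1) > 0 for v in vals.values() if len(v) > 1)
        for i in range(len(cell_names)):
            for j in range(i + 1, len(cell_names)):
                a, b = cell_names[i], cell_names[j]
                va, vb = vals[a], vals[b]
                if not testable:
                    nsd.add((a, b))
                    continue
                same_group = a.split()[0] == b.split()[0]
                if same_group:
                    diff = (vb - va.reindex(vb.index)).dropna().to_numpy()
                    if np.allclose(np.std(diff, ddof=1), 0.0):
                        nsd.add((a, b))
                        continue
                    _, p = stats.ttest_rel(
                        va.reindex(vb.index).to_numpy(), vb.to_numpy()
                    )
                else:
                    _, p = stats.ttest_ind(va.to_numpy(), vb.to_numpy())
                if p >= alpha:
                    nsd.add((a, b))
        letters = (
            {c: "" for c in cell_names}
            if not testable
            else _letter_display(cell_names, nsd)
        )
        row = {"variable": col}
        for name in cell_names:
            v = vals[name]
            sd = v.std(ddof=1) if len(v) > 1 else 0.0
            cell_txt = f"{v.mean():.2f} ± {sd:.2f}"
            if letters[name]:
                cell_txt += f" {letters[name]}"
            row[name] = cell_txt
        rows.append(row)
    cat_cols = [
        c for c in metadata.columns
        if c not in num_cols + ["subject_id", "timepoint", "weight_group"]
    ]
    for col in cat_cols:
        row = {"variable": col}
        for (g, t), name in zip(cells, cell_names):
            m = metadata[(metadata["weight_group"] == g) & (metadata["timepoint"] == t)]
            counts = m[col].value_counts()
            row[name] = "; ".join(
                f"{k}: {v} ({100.0 * v / len(m):.1f}%)" for k, v in counts.items()
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


# ---------------------------------------------------------------------------
# pipeline stages


def _paired_alpha_tests(
    alpha_tab: pd.DataFrame, meta: pd.DataFrame, group: str
) -> dict[str, dict[str, float]]:
    m = meta.loc[alpha_tab.index]
    m = m[m["weight_group"] == group]
    # only subjects observed at both timepoints (rarefaction may drop one)
    subj_tp = m.groupby("subject_id")["timepoint"].nunique()
    complete = set(subj_tp.index[subj_tp == 2])
    m = m[m["subject_id"].isin(complete)]
    out = {}
    for metric in alpha_tab.columns:
        s1 = m.index[m["timepoint"] == "1m"]
        s6 = m.index[m["timepoint"] == "6m"]
        v1 = pd.Series(
            alpha_tab.loc[s1, metric].to_numpy(), index=m.loc[s1, "subject_id"].to_numpy()
        )
        v6 = pd.Series(
            alpha_tab.loc[s6, metric].to_numpy(), index=m.loc[s6, "subject_id"].to_numpy()
        )
        t, p = dv.paired_ttest(v1, v6)
        out[metric] = {
            "mean_1m": float(v1.mean()),
            "mean_6m": float(v6.mean()),
            "t": t,
            "p": p,
            "n_pairs": int(len(v1)),
        }
    return out


def _load_inputs(paths: dict) -> tuple[CountTable, pd.DataFrame, str | None]:
    table = CountTable.from_tsv(paths["counts"])
    metadata = pd.read_csv(paths["metadata"], sep="\t", index_col=0)
    for col in ("subject_id", "timepoint", "weight_group"):
        if col not in metadata.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    tree = None
    if paths.get("tree"):
        tree = Path(paths["tree"]).read_text().strip()
    return table, metadata, tree


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def run(config: PipelineConfig) -> dict:
    """Execute the full analysis and return the report bundle as a dict.

    When ``config.out_dir`` is set, tables and JSON reports are also
    written there together with a run manifest; a failure leaves a FAILED
    marker naming the stage.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "FAILED").unlink(missing_ok=True)
    report: dict = {}
    stage = "setup"
    try:
        # ---- data ------------------------------------------------------
        stage = "data"
        if config.synthetic is not None:
            table, metadata, tree, truth = generate_study(config.synthetic)
            report["planted_truth_available"] = True
        else:
            table, metadata, tree = _load_inputs(config.input_paths)
            truth = None
            report["planted_truth_available"] = False
        log.info("data: %d samples x %d taxa", table.n_samples, table.n_taxa)

        # ---- preprocessing: three branches -----------------------------
        stage = "preprocess"
        filtered = filter_taxa(table, config.filter_params)
        net_table = filter_for_network(table, config.filter_params)
        rarefied, dropped = rarefy(
            filtered, config.filter_params.rarefaction_depth,
            seed=np.random.SeedSequence([config.seed, 41]),
        )
        report["preprocess"] = {
            "n_taxa_input": table.n_taxa,
            "n_taxa_filtered": filtered.n_taxa,
            "n_taxa_network": net_table.n_taxa,
            "n_samples_dropped_by_rarefaction": len(dropped),
            "dropped_samples": dropped,
        }

        # ---- cohort descriptives ---------------------------------------
        stage = "descriptives"
        cohort = describe_cohort(metadata)
        report["cohort"] = cohort

        # ---- networks --------------------------------------------------
        stage = "network"
        net_cfg_by_group = {}
        report["network"] = {}
        for gi, group in enumerate(GROUPS):
            meta_g = metadata[metadata["weight_group"] == group]
            cnt = {
                tp: net_table.counts.loc[meta_g.index[meta_g["timepoint"] == tp]]
                for tp in TIMEPOINTS
            }
            cfg = nw.TimepointComparisonConfig(
                alpha=config.network_alpha,
                n_subsample=config.n_subsample,
                n_replicates=config.n_network_replicates,
                sparcc_params=config.sparcc_params,
                seed=config.seed + 1000 * (gi + 1),
            )
            net_cfg_by_group[group] = cfg
            report["network"][group] = nw.compare_timepoints(
                cnt["1m"], cnt["6m"], cfg
            )
            log.info("network[%s]: %s", group, report["network"][group]["percent_change"])

        # ---- alpha diversity -------------------------------------------
        stage = "alpha_diversity"
        alpha_tab = dv.alpha_diversity_table(
            rarefied.counts, tree=tree, base=config.shannon_base
        )
        report["alpha_diversity"] = alpha_tab
        report["alpha_tests"] = {
            g: _paired_alpha_tests(alpha_tab, metadata, g) for g in GROUPS
        }

        # ---- beta diversity --------------------------------------------
        stage = "beta_diversity"
        rel = rarefied.relative_abundance()
        report["beta"] = {}
        for gi, group in enumerate(GROUPS):
            meta_g = metadata.loc[rel.index]
            meta_g = meta_g[meta_g["weight_group"] == group]
            sub = rel.loc[meta_g.index]
            D = dv.bray_curtis(sub)
            perma = dv.permanova(
                D, meta_g["timepoint"],
                n_permutations=config.permanova_permutations,
                seed=np.random.default_rng(
                    np.random.SeedSequence([config.seed, 53, gi])
                ),
            )
            within = dv.mean_within_group_dissimilarity(D, meta_g["timepoint"])
            report["beta"][group] = {
                "permanova": dataclasses.asdict(perma),
                "mean_within_timepoint_dissimilarity": within,
            }

        # ---- abundance --------------------------------------------------
        stage = "abundance"
        report["abundance"] = {}
        for group in GROUPS:
            res = ab.abundance_report(
                filtered, metadata, group,
                levels=config.abundance_levels,
                pooled=config.pooled_bh,
                transform_params=config.transform_params,
            )
            report["abundance"][group] = res

        # ---- weight-return sensitivity (loss group) --------------------
        stage = "sensitivity"
        strat = ab.stratify_by_weight_return(metadata)
        sens = {"threshold_kg": strat.threshold_kg, "n_excluded": strat.n_excluded}
        for label, flag in (("within_5kg", True), ("outside_5kg", False)):
            subjects = set(strat.within.index[strat.within == flag])
            meta_s = metadata[
                (metadata["weight_group"] == "loss")
                & (metadata["subject_id"].isin(subjects))
            ]
            sens[label] = {"n_subjects": int(meta_s["subject_id"].nunique())}
            if meta_s["subject_id"].nunique() >= 3:
                alpha_sub = alpha_tab.loc[alpha_tab.index.intersection(meta_s.index)]
                try:
                    sens[label]["alpha_tests"] = _paired_alpha_tests(
                        alpha_sub, metadata, "loss"
                    )
                except ValueError:
                    sens[label]["alpha_tests"] = None
                res = ab.abundance_report(
                    filtered, meta_s, "loss",
                    levels=("genus",),
                    transform_params=config.transform_params,
                )
                sens[label]["n_significant_genera"] = int(res["significant"].sum())
        report["sensitivity"] = sens

        if truth is not None:
            report["planted_truth"] = truth

        # ---- write bundle ----------------------------------------------
        stage = "write"
        if out_dir:
            _write_bundle(report, config, out_dir)
    except Exception as err:
        if out_dir:
            (out_dir / "FAILED").write_text(f"stage={stage}: {err}\n")
        raise PipelineError(f"stage {stage!r} failed: {err}") from err
    return report


def _write_bundle(report: dict, config: PipelineConfig, out_dir: Path) -> None:
    report["cohort"].to_csv(out_dir / "cohort_characteristics.tsv", sep="\t")
    report["alpha_diversity"].to_csv(out_dir / "alpha_diversity.tsv", sep="\t")
    for group in GROUPS:
        report["abundance"][group].to_csv(
            out_dir / f"abundance_{group}.tsv", sep="\t", index=False
        )
        sig = report["abundance"][group]
        sig[sig["significant"]].to_csv(
            out_dir / f"abundance_{group}_significant.tsv", sep="\t", index=False
        )
    with open(out_dir / "network_comparison.json", "w") as fh:
        json.dump(_jsonable(report["network"]), fh, indent=2)
    with open(out_dir / "alpha_tests.json", "w") as fh:
        json.dump(_jsonable(report["alpha_tests"]), fh, indent=2)
    with open(out_dir / "beta_diversity.json", "w") as fh:
        json.dump(_jsonable(report["beta"]), fh, indent=2)
    with open(out_dir / "sensitivity.json", "w") as fh:
        json.dump(_jsonable(report["sensitivity"]), fh, indent=2)
    import micronet

    manifest = {
        "package_version": micronet.__version__,
        "seed": config.seed,
        "filter_params": dataclasses.asdict(config.filter_params),
        "sparcc_params": dataclasses.asdict(config.sparcc_params),
        "network": {
            "alpha": config.network_alpha,
            "n_subsample": config.n_subsample,
            "n_replicates": config.n_network_replicates,
        },
        "permanova_permutations": config.permanova_permutations,
        "shannon_base": config.shannon_base,
        "abundance_levels": list(config.abundance_levels),
        "synthetic": (
            {
                "n_gain": config.synthetic.n_gain,
                "n_loss": config.synthetic.n_loss,
                "n_taxa": config.synthetic.n_taxa,
                "seed": config.synthetic.seed,
            }
            if config.synthetic is not None
            else None
        ),
        "preprocess": _jsonable(report["preprocess"]),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
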