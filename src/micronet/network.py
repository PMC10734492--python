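"""Co-occurrence networks from significance matrices, their summary
metrics, and the subsample-equalized comparison of unequal-size groups.

A larger group yields a denser network purely through sample size, so the
bigger group is repeatedly subsampled (without replacement, 250 draws by
default) down to the smaller group's size; metrics are averaged over the
replicate networks and a representative replicate closest to those averages
is kept for display. A replicate whose correlation estimation hits a
singular basis system is discarded and redrawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .sparcc import (
    CorrelationResult,
    SingularBasisError,
    SparccParams,
    bootstrap_pvalues,
    sparcc,
)

__all__ = [
    "CooccurrenceNetwork",
    "NetworkMetrics",
    "SubsampleComparison",
    "build_network",
    "compute_metrics",
    "subsample_networks",
    "representative_network",
    "compare_timepoints",
    "percent_change",
]


@dataclass
class CooccurrenceNetwork:
    """Undirected graph: taxa as nodes, significant correlations as edges."""

    graph: nx.Graph
    alpha: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"taxon_a": a, "taxon_b": b,
             "r": d.get("r", np.nan), "p": d.get("p", np.nan)}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "r", "p"])


@dataclass
class NetworkMetrics:
    """The three reported summaries of one network."""

    n_nodes: int
    n_edges: int
    edge_density: float
    avg_clustering: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (float(self.n_edges), self.edge_density, self.avg_clustering)


@dataclass
class SubsampleComparison:
    """Replicate metrics and their means for one subsampled group/timepoint."""

    metrics: list[NetworkMetrics]
    networks: list[CooccurrenceNetwork]
    replicate_seeds: list[int]
    n_discarded: int

    @property
    def mean_n_edges(self) -> float:
        return float(np.mean([m.n_edges for m in self.metrics]))

    @property
    def mean_edge_density(self) -> float:
        return float(np.mean([m.edge_density for m in self.metrics]))

    @property
    def mean_avg_clustering(self) -> float:
        return float(np.mean([m.avg_clustering for m in self.metrics]))

    def mean_metrics(self) -> dict[str, float]:
        return {
            "n_edges": self.mean_n_edges,
            "edge_density": self.mean_edge_density,
            "avg_clustering": self.mean_avg_clustering,
        }


def build_network(
    correlation_result: CorrelationResult, alpha: float = 0.05
) -> CooccurrenceNetwork:
    """Draw an edge between two taxa iff their p-value is strictly below
    ``alpha``; every taxon is a node regardless of degree."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    taxa = correlation_result.taxa
    g = nx.Graph()
    g.add_nodes_from(taxa)
    d = len(taxa)
    for i in range(d):
        for j in range(i + 1, d):
            if correlation_result.p[i, j] < alpha:
                g.add_edge(
                    taxa[i], taxa[j],
                    r=float(correlation_result.r[i, j]),
                    p=float(correlation_result.p[i, j]),
                )
    return CooccurrenceNetwork(graph=g, alpha=alpha)


def compute_metrics(network: CooccurrenceNetwork) -> NetworkMetrics:
    """Edge count, edge density (edges over all unordered node pairs) and
    average clustering coefficient (degree-<2 nodes contribute 0)."""
    g = network.graph
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("network metrics need at least 2 nodes")
    m = g.number_of_edges()
    density = 2.0 * m / (n * (n - 1))
    clustering = float(nx.average_clustering(g))
    return NetworkMetrics(
        n_nodes=n, n_edges=m, edge_density=density, avg_clustering=clustering
    )


def _network_from_counts(
    counts: np.ndarray,
    taxa: list[str],
    sparcc_params: SparccParams,
    alpha: float,
    rng: np.random.Generator,
) -> tuple[CooccurrenceNetwork, NetworkMetrics]:
    r = sparcc(counts, sparcc_params, rng=rng)
    p = bootstrap_pvalues(counts, r, sparcc_params, rng=rng)
    res = CorrelationResult(r=r, p=p, taxa=taxa, params=sparcc_params)
    net = build_network(res, alpha)
    return net, compute_metrics(net)


def subsample_networks(
    counts: pd.DataFrame | np.ndarray,
    taxa: list[str] | None = None,
    n_subsample: int = 40,
    n_replicates: int = 250,
    sparcc_params: SparccParams | None = None,
    alpha: float = 0.05,
    seed: int = 0,
    retry_factor: int = 10,
    reseed_per_replicate: bool = True,
) -> SubsampleComparison:
    """Equalize group size by repeated subsampling.

    Each replicate draws ``n_subsample`` samples without replacement from
    ``counts`` (samples x taxa), runs correlation estimation, permutation
    p-values, edge construction and metric computation, and records the
    result. Replicates whose estimation raises :class:`SingularBasisError`
    are discarded and redrawn; the retry budget is ``retry_factor *
    n_replicates`` total draws.

    By default every replicate re-randomizes the estimator seed (replicate
    spread then includes estimator noise, as it would when rerunning the
    tool); ``reseed_per_replicate=False`` fixes the estimator seed, so
    subsampling at the full group size degenerates to the identical network
    every replicate.
    """
    if isinstance(counts, pd.DataFrame):
        taxa = list(counts.columns)
        counts = counts.to_numpy()
    if taxa is None:
        taxa = [f"taxon_{j}" for j in range(counts.shape[1])]
    n_samples = counts.shape[0]
    if n_subsample > n_samples:
        raise ValueError(
            f"cannot subsample {n_subsample} from {n_samples} samples"
        )
    sparcc_params = sparcc_params or SparccParams()
    master = np.random.SeedSequence([seed, 11])
    draw_rng = np.random.default_rng(master.spawn(1)[0])
    metrics: list[NetworkMetrics] = []
    networks: list[CooccurrenceNetwork] = []
    replicate_seeds: list[int] = []
    discarded = 0
    budget = retry_factor * n_replicates
    attempts = 0
    while len(metrics) < n_replicates:
        if attempts >= budget:
            raise SingularBasisError(
                f"retry budget exhausted: {len(metrics)} of {n_replicates} "
                f"replicates constructed after {attempts} draws"
            )
        attempts += 1
        idx = np.sort(draw_rng.choice(n_samples, size=n_subsample, replace=False))
        rep_seed = (
            int(draw_rng.integers(0, 2**31 - 1))
            if reseed_per_replicate
            else sparcc_params.seed
        )
        rep_rng = np.random.default_rng(rep_seed)
        try:
            net, met = _network_from_counts(
                counts[idx], taxa, sparcc_params, alpha, rep_rng
            )
        except SingularBasisError:
            discarded += 1
            continue
        metrics.append(met)
        networks.append(net)
        replicate_seeds.append(rep_seed)
    return SubsampleComparison(
        metrics=metrics,
        networks=networks,
        replicate_seeds=replicate_seeds,
        n_discarded=discarded,
    )


def representative_network(comparison: SubsampleComparison) -> CooccurrenceNetwork:
    """The replicate closest (z-scored Euclidean distance over edge count,
    density and clustering) to the replicate means; ties break to the lowest
    replicate index."""
    if not comparison.metrics:
        raise ValueError("no replicates to choose from")
    X = np.array([m.as_tuple() for m in comparison.metrics])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    dist = np.sqrt((((X - mu) / sd) ** 2).sum(axis=1))
    return comparison.networks[int(np.argmin(dist))]


def percent_change(before: float, after: float) -> float | None:
    """100 x (after - before) / before, rounded to two decimals; None when
    the baseline is zero (undefined, not infinite)."""
    if before == 0:
        return None
    return round(100.0 * (after - before) / before, 2)


@dataclass
class TimepointComparisonConfig:
    """Settings for a two-timepoint network comparison of one group."""

    alpha: float = 0.05
    n_subsample: int | None = 40
    n_replicates: int = 250
    sparcc_params: SparccParams = field(default_factory=SparccParams)
    seed: int = 0
    include_full_sample: bool = True


def _direct_metrics(
    counts: np.ndarray, taxa: list[str], cfg: TimepointComparisonConfig, salt: int
) -> NetworkMetrics:
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 23, salt]))
    _, met = _network_from_counts(counts, taxa, cfg.sparcc_params, cfg.alpha, rng)
    return met


def compare_timepoints(
    group_counts_1m: pd.DataFrame,
    group_counts_6m: pd.DataFrame,
    config: TimepointComparisonConfig | None = None,
) -> dict:
    """Per-timepoint network metrics and their percent change for one group.

    When the group is larger than ``n_subsample``, metrics are replicate
    means from the subsampling scheme; otherwise a single direct network is
    built. A full-sample (no subsampling) variant is also reported for
    comparison when subsampling was used.
    """
    config = config or TimepointComparisonConfig()
    if list(group_counts_1m.columns) != list(group_counts_6m.columns):
        raise ValueError("timepoints must share an identical taxon set")
    taxa = list(group_counts_1m.columns)
    out: dict = {"metrics": {}, "percent_change": {}, "full_sample": {}}
    per_tp: dict[str, dict[str, float]] = {}
    for salt, (tp, cnt) in enumerate(
        (("1m", group_counts_1m), ("6m", group_counts_6m))
    ):
        n = cnt.shape[0]
        use_subsample = (
            config.n_subsample is not None and n > config.n_subsample
        )
        if use_subsample:
            comp = subsample_networks(
                cnt,
                n_subsample=config.n_subsample,
                n_replicates=config.n_replicates,
                sparcc_params=config.sparcc_params,
                alpha=config.alpha,
                seed=config.seed + salt,
            )
            per_tp[tp] = comp.mean_metrics()
            out["metrics"][tp] = {
                **comp.mean_metrics(),
                "mode": "subsampled",
                "n_replicates": len(comp.metrics),
                "n_discarded": comp.n_discarded,
            }
            if config.include_full_sample:
                met = _direct_metrics(cnt.to_numpy(), taxa, config, 100 + salt)
                out["full_sample"][tp] = {
                    "n_edges": met.n_edges,
                    "edge_density": met.edge_density,
                    "avg_clustering": met.avg_clustering,
                }
        else:
            met = _direct_metrics(cnt.to_numpy(), taxa, config, salt)
            per_tp[tp] = {
                "n_edges": float(met.n_edges),
                "edge_density": met.edge_density,
                "avg_clustering": met.avg_clustering,
            }
            out["metrics"][tp] = {**per_tp[tp], "mode": "direct"}
    for key in ("n_edges", "edge_density", "avg_clustering"):
        out["percent_change"][key] = percent_change(
            per_tp["1m"][key], per_tp["6m"][key]
        )
    return out
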