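"""Synthetic paired two-timepoint gut-microbiome count data with known truth.

The generator emulates a postpartum cohort of 105 mothers (65 who gained
weight, 40 who lost weight) sampled at 1 and 6 months, with ~70 genus-level
taxa spanning 8 phyla. The generative model is the one compositional
correlation estimation assumes: a multivariate log-normal "basis" abundance
per sample, closed to a finite library size by multinomial sampling. Planted
structure — inter-taxon correlation blocks that differ by group x timepoint,
per-taxon fold changes at 6 months in the gain group, and an evenness drop
that lowers Shannon diversity — gives every downstream stage a ground truth
to recover.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import CountTable

__all__ = [
    "GROUPS",
    "TIMEPOINTS",
    "LibrarySizeLaw",
    "SyntheticConfig",
    "PlantedTruth",
    "default_lineages",
    "default_fold_changes",
    "default_basis_correlations",
    "block_correlation",
    "nearest_psd",
    "generate_basis",
    "sample_counts",
    "generate_study",
    "random_tree_newick",
]

GROUPS = ("gain", "loss")
TIMEPOINTS = ("1m", "6m")

# ---------------------------------------------------------------------------
# Default taxonomy: 70 genus-level taxa over 8 phyla, listed roughly in
# descending typical gut abundance. Entries with an empty genus represent
# features identifiable only to family ("Family X—unknown genus" after
# genus-level aggregation).
# (phylum, class, order, family, genus)
_TAXA: list[tuple[str, str, str, str, str]] = [
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidaceae", "Bacteroides"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Prevotella"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Faecalibacterium"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Blautia"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Ruminococcus"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Rikenellaceae", "Alistipes"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Roseburia"),
    ("Verrucomicrobia", "Verrucomicrobiae", "Verrucomicrobiales", "Verrucomicrobiaceae", "Akkermansia"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Porphyromonadaceae", "Parabacteroides"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Oscillospira"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Coprococcus"),
    ("Actinobacteria", "Actinobacteria", "Bifidobacteriales", "Bifidobacteriaceae", "Bifidobacterium"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Dorea"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Lachnospira"),
    ("Firmicutes", "Negativicutes", "Selenomonadales", "Veillonellaceae", "Dialister"),
    ("Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Alcaligenaceae", "Sutterella"),
    ("Firmicutes", "Negativicutes", "Selenomonadales", "Acidaminococcaceae", "Phascolarctobacterium"),
    ("Actinobacteria", "Coriobacteriia", "Coriobacteriales", "Coriobacteriaceae", "Collinsella"),
    ("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Clostridiaceae", "Clostridium"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Eubacteriaceae", "Eubacterium"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Odoribacteraceae", "Odoribacter"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Rikenellaceae", ""),
    ("Firmicutes", "Negativicutes", "Selenomonadales", "Veillonellaceae", "Veillonella"),
    ("Firmicutes", "Negativicutes", "Selenomonadales", "Veillonellaceae", "Megasphaera"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Paraprevotella"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Odoribacteraceae", "Butyricimonas"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Christensenellaceae", ""),
    ("Proteobacteria", "Gammaproteobacteria", "Pasteurellales", "Pasteurellaceae", "Haemophilus"),
    ("Proteobacteria", "Gammaproteobacteria", "Enterobacteriales", "Enterobacteriaceae", "Escherichia"),
    ("Thermodesulfobacteriota", "Desulfovibrionia", "Desulfovibrionales", "Desulfovibrionaceae", "Desulfovibrio"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Barnesiellaceae", "Barnesiella"),
    ("Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Lactobacillus"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Mogibacteriaceae", ""),
    ("Thermodesulfobacteriota", "Desulfovibrionia", "Desulfovibrionales", "Desulfovibrionaceae", "Bilophila"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Peptococcaceae", "Peptococcus"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Anaerostipes"),
    ("Actinobacteria", "Coriobacteriia", "Coriobacteriales", "Coriobacteriaceae", "Eggerthella"),
    ("Lentisphaerae", "Lentisphaeria", "Victivallales", "Victivallaceae", "Victivallis"),
    ("Actinobacteria", "Coriobacteriia", "Coriobacteriales", "Coriobacteriaceae", "Adlercreutzia"),
    ("Firmicutes", "Bacilli", "Turicibacterales", "Turicibacteraceae", "Turicibacter"),
    ("Proteobacteria", "Gammaproteobacteria", "Pasteurellales", "Pasteurellaceae", "Aggregatibacter"),
    ("Verrucomicrobia", "Opitutae", "Cerasicoccales", "Cerasicoccaceae", ""),
    ("Firmicutes", "Erysipelotrichia", "Erysipelotrichales", "Erysipelotrichaceae", "Holdemania"),
    ("Lentisphaerae", "Lentisphaeria", "Victivallales", "Victivallaceae", ""),
    ("Firmicutes", "Erysipelotrichia", "Erysipelotrichales", "Erysipelotrichaceae", "Catenibacterium"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Oribacterium"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Butyrivibrio"),
    ("Proteobacteria", "Gammaproteobacteria", "Enterobacteriales", "Enterobacteriaceae", "Klebsiella"),
    ("Firmicutes", "Bacilli", "Lactobacillales", "Enterococcaceae", "Enterococcus"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Porphyromonadaceae", "Porphyromonas"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Porphyromonadaceae", "Tannerella"),
    ("Verrucomicrobia", "Verrucomicrobiae", "Verrucomicrobiales", "Verrucomicrobiaceae", "Luteolibacter"),
    ("Actinobacteria", "Actinobacteria", "Actinomycetales", "Actinomycetaceae", "Actinomyces"),
    ("Proteobacteria", "Gammaproteobacteria", "Enterobacteriales", "Enterobacteriaceae", "Citrobacter"),
    ("Firmicutes", "Bacilli", "Gemellales", "Gemellaceae", "Gemella"),
    ("Firmicutes", "Bacilli", "Lactobacillales", "Carnobacteriaceae", "Granulicatella"),
    ("Proteobacteria", "Betaproteobacteria", "Neisseriales", "Neisseriaceae", "Neisseria"),
    ("Proteobacteria", "Epsilonproteobacteria", "Campylobacterales", "Campylobacteraceae", "Campylobacter"),
    ("Lentisphaerae", "Lentisphaeria", "Lentisphaerales", "Lentisphaeraceae", "Lentisphaera"),
    ("Verrucomicrobia", "Verrucomicrobiae", "Verrucomicrobiales", "Verrucomicrobiaceae", "Prosthecobacter"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Dysgonomonadaceae", "Dysgonomonas"),
    ("Bacteroidetes", "Flavobacteriia", "Flavobacteriales", "Flavobacteriaceae", "Flavobacterium"),
    ("Bacteroidetes", "Flavobacteriia", "Flavobacteriales", "Flavobacteriaceae", "Capnocytophaga"),
    ("Bacteroidetes", "Sphingobacteriia", "Sphingobacteriales", "Sphingobacteriaceae", "Sphingobacterium"),
    ("Firmicutes", "Bacilli", "Bacillales", "Staphylococcaceae", "Staphylococcus"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Clostridiaceae", "Sarcina"),
    ("Actinobacteria", "Actinobacteria", "Actinomycetales", "Corynebacteriaceae", "Corynebacterium"),
    ("Cyanobacteria", "Cyanophyceae", "Oscillatoriales", "Microcoleaceae", "Arthrospira"),
    ("Cyanobacteria", "Cyanophyceae", "Synechococcales", "Synechococcaceae", "Synechococcus"),
]


def _taxon_id(row: tuple[str, str, str, str, str]) -> str:
    phylum, _, _, family, genus = row
    return genus if genus else f"{family}_unknown"


def default_taxon_ids() -> list[str]:
    return [_taxon_id(r) for r in _TAXA]


def default_lineages() -> list[str]:
    """7-rank GREENGENES-style lineage strings for the default 70 taxa."""
    out = []
    for phylum, cls, order, family, genus in _TAXA:
        out.append(
            f"k__Bacteria; p__{phylum}; c__{cls}; o__{order}; "
            f"f__{family}; g__{genus}; s__"
        )
    return out


def _generic_lineages(n_taxa: int) -> list[str]:
    phyla = sorted({row[0] for row in _TAXA})
    out = []
    for j in range(n_taxa):
        p = phyla[j % len(phyla)]
        out.append(
            f"k__Bacteria; p__{p}; c__ClassX; o__OrderX; "
            f"f__Family{j:02d}; g__Genus{j:02d}; s__"
        )
    return out


def default_fold_changes(taxon_ids: list[str] | None = None) -> np.ndarray:
    """Multiplicative 6-month effects for the gain group.

    Magnitudes mirror the percent changes reported for the significant taxa
    (e.g. +85% for the Pasteurellaceae, +65% Streptococcus, -50% Akkermansia,
    -47% for the unknown Cerasicoccaceae genus); taxa without a planted
    effect get multiplier 1.
    """
    taxon_ids = taxon_ids or default_taxon_ids()
    planted = {
        "Prevotella": 1.09,
        "Faecalibacterium": 1.08,
        "Streptococcus": 1.65,
        "Veillonella": 1.51,
        "Haemophilus": 1.84,
        "Aggregatibacter": 1.85,
        "Collinsella": 0.81,
        "Eggerthella": 0.81,
        "Adlercreutzia": 0.81,
        "Mogibacteriaceae_unknown": 0.76,
        "Rikenellaceae_unknown": 0.80,
        "Christensenellaceae_unknown": 0.75,
        "Peptococcus": 0.63,
        "Oscillospira": 0.92,
        "Victivallis": 0.64,
        "Victivallaceae_unknown": 0.64,
        "Lentisphaera": 0.64,
        "Desulfovibrio": 0.75,
        "Cerasicoccaceae_unknown": 0.53,
        "Akkermansia": 0.50,
        "Luteolibacter": 0.60,
        "Prosthecobacter": 0.60,
    }
    return np.array([planted.get(t, 1.0) for t in taxon_ids])


def block_correlation(n_taxa: int, members: list[int], r: float) -> np.ndarray:
    """Identity correlation matrix with one constant-r block (always PSD for
    0 <= r < 1)."""
    C = np.eye(n_taxa)
    for a in members:
        for b in members:
            if a != b:
                C[a, b] = r
    return C


def default_basis_correlations(n_taxa: int = 70) -> dict[tuple[str, str], np.ndarray]:
    """Planted co-occurrence structure per (group, timepoint) cell.

    The gain group loses connectivity from 1 to 6 months (a 16-taxon
    correlated block shrinks to 10 taxa); the loss group keeps its block but
    its internal correlation strengthens (clustering rises while edge count
    stays comparable).
    """
    def _members(lo: int, hi: int) -> list[int]:
        return [m for m in range(lo, hi) if m < n_taxa]

    gain_1m = block_correlation(n_taxa, _members(2, 18), 0.60)
    gain_6m = block_correlation(n_taxa, _members(2, 12), 0.60)
    loss_1m = block_correlation(n_taxa, _members(20, 32) or _members(2, 8), 0.45)
    loss_6m = block_correlation(n_taxa, _members(20, 32) or _members(2, 8), 0.65)
    return {
        ("gain", "1m"): gain_1m,
        ("gain", "6m"): gain_6m,
        ("loss", "1m"): loss_1m,
        ("loss", "6m"): loss_6m,
    }


def nearest_psd(C: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Eigenvalue-clipping repair of a nearly-PSD correlation matrix, with
    the diagonal rescaled back to 1."""
    w, V = np.linalg.eigh((C + C.T) / 2.0)
    if w.min() >= -tol:
        return C
    w = np.clip(w, 0.0, None)
    R = (V * w) @ V.T
    d = np.sqrt(np.clip(np.diag(R), tol, None))
    R = R / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


@dataclass
class LibrarySizeLaw:
    """Truncated log-normal law for per-sample read depth.

    Defaults target the observed depth distribution: range [12, 64069] with
    a median near 30,785 reads.
    """

    mu: float = float(np.log(30_785.0))
    sigma: float = 0.55
    lower: int = 12
    upper: int = 64_069

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        out = np.empty(n, dtype=np.int64)
        filled = 0
        while filled < n:
            x = np.exp(rng.normal(self.mu, self.sigma, size=2 * (n - filled)))
            x = x[(x >= self.lower) & (x <= self.upper)]
            take = min(len(x), n - filled)
            out[filled:filled + take] = np.round(x[:take]).astype(np.int64)
            filled += take
        return out


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions.

    ``mean_log_abundance`` sets the rank-abundance profile of the 70 genera
    (taxa are listed in roughly descending typical gut abundance);
    ``fold_changes`` multiply the gain-group basis at 6 months;
    ``dominance_factor`` additionally scales the most abundant taxon at
    6 months in the gain group, planting the Shannon-diversity drop;
    ``subject_sd`` is the per-subject, per-taxon log-scale random effect
    shared between a subject's two timepoints (what makes pairing
    informative); ``dropout`` optionally zeroes basis entries to emulate
    extra sparsity (0 keeps the closure exact).
    """

    n_gain: int = 65
    n_loss: int = 40
    n_taxa: int = 70
    lineages: list[str] = field(default_factory=default_lineages)
    taxon_ids: list[str] | None = None
    library_size_law: LibrarySizeLaw = field(default_factory=LibrarySizeLaw)
    basis_correlations: dict[tuple[str, str], np.ndarray] | None = None
    fold_changes: np.ndarray | None = None
    dominance_factor: float = 3.5
    mean_log_abundance: np.ndarray | None = None
    log_variance: float = 1.0
    subject_sd: float = 0.6
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_gain < 1 or self.n_loss < 1 or self.n_taxa < 2:
            raise ValueError("cohort and taxon counts must be positive")
        if len(self.lineages) != self.n_taxa:
            if self.lineages == default_lineages():
                self.lineages = _generic_lineages(self.n_taxa)
            else:
                raise ValueError(
                    f"n_taxa={self.n_taxa} but {len(self.lineages)} lineages given"
                )
        if self.taxon_ids is None:
            if self.lineages == default_lineages():
                self.taxon_ids = default_taxon_ids()
            else:
                from .preprocess import parse_lineage

                ids = []
                for j, lin in enumerate(self.lineages):
                    r = parse_lineage(lin)
                    ids.append(r["genus"] or f"{r['family'] or 'taxon'}_unknown{j}")
                # force uniqueness
                seen: dict[str, int] = {}
                uniq = []
                for t in ids:
                    k = seen.get(t, 0)
                    seen[t] = k + 1
                    uniq.append(t if k == 0 else f"{t}.{k}")
                self.taxon_ids = uniq
        if len(self.taxon_ids) != self.n_taxa:
            raise ValueError("taxon_ids length must equal n_taxa")
        if self.basis_correlations is None:
            self.basis_correlations = default_basis_correlations(self.n_taxa)
        for cell, C in self.basis_correlations.items():
            C = np.asarray(C, dtype=float)
            if C.shape != (self.n_taxa, self.n_taxa):
                raise ValueError(f"basis_correlations[{cell}] has shape {C.shape}")
            if not np.allclose(C, C.T, atol=1e-10):
                raise ValueError(f"basis_correlations[{cell}] is not symmetric")
            if not np.allclose(np.diag(C), 1.0, atol=1e-10):
                raise ValueError(f"basis_correlations[{cell}] diagonal is not 1")
            w = np.linalg.eigvalsh((C + C.T) / 2.0)
            if w.min() < -1e-8:
                warnings.warn(
                    f"basis_correlations[{cell}] is not positive semi-definite "
                    f"(min eigenvalue {w.min():.3g}); applying nearest-PSD repair",
                    UserWarning,
                )
                C = nearest_psd(C)
            self.basis_correlations[cell] = C
        if self.fold_changes is None:
            if self.taxon_ids == default_taxon_ids():
                self.fold_changes = default_fold_changes(self.taxon_ids)
            else:
                self.fold_changes = np.ones(self.n_taxa)
        self.fold_changes = np.asarray(self.fold_changes, dtype=float)
        if self.fold_changes.shape != (self.n_taxa,):
            raise ValueError("fold_changes must have one multiplier per taxon")
        if (self.fold_changes <= 0).any():
            raise ValueError("fold_changes must be strictly positive multipliers")
        if self.dominance_factor <= 0:
            raise ValueError("dominance_factor must be strictly positive")
        if self.mean_log_abundance is None:
            # descending rank-abundance profile; spread of ~e^6 between the
            # most and least abundant genus
            self.mean_log_abundance = np.linspace(3.2, -2.8, self.n_taxa)
        self.mean_log_abundance = np.asarray(self.mean_log_abundance, dtype=float)
        if self.mean_log_abundance.shape != (self.n_taxa,):
            raise ValueError("mean_log_abundance must have one entry per taxon")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    # ------------------------------------------------------------------
    def cell_multipliers(self, group: str, timepoint: str) -> np.ndarray:
        """Effective per-taxon basis multipliers for one design cell."""
        mult = np.ones(self.n_taxa)
        if group == "gain" and timepoint == "6m":
            mult = self.fold_changes.copy()
            mult[int(np.argmax(self.mean_log_abundance))] *= self.dominance_factor
        return mult

    def expected_relative_abundance(self, group: str, timepoint: str) -> np.ndarray:
        """Large-sample expected composition of one cell (log-normal means
        under the planted multipliers, closed to sum 1)."""
        m = np.exp(self.mean_log_abundance) * self.cell_multipliers(group, timepoint)
        return m / m.sum()

    @classmethod
    def null(cls, **kwargs) -> "SyntheticConfig":
        """A no-effect configuration: identical correlation structure in all
        cells, all fold changes 1, no dominance shift."""
        n_taxa = kwargs.pop("n_taxa", 70)
        base = block_correlation(n_taxa, list(range(2, 12)), 0.5)
        cells = {(g, t): base.copy() for g in GROUPS for t in TIMEPOINTS}
        kwargs.setdefault("basis_correlations", cells)
        kwargs.setdefault("fold_changes", np.ones(n_taxa))
        kwargs.setdefault("dominance_factor", 1.0)
        return cls(n_taxa=n_taxa, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("n_gain", "n_loss", "n_taxa", "seed", "dominance_factor",
                    "log_variance", "subject_sd", "dropout"):
            if key in raw:
                kwargs[key] = raw[key]
        if "lineages" in raw:
            kwargs["lineages"] = list(raw["lineages"])
        if "library_size_law" in raw:
            kwargs["library_size_law"] = LibrarySizeLaw(**raw["library_size_law"])
        if "fold_changes" in raw:
            kwargs["fold_changes"] = np.asarray(raw["fold_changes"], dtype=float)
        if "correlation_blocks" in raw:
            n_taxa = kwargs.get("n_taxa", 70)
            cells = {(g, t): np.eye(n_taxa) for g in GROUPS for t in TIMEPOINTS}
            for blk in raw["correlation_blocks"]:
                key = (blk["group"], blk["timepoint"])
                cells[key] = block_correlation(n_taxa, list(blk["taxa"]), float(blk["r"]))
            kwargs["basis_correlations"] = cells
        return cls(**kwargs)


@dataclass
class PlantedTruth:
    """Ground truth planted into one synthetic study.

    ``true_fold_changes`` are expected *relative-abundance* ratios
    (6 months / 1 month, gain group) — i.e. the planted basis multipliers
    after compositional closure, which is what abundance testing can see.
    ``true_diversity_shift`` is the change in effective genus count
    (2**Shannon, bits) of the expected composition per group.
    """

    true_correlations: dict[tuple[str, str], np.ndarray]
    true_fold_changes: np.ndarray
    true_diversity_shift: dict[str, float]
    expected_composition: dict[tuple[str, str], np.ndarray]


# ---------------------------------------------------------------------------
# Generation


def _cell_rng(config: SyntheticConfig, group: str, timepoint: str) -> np.random.Generator:
    gi, ti = GROUPS.index(group), TIMEPOINTS.index(timepoint)
    return np.random.default_rng(np.random.SeedSequence([config.seed, 7, gi, ti]))


def generate_basis(
    config: SyntheticConfig,
    group: str,
    timepoint: str,
    n_samples: int,
    rng: np.random.Generator | None = None,
    subject_effects: np.ndarray | None = None,
) -> np.ndarray:
    """Draw an (n_samples x n_taxa) strictly positive latent abundance
    matrix whose log has the configured marginal variance and the planted
    correlation matrix of the requested design cell."""
    key = (group, timepoint)
    if key not in config.basis_correlations:
        raise KeyError(f"no basis_correlations entry for cell {key}")
    if n_samples < 0:
        raise ValueError("n_samples must be non-negative")
    rng = rng or _cell_rng(config, group, timepoint)
    C = config.basis_correlations[key]
    w, V = np.linalg.eigh(C)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((n_samples, config.n_taxa)) @ L.T
    logs = config.mean_log_abundance + np.sqrt(config.log_variance) * z
    if subject_effects is not None:
        logs = logs + subject_effects
    logs = logs + np.log(config.cell_multipliers(group, timepoint))
    return np.exp(logs)


def sample_counts(
    basis: np.ndarray,
    library_sizes: np.ndarray,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Close each basis row to integer counts by multinomial sampling at the
    given library size; row i sums exactly to ``library_sizes[i]``."""
    basis = np.asarray(basis, dtype=float)
    if (basis < 0).any():
        raise ValueError("basis abundances must be non-negative")
    libs = np.asarray(library_sizes)
    if libs.shape != (basis.shape[0],):
        raise ValueError("need one library size per basis row")
    if (libs < 0).any():
        raise ValueError("library sizes must be non-negative integers")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = np.zeros(basis.shape, dtype=np.int64)
    for i in range(basis.shape[0]):
        tot = basis[i].sum()
        if tot == 0 or libs[i] == 0:
            continue
        out[i] = rng.multinomial(int(libs[i]), basis[i] / tot)
    return out


def random_tree_newick(leaf_names: list[str], rng: np.random.Generator) -> str:
    """Random rooted bifurcating topology over the leaves with exponential
    branch lengths (mean 0.1)."""

    def build(names: list[str]) -> str:
        if len(names) == 1:
            return f"{names[0]}:{rng.exponential(0.1):.6f}"
        k = int(rng.integers(1, len(names)))
        return (
            f"({build(names[:k])},{build(names[k:])}):{rng.exponential(0.1):.6f}"
        )

    names = list(leaf_names)
    perm = rng.permutation(len(names))
    names = [names[i] for i in perm]
    if len(names) == 1:
        return f"({names[0]}:{rng.exponential(0.1):.6f});"
    k = int(rng.integers(1, len(names)))
    return f"({build(names[:k])},{build(names[k:])});"


def _shannon_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def generate_study(
    config: SyntheticConfig,
) -> tuple[CountTable, pd.DataFrame, str, PlantedTruth]:
    """Generate the full paired cohort.

    Returns the count table (2 x (n_gain + n_loss) samples), sample
    metadata (subject, timepoint, weight group, weights), a rooted newick
    tree over the taxa, and the planted truth. Identical config (including
    seed) gives bit-identical output.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_subjects = config.n_gain + config.n_loss
    subjects = [f"S{i + 1:03d}" for i in range(n_subjects)]
    groups = ["gain"] * config.n_gain + ["loss"] * config.n_loss

    # per-subject, per-taxon log-scale effect shared across timepoints
    subj_eff = rng.normal(0.0, config.subject_sd, size=(n_subjects, config.n_taxa))

    rows, sample_ids, meta_rows = [], [], []
    # weights: gain group trends up ~+4.1 kg, loss group down ~-3.4 kg
    w1 = np.where(
        np.array(groups) == "gain",
        rng.normal(74.57, 13.40, n_subjects),
        rng.normal(71.50, 12.33, n_subjects),
    ).clip(45.0, 130.0)
    delta = np.where(
        np.array(groups) == "gain",
        np.abs(rng.normal(4.11, 2.5, n_subjects)),
        -np.abs(rng.normal(3.36, 2.0, n_subjects)),
    )
    w6 = w1 + delta
    pre_preg = w6 + rng.normal(0.0, 7.0, n_subjects)
    age = rng.normal(29.4, 6.4, n_subjects).clip(18.0, 45.0)
    # sparse antibiotic usage: ~7.7% of the gain group, ~10% of the loss group
    antibiotics = np.zeros(n_subjects, dtype=bool)
    antibiotics[: max(1, round(0.077 * config.n_gain))] = True
    n_loss_ab = max(1, round(0.10 * config.n_loss))
    antibiotics[config.n_gain: config.n_gain + n_loss_ab] = True

    for tp in TIMEPOINTS:
        for g in GROUPS:
            idx = [i for i, gg in enumerate(groups) if gg == g]
            cell_rng = np.random.default_rng(
                np.random.SeedSequence(
                    [config.seed, 2, GROUPS.index(g), TIMEPOINTS.index(tp)]
                )
            )
            basis = generate_basis(
                config, g, tp, len(idx), rng=cell_rng,
                subject_effects=subj_eff[idx],
            )
            if config.dropout > 0:
                mask = cell_rng.random(basis.shape) < config.dropout
                basis = np.where(mask, 0.0, basis)
            libs = config.library_size_law.draw(cell_rng, len(idx))
            counts = sample_counts(basis, libs, seed=cell_rng)
            for row, i in zip(counts, idx):
                rows.append(row)
                sid = f"{subjects[i]}_{tp}"
                sample_ids.append(sid)
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "subject_id": subjects[i],
                        "timepoint": tp,
                        "weight_group": g,
                        "weight_kg": round(float(w1[i] if tp == "1m" else w6[i]), 2),
                        "pre_pregnancy_weight_kg": round(float(pre_preg[i]), 2),
                        "age_years": round(float(age[i]), 1),
                        "antibiotics": "yes" if antibiotics[i] else "no",
                    }
                )

    counts_df = pd.DataFrame(
        np.vstack(rows), index=sample_ids, columns=config.taxon_ids
    )
    table = CountTable(counts_df, pd.Series(config.lineages, index=config.taxon_ids))
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")

    tree_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    newick = random_tree_newick(config.taxon_ids, tree_rng)

    comp = {
        (g, t): config.expected_relative_abundance(g, t)
        for g in GROUPS
        for t in TIMEPOINTS
    }
    truth = PlantedTruth(
        true_correlations={k: v.copy() for k, v in config.basis_correlations.items()},
        true_fold_changes=comp[("gain", "6m")] / comp[("gain", "1m")],
        true_diversity_shift={
            g: 2.0 ** _shannon_bits(comp[(g, "6m")]) - 2.0 ** _shannon_bits(comp[(g, "1m")])
            for g in GROUPS
        },
        expected_composition=comp,
    )
    return table, metadata, newick, truth
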