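"""Alpha diversity on rarefied counts, paired timepoint testing, and
Bray-Curtis beta diversity with PERMANOVA."""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

__all__ = [
    "AlphaDiversityResult",
    "PermanovaResult",
    "richness",
    "shannon",
    "faiths_pd",
    "alpha_diversity_table",
    "paired_ttest",
    "bray_curtis",
    "permanova",
    "mean_within_group_dissimilarity",
]


@dataclass
class PermanovaResult:
    """Distance-based variance decomposition test of a grouping factor."""

    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int


# ---------------------------------------------------------------------------
# alpha diversity


def richness(sample: np.ndarray) -> int:
    """Number of taxa with a non-zero count."""
    return int(np.count_nonzero(np.asarray(sample)))


def shannon(sample: np.ndarray, base: float = 2.0) -> float:
    """Shannon entropy of the sample's composition (bits by default)."""
    x = np.asarray(sample, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("Shannon entropy is undefined for a zero-total sample")
    p = x[x > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def _load_tree(tree: TreeNode | str) -> TreeNode:
    if isinstance(tree, TreeNode):
        return tree
    t = TreeNode.read(StringIO(tree))
    # newick readers map underscores to spaces; undo to match taxon ids
    for tip in t.tips():
        if tip.name:
            tip.name = tip.name.replace(" ", "_")
    return t


def faiths_pd(
    sample: np.ndarray, taxa: list[str], tree: TreeNode | str
) -> float:
    """Faith's phylogenetic diversity: total branch length of the minimal
    rooted subtree spanning the observed taxa.

    Uses the rooted convention: branches from the root down to the observed
    leaves are all included, so observing every leaf returns the tree's
    total branch length.
    """
    t = _load_tree(tree)
    sample = np.asarray(sample)
    observed = {taxa[j] for j in range(len(taxa)) if sample[j] > 0}
    if not observed:
        return 0.0
    leaf_names = {leaf.name for leaf in t.tips()}
    missing = observed - leaf_names
    if missing:
        raise ValueError(f"observed taxa missing from tree: {sorted(missing)[:5]}")
    total = 0.0
    # postorder: mark every node whose subtree holds an observed leaf and
    # sum the branch lengths of marked non-root nodes
    marked: dict[int, bool] = {}
    for node in t.postorder():
        if node.is_tip():
            hit = node.name in observed
        else:
            hit = any(marked[id(c)] for c in node.children)
        marked[id(node)] = hit
        if hit and not node.is_root() and node.length is not None:
            total += float(node.length)
    return total


def alpha_diversity_table(
    counts: pd.DataFrame, tree: TreeNode | str | None = None, base: float = 2.0
) -> pd.DataFrame:
    """Per-sample richness, Shannon entropy and (when a tree is given)
    Faith's PD, from a rarefied samples x taxa table."""
    t = _load_tree(tree) if tree is not None else None
    taxa = list(counts.columns)
    rows = {}
    for sid, row in counts.iterrows():
        vals = row.to_numpy()
        entry = {
            "richness": richness(vals),
            "shannon": shannon(vals, base=base),
        }
        if t is not None:
            entry["faith_pd"] = faiths_pd(vals, taxa, t)
        rows[sid] = entry
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# paired testing


def paired_ttest(
    values_1m: pd.Series, values_6m: pd.Series, subject_pairing: pd.Series | None = None
) -> tuple[float, float]:
    """Two-sided paired t-test on per-subject differences.

    ``values_*`` are indexed by subject (or by sample with
    ``subject_pairing`` mapping sample -> subject). Subjects missing either
    timepoint raise; so do all-identical differences (zero variance).
    """
    v1, v6 = pd.Series(values_1m), pd.Series(values_6m)
    if subject_pairing is not None:
        v1 = v1.groupby(subject_pairing.reindex(v1.index)).mean()
        v6 = v6.groupby(subject_pairing.reindex(v6.index)).mean()
    unpaired = v1.index.symmetric_difference(v6.index)
    if len(unpaired):
        raise ValueError(f"subjects missing a timepoint: {list(unpaired)[:5]}")
    if len(v1) < 2:
        raise ValueError("need at least 2 pairs")
    diff = (v6 - v1.reindex(v6.index)).to_numpy(dtype=float)
    if np.allclose(diff.std(ddof=1), 0.0):
        raise ValueError("zero-variance differences: paired t is undefined")
    t, p = stats.ttest_rel(v6.to_numpy(dtype=float), v1.reindex(v6.index).to_numpy(dtype=float))
    return float(t), float(p)


# ---------------------------------------------------------------------------
# beta diversity


def bray_curtis(abundance: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity: sum|u-v| / sum(u+v), in [0, 1]."""
    if isinstance(abundance, pd.DataFrame):
        index = abundance.index
        X = abundance.to_numpy(dtype=float)
    else:
        X = np.asarray(abundance, dtype=float)
        index = pd.RangeIndex(X.shape[0])
    if (X < 0).any():
        raise ValueError("abundances must be non-negative")
    if (X.sum(axis=1) == 0).any():
        bad = list(index[X.sum(axis=1) == 0])
        raise ValueError(f"zero-total samples have no composition: {bad[:5]}")
    D = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(D, index=index, columns=index)


def _permanova_ss(D2: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    n = D2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = D2[iu].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = D2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return ss_total, ss_within, ss_total - ss_within


def permanova(
    distance_matrix: pd.DataFrame | np.ndarray,
    grouping,
    n_permutations: int = 999,
    seed: int | np.random.Generator = 0,
    strata=None,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Pseudo-F comes from the squared-distance sum decomposition (between vs
    within groups); the p-value counts label permutations with F_perm >=
    F_obs, with the +1 pseudo-count on both sides. ``strata`` (e.g. subject
    ids in a paired design) restricts permutations to relabelings within
    each stratum; the default is free permutation.
    """
    D = np.asarray(distance_matrix, dtype=float)
    labels = np.asarray(pd.Series(list(grouping)))
    n = D.shape[0]
    if labels.shape[0] != n:
        raise ValueError("grouping length must match the distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 samples each")
    a = len(uniq)
    D2 = D**2

    def f_stat(lab: np.ndarray) -> float:
        ss_total, ss_within, ss_between = _permanova_ss(D2, lab)
        return (ss_between / (a - 1)) / (ss_within / (n - a))

    ss_total, ss_within, ss_between = _permanova_ss(D2, labels)
    f_obs = (ss_between / (a - 1)) / (ss_within / (n - a))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if strata is not None:
        strata = np.asarray(pd.Series(list(strata)))
        if strata.shape[0] != n:
            raise ValueError("strata length must match the distance matrix")
        strata_idx = [np.flatnonzero(strata == s) for s in np.unique(strata)]

    def permute(lab: np.ndarray) -> np.ndarray:
        if strata is None:
            return rng.permutation(lab)
        out = lab.copy()
        for idx in strata_idx:
            out[idx] = lab[idx][rng.permutation(len(idx))]
        return out

    hits = 0
    for _ in range(n_permutations):
        hits += f_stat(permute(labels)) >= f_obs
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r_squared=float(ss_between / ss_total),
        p_value=float((1 + hits) / (1 + n_permutations)),
        n_permutations=n_permutations,
    )


def mean_within_group_dissimilarity(
    distance_matrix: pd.DataFrame, grouping: pd.Series
) -> dict[str, float]:
    """Arithmetic mean of the pairwise dissimilarities within each group."""
    D = np.asarray(distance_matrix, dtype=float)
    labels = pd.Series(list(grouping))
    out: dict[str, float] = {}
    for g in labels.unique():
        idx = np.flatnonzero((labels == g).to_numpy())
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        sub = D[np.ix_(idx, idx)]
        out[g] = float(sub[np.triu_indices(len(idx), k=1)].mean())
    return out


#: alias kept for symmetry with the per-sample metric names
AlphaDiversityResult = pd.DataFrame
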