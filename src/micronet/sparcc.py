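"""SparCC-style compositional correlation inference with permutation p-values.

Naive Pearson correlation of relative abundances is biased by closure (the
proportions of a sample must sum to one). The estimator implemented here
works around the closure by modelling the variance of pairwise log ratios:
for basis abundances w_i, t_ij = Var[log(x_i/x_j)] = omega_i^2 + omega_j^2
- 2 rho_ij omega_i omega_j, and under approximate sparsity of the true
correlation network the basis variances omega^2 solve a linear system in
the row sums of T. Counts are treated probabilistically: each sample's
fractions are resampled from Dirichlet(counts + 1) a number of times, the
basis correlations are re-estimated per draw with iterative exclusion of
the most strongly correlated pair, and the median over draws is reported.

Significance is assessed by a permutation null that shuffles every taxon's
counts across samples independently, destroying co-occurrence while keeping
marginals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SparccParams",
    "CorrelationResult",
    "SingularBasisError",
    "draw_fractions",
    "log_ratio_variances",
    "estimate_basis",
    "sparcc",
    "bootstrap_pvalues",
    "correlation_and_pvalues",
]


class SingularBasisError(RuntimeError):
    """The basis-variance linear system is singular — typically because the
    exclusion loop removed every usable pair of some taxon, or the input had
    too few distinct taxa. The subsampling scheme catches this to redraw."""


@dataclass
class SparccParams:
    """Estimator settings.

    ``n_estimation_iterations`` Dirichlet resampling draws are aggregated by
    the median; ``exclusion_threshold`` is the |r| above which the single
    most-correlated pair is dropped from basis estimation each round (up to
    ``max_exclusion_rounds`` rounds); ``n_bootstraps`` controls permutation
    p-value resolution; ``variance_floor`` guards against degenerate basis
    variances.
    """

    n_estimation_iterations: int = 20
    exclusion_threshold: float = 0.1
    max_exclusion_rounds: int = 10
    n_bootstraps: int = 1000
    variance_floor: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.exclusion_threshold < 1.0:
            raise ValueError("exclusion_threshold must lie in (0, 1)")
        if self.n_estimation_iterations < 1:
            raise ValueError("n_estimation_iterations must be positive")
        if self.max_exclusion_rounds < 0:
            raise ValueError("max_exclusion_rounds must be non-negative")
        if self.variance_floor <= 0:
            raise ValueError("variance_floor must be positive")


@dataclass
class CorrelationResult:
    """Symmetric correlation matrix, matching two-sided permutation
    p-values, and the taxon labels they index."""

    r: np.ndarray
    p: np.ndarray
    taxa: list[str]
    params: SparccParams = field(default_factory=SparccParams)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        d = len(self.taxa)
        if self.r.shape != (d, d) or self.p.shape != (d, d):
            raise ValueError("r and p must be square over the taxon labels")
        if not np.allclose(self.r, self.r.T, atol=1e-9):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(self.p, self.p.T, atol=1e-9):
            raise ValueError("p-value matrix must be symmetric")

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        r = pd.DataFrame(self.r, index=self.taxa, columns=self.taxa)
        p = pd.DataFrame(self.p, index=self.taxa, columns=self.taxa)
        return r, p


# ---------------------------------------------------------------------------


def draw_fractions(counts: np.ndarray, seed: int | np.random.Generator = 0) -> np.ndarray:
    """One Dirichlet(counts + 1) draw of compositional fractions per sample;
    rows sum to 1 and are strictly positive."""
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = rng.standard_gamma(counts + 1.0)
    return g / g.sum(axis=1, keepdims=True)


def log_ratio_variances(fractions: np.ndarray) -> np.ndarray:
    """Matrix T with t_ij = sample variance of log(x_i/x_j) over samples
    (symmetric, zero diagonal)."""
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape[0] < 2:
        raise ValueError("need at least 2 samples to form log-ratio variances")
    if (fractions <= 0).any():
        raise ValueError("fractions must be strictly positive")
    L = np.log(fractions)
    C = np.cov(L, rowvar=False)
    v = np.diag(C)
    T = v[:, None] + v[None, :] - 2.0 * C
    np.fill_diagonal(T, 0.0)
    return T


def estimate_basis(
    T: np.ndarray,
    excluded_pairs: set[tuple[int, int]] | None = None,
    variance_floor: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the sparsity-approximation linear system for basis variances
    and convert to basis correlations.

    With no exclusions the system is M w = t with M = (D-2) I + 11' and
    t_i = sum_j t_ij; each excluded pair removes its t_ij contribution and
    the matching coefficients. Returns (omega^2, r) with r clamped to
    [-1, 1] and unit diagonal.
    """
    T = np.asarray(T, dtype=float)
    d = T.shape[0]
    if d < 3:
        raise SingularBasisError(f"basis system needs >= 3 taxa, got {d}")
    excluded = excluded_pairs or set()
    M = np.ones((d, d)) + (d - 2.0) * np.eye(d)
    t = T.sum(axis=1)
    for (i, j) in excluded:
        t[i] -= T[i, j]
        t[j] -= T[i, j]
        M[i, i] -= 1.0
        M[j, j] -= 1.0
        M[i, j] -= 1.0
        M[j, i] -= 1.0
    # a taxon whose pairs are all excluded has no information left
    remaining = np.full(d, d - 1)
    for (i, j) in excluded:
        remaining[i] -= 1
        remaining[j] -= 1
    if (remaining <= 0).any():
        bad = int(np.argmin(remaining))
        raise SingularBasisError(
            f"taxon index {bad} has no non-excluded pairs left"
        )
    try:
        om2 = np.linalg.solve(M, t)
    except np.linalg.LinAlgError as err:
        raise SingularBasisError(f"basis system is singular: {err}") from err
    if not np.isfinite(om2).all():
        raise SingularBasisError("basis variance solution is not finite")
    om2 = np.clip(om2, variance_floor, None)
    w = np.sqrt(om2)
    r = (om2[:, None] + om2[None, :] - T) / (2.0 * np.outer(w, w))
    r = np.clip(r, -1.0, 1.0)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return om2, r


def _single_estimate(T: np.ndarray, params: SparccParams) -> np.ndarray:
    """One exclusion-iterated correlation estimate from a T matrix."""
    d = T.shape[0]
    excluded: set[tuple[int, int]] = set()
    r = None
    for _ in range(params.max_exclusion_rounds + 1):
        _, r = estimate_basis(T, excluded, params.variance_floor)
        absr = np.abs(r.copy())
        np.fill_diagonal(absr, 0.0)
        for (i, j) in excluded:
            absr[i, j] = absr[j, i] = 0.0
        flat = int(np.argmax(absr))
        i, j = divmod(flat, d)
        if absr[i, j] <= params.exclusion_threshold or len(excluded) >= params.max_exclusion_rounds:
            break
        excluded.add((min(i, j), max(i, j)))
    return r


def sparcc(
    counts: np.ndarray,
    params: SparccParams | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Median-aggregated SparCC correlation estimate from raw counts."""
    params = params or SparccParams()
    counts = np.asarray(counts)
    if counts.shape[1] < 4:
        raise ValueError("need at least 4 taxa for a well-posed basis system")
    if counts.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    rng = rng or np.random.default_rng(params.seed)
    estimates = np.empty((params.n_estimation_iterations, counts.shape[1], counts.shape[1]))
    for k in range(params.n_estimation_iterations):
        fr = draw_fractions(counts, rng)
        T = log_ratio_variances(fr)
        estimates[k] = _single_estimate(T, params)
    r = np.median(estimates, axis=0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def _permute_columns(counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    idx = rng.random(counts.shape).argsort(axis=0)
    return counts[idx, np.arange(counts.shape[1])]


def bootstrap_pvalues(
    counts: np.ndarray,
    r_observed: np.ndarray,
    params: SparccParams | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Two-sided permutation p-values for every pair.

    Each replicate permutes every taxon's counts across samples
    independently, re-runs the full estimator, and counts replicates with
    |r_perm| >= |r_obs|; p = (1 + exceedances) / (1 + n_bootstraps), so p is
    never 0 and never below the permutation floor. Replicates that hit a
    singular basis system are redrawn (bounded retries).
    """
    params = params or SparccParams()
    if params.n_bootstraps < 1:
        raise ValueError("n_bootstraps must be positive")
    counts = np.asarray(counts)
    rng = rng or np.random.default_rng(np.random.SeedSequence([params.seed, 101]))
    abs_obs = np.abs(np.asarray(r_observed))
    exceed = np.zeros_like(abs_obs)
    done, attempts = 0, 0
    max_attempts = 10 * params.n_bootstraps
    while done < params.n_bootstraps:
        if attempts >= max_attempts:
            raise SingularBasisError(
                f"permutation null kept failing: {done} of "
                f"{params.n_bootstraps} replicates completed"
            )
        attempts += 1
        perm = _permute_columns(counts, rng)
        try:
            r_b = sparcc(perm, params, rng=rng)
        except SingularBasisError:
            continue
        exceed += np.abs(r_b) >= abs_obs
        done += 1
    p = (1.0 + exceed) / (1.0 + params.n_bootstraps)
    p = np.clip((p + p.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(p, 1.0)
    return p


def correlation_and_pvalues(
    counts: np.ndarray,
    taxa: list[str],
    params: SparccParams | None = None,
    rng: np.random.Generator | None = None,
) -> CorrelationResult:
    """Convenience wrapper: estimate correlations, then permutation
    p-values, on the same counts."""
    params = params or SparccParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    r = sparcc(counts, params, rng=rng)
    p = bootstrap_pvalues(counts, r, params, rng=rng)
    return CorrelationResult(r=r, p=p, taxa=list(taxa), params=replace(params))
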