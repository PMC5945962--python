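"""Event-sequence inference: likelihood, search, MCMC, positional variance.

The data likelihood of an event ordering S over Z biomarkers for N subjects is

    P(X|S) = prod_j sum_{k=0..Z} P(k) prod_{i<=k} P(x_ij|E_si)
                                  prod_{i>k}  P(x_ij|not-E_si)

with a uniform stage prior P(k) = 1/(Z+1).  Everything here works in log
space: for each subject the stage terms are prefix sums of the per-biomarker
log-density differences along the ordering, combined with log-sum-exp, so one
evaluation costs O(N*Z) and never underflows.

The maximum-likelihood ordering is found by greedy pairwise-swap ascent from
random restarts; posterior uncertainty over orderings is sampled by
Metropolis-Hastings with symmetric random pairwise-swap proposals and
summarised as a positional variance diagram (PVD): the fraction of posterior
samples placing each biomarker at each sequence position.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

__all__ = [
    "MCMCTrace",
    "PositionalVarianceDiagram",
    "sequence_log_likelihood",
    "stage_log_likelihoods",
    "find_ml_sequence",
    "mcmc_sample",
    "positional_variance",
    "exhaustive_ml_sequence",
]

MAX_EXHAUSTIVE_Z = 8


def _check_sequence(order, z: int) -> np.ndarray:
    order = np.asarray(order, dtype=int)
    if order.shape != (z,) or sorted(order.tolist()) != list(range(z)):
        raise ValueError(f"sequence must be a permutation of 0..{z - 1}")
    return order


def stage_log_likelihoods(table, order) -> np.ndarray:
    """Per-subject log P(X_j, k | S) for every stage k = 0..Z.

    Row j, column k is the log joint of subject j's data with stage k under
    ordering ``order`` (uniform stage prior included).  Eq.-1-style dataset
    likelihoods and per-subject staging both reduce to this array.
    """
    order = _check_sequence(order, table.n_biomarkers)
    lpe = table.log_p_event[:, order]
    lpn = table.log_p_not_event[:, order]
    base = lpn.sum(axis=1, keepdims=True)          # stage 0: nothing abnormal
    diff = np.cumsum(lpe - lpn, axis=1)            # switching prefix to abnormal
    stage_ll = np.concatenate([base, base + diff], axis=1)
    return stage_ll - np.log(table.n_biomarkers + 1)


def sequence_log_likelihood(table, order) -> float:
    """Log data likelihood of an ordering (log of the Eq.-1 product)."""
    stage_ll = stage_log_likelihoods(table, order)
    m = stage_ll.max(axis=1, keepdims=True)
    per_subject = m[:, 0] + np.log(np.exp(stage_ll - m).sum(axis=1))
    return float(per_subject.sum())


def _greedy_ascent(table, order: np.ndarray) -> tuple[np.ndarray, float]:
    """Steepest-ascent over all pairwise swaps until no swap improves."""
    z = len(order)
    cur = order.copy()
    cur_ll = sequence_log_likelihood(table, cur)
    improved = True
    while improved:
        improved = False
        best_ll, best_pair = cur_ll, None
        for a in range(z - 1):
            for b in range(a + 1, z):
                cur[a], cur[b] = cur[b], cur[a]
                ll = sequence_log_likelihood(table, cur)
                cur[a], cur[b] = cur[b], cur[a]
                if ll > best_ll:
                    best_ll, best_pair = ll, (a, b)
        if best_pair is not None:
            a, b = best_pair
            cur[a], cur[b] = cur[b], cur[a]
            cur_ll = best_ll
            improved = True
    return cur, cur_ll


def find_ml_sequence(table, n_restarts: int = 10, seed: int | None = None,
                     ) -> np.ndarray:
    """Maximum-likelihood ordering by greedy pairwise-swap hill-climbing.

    Runs ``n_restarts`` ascents from random initial permutations and keeps
    the best; deterministic given ``seed``.  The returned ordering's
    likelihood is at least that of every permutation visited.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    rng = np.random.default_rng(seed)
    z = table.n_biomarkers
    best_order, best_ll = None, -np.inf
    for _ in range(n_restarts):
        start = rng.permutation(z)
        order, ll = _greedy_ascent(table, start)
        if ll > best_ll:
            best_order, best_ll = order, ll
    return best_order


@dataclass
class MCMCTrace:
    """Post-burn-in posterior samples over orderings."""

    samples: np.ndarray           # (n_samples, Z) permutations
    log_likelihoods: np.ndarray   # (n_samples,)
    acceptance_rate: float
    seed: int | None
    n_burn_in: int

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.log_likelihoods):
            raise ValueError("samples and log_likelihoods lengths differ")
        if not 0.0 <= self.acceptance_rate <= 1.0:
            raise ValueError("acceptance_rate must lie in [0, 1]")

    @property
    def ml_sample(self) -> np.ndarray:
        return self.samples[int(np.argmax(self.log_likelihoods))]


def mcmc_sample(table, init, n_samples: int, n_burn_in: int = 0,
                seed: int | None = None) -> MCMCTrace:
    """Metropolis-Hastings over permutations with pairwise-swap proposals.

    The proposal swaps a uniformly random pair of positions (symmetric), so
    acceptance is ``min(1, exp(delta log-likelihood))``.  Burn-in iterations
    are discarded; the post-burn-in chain is returned.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    z = table.n_biomarkers
    cur = _check_sequence(init, z).copy()
    rng = np.random.default_rng(seed)
    cur_ll = sequence_log_likelihood(table, cur)
    total = n_burn_in + n_samples
    samples = np.empty((n_samples, z), dtype=int)
    lls = np.empty(n_samples)
    n_accept = 0
    for t in range(total):
        a, b = rng.choice(z, size=2, replace=False)
        cur[a], cur[b] = cur[b], cur[a]
        prop_ll = sequence_log_likelihood(table, cur)
        if np.log(rng.random()) < prop_ll - cur_ll:
            cur_ll = prop_ll
            n_accept += 1
        else:
            cur[a], cur[b] = cur[b], cur[a]
        if t >= n_burn_in:
            samples[t - n_burn_in] = cur
            lls[t - n_burn_in] = cur_ll
    return MCMCTrace(samples, lls, n_accept / total, seed, n_burn_in)


@dataclass
class PositionalVarianceDiagram:
    """Posterior positional frequencies: entry (i, p) is the fraction of
    samples placing biomarker i at sequence position p (0-based column,
    displayed 1-based).  Rows and columns each sum to 1."""

    matrix: np.ndarray
    biomarker_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        z1, z2 = self.matrix.shape
        if z1 != z2:
            raise ValueError("PVD matrix must be square")

    def ordered(self, sequence) -> np.ndarray:
        """Rows reordered by an event sequence (earliest event first) for
        display, so a confident posterior shows a dark diagonal."""
        return self.matrix[np.asarray(sequence, dtype=int)]

    def plot(self, sequence=None, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        mat = self.matrix if sequence is None else self.ordered(sequence)
        names = self.biomarker_names
        if names is not None and sequence is not None:
            names = [names[i] for i in np.asarray(sequence, dtype=int)]
        ax.imshow(mat, cmap="Greys", vmin=0, vmax=1, aspect="auto")
        ax.set_xlabel("sequence position")
        ax.set_ylabel("biomarker")
        z = mat.shape[0]
        ax.set_xticks(range(z), [str(p + 1) for p in range(z)], fontsize=7)
        if names is not None:
            ax.set_yticks(range(z), names, fontsize=7)
        return ax


def positional_variance(trace_or_samples, biomarker_names=None,
                        ) -> PositionalVarianceDiagram:
    """PVD from MCMC samples: empirical frequency of (biomarker, position)."""
    samples = getattr(trace_or_samples, "samples", trace_or_samples)
    samples = np.asarray(samples, dtype=int)
    if samples.ndim != 2 or len(samples) == 0:
        raise ValueError("need a non-empty (n_samples, Z) array of sequences")
    n, z = samples.shape
    mat = np.zeros((z, z))
    for pos in range(z):
        counts = np.bincount(samples[:, pos], minlength=z)
        mat[:, pos] = counts / n
    return PositionalVarianceDiagram(mat, biomarker_names)


def exhaustive_ml_sequence(table) -> np.ndarray:
    """Exact maximum-likelihood ordering by enumerating all Z! permutations.

    Test oracle for small problems; refuses Z > 8.  Ties break to the
    lexicographically smallest ordering.
    """
    z = table.n_biomarkers
    if z > MAX_EXHAUSTIVE_Z:
        raise ValueError(
            f"exhaustive enumeration of {z}! orderings is infeasible; "
            f"use find_ml_sequence for Z > {MAX_EXHAUSTIVE_Z}")
    best, best_ll = None, -np.inf
    for perm in permutations(range(z)):   # lexicographic order; strict '>' keeps first
        ll = sequence_log_likelihood(table, np.array(perm))
        if ll > best_ll:
            best, best_ll = perm, ll
    return np.array(best)
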