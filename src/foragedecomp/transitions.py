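"""Module-transition dynamics: 1-step Markov chains over expressed modules.

Per mouse, the modules expressed in a phase are ordered by excursion start
time; consecutive pairs pooled across mice give a 1-step transition count
matrix (never across mice or phases).  Dependence of the next module on the
previous one is a Monte Carlo Fisher test on the count matrix.  Group
comparisons (e.g., males vs females) use the Euclidean distance between the
stationary distributions of the two groups' chains, with a permutation null
that reassigns whole per-mouse sequences between groups.

Count matrices are regularized with a pseudo-count alpha (default 0.5) added
to every cell before row normalization, guaranteeing a strictly positive,
ergodic probability matrix with a unique stationary distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import ContingencyResult, fisher_exact

__all__ = [
    "TransitionMatrix",
    "build_transition_matrix",
    "dependence_test",
    "stationary_distribution",
    "compare_groups_permutation",
    "simulate_sequences",
]

DEFAULT_ALPHA = 0.5


@dataclass
class TransitionMatrix:
    counts: pd.DataFrame  # modules x modules transition counts
    alpha: float = DEFAULT_ALPHA
    empty: bool = False

    def probabilities(self) -> pd.DataFrame:
        """Row-stochastic form of the alpha-regularized counts."""
        reg = self.counts.to_numpy(dtype=float) + self.alpha
        return pd.DataFrame(reg / reg.sum(axis=1, keepdims=True),
                            index=self.counts.index,
                            columns=self.counts.columns)


def build_transition_matrix(sequences: dict, vocabulary=None,
                            alpha: float = DEFAULT_ALPHA) -> TransitionMatrix:
    """Pool consecutive-pair counts over per-mouse module sequences.

    ``sequences`` maps mouse id -> temporally ordered module list; pairs are
    never counted across mice.  ``vocabulary`` fixes the module axis (else
    the union of observed modules).
    """
    if vocabulary is None:
        vocabulary = sorted({m for seq in sequences.values() for m in seq})
    vocabulary = list(vocabulary)
    idx = {m: i for i, m in enumerate(vocabulary)}
    k = len(vocabulary)
    counts = np.zeros((k, k), dtype=int)
    total = 0
    for seq in sequences.values():
        for a, b in zip(seq[:-1], seq[1:]):
            counts[idx[a], idx[b]] += 1
            total += 1
    return TransitionMatrix(
        counts=pd.DataFrame(counts, index=vocabulary, columns=vocabulary),
        alpha=alpha, empty=(total == 0),
    )


def dependence_test(t: TransitionMatrix, mc_iterations: int = 100_000,
                    seed=None) -> ContingencyResult:
    """Does the next module depend on the previous one? (Fisher on counts.)"""
    c = t.counts.to_numpy()
    keep_r = c.sum(axis=1) > 0
    keep_c = c.sum(axis=0) > 0
    sub = c[np.ix_(keep_r, keep_c)]
    if sub.size <= 1 or 1 in sub.shape:
        return ContingencyResult(table=sub, p=1.0, method="exact")
    return fisher_exact(sub, mc_iterations=mc_iterations, seed=seed)


def stationary_distribution(t: TransitionMatrix | np.ndarray,
                            tol: float = 1e-10) -> np.ndarray:
    """Stationary probabilities pi of the regularized chain (pi P = pi).

    Solved as the null space of (P^T - I) with the sum-to-one constraint;
    the residual ||pi P - pi|| is checked against ``tol``.
    """
    if isinstance(t, TransitionMatrix):
        P = t.probabilities().to_numpy()
        if t.empty and t.alpha == 0:
            raise ValueError("all-zero transition matrix")
    else:
        P = np.asarray(t, dtype=float)
    if P.size == 0 or not np.all(np.isfinite(P)):
        raise ValueError("invalid transition matrix")
    k = P.shape[0]
    if k == 1:
        return np.array([1.0])
    A = np.vstack([P.T - np.eye(k), np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    residual = np.abs(pi @ P - pi).max()
    if residual > tol:
        raise ArithmeticError(f"stationary solve residual {residual:.2e} > {tol}")
    return pi


def _group_stationary(seqs: list, vocabulary, alpha: float) -> np.ndarray:
    t = build_transition_matrix(dict(enumerate(seqs)), vocabulary, alpha)
    if t.counts.to_numpy().sum() == 0:
        raise ValueError("group has zero transitions")
    return stationary_distribution(t)


def compare_groups_permutation(sequences_a, sequences_b, nperm: int = 10_000,
                               seed=None, vocabulary=None,
                               alpha: float = DEFAULT_ALPHA,
                               unit: str = "mouse"):
    """Permutation test of stationary-distribution distance between groups.

    Observed statistic: Euclidean distance between the two groups' stationary
    distributions.  Null: whole per-mouse sequences are reshuffled between
    the groups, preserving group sizes (``unit="token"`` instead reshuffles
    individual module tokens, an alternative reading of the same null).
    p = (1 + #{null >= observed}) / (nperm + 1).
    """
    seqs_a = list(sequences_a.values()) if isinstance(sequences_a, dict) else list(sequences_a)
    seqs_b = list(sequences_b.values()) if isinstance(sequences_b, dict) else list(sequences_b)
    if not seqs_a or not seqs_b:
        raise ValueError("both groups must be non-empty")
    if vocabulary is None:
        vocabulary = sorted({m for s in seqs_a + seqs_b for m in s})
    rng = np.random.default_rng(seed)
    pi_a = _group_stationary(seqs_a, vocabulary, alpha)
    pi_b = _group_stationary(seqs_b, vocabulary, alpha)
    observed = float(np.linalg.norm(pi_a - pi_b))

    n_a = len(seqs_a)
    exceed = 0
    if unit == "mouse":
        # per-mouse pair-count matrices; a permutation only re-sums them
        idx = {m: i for i, m in enumerate(vocabulary)}
        k = len(vocabulary)
        per_seq = np.zeros((n_a + len(seqs_b), k, k))
        for s, seq in enumerate(seqs_a + seqs_b):
            for a, b in zip(seq[:-1], seq[1:]):
                per_seq[s, idx[a], idx[b]] += 1

        def stat_from(counts_sum: np.ndarray) -> np.ndarray:
            reg = counts_sum + alpha
            return stationary_distribution(reg / reg.sum(axis=1, keepdims=True))

        for _ in range(nperm):
            perm = rng.permutation(per_seq.shape[0])
            d = float(np.linalg.norm(
                stat_from(per_seq[perm[:n_a]].sum(axis=0))
                - stat_from(per_seq[perm[n_a:]].sum(axis=0))))
            if d >= observed:
                exceed += 1
    elif unit == "token":
        lens_a = [len(s) for s in seqs_a]
        lens_b = [len(s) for s in seqs_b]
        tokens = np.array([m for s in seqs_a + seqs_b for m in s], dtype=object)
        for _ in range(nperm):
            shuffled = tokens[rng.permutation(tokens.size)]
            pa, pb, pos = [], [], 0
            for L in lens_a:
                pa.append(list(shuffled[pos:pos + L])); pos += L
            for L in lens_b:
                pb.append(list(shuffled[pos:pos + L])); pos += L
            d = float(np.linalg.norm(_group_stationary(pa, vocabulary, alpha)
                                     - _group_stationary(pb, vocabulary, alpha)))
            if d >= observed:
                exceed += 1
    else:
        raise ValueError("unit must be 'mouse' or 'token'")
    p = (1 + exceed) / (nperm + 1)
    return observed, p


def simulate_sequences(P: np.ndarray, n_mice: int, length: int, seed=None,
                       vocabulary=None) -> dict:
    """Simulate per-mouse module sequences from a transition chain."""
    rng = np.random.default_rng(seed)
    P = np.asarray(P, dtype=float)
    k = P.shape[0]
    if vocabulary is None:
        vocabulary = list(range(k))
    start = stationary_distribution(P)
    out = {}
    for m in range(n_mice):
        seq = [int(rng.choice(k, p=start))]
        for _ in range(length - 1):
            seq.append(int(rng.choice(k, p=P[seq[-1]])))
        out[f"m{m}"] = [vocabulary[s] for s in seq]
    return out
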