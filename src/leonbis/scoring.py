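"""Bayesian column-scoring primitives.

Everything downstream (core blocks, block relatedness, segment consistency)
reduces to Dirichlet-multinomial marginal likelihoods of alignment columns.
For a column with residue counts ``c`` (total ``M``) and a mixture with
weights ``q_j`` and parameters ``alpha_j``, the probability of the column
under the hypothesis that its residues descend from one common composition is

    Q(x) = sum_j q_j * [Gamma(|a_j|)/Gamma(|a_j|+M)] * prod_a Gamma(a_ja+c_a)/Gamma(a_ja)

and the BILD (Bayesian Integral Log-odds) score is the log-odds against the
background-independence hypothesis:

    S(x) = log Q(x) - sum_a c_a log p_a      [nats]

Scores are exchangeable in the observations, so columns are represented as
count vectors only. All heavy lifting is scipy ``gammaln``/``logsumexp``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .msa_io import AMINO_ACIDS, GAP, UNKNOWN
from .priors import N_AA, DirichletMixture

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

# floor before taking logs of probabilities on pathological inputs
_PROB_FLOOR = 1e-300


@dataclass(frozen=True)
class ColumnObservation:
    """Residue counts observed in one alignment column (gaps/'X' excluded)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (N_AA,) or np.any(counts < 0):
            raise ValueError("counts must be a 20-vector of non-negative numbers")
        object.__setattr__(self, "counts", counts)

    @property
    def n_obs(self) -> int:
        return int(round(self.counts.sum()))

    @classmethod
    def from_residues(cls, residues: str) -> "ColumnObservation":
        counts = np.zeros(N_AA)
        for ch in residues:
            if ch in (GAP, UNKNOWN):
                continue
            counts[_AA_INDEX[ch]] += 1
        return cls(counts)

    def add(self, residue: str) -> "ColumnObservation":
        counts = self.counts.copy()
        counts[_AA_INDEX[residue]] += 1
        return ColumnObservation(counts)

    def remove(self, residue: str) -> "ColumnObservation":
        counts = self.counts.copy()
        i = _AA_INDEX[residue]
        if counts[i] < 1:
            raise ValueError(f"cannot remove {residue!r}: count is {counts[i]}")
        counts[i] -= 1
        return ColumnObservation(counts)

    def __add__(self, other: "ColumnObservation") -> "ColumnObservation":
        return ColumnObservation(self.counts + other.counts)


@dataclass(frozen=True)
class ColumnScore:
    """BILD log-odds ``S`` (nats) and its normalized [0, 1] conservation score.

    ``prob = clip(S / S_max(M), 0, 1)`` where ``S_max(M)`` is the BILD score
    of the best perfectly conserved column with the same number of
    observations: 0 for anything scoring at or below background, 1 for
    maximal conservation. The scale is comparable across subfamilies of
    different sizes, and the 0.05 block threshold reads as 5 % of the
    maximal attainable conservation.
    """

    S: float
    prob: float


def _component_log_marglik(col: ColumnObservation, prior: DirichletMixture) -> np.ndarray:
    """log of the per-component Dirichlet-multinomial marginal, shape (J,)."""
    counts = col.counts
    m = counts.sum()
    a = prior.alpha
    return (
        gammaln(prior.alpha_sum)
        - gammaln(prior.alpha_sum + m)
        + (gammaln(a + counts) - gammaln(a)).sum(axis=1)
    )


def column_log_Q(col: ColumnObservation, prior: DirichletMixture) -> float:
    """log Q(x): marginal likelihood of the column under relatedness.

    Returns 0.0 (log 1) for an empty column.
    """
    if col.n_obs == 0:
        return 0.0
    return float(logsumexp(_component_log_marglik(col, prior), b=prior.weights))


def max_conserved_score(prior: DirichletMixture, m: int) -> float:
    """BILD score of the best perfectly conserved column of ``m`` residues.

    Maximized over the 20 candidate residues; cached per mixture instance.
    """
    cache = getattr(prior, "_smax_cache", None)
    if cache is None:
        cache = {}
        prior._smax_cache = cache
    if m not in cache:
        log_p = np.log(np.maximum(prior.background, _PROB_FLOOR))
        best = -np.inf
        for a in range(N_AA):
            counts = np.zeros(N_AA)
            counts[a] = m
            col = ColumnObservation(counts)
            best = max(best, column_log_Q(col, prior) - m * log_p[a])
        cache[m] = float(best)
    return cache[m]


def bild_score(col: ColumnObservation, prior: DirichletMixture) -> ColumnScore:
    """BILD score of a column: log Q(x) minus the background log-probability."""
    log_p = np.log(np.maximum(prior.background, _PROB_FLOOR))
    s = column_log_Q(col, prior) - float(col.counts @ log_p)
    s_max = max_conserved_score(prior, col.n_obs)
    prob = 0.0 if s_max <= 0 else min(max(s / s_max, 0.0), 1.0)
    return ColumnScore(S=s, prob=float(prob))


def posterior_predictive(
    col: ColumnObservation, prior: DirichletMixture, residue: str
) -> float:
    """Probability of observing ``residue`` next, given the column so far.

    Component posterior weights are proportional to ``q_j`` times the
    component marginal likelihood of the column; within each component the
    predictive is the usual Dirichlet-multinomial ``(a_jr + c_r)/(|a_j| + M)``.
    """
    return float(posterior_predictive_all(col, prior)[_AA_INDEX[residue]])


def posterior_predictive_all(col: ColumnObservation, prior: DirichletMixture) -> np.ndarray:
    """Posterior-predictive distribution over all 20 residues, sums to 1."""
    log_w = np.log(np.maximum(prior.weights, _PROB_FLOOR)) + _component_log_marglik(col, prior)
    w = np.exp(log_w - logsumexp(log_w))
    m = col.counts.sum()
    per_comp = (prior.alpha + col.counts) / (prior.alpha_sum + m)[:, None]
    return w @ per_comp


def column_pair_score(
    col_x: ColumnObservation, col_y: ColumnObservation, prior: DirichletMixture
) -> float:
    """Relatedness score R(x, y) = log[Q(xy) / (Q(x) Q(y))] for two columns.

    ``xy`` is the pooled column (count sum); the background terms of the
    underlying BILD scores cancel. Symmetric; zero when either column is
    empty.
    """
    return (
        column_log_Q(col_x + col_y, prior)
        - column_log_Q(col_x, prior)
        - column_log_Q(col_y, prior)
    )


def mixture_relative_entropy(prior: DirichletMixture) -> float:
    """Relative entropy (bits) of the implied pair substitution scores.

    The joint distribution of an aligned residue pair under relatedness is
    ``Q2(x, y) ∝ exp(column_log_Q({x, y}))``; the returned value is the
    Kullback-Leibler divergence of that joint from the background product
    ``p_x p_y``, the conventional figure used to place a scoring system on
    the PAM scale.
    """
    log_q2 = np.empty((N_AA, N_AA))
    for i in range(N_AA):
        for j in range(i, N_AA):
            counts = np.zeros(N_AA)
            counts[i] += 1
            counts[j] += 1
            log_q2[i, j] = log_q2[j, i] = column_log_Q(ColumnObservation(counts), prior)
    q2 = np.exp(log_q2 - logsumexp(log_q2))
    p = np.maximum(prior.background, _PROB_FLOOR)
    ratio = np.maximum(q2, _PROB_FLOOR) / (p[:, None] * p[None, :])
    return float((q2 * np.log2(ratio)).sum())
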