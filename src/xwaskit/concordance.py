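"""Joint multi-study concordance via a 2^J-pattern mixture model.

Gene-level p-values from J studies (trait x tissue x paradigm) are
transformed to t = -2 ln p, which is chi2_2 under the null.  Each study j
contributes a two-group mixture: a chi2_2 null density and a scaled-chi2_2
alternative whose scale a_j > 1 is estimated from the upper tail of the
observed statistics (the mean of the top ceil(alt_prop * G) statistics
divided by 2, the null mean).  Each gene belongs to one of K = 2^J binary
association patterns q_k in {0,1}^J; conditional on its pattern the
statistics are independent across studies with density alt or null per
coordinate.  An EM over the pattern weights pi_k yields per-gene pattern
posteriors, and the marginal posterior probability of association in
study j is

    PP_ij = sum_{k : q_kj = 1} posterior_ik.

Genes with PP > 0.95 are called significant.  Between-study correlation
from sample overlap is not modeled (pattern-conditional independence).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "StudyMatrix",
    "StudyMixture",
    "PatternFit",
    "pattern_matrix",
    "transform_pvalues",
    "fit_study_mixture",
    "em_pattern_weights",
    "pattern_posteriors",
    "fit_concordance",
]


@dataclass
class StudyMatrix:
    """G x J matrix of gene-level p-values with row/column labels."""

    genes: list[str]
    studies: list[str]
    P: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (len(self.genes), len(self.studies)):
            raise ValueError("P shape does not match gene/study labels")
        if len(self.studies) < 2:
            raise ValueError("concordance needs at least 2 studies")
        if np.any(self.P <= 0) or np.any(self.P > 1):
            raise ValueError("p-values must lie in (0, 1]")


@dataclass(frozen=True)
class StudyMixture:
    """Null and alternative densities for one study's -2 ln p statistics.

    Null: chi2_2, log f0(t) = -t/2 - ln 2.  Alternative: chi2_2 scaled by
    a > 1, log f1(t) = -t/(2a) - ln(2a).
    """

    scale: float

    def log_null(self, t: np.ndarray) -> np.ndarray:
        return -np.asarray(t) / 2.0 - math.log(2.0)

    def log_alt(self, t: np.ndarray) -> np.ndarray:
        return -np.asarray(t) / (2.0 * self.scale) - math.log(2.0 * self.scale)


@dataclass
class PatternFit:
    """Fitted concordance model."""

    studies: list[str]
    patterns: np.ndarray  # K x J binary matrix, row 0 = all-null
    mixtures: list[StudyMixture]
    alt_props: np.ndarray
    pi: np.ndarray  # K pattern weights
    loglik_trace: list[float]
    converged: bool
    n_iter: int


def pattern_matrix(n_studies: int) -> np.ndarray:
    """K x J binary pattern matrix; pattern k has bit j = (k >> j) & 1,
    so row 0 is the all-null pattern."""
    k = 2 ** n_studies
    return ((np.arange(k)[:, None] >> np.arange(n_studies)[None, :]) & 1).astype(float)


def transform_pvalues(P: np.ndarray) -> np.ndarray:
    """t = -2 ln p; chi2_2 under the null, 0 at p = 1."""
    P = np.asarray(P, dtype=float)
    if np.any(P <= 0):
        raise ValueError("p-values must be > 0")
    if np.any(P > 1):
        raise ValueError("p-values must be <= 1")
    return -2.0 * np.log(P)


_SCALE_FLOOR = 1.0 + 1e-6


def fit_study_mixture(t_column: np.ndarray, alt_prop: float) -> StudyMixture:
    """Estimate one study's alternative scale from its extreme statistics.

    a = max(floor, mean of the ceil(alt_prop * G) largest t / 2); with
    fewer than 5 tail statistics a warning is issued (the estimate is
    noisy) and the floor still applies.
    """
    t = np.asarray(t_column, dtype=float)
    if not 0.0 < alt_prop < 0.5:
        raise ValueError("alt_prop must be in (0, 0.5)")
    m = math.ceil(alt_prop * t.size)
    if m < 5:
        warnings.warn(
            f"only {m} tail statistics available to estimate the alternative "
            "scale; estimate will be noisy",
            stacklevel=2,
        )
    m = max(m, 1)
    top = np.sort(t)[-m:]
    scale = max(_SCALE_FLOOR, float(top.mean()) / 2.0)
    return StudyMixture(scale=scale)


def _pattern_logliks(T: np.ndarray, mixtures: Sequence[StudyMixture], Q: np.ndarray):
    """G x K matrix of per-pattern log-likelihoods."""
    lf0 = np.column_stack([mx.log_null(T[:, j]) for j, mx in enumerate(mixtures)])
    lf1 = np.column_stack([mx.log_alt(T[:, j]) for j, mx in enumerate(mixtures)])
    base = lf0.sum(axis=1)
    delta = lf1 - lf0
    return base[:, None] + delta @ Q.T


def em_pattern_weights(
    T: np.ndarray,
    mixtures: Sequence[StudyMixture],
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[np.ndarray, list[float], bool, int]:
    """EM for the 2^J pattern weights with fixed component densities.

    E-step: posterior_ik proportional to pi_k prod_j f_j^(q_kj)(t_ij),
    in log space.  M-step: pi_k = mean_i posterior_ik.  Initial weights
    put 0.9 on the all-null pattern and spread the rest uniformly.
    Convergence when max |delta pi| < tol; non-convergence at max_iter
    warns and returns the current state flagged.

    Returns (pi, observed-data log-likelihood trace, converged, n_iter).
    """
    J = len(mixtures)
    if 2 ** J > 256:
        raise ValueError("at most 8 studies supported (K = 2^J <= 256)")
    Q = pattern_matrix(J)
    K = Q.shape[0]
    L = _pattern_logliks(np.asarray(T, dtype=float), mixtures, Q)
    pi = np.full(K, 0.1 / (K - 1))
    pi[0] = 0.9
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_num = np.log(pi)[None, :] + L
        norm = logsumexp(log_num, axis=1)
        trace.append(float(norm.sum()))
        post = np.exp(log_num - norm[:, None])
        new_pi = post.mean(axis=0)
        new_pi = new_pi / new_pi.sum()
        if np.max(np.abs(new_pi - pi)) < tol:
            pi = new_pi
            converged = True
            break
        pi = new_pi
    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} iterations", stacklevel=2)
    return pi, trace, converged, it


def pattern_posteriors(fit: PatternFit, T: np.ndarray):
    """Per-gene pattern posteriors and marginal association posteriors.

    Returns (posterior G x K, PP G x J); rows of the posterior sum to 1
    and PP_ij sums posterior mass over patterns with a 1 in study j.
    """
    L = _pattern_logliks(np.asarray(T, dtype=float), fit.mixtures, fit.patterns)
    log_num = np.log(fit.pi)[None, :] + L
    post = np.exp(log_num - logsumexp(log_num, axis=1)[:, None])
    pp = post @ fit.patterns
    return post, pp


def fit_concordance(
    matrix: StudyMatrix,
    alt_props: float | Sequence[float] = 1e-3,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[PatternFit, np.ndarray, np.ndarray]:
    """Fit the full concordance model to a gene x study p-value matrix.

    Returns (fit, posterior, PP).  ``alt_props`` is the per-study prior
    alternative proportion (scalar or one per study); 1e-3 is the
    conventional default for well-powered scans.
    """
    J = len(matrix.studies)
    props = np.asarray(
        np.broadcast_to(np.asarray(alt_props, dtype=float), (J,)), dtype=float
    )
    T = transform_pvalues(matrix.P)
    mixtures = [fit_study_mixture(T[:, j], props[j]) for j in range(J)]
    pi, trace, converged, n_iter = em_pattern_weights(T, mixtures, tol=tol, max_iter=max_iter)
    fit = PatternFit(
        studies=list(matrix.studies),
        patterns=pattern_matrix(J),
        mixtures=mixtures,
        alt_props=props,
        pi=pi,
        loglik_trace=trace,
        converged=converged,
        n_iter=n_iter,
    )
    post, pp = pattern_posteriors(fit, T)
    return fit, post, pp
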