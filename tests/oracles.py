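"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's recursions: likelihoods come from
exhaustive enumeration over all hidden-state paths, the Bessel function
from its power series, and the signed-rank null from full enumeration.
"""

import itertools
import math

import numpy as np

from walkhmm.distributions import angle_logpdf, step_logpdf


def brute_force_loglik(obs, params):
    """Log likelihood by summing over every hidden-state path."""
    n, T = params.n_states, obs.n_steps
    delta = params.initial_distribution()
    total = -np.inf
    for path in itertools.product(range(n), repeat=T):
        lp = np.log(delta[path[0]])
        for t in range(T):
            if t > 0:
                lp += np.log(params.tpm[path[t - 1], path[t]])
            if obs.step_included[t]:
                lp += step_logpdf(obs.steps[t], params.step_dists[path[t]])
            if np.isfinite(obs.angles[t]):
                lp += angle_logpdf(obs.angles[t], params.angle_dists[path[t]])
        total = np.logaddexp(total, lp)
    return float(total)


def brute_force_viterbi(obs, params):
    """Most probable path by exhaustive enumeration (first max in
    lexicographic path order, matching lowest-state-index tie-breaking)."""
    n, T = params.n_states, obs.n_steps
    delta = params.initial_distribution()
    best_lp, best_path = -np.inf, None
    for path in itertools.product(range(n), repeat=T):
        lp = np.log(delta[path[0]])
        for t in range(T):
            if t > 0:
                lp += np.log(params.tpm[path[t - 1], path[t]])
            if obs.step_included[t]:
                lp += step_logpdf(obs.steps[t], params.step_dists[path[t]])
            if np.isfinite(obs.angles[t]):
                lp += angle_logpdf(obs.angles[t], params.angle_dists[path[t]])
        if lp > best_lp:
            best_lp, best_path = lp, path
    return np.array(best_path), best_lp


def bessel_i0_series(x, terms=60):
    """Modified Bessel function I0 by its power series."""
    total = 0.0
    for k in range(terms):
        total += (x / 2.0) ** (2 * k) / math.factorial(k) ** 2
    return total


def bessel_i1_series(x, terms=60):
    """Modified Bessel function I1 by its power series."""
    total = 0.0
    for k in range(terms):
        total += (x / 2.0) ** (2 * k + 1) / (math.factorial(k) * math.factorial(k + 1))
    return total


def wrap_naive(theta):
    """Scalar angle wrapping into (-pi, pi] by repeated shifting."""
    while theta <= -math.pi:
        theta += 2.0 * math.pi
    while theta > math.pi:
        theta -= 2.0 * math.pi
    return theta


def signed_rank_exact_pvalue(values):
    """Two-sided Wilcoxon signed-rank p by enumerating all sign patterns.

    Assumes no zeros and no tied absolute values (use on generic data).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    ranks = np.argsort(np.argsort(np.abs(values))) + 1
    w_obs = ranks[values > 0].sum()
    stats = []
    for signs in itertools.product((0, 1), repeat=n):
        stats.append(sum(r for r, s in zip(ranks, signs) if s))
    stats = np.array(stats)
    mean = stats.mean()
    # two-sided: probability of a statistic at least as extreme as observed
    extreme = np.abs(stats - mean) >= abs(w_obs - mean) - 1e-12
    return extreme.mean()
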