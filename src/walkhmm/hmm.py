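"""Movement HMM core: likelihood, fitting, decoding and fitted summaries.

The model is a hidden Markov chain with ``N`` states; conditional on the
state at time ``t``, the step length ``S_t`` is Gamma distributed and the
angle is drawn from a circular law (von Mises by default).  Two angular
modes exist:

* ``"relative"`` — the emitted angle is the turning angle ``theta_t``
  (piecewise-stationary correlated random walk, "r-HMM"); the first step
  has no defined turning angle.
* ``"absolute"`` — the emitted angle is the absolute angle ``alpha_t``
  from a fixed reference axis (piecewise-stationary biased random walk,
  "a-HMM"); every step has a defined angle.

The likelihood is computed by the scaled forward recursion; undefined
(NaN) angle terms and excluded step terms contribute a factor of one.  The
initial state distribution is tied to the stationary distribution of the
transition matrix, which keeps the parameter count at
``4 N + N (N - 1)`` and makes BIC comparable across modes.

The scikit-learn-style estimator :class:`MovementHMM` wraps multi-start
numerical maximization over unconstrained working parameters; the
module-level functions (:func:`forward_loglik`, :func:`viterbi`,
:func:`fit`, ...) expose the same machinery functionally.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import digamma, gammaln, i0e, i1e

from ._core import forward_backward, forward_scaled
from .distributions import (
    VON_MISES,
    WRAPPED_CAUCHY,
    AngleDist,
    StepDist,
    angle_logpdf,
    step_logpdf,
)
from .geometry import InvalidTrackError, StepSeries, Track, wrap_angle

__all__ = [
    "RELATIVE",
    "ABSOLUTE",
    "HMMSpec",
    "HMMParams",
    "FitResult",
    "FitFailedError",
    "Observations",
    "observations",
    "stationary_distribution",
    "forward_loglik",
    "viterbi",
    "fit",
    "transition_summary",
    "dwell_times",
    "MovementHMM",
]

RELATIVE = "relative"
ABSOLUTE = "absolute"

MAX_STATES = 4

# a start is discarded as "warning-equivalent" when the optimizer fails,
# the likelihood is non-finite, or estimates sit on these boundaries
KAPPA_MAX = 1e3
GAMMA_MIN = 1e-6


@dataclass(frozen=True)
class HMMSpec:
    """Structural choice of a movement HMM: state count, mode, angle family."""

    n_states: int
    angle_mode: str = RELATIVE
    angle_family: str = VON_MISES

    def __post_init__(self):
        if not 1 <= self.n_states <= MAX_STATES:
            raise ValueError(f"n_states must be in 1..{MAX_STATES}")
        if self.angle_mode not in (RELATIVE, ABSOLUTE):
            raise ValueError(f"unknown angle mode {self.angle_mode!r}")
        if self.angle_family not in (VON_MISES, WRAPPED_CAUCHY):
            raise ValueError(f"unknown angle family {self.angle_family!r}")


@dataclass(frozen=True)
class HMMParams:
    """Full parameter set: per-state emission laws plus transition matrix.

    The initial distribution ``delta`` defaults to the stationary
    distribution of ``tpm``.
    """

    angle_dists: tuple
    step_dists: tuple
    tpm: np.ndarray
    delta: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.angle_dists)
        if len(self.step_dists) != n:
            raise ValueError("angle_dists and step_dists must have equal length")
        tpm = np.atleast_2d(np.asarray(self.tpm, dtype=float))
        if tpm.shape != (n, n):
            raise ValueError(f"transition matrix must be {n}x{n}")
        if np.any(tpm < 0) or np.any(tpm > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(tpm.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition matrix rows must sum to 1")
        object.__setattr__(self, "tpm", tpm)
        if self.delta is not None:
            delta = np.asarray(self.delta, dtype=float)
            if delta.shape != (n,) or not np.isclose(delta.sum(), 1.0, atol=1e-10):
                raise ValueError("delta must be a length-n probability vector")
            object.__setattr__(self, "delta", delta)

    @property
    def n_states(self) -> int:
        return len(self.angle_dists)

    def initial_distribution(self) -> np.ndarray:
        if self.delta is not None:
            return self.delta
        return stationary_distribution(self.tpm)


def stationary_distribution(tpm: np.ndarray) -> np.ndarray:
    """Solve ``delta @ tpm = delta`` with ``sum(delta) = 1``."""
    tpm = np.atleast_2d(np.asarray(tpm, dtype=float))
    n = tpm.shape[0]
    if n == 1:
        return np.ones(1)
    # delta (I - tpm) = 0 with sum(delta) = 1: replace one equation by the
    # normalization constraint
    a = np.eye(n) - tpm.T
    a[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    try:
        delta = np.linalg.solve(a, b)
    except np.linalg.LinAlgError:
        delta, *_ = np.linalg.lstsq(a, b, rcond=None)
    delta = np.clip(delta, 0.0, None)
    return delta / delta.sum()


@dataclass(frozen=True)
class Observations:
    """Likelihood-ready per-step observations of one track.

    ``steps`` and ``angles`` have length T; NaN angles are skipped in the
    likelihood, and ``step_included`` masks steps out of the step-length
    likelihood (used for the dummy increment of transformed tracks).
    """

    steps: np.ndarray
    angles: np.ndarray
    mode: str
    step_included: np.ndarray = None

    def __post_init__(self):
        steps = np.asarray(self.steps, dtype=float)
        angles = np.asarray(self.angles, dtype=float)
        if steps.shape != angles.shape or steps.ndim != 1:
            raise ValueError("steps and angles must be 1-D arrays of equal length")
        object.__setattr__(self, "steps", steps)
        object.__setattr__(self, "angles", angles)
        if self.step_included is None:
            object.__setattr__(self, "step_included", steps > 0.0)
        else:
            inc = np.asarray(self.step_included, dtype=bool) & (steps > 0.0)
            object.__setattr__(self, "step_included", inc)

    @property
    def n_steps(self) -> int:
        return len(self.steps)


def observations(track: Track, mode: str = RELATIVE,
                 exclude_first_step: bool = False) -> Observations:
    """Derive the step/angle pairs that enter the likelihood.

    Relative mode pairs each step with the turning angle ending at it
    (undefined at t=1); absolute mode pairs it with the increment's
    absolute angle.  ``exclude_first_step`` drops the first step length
    from the likelihood — used when the first increment is the dummy step
    of an absolutized track.
    """
    if mode not in (RELATIVE, ABSOLUTE):
        raise ValueError(f"unknown angle mode {mode!r}")
    min_pos = 3 if mode == RELATIVE else 2
    if track.positions.shape[0] < min_pos:
        raise InvalidTrackError(
            f"track {track.id!r} too short for {mode} mode (needs >= {min_pos} positions)"
        )
    series = StepSeries.from_track(track)
    angles = series.rel_angles if mode == RELATIVE else series.abs_angles
    included = np.ones(len(series.steps), dtype=bool)
    if exclude_first_step:
        included[0] = False
    return Observations(steps=series.steps, angles=angles, mode=mode,
                        step_included=included)


def _log_emissions(obs: Observations, params: HMMParams) -> np.ndarray:
    """(T, N) matrix of per-step log emission densities; skipped terms are 0."""
    T, n = obs.n_steps, params.n_states
    logp = np.zeros((T, n))
    angle_ok = np.isfinite(obs.angles)
    for i in range(n):
        if np.any(obs.step_included):
            logp[obs.step_included, i] += step_logpdf(
                obs.steps[obs.step_included], params.step_dists[i]
            )
        if np.any(angle_ok):
            logp[angle_ok, i] += angle_logpdf(
                obs.angles[angle_ok], params.angle_dists[i]
            )
    return logp


def forward_loglik(obs: Observations, params: HMMParams) -> float:
    """Marginal log likelihood via the scaled forward recursion."""
    logp = _log_emissions(obs, params)
    # scale each time slice by its max before exponentiating to avoid underflow
    row_max = logp.max(axis=1)
    if not np.all(np.isfinite(row_max)):
        return -np.inf
    p = np.exp(logp - row_max[:, None])
    total = forward_scaled(p, params.tpm, params.initial_distribution())
    if not np.isfinite(total):
        return -np.inf
    return float(total + row_max.sum())


def viterbi(obs: Observations, params: HMMParams) -> np.ndarray:
    """Most probable joint state path (0-based); ties go to the lower index."""
    logp = _log_emissions(obs, params)
    T, n = logp.shape
    with np.errstate(divide="ignore"):
        log_tpm = np.log(params.tpm)
        log_delta = np.log(params.initial_distribution())
    score = log_delta + logp[0]
    back = np.zeros((T, n), dtype=np.intp)
    for t in range(1, T):
        cand = score[:, None] + log_tpm  # (from, to)
        back[t] = np.argmax(cand, axis=0)
        score = cand[back[t], np.arange(n)] + logp[t]
    path = np.zeros(T, dtype=np.intp)
    path[-1] = int(np.argmax(score))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


# ---------------------------------------------------------------------------
# working-parameter transform (unconstrained optimization space)
# ---------------------------------------------------------------------------

def _n_working(n_states: int) -> int:
    return 4 * n_states + n_states * (n_states - 1)


def _pack(params: HMMParams, family: str) -> np.ndarray:
    n = params.n_states
    mus = np.array([d.mu for d in params.angle_dists])
    conc = np.array([d.kappa for d in params.angle_dists])
    if family == VON_MISES:
        zconc = np.log(np.maximum(conc, 1e-12))
    else:
        conc = np.clip(conc, 1e-12, 1 - 1e-12)
        zconc = np.log(conc / (1 - conc))
    zmu_g = np.log([d.mu_gamma for d in params.step_dists])
    zsd_g = np.log([d.sigma_gamma for d in params.step_dists])
    parts = [mus, zconc, zmu_g, zsd_g]
    if n > 1:
        tpm = np.clip(params.tpm, 1e-12, None)
        logits = []
        for i in range(n):
            for j in range(n):
                if j != i:
                    logits.append(np.log(tpm[i, j] / tpm[i, i]))
        parts.append(np.array(logits))
    return np.concatenate(parts)


def _unpack(z: np.ndarray, n: int, family: str) -> HMMParams:
    mus = wrap_angle(z[:n])
    if family == VON_MISES:
        conc = np.exp(z[n:2 * n])
    else:
        conc = 1.0 / (1.0 + np.exp(-z[n:2 * n]))
    mu_g = np.exp(z[2 * n:3 * n])
    sd_g = np.exp(z[3 * n:4 * n])
    if n > 1:
        logits = z[4 * n:]
        tpm = np.zeros((n, n))
        k = 0
        for i in range(n):
            row = np.zeros(n)
            for j in range(n):
                if j != i:
                    row[j] = logits[k]
                    k += 1
            row = np.exp(row - row.max())
            tpm[i] = row / row.sum()
    else:
        tpm = np.ones((1, 1))
    angle_dists = tuple(
        AngleDist(mu=float(m), kappa=float(c), family=family)
        for m, c in zip(mus, conc, strict=True)
    )
    step_dists = tuple(
        StepDist(mu_gamma=float(m), sigma_gamma=float(s))
        for m, s in zip(mu_g, sd_g, strict=True)
    )
    return HMMParams(angle_dists=angle_dists, step_dists=step_dists, tpm=tpm)


def _order_states(params: HMMParams) -> HMMParams:
    """Relabel states by increasing step mean (then angle mean) for stability."""
    keys = [(d.mu_gamma, a.mu) for d, a in zip(params.step_dists, params.angle_dists)]
    order = sorted(range(params.n_states), key=lambda i: keys[i])
    if order == list(range(params.n_states)):
        return params
    idx = np.array(order)
    return HMMParams(
        angle_dists=tuple(params.angle_dists[i] for i in order),
        step_dists=tuple(params.step_dists[i] for i in order),
        tpm=params.tpm[np.ix_(idx, idx)],
    )


_LOG_2PI = np.log(2.0 * np.pi)


def _unpack_raw(z, n, family):
    """Working parameters -> natural-parameter arrays plus tpm and delta."""
    mus = z[:n]
    if family == WRAPPED_CAUCHY:
        conc = 1.0 / (1.0 + np.exp(-z[n:2 * n]))
    else:
        conc = np.exp(z[n:2 * n])
    mu_g = np.exp(z[2 * n:3 * n])
    sd_g = np.exp(z[3 * n:4 * n])
    if n > 1:
        logits = z[4 * n:]
        tpm = np.zeros((n, n))
        k = 0
        for i in range(n):
            row = np.zeros(n)
            for j in range(n):
                if j != i:
                    row[j] = logits[k]
                    k += 1
            row = np.exp(row - row.max())
            tpm[i] = row / row.sum()
        delta = stationary_distribution(tpm)
    else:
        tpm = np.ones((1, 1))
        delta = np.ones(1)
    return mus, conc, mu_g, sd_g, tpm, delta


def _make_objective(obs: Observations, n: int, family: str):
    """Negative log likelihood with its analytic gradient.

    The gradient uses the Fisher identity: the score of the marginal
    likelihood equals the posterior expectation of the complete-data
    score, so one forward-backward pass yields exact derivatives for all
    working parameters — including the correction for tying the initial
    distribution to the stationary distribution of the transition matrix.
    """
    step_ok = np.isfinite(obs.steps) & obs.step_included
    angle_ok = np.isfinite(obs.angles)
    steps = np.where(step_ok, obs.steps, 1.0)
    log_steps = np.log(steps)
    angles = np.where(angle_ok, obs.angles, 0.0)
    T = obs.n_steps
    wrapped_cauchy = family == WRAPPED_CAUCHY

    def objective(z):
        if not np.all(np.isfinite(z)) or np.any(np.abs(z) > 300.0):
            return np.inf, np.zeros_like(z)
        mus, conc, mu_g, sd_g, tpm, delta = _unpack_raw(z, n, family)
        shape = (mu_g / sd_g) ** 2
        scale = sd_g**2 / mu_g
        const_step = -gammaln(shape) - shape * np.log(scale)
        if wrapped_cauchy:
            const_angle = np.log1p(-conc * conc) - _LOG_2PI
        else:
            const_angle = -_LOG_2PI - np.log(i0e(conc)) - conc
        logp = np.empty((T, n))
        dmat = np.empty((T, n)) if wrapped_cauchy else None
        for i in range(n):
            sterm = (shape[i] - 1.0) * log_steps - steps / scale[i] + const_step[i]
            if wrapped_cauchy:
                r = conc[i]
                d = 1.0 + r * r - 2.0 * r * np.cos(angles - mus[i])
                dmat[:, i] = d
                aterm = const_angle[i] - np.log(d)
            else:
                aterm = conc[i] * np.cos(angles - mus[i]) + const_angle[i]
            logp[:, i] = np.where(step_ok, sterm, 0.0) + np.where(angle_ok, aterm, 0.0)
        ll, gamma, xi = forward_backward(logp, tpm, delta)
        if np.isnan(ll):
            return np.inf, np.zeros_like(z)

        grad = np.empty_like(z)
        w_ang = gamma * angle_ok[:, None]
        w_step = gamma * step_ok[:, None]
        for i in range(n):
            delta_ang = angles - mus[i]
            wa = w_ang[:, i]
            sw = wa.sum()
            if wrapped_cauchy:
                r = conc[i]
                d = dmat[:, i]
                grad[i] = np.sum(wa * 2.0 * r * np.sin(delta_ang) / d)
                dldr = -2.0 * r / (1.0 - r * r) * sw - np.sum(
                    wa * (2.0 * r - 2.0 * np.cos(delta_ang)) / d
                )
                grad[n + i] = dldr * r * (1.0 - r)
            else:
                kap = conc[i]
                grad[i] = kap * np.sum(wa * np.sin(delta_ang))
                a1 = i1e(kap) / i0e(kap)
                grad[n + i] = kap * (np.sum(wa * np.cos(delta_ang)) - a1 * sw)
            ws = w_step[:, i]
            s1 = ws.sum()
            sl = np.sum(ws * log_steps)
            ss = np.sum(ws * steps)
            k_i, th_i = shape[i], scale[i]
            dldk = sl - s1 * (digamma(k_i) + np.log(th_i))
            dldth = ss / th_i**2 - s1 * k_i / th_i
            grad[2 * n + i] = 2.0 * k_i * dldk - th_i * dldth
            grad[3 * n + i] = -2.0 * k_i * dldk + 2.0 * th_i * dldth
        if n > 1:
            # transition part plus the stationary-initial-distribution term
            u = gamma[0] / np.maximum(delta, 1e-300)
            zmat = np.eye(n) - tpm + np.tile(delta, (n, 1))
            try:
                w_vec = np.linalg.solve(zmat, u)  # w = Zinv @ u
            except np.linalg.LinAlgError:
                w_vec = np.zeros(n)
            xi_row = xi.sum(axis=1)
            gw = tpm @ w_vec
            k = 4 * n
            for i in range(n):
                for j in range(n):
                    if j == i:
                        continue
                    g = xi[i, j] - xi_row[i] * tpm[i, j]
                    g += delta[i] * tpm[i, j] * (w_vec[j] - gw[i])
                    grad[k] = g
                    k += 1
        return -ll, -grad

    return objective


class FitFailedError(RuntimeError):
    """All starting points failed or produced warning-flagged fits."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass(frozen=True)
class FitResult:
    """Outcome of a (multi-start) maximum-likelihood fit on one track."""

    params: HMMParams
    loglik: float
    n_params: int
    n_obs: int
    aic: float
    bic: float
    viterbi_path: np.ndarray
    converged: bool
    warnings: tuple = ()
    n_starts_tried: int = 1
    n_starts_failed: int = 0
    spec: HMMSpec | None = None

    @property
    def n_states(self) -> int:
        return self.params.n_states

    def state_counts(self) -> np.ndarray:
        """Occupancy count of each state along the Viterbi path."""
        return np.bincount(self.viterbi_path, minlength=self.params.n_states)


def _boundary_warnings(params: HMMParams, family: str) -> list:
    notes = []
    for i, (a, s) in enumerate(zip(params.angle_dists, params.step_dists)):
        if family == VON_MISES and a.kappa > KAPPA_MAX:
            notes.append(f"state {i}: kappa at boundary ({a.kappa:.3g})")
        if s.mu_gamma < GAMMA_MIN or s.sigma_gamma < GAMMA_MIN:
            notes.append(f"state {i}: Gamma parameter at boundary")
    return notes


def fit(obs: Observations, spec: HMMSpec, starts, tol: float = 1e-8,
        maxiter: int = 1000) -> FitResult:
    """Maximize the likelihood from multiple starting points.

    Each start is optimized over the unconstrained working parameters with
    L-BFGS-B; starts whose optimization fails, yields a non-finite
    likelihood, or ends on a parameter boundary are discarded, mirroring
    the practice of ignoring warning-flagged fits.  The best surviving
    start wins.

    Parameters
    ----------
    obs : Observations
    spec : HMMSpec
    starts : sequence of HMMParams
    tol, maxiter
        Optimizer tolerance (on the relative likelihood change) and
        iteration cap.

    Raises
    ------
    FitFailedError
        If no start survives; carries per-start diagnostics.
    """
    starts = list(starts)
    if not starts:
        raise ValueError("need at least one starting point")
    n = spec.n_states
    family = spec.angle_family
    objective = _make_objective(obs, n, family)

    best = None
    diagnostics = []
    n_failed = 0
    for s_idx, start in enumerate(starts):
        if start.n_states != n:
            raise ValueError("start has wrong number of states")
        z0 = _pack(start, family)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            res = optimize.minimize(
                objective, z0, method="L-BFGS-B", jac=True,
                options={"maxiter": maxiter, "ftol": tol, "maxfun": 5 * maxiter},
            )
        ll = -res.fun
        notes = []
        if not res.success:
            notes.append(f"optimizer: {res.message}")
        if not np.isfinite(ll):
            notes.append("non-finite likelihood")
            params_hat = None
        else:
            params_hat = _unpack(res.x, n, family)
            notes.extend(_boundary_warnings(params_hat, family))
        if notes:
            n_failed += 1
            diagnostics.append((s_idx, ll, tuple(notes)))
            continue
        if best is None or ll > best[0]:
            best = (ll, params_hat)
    if best is None:
        raise FitFailedError(
            f"all {len(starts)} starting points failed", diagnostics=diagnostics
        )
    ll, params_hat = best
    params_hat = _order_states(params_hat)
    n_params = _n_working(n)
    n_obs = obs.n_steps
    path = viterbi(obs, params_hat)
    return FitResult(
        params=params_hat,
        loglik=ll,
        n_params=n_params,
        n_obs=n_obs,
        aic=-2.0 * ll + 2.0 * n_params,
        bic=-2.0 * ll + n_params * np.log(n_obs),
        viterbi_path=path,
        converged=True,
        warnings=tuple(f"start {i}: {'; '.join(w)}" for i, _, w in diagnostics),
        n_starts_tried=len(starts),
        n_starts_failed=n_failed,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# fitted-model summaries
# ---------------------------------------------------------------------------

def transition_summary(result: FitResult):
    """Fitted transition matrix, observed transition counts, occupancies.

    Returns ``(tpm, counts, occupancy, unobserved)`` where ``counts[i, j]``
    is the number of ``i -> j`` transitions along the Viterbi path,
    ``occupancy`` the fraction of time steps spent in each state, and
    ``unobserved`` a boolean matrix flagging transitions never decoded.
    """
    path = result.viterbi_path
    n = result.params.n_states
    counts = np.zeros((n, n), dtype=int)
    np.add.at(counts, (path[:-1], path[1:]), 1)
    occupancy = np.bincount(path, minlength=n) / len(path)
    return result.params.tpm, counts, occupancy, counts == 0


def dwell_times(result: FitResult, method: str = "viterbi_runs") -> np.ndarray:
    """Mean number of consecutive steps spent in each state before leaving.

    ``"viterbi_runs"`` averages the lengths of maximal constant runs of the
    decoded path; ``"geometric"`` uses the implied geometric mean
    ``1 / (1 - tpm[i, i])``.  States never visited give NaN under
    ``viterbi_runs``.
    """
    n = result.params.n_states
    if method == "geometric":
        diag = np.diag(result.params.tpm)
        with np.errstate(divide="ignore"):
            return 1.0 / (1.0 - diag)
    if method != "viterbi_runs":
        raise ValueError(f"unknown dwell-time method {method!r}")
    path = result.viterbi_path
    out = np.full(n, np.nan)
    boundaries = np.flatnonzero(np.diff(path) != 0)
    run_starts = np.concatenate([[0], boundaries + 1])
    run_ends = np.concatenate([boundaries, [len(path) - 1]])
    run_states = path[run_starts]
    run_lengths = run_ends - run_starts + 1
    for i in range(n):
        mask = run_states == i
        if np.any(mask):
            out[i] = run_lengths[mask].mean()
    return out


# ---------------------------------------------------------------------------
# scikit-learn style estimator
# ---------------------------------------------------------------------------

def _as_observations(X, angle_mode, exclude_first_step=False) -> Observations:
    if isinstance(X, Observations):
        return X
    if isinstance(X, Track):
        return observations(X, angle_mode, exclude_first_step)
    arr = np.asarray(X, dtype=float)
    return observations(Track(id="<array>", positions=arr), angle_mode,
                        exclude_first_step)


class MovementHMM:
    """Hidden Markov model for 2-D movement tracks.

    Scikit-learn style estimator: construct with hyperparameters, ``fit``
    on a track (a :class:`Track`, an ``(T+1, 2)`` position array, or
    pre-built :class:`Observations`), then ``predict`` Viterbi state paths
    or ``score`` log likelihoods for new tracks.

    Parameters
    ----------
    n_states : int
        Number of hidden states (1..4).
    angle_mode : {"relative", "absolute"}
        Turning-angle (CRW) or absolute-angle (BRW) emissions.
    angle_family : {"vonmises", "wrappedcauchy"}
    starts : "grid", int, or sequence of HMMParams
        Starting points for the multi-start maximization.  ``"grid"`` uses
        the canonical starting grid for ``n_states``; an integer uses a
        deterministic thinning of that grid to at most that many starts.
    tpm_diag : float
        Diagonal of the starting transition matrices.
    tol, maxiter
        Optimizer settings.

    Attributes
    ----------
    params_ : HMMParams
    loglik_, aic_, bic_ : float
    n_params_, n_obs_ : int
    viterbi_path_ : ndarray
        Decoded path of the training track.
    converged_ : bool
    n_starts_tried_, n_starts_failed_ : int
    """

    def __init__(self, n_states: int = 2, angle_mode: str = RELATIVE,
                 angle_family: str = VON_MISES, starts="grid",
                 tpm_diag: float = 0.8, tol: float = 1e-8, maxiter: int = 1000):
        self.n_states = n_states
        self.angle_mode = angle_mode
        self.angle_family = angle_family
        self.starts = starts
        self.tpm_diag = tpm_diag
        self.tol = tol
        self.maxiter = maxiter

    # -- sklearn plumbing --------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_states": self.n_states,
            "angle_mode": self.angle_mode,
            "angle_family": self.angle_family,
            "starts": self.starts,
            "tpm_diag": self.tpm_diag,
            "tol": self.tol,
            "maxiter": self.maxiter,
        }

    def set_params(self, **kwargs):
        for key, value in kwargs.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def __repr__(self):
        args = ", ".join(f"{k}={v!r}" for k, v in self.get_params().items())
        return f"MovementHMM({args})"

    # -- core API ----------------------------------------------------------
    def _spec(self) -> HMMSpec:
        return HMMSpec(n_states=self.n_states, angle_mode=self.angle_mode,
                       angle_family=self.angle_family)

    def _starting_points(self):
        from .model_selection import default_starts, starting_grid

        if isinstance(self.starts, str) and self.starts == "grid":
            return starting_grid(self._spec(), tpm_diag=self.tpm_diag)
        if isinstance(self.starts, (int, np.integer)):
            return default_starts(self._spec(), max_starts=int(self.starts),
                                  tpm_diag=self.tpm_diag)
        return list(self.starts)

    def fit(self, X, y=None, exclude_first_step: bool = False):
        """Fit by multi-start maximum likelihood on a single track."""
        spec = self._spec()
        obs = _as_observations(X, self.angle_mode, exclude_first_step)
        result = fit(obs, spec, self._starting_points(), tol=self.tol,
                     maxiter=self.maxiter)
        self.result_ = result
        self.params_ = result.params
        self.loglik_ = result.loglik
        self.aic_ = result.aic
        self.bic_ = result.bic
        self.n_params_ = result.n_params
        self.n_obs_ = result.n_obs
        self.viterbi_path_ = result.viterbi_path
        self.converged_ = result.converged
        self.n_starts_tried_ = result.n_starts_tried
        self.n_starts_failed_ = result.n_starts_failed
        return self

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("this MovementHMM instance is not fitted yet")

    def predict(self, X) -> np.ndarray:
        """Viterbi-decode the most probable state path of a track."""
        self._check_fitted()
        obs = _as_observations(X, self.angle_mode)
        return viterbi(obs, self.params_)

    def score(self, X, y=None) -> float:
        """Log likelihood of a track under the fitted parameters."""
        self._check_fitted()
        obs = _as_observations(X, self.angle_mode)
        return forward_loglik(obs, self.params_)
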