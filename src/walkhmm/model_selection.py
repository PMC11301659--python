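"""Starting grids, degenerate-state filtering and state-count selection.

The number of hidden states is chosen by fitting candidate state counts,
each from a deterministic grid of starting parameters, discarding fits
that contain a *degenerate state* (a state decoded for exactly one time
step), and taking the surviving candidate with the smallest BIC.  The
same machinery supports the paired comparison of the turning-angle
(relative, "r-HMM") and absolute-angle ("a-HMM") model on one track.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .distributions import VON_MISES, AngleDist, StepDist
from .geometry import Track
from .hmm import (
    ABSOLUTE,
    RELATIVE,
    FitFailedError,
    FitResult,
    HMMParams,
    HMMSpec,
    MovementHMM,
)

__all__ = [
    "starting_grid",
    "default_starts",
    "degenerate_filter",
    "ModelChoice",
    "ModelSelectionError",
    "StateCountSelector",
    "choose_model",
    "ModeComparison",
    "compare_modes",
    "paired_sign_test",
]

# per-state axes of the canonical starting grids: (angle mean, concentration,
# step mean, step sd).  The one-state step-sd value 5 is the published grid
# value; multi-state grids use 0.5.
_GRID_AXES = {
    1: [
        ([0.0, np.pi], [1.0, 5.0], [0.1, 0.4], [0.1, 5.0]),
    ],
    2: [
        ([0.0, np.pi / 8], [1.0, 2.0], [0.1, 0.4], [0.1, 0.5]),
        ([0.0, np.pi / 8], [1.0, 2.0], [0.1, 0.8], [0.1, 0.5]),
    ],
    3: [
        ([0.0], [1.0], [0.1], [0.1]),
        ([0.0, np.pi / 2], [1.0, 2.0], [0.1, 0.8], [0.1, 0.5]),
        ([0.0, np.pi / 2], [1.0, 2.0], [0.1, 0.4], [0.1, 0.5]),
    ],
    # extension beyond the published 1-3 state grids, used when fitting a
    # 4-state candidate (e.g. in the simulation study)
    4: [
        ([0.0], [1.0], [0.1], [0.1]),
        ([0.0, np.pi / 2], [1.0, 2.0], [0.1, 0.8], [0.1, 0.5]),
        ([0.0, np.pi / 2], [1.0, 2.0], [0.1, 0.4], [0.1, 0.5]),
        ([0.0, np.pi / 2], [1.0, 2.0], [0.1, 0.6], [0.1, 0.5]),
    ],
}


def _vm_conc_to_rho(kappa: float) -> float:
    """Map a von-Mises concentration start to a wrapped-Cauchy rho start."""
    return kappa / (kappa + 1.0)


def _uniform_offdiag_tpm(n: int, diag: float) -> np.ndarray:
    if n == 1:
        return np.ones((1, 1))
    off = (1.0 - diag) / (n - 1)
    return np.full((n, n), off) + np.eye(n) * (diag - off)


def _combo_to_params(combo, spec: HMMSpec, tpm_diag: float) -> HMMParams:
    n = spec.n_states
    angle_dists, step_dists = [], []
    for i in range(n):
        mu, conc, mu_g, sd_g = combo[4 * i:4 * i + 4]
        if spec.angle_family != VON_MISES:
            conc = _vm_conc_to_rho(conc)
        angle_dists.append(AngleDist(mu=mu, kappa=conc, family=spec.angle_family))
        step_dists.append(StepDist(mu_gamma=mu_g, sigma_gamma=sd_g))
    return HMMParams(
        angle_dists=tuple(angle_dists),
        step_dists=tuple(step_dists),
        tpm=_uniform_offdiag_tpm(n, tpm_diag),
    )


def _grid_combos(n_states: int):
    axes = []
    for state_axes in _GRID_AXES[n_states]:
        axes.extend(state_axes)
    return list(itertools.product(*axes))


def starting_grid(spec: HMMSpec, tpm_diag: float = 0.8,
                  extended: bool = False) -> list:
    """The canonical starting-parameter grid for ``spec.n_states`` states.

    Grid sizes are 16, 256 and 256 for one, two and three states.  Four
    states are outside the canonical grids; pass ``extended=True`` to get
    the analogous extension (4096 combinations).  Transition matrices
    start at diagonal ``tpm_diag`` with uniform off-diagonal mass.
    """
    n = spec.n_states
    if n not in _GRID_AXES or (n == 4 and not extended):
        raise ValueError(
            f"no canonical starting grid for {n} states; "
            "use extended=True or default_starts()"
        )
    return [_combo_to_params(c, spec, tpm_diag) for c in _grid_combos(n)]


def default_starts(spec: HMMSpec, max_starts: int | None = None,
                   tpm_diag: float = 0.8) -> list:
    """Starting points for fitting: the canonical grid, optionally thinned.

    ``max_starts`` keeps every grid point when None, otherwise selects a
    deterministic evenly-strided subset of at most ``max_starts`` points.
    Thinning keeps the corners of the grid spread (the product order
    interleaves all axes), and is the practical choice for simulation
    studies where the full 256-point grids are unnecessarily expensive.
    """
    combos = _grid_combos(spec.n_states)
    if max_starts is not None and max_starts < len(combos):
        idx = np.unique(np.linspace(0, len(combos) - 1, max_starts).astype(int))
        combos = [combos[i] for i in idx]
    return [_combo_to_params(c, spec, tpm_diag) for c in combos]


def degenerate_filter(result: FitResult, include_zero: bool = False):
    """Keep/discard rule for fits with degenerate states.

    A fit is discarded when some state is decoded for exactly one time
    step along the Viterbi path (optionally also when never decoded).

    Returns
    -------
    (bool, str or None)
        ``(True, None)`` to keep, ``(False, reason)`` to discard.
    """
    counts = result.state_counts()
    bad = counts == 1
    if include_zero:
        bad |= counts == 0
    if np.any(bad):
        states = np.flatnonzero(bad)
        return False, (
            "degenerate state(s) "
            + ", ".join(str(s) for s in states)
            + " occupied for "
            + ("<= 1" if include_zero else "exactly 1")
            + " time step"
        )
    return True, None


class ModelSelectionError(RuntimeError):
    """Every candidate state count failed or was discarded."""


@dataclass(frozen=True)
class ModelChoice:
    """Outcome of BIC selection across candidate state counts for one track."""

    mode: str
    candidates: dict  # n_states -> FitResult
    discarded: dict  # n_states -> reason string
    n_states: int
    result: FitResult

    @property
    def bic(self) -> float:
        return self.result.bic

    @property
    def aic(self) -> float:
        return self.result.aic


def select_by(candidates: dict, criterion: str = "bic",
              tie_tol: float = 1e-6) -> int:
    """Smallest-criterion state count; ties (within ``tie_tol``) go to fewer states."""
    if not candidates:
        raise ModelSelectionError("no surviving candidates to select from")
    values = {n: getattr(fit_res, criterion) for n, fit_res in candidates.items()}
    best = min(values.values())
    return min(n for n, v in values.items() if v <= best + tie_tol)


class StateCountSelector:
    """Fit 1..``max_states`` candidate HMMs and select the state count by BIC.

    Scikit-learn style: hyperparameters in ``__init__``, results in
    trailing-underscore attributes after :meth:`fit`.

    Parameters
    ----------
    angle_mode : {"relative", "absolute"}
    max_states : int
        Largest candidate state count (fits 1..max_states).
    angle_family : {"vonmises", "wrappedcauchy"}
    max_starts : int or None
        None fits every grid point; an integer thins the grid (see
        :func:`default_starts`).
    include_zero_occupancy : bool
        Extend the degenerate-state rule to never-decoded states.

    Attributes
    ----------
    candidates_ : dict mapping state count to FitResult
    discarded_ : dict mapping state count to discard/failure reason
    n_states_ : int
    best_result_ : FitResult
    bic_ : float
    """

    def __init__(self, angle_mode: str = RELATIVE, max_states: int = 3,
                 angle_family: str = VON_MISES, max_starts: int | None = None,
                 tpm_diag: float = 0.8, tol: float = 1e-8, maxiter: int = 1000,
                 include_zero_occupancy: bool = False, tie_tol: float = 1e-6):
        self.angle_mode = angle_mode
        self.max_states = max_states
        self.angle_family = angle_family
        self.max_starts = max_starts
        self.tpm_diag = tpm_diag
        self.tol = tol
        self.maxiter = maxiter
        self.include_zero_occupancy = include_zero_occupancy
        self.tie_tol = tie_tol

    def get_params(self, deep: bool = True) -> dict:
        return {
            "angle_mode": self.angle_mode,
            "max_states": self.max_states,
            "angle_family": self.angle_family,
            "max_starts": self.max_starts,
            "tpm_diag": self.tpm_diag,
            "tol": self.tol,
            "maxiter": self.maxiter,
            "include_zero_occupancy": self.include_zero_occupancy,
            "tie_tol": self.tie_tol,
        }

    def set_params(self, **kwargs):
        for key, value in kwargs.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y=None):
        candidates, discarded = {}, {}
        for n in range(1, self.max_states + 1):
            spec = HMMSpec(n_states=n, angle_mode=self.angle_mode,
                           angle_family=self.angle_family)
            est = MovementHMM(
                n_states=n, angle_mode=self.angle_mode,
                angle_family=self.angle_family,
                starts=(self.max_starts if self.max_starts is not None else "grid"),
                tpm_diag=self.tpm_diag, tol=self.tol, maxiter=self.maxiter,
            )
            try:
                est.fit(X)
            except FitFailedError as err:
                discarded[n] = f"fit failed: {err}"
                continue
            keep, reason = degenerate_filter(
                est.result_, include_zero=self.include_zero_occupancy
            )
            if keep:
                candidates[n] = est.result_
            else:
                discarded[n] = reason
        if not candidates:
            raise ModelSelectionError(
                f"all candidate state counts failed or were discarded: {discarded}"
            )
        self.candidates_ = candidates
        self.discarded_ = discarded
        self.n_states_ = select_by(candidates, "bic", self.tie_tol)
        self.best_result_ = candidates[self.n_states_]
        self.bic_ = self.best_result_.bic
        return self

    def choice_(self) -> ModelChoice:
        return ModelChoice(mode=self.angle_mode, candidates=self.candidates_,
                           discarded=self.discarded_, n_states=self.n_states_,
                           result=self.best_result_)


def choose_model(track: Track, mode: str = RELATIVE, max_states: int = 3,
                 **kwargs) -> ModelChoice:
    """BIC-selected state count for one track in one angular mode."""
    selector = StateCountSelector(angle_mode=mode, max_states=max_states, **kwargs)
    selector.fit(track)
    return selector.choice_()


@dataclass(frozen=True)
class ModeComparison:
    """Paired r-HMM vs a-HMM selection on the same track."""

    track_id: str
    relative: ModelChoice
    absolute: ModelChoice

    @property
    def delta_bic(self) -> float:
        """BIC(a-HMM) - BIC(r-HMM); negative favours the absolute-angle model."""
        return self.absolute.bic - self.relative.bic


def compare_modes(track: Track, max_states: int = 3, **kwargs) -> ModeComparison:
    """Run BIC state-count selection in both angular modes on one track."""
    rel = choose_model(track, RELATIVE, max_states=max_states, **kwargs)
    ab = choose_model(track, ABSOLUTE, max_states=max_states, **kwargs)
    return ModeComparison(track_id=track.id, relative=rel, absolute=ab)


def paired_sign_test(deltas):
    """Count of negative paired BIC differences plus a Wilcoxon signed-rank p.

    Returns ``(n_negative, n_total, p_value)`` for the two-sided test on
    the paired differences (a-HMM minus r-HMM BIC per track).
    """
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size < 2:
        raise ValueError("need at least 2 paired differences")
    if np.all(deltas == 0.0):
        raise ValueError("all differences are zero: signed-rank test undefined")
    n_negative = int(np.sum(deltas < 0))
    res = stats.wilcoxon(deltas, alternative="two-sided")
    return n_negative, int(deltas.size), float(res.pvalue)
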