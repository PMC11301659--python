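"""Track geometry: step lengths, turning and absolute angles, per-track PCA.

A track is an ordered sequence of positions ``X_0 .. X_T`` recorded at regular
time intervals.  Two angular views of the same increments exist:

* the *absolute angle* ``alpha_t`` of increment ``X_t - X_{t-1}``, measured
  counterclockwise from the positive x-axis (the convention of a biased
  random walk, BRW), and
* the *turning angle* ``theta_t`` between successive increments (the
  convention of a correlated random walk, CRW).

Both live in ``(-pi, pi]`` and are related by
``theta_t = wrap(alpha_t - alpha_{t-1})``.  Angles are undefined (NaN) where
an increment has zero length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Track",
    "StepSeries",
    "InvalidTrackError",
    "wrap_angle",
    "step_sizes",
    "absolute_angles",
    "turning_angles",
    "pca_project",
]


class InvalidTrackError(ValueError):
    """Raised when a track violates the preconditions of an operation."""


def wrap_angle(theta):
    """Wrap angles into ``(-pi, pi]``, choosing ``pi`` at the branch cut."""
    theta = np.asarray(theta, dtype=float)
    wrapped = np.mod(theta + np.pi, 2.0 * np.pi) - np.pi
    # mod maps the cut to -pi; the convention picks +pi
    wrapped = np.where(wrapped == -np.pi, np.pi, wrapped)
    return wrapped if wrapped.ndim else float(wrapped)


@dataclass(frozen=True)
class Track:
    """Ordered positions of one moving object at regular time steps.

    Parameters
    ----------
    id : str
        Track label.
    positions : ndarray of shape (T+1, d)
        Coordinates, ``d`` either 2 or 3.  The time step is implicit and
        constant.
    """

    id: str
    positions: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] not in (2, 3):
            raise InvalidTrackError(
                f"track {self.id!r}: positions must be (T+1, 2) or (T+1, 3), "
                f"got shape {pos.shape}"
            )
        if pos.shape[0] < 2:
            raise InvalidTrackError(
                f"track {self.id!r}: at least 2 positions required, got {pos.shape[0]}"
            )
        if not np.all(np.isfinite(pos)):
            raise InvalidTrackError(f"track {self.id!r}: non-finite coordinates")
        object.__setattr__(self, "positions", pos)

    @property
    def n_steps(self) -> int:
        """Number of increments T."""
        return self.positions.shape[0] - 1

    @property
    def ndim(self) -> int:
        return self.positions.shape[1]


@dataclass(frozen=True)
class StepSeries:
    """Per-increment step lengths and angles derived from a :class:`Track`.

    ``steps[t]``, ``abs_angles[t]`` refer to increment ``t+1`` of the track
    (1-based ``t = 1..T``); ``rel_angles`` has the same length with the first
    entry NaN because a turning angle needs two increments.  NaN marks any
    angle undefined due to a zero-length increment.
    """

    steps: np.ndarray
    abs_angles: np.ndarray
    rel_angles: np.ndarray

    def __post_init__(self):
        if not (len(self.steps) == len(self.abs_angles) == len(self.rel_angles)):
            raise ValueError("steps, abs_angles and rel_angles must share length")

    @classmethod
    def from_track(cls, track: Track) -> "StepSeries":
        steps = step_sizes(track)
        alpha = absolute_angles(track)
        theta = np.full_like(alpha, np.nan)
        if len(alpha) >= 2:
            theta[1:] = wrap_angle(alpha[1:] - alpha[:-1])
        return cls(steps=steps, abs_angles=alpha, rel_angles=theta)


def _increments(track: Track) -> np.ndarray:
    return np.diff(track.positions, axis=0)


def step_sizes(track: Track) -> np.ndarray:
    """Euclidean length of each increment ``X_t - X_{t-1}``, ``t = 1..T``."""
    if track.positions.shape[0] < 2:
        raise InvalidTrackError("need at least 2 positions for step sizes")
    return np.linalg.norm(_increments(track), axis=1)


def absolute_angles(track: Track) -> np.ndarray:
    """Angle of each increment from the positive x-axis, in ``(-pi, pi]``.

    NaN where the increment has zero length (direction undefined).  Only
    2-D tracks have a well-defined planar angle; reduce 3-D tracks with
    :func:`pca_project` first.
    """
    if track.ndim != 2:
        raise InvalidTrackError(
            "absolute angles are defined for 2-D tracks; apply pca_project first"
        )
    if track.positions.shape[0] < 2:
        raise InvalidTrackError("need at least 2 positions for absolute angles")
    inc = _increments(track)
    lengths = np.linalg.norm(inc, axis=1)
    alpha = np.arctan2(inc[:, 1], inc[:, 0])
    alpha = np.where(alpha == -np.pi, np.pi, alpha)
    return np.where(lengths > 0.0, alpha, np.nan)


def turning_angles(track: Track) -> np.ndarray:
    """Turning angles ``theta_t = wrap(alpha_t - alpha_{t-1})``, ``t = 2..T``.

    Returns T-1 values; NaN wherever either adjacent increment has zero
    length.
    """
    if track.positions.shape[0] < 3:
        raise InvalidTrackError("need at least 3 positions for turning angles")
    alpha = absolute_angles(track)
    return wrap_angle(alpha[1:] - alpha[:-1])


def pca_project(track: Track) -> tuple[Track, float]:
    """Project a 3-D track onto its first two principal components.

    Positions are centred (not scaled — all coordinates share units) and
    rotated onto the two leading eigenvectors of the position covariance.
    The sign of each component is fixed so that its largest-magnitude
    loading is positive, which makes the output orientation reproducible.

    Returns
    -------
    (Track, float)
        The projected 2-D track and the fraction of total coordinate
        variance captured by the two components.
    """
    pos = track.positions
    if pos.shape[1] != 3:
        raise InvalidTrackError("pca_project expects a 3-D track")
    if pos.shape[0] < 3:
        raise InvalidTrackError("need at least 3 positions for PCA")
    centred = pos - pos.mean(axis=0)
    cov = centred.T @ centred / (pos.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    total = eigvals.sum()
    if total <= 0.0:
        raise InvalidTrackError("degenerate track: all positions identical")
    comps = eigvecs[:, :2]
    for j in range(2):  # sign convention: largest loading positive
        k = np.argmax(np.abs(comps[:, j]))
        if comps[k, j] < 0:
            comps[:, j] = -comps[:, j]
    projected = centred @ comps
    var_explained = float(eigvals[:2].sum() / total)
    return Track(id=track.id, positions=projected), var_explained
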