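"""Track transformation turning absolute angles into turning angles.

A turning-angle HMM engine only ever sees the angles *between* successive
increments.  To fit a biased-random-walk model (absolute angles measured
from a fixed axis) with such an engine, the track is rebuilt so that the
original absolute angles ``alpha_1 .. alpha_T`` reappear as the turning
angles of the new track:

* a dummy first increment of configurable length is laid along the
  reference axis, so that even ``alpha_1`` becomes a defined turning angle;
* increment ``t`` of the output has the original step length ``S_t`` and
  heading ``psi_t = psi_{t-1} + alpha_t`` (cumulative rotation), so the
  turn at time ``t`` is exactly ``alpha_t``.

The dummy step carries no information about the data and is excluded from
the step-length likelihood downstream.
"""

from __future__ import annotations

import numpy as np

from .geometry import InvalidTrackError, Track, absolute_angles, step_sizes, wrap_angle

__all__ = ["absolutize", "heading_cumsum", "DUMMY_STEP_MEAN"]

#: sentinel: use the mean observed step length for the dummy increment
DUMMY_STEP_MEAN = "mean"


def heading_cumsum(abs_angles) -> np.ndarray:
    """Cumulative heading ``psi_t = wrap(sum_{u<=t} alpha_u)``."""
    abs_angles = np.asarray(abs_angles, dtype=float)
    if not np.all(np.isfinite(abs_angles)):
        raise ValueError("heading_cumsum requires finite angles")
    return wrap_angle(np.cumsum(abs_angles))


def absolutize(track: Track, dummy_step=DUMMY_STEP_MEAN) -> Track:
    """Rebuild ``track`` so its absolute angles become turning angles.

    Parameters
    ----------
    track : Track
        2-D input track with T increments.
    dummy_step : float or "mean"
        Length of the prepended reference increment; by default the mean
        observed step length, so the dummy does not distort step scale if
        a downstream consumer forgets to drop it.

    Returns
    -------
    Track
        Output with T+2 positions starting at the origin.  Its turning
        angles equal the input's absolute angles element-wise, and its step
        sizes (dummy excluded) equal the input's.  Zero-length input
        increments propagate as NaN turning angles.
    """
    if track.ndim != 2:
        raise InvalidTrackError("absolutize expects a 2-D track")
    steps = step_sizes(track)
    alpha = absolute_angles(track)
    if dummy_step == DUMMY_STEP_MEAN:
        dummy = float(steps.mean()) if steps.size else 1.0
        if dummy <= 0.0:
            dummy = 1.0
    else:
        dummy = float(dummy_step)
        if dummy <= 0.0:
            raise ValueError("dummy_step must be positive")

    # zero-length increments have undefined direction; carry the previous
    # heading forward so later angles are unaffected
    headings = np.zeros(len(alpha))
    psi = 0.0
    for t, a in enumerate(alpha):
        if np.isfinite(a):
            psi = psi + a
        headings[t] = psi
    headings = wrap_angle(headings)

    out = np.zeros((track.n_steps + 2, 2))
    out[1] = (dummy, 0.0)
    out[2:, 0] = dummy + np.cumsum(steps * np.cos(headings))
    out[2:, 1] = np.cumsum(steps * np.sin(headings))
    return Track(id=track.id, positions=out)
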