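"""Track table reading/writing, run configuration and result reports.

Track tables are plain-text CSV with header ``ID,x,y`` (optionally ``z``),
one row per time step, rows of one track contiguous and in time order —
the shape of typical 2-D particle-tracking exports.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .geometry import Track

__all__ = [
    "TrackParseError",
    "read_tracks",
    "write_tracks",
    "RunConfig",
    "report",
    "plot_decoded_track",
]


class TrackParseError(ValueError):
    """A track table could not be parsed; message includes row numbers."""


def read_tracks(path) -> list:
    """Read a track table into a list of :class:`Track`.

    Tracks are split on contiguous runs of the ID column, preserving row
    order; 2-D vs 3-D is detected from the presence of a ``z`` column.
    """
    try:
        df = pd.read_csv(path)
    except Exception as err:  # pragma: no cover - pandas message passthrough
        raise TrackParseError(f"{path}: {err}") from err
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in ("id", "x", "y") if c not in cols]
    if missing:
        raise TrackParseError(
            f"{path}: missing required column(s) {', '.join(missing)} "
            f"(found: {', '.join(df.columns)})"
        )
    coord_cols = [cols["x"], cols["y"]] + ([cols["z"]] if "z" in cols else [])
    for c in coord_cols:
        numeric = pd.to_numeric(df[c], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            rows = (np.flatnonzero(bad.to_numpy()) + 2)[:5]  # +2: header + 1-based
            raise TrackParseError(
                f"{path}: non-numeric value(s) in column {c!r} at row(s) "
                + ", ".join(map(str, rows))
            )
        df[c] = numeric
    ids = df[cols["id"]].astype(str).to_numpy()
    # contiguous runs of equal ID
    boundaries = np.flatnonzero(ids[1:] != ids[:-1])
    starts = np.concatenate([[0], boundaries + 1])
    ends = np.concatenate([boundaries + 1, [len(ids)]])
    tracks = []
    for a, b in zip(starts, ends):
        if b - a < 2:
            raise TrackParseError(
                f"{path}: track {ids[a]!r} starting at row {a + 2} has fewer "
                "than 2 positions"
            )
        tracks.append(Track(id=ids[a], positions=df.iloc[a:b][coord_cols].to_numpy()))
    return tracks


def write_tracks(tracks, path) -> None:
    """Write tracks to the CSV table format read by :func:`read_tracks`."""
    frames = []
    ndim = {t.ndim for t in tracks}
    if len(ndim) > 1:
        raise ValueError("cannot mix 2-D and 3-D tracks in one table")
    coord_cols = ["x", "y", "z"][: ndim.pop()]
    for t in tracks:
        frame = pd.DataFrame(t.positions, columns=coord_cols)
        frame.insert(0, "ID", t.id)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Serializable run configuration shared by the CLI commands."""

    angle_mode: str = "relative"
    angle_family: str = "vonmises"
    max_states: int = 3
    max_starts: int | None = None
    tpm_diag: float = 0.8
    tol: float = 1e-8
    maxiter: int = 1000
    seed: int = 0
    dwell_method: str = "viterbi_runs"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    def selector_kwargs(self) -> dict:
        return {
            "angle_family": self.angle_family,
            "max_states": self.max_states,
            "max_starts": self.max_starts,
            "tpm_diag": self.tpm_diag,
            "tol": self.tol,
            "maxiter": self.maxiter,
        }


def _params_record(params) -> dict:
    return {
        "states": [
            {
                "angle_mu": float(a.mu),
                "angle_concentration": float(a.kappa),
                "angle_family": a.family,
                "step_mean": float(s.mu_gamma),
                "step_sd": float(s.sigma_gamma),
            }
            for a, s in zip(params.angle_dists, params.step_dists)
        ],
        "tpm": np.asarray(params.tpm).round(6).tolist(),
        "delta": np.asarray(params.initial_distribution()).round(6).tolist(),
    }


def fit_record(result, dwell_method: str = "viterbi_runs") -> dict:
    """JSON-ready summary of one :class:`FitResult`."""
    from .hmm import dwell_times, transition_summary

    tpm, counts, occupancy, unobserved = transition_summary(result)
    dwell = dwell_times(result, method=dwell_method)
    return {
        "n_states": result.n_states,
        "loglik": round(result.loglik, 6),
        "aic": round(result.aic, 6),
        "bic": round(result.bic, 6),
        "n_params": result.n_params,
        "n_obs": result.n_obs,
        "params": _params_record(result.params),
        "transition_counts": counts.tolist(),
        "occupancy": occupancy.round(6).tolist(),
        "unobserved_transitions": unobserved.tolist(),
        "mean_dwell": [None if np.isnan(d) else round(float(d), 6) for d in dwell],
        "viterbi_path": [int(s) for s in result.viterbi_path],
        "n_starts_tried": result.n_starts_tried,
        "n_starts_failed": result.n_starts_failed,
    }


def report(results, out_prefix, dwell_method: str = "viterbi_runs") -> dict:
    """Write per-track JSON and a flat CSV summary for selection results.

    ``results`` maps track IDs to :class:`~walkhmm.model_selection.ModelChoice`
    or :class:`~walkhmm.model_selection.ModeComparison` objects.  Writes
    ``<out_prefix>.json`` and ``<out_prefix>.csv`` and returns the JSON
    payload.
    """
    from .model_selection import ModeComparison

    payload, rows = {}, []
    for track_id, res in results.items():
        if isinstance(res, ModeComparison):
            payload[track_id] = {
                "relative": fit_record(res.relative.result, dwell_method),
                "absolute": fit_record(res.absolute.result, dwell_method),
                "delta_bic": round(res.delta_bic, 6),
            }
            rows.append({
                "track_id": track_id,
                "n_states_relative": res.relative.n_states,
                "n_states_absolute": res.absolute.n_states,
                "bic_relative": round(res.relative.bic, 6),
                "bic_absolute": round(res.absolute.bic, 6),
                "delta_bic": round(res.delta_bic, 6),
            })
        else:  # ModelChoice
            payload[track_id] = {
                "mode": res.mode,
                "chosen": fit_record(res.result, dwell_method),
                "discarded": res.discarded,
            }
            rows.append({
                "track_id": track_id,
                "mode": res.mode,
                "n_states": res.n_states,
                "bic": round(res.bic, 6),
            })
    json_path = f"{out_prefix}.json"
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    pd.DataFrame(rows).to_csv(f"{out_prefix}.csv", index=False)
    return payload


def plot_decoded_track(track, path, out_path, cmap="viridis"):
    """Plot a track coloured by its decoded state sequence (optional extra)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    pos = track.positions
    path = np.asarray(path)
    colors = plt.get_cmap(cmap)(path / max(path.max(), 1))
    for t in range(len(path)):
        ax.plot(pos[t:t + 2, 0], pos[t:t + 2, 1], color=colors[t], lw=1.5)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.set_title(f"track {track.id}: decoded states")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
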