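"""Per-dog path characteristics: speeds, distances, return loops.

For each dog and walk this module computes the descriptive variables that
characterise how an individual uses the space around its owner: preferred
running speed (mode of the fast component of a two-lognormal fit to the
speed distribution), distance covered relative to the owner, mean distances
to the owner and to the other dogs, automatic detection of out-and-back
return loops, and the fraction of time spent relatively far from the owner.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from sklearn.mixture import GaussianMixture

from .track_preprocess import (
    PreprocessConfig,
    Walk,
    derive_motion,
    gaussian_smooth_series,
)

__all__ = [
    "ReturnParams",
    "ReturnEvent",
    "path_length",
    "relative_distance_covered",
    "preferred_running_speed",
    "detect_returns",
    "far_from_owner_ratio",
    "summarize_walk",
    "aggregate_study",
]


@dataclass(frozen=True)
class ReturnParams:
    """Return-loop detector thresholds.

    p_min : m       minimum prominence of a dog-owner distance maximum
    d_near : m      distance at which the dog counts as back with the owner
    smooth_sd : s   Gaussian smoothing of the distance series before peaks
    """

    p_min: float = 5.0
    d_near: float = 5.0
    smooth_sd: float = 1.0


@dataclass(frozen=True)
class ReturnEvent:
    dog_id: str
    t_start: float
    t_end: float
    start_distance: float
    end_distance: float
    loop_length: float

    def validate(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError("return event must have t_end > t_start")
        if not self.start_distance > self.end_distance:
            raise ValueError("return must start farther from the owner than it ends")


def path_length(track: np.ndarray) -> float:
    """Sum of consecutive-sample displacements of an (n, 2) track."""
    track = np.asarray(track, float)
    if len(track) < 2:
        raise ValueError("path_length needs at least 2 samples")
    return float(np.linalg.norm(np.diff(track, axis=0), axis=1).sum())


def relative_distance_covered(dog: np.ndarray, owner: np.ndarray) -> float:
    owner_len = path_length(owner)
    if owner_len == 0:
        raise ValueError("owner track has zero length")
    return path_length(dog) / owner_len


def preferred_running_speed(speeds: np.ndarray, random_state: int = 0) -> float:
    """Mode of the faster component of a two-lognormal mixture fit.

    Instantaneous speed distributions of running dogs are bimodal: a
    near-zero mode (standing, sniffing) and a running mode.  A two-component
    lognormal mixture is fitted by maximum likelihood to the positive
    speeds; the preferred running speed is the mode exp(mu2 - sigma2^2) of
    the higher-location component.  If the components collapse, a single
    lognormal is used instead (with a warning).
    """
    speeds = np.asarray(speeds, float)
    logs = np.log(speeds[speeds > 0])
    if len(logs) < 500:
        raise ValueError("need >= 500 positive-speed samples for the mixture fit")

    def _single_mode() -> float:
        return float(math.exp(logs.mean() - logs.var()))

    if np.ptp(logs) < 1e-12:
        warnings.warn("degenerate speed distribution; single-lognormal fallback")
        return _single_mode()
    gm = GaussianMixture(n_components=2, n_init=3, random_state=random_state)
    gm.fit(logs[:, None])
    mus = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    order = np.argsort(mus)
    mu_lo, mu_hi = mus[order]
    collapsed = (mu_hi - mu_lo) < 0.5 * max(sds) or gm.weights_.min() < 0.02
    if collapsed:
        warnings.warn("mixture components collapsed; single-lognormal fallback")
        return _single_mode()
    k = order[1]
    return float(math.exp(mus[k] - sds[k] ** 2))


def _distance_series(dog: np.ndarray, owner: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.asarray(dog, float) - np.asarray(owner, float), axis=1)


def detect_returns(dog: np.ndarray, owner: np.ndarray, dt: float,
                   params: ReturnParams = ReturnParams(),
                   dog_name: str = "dog") -> list[ReturnEvent]:
    """Find out-and-back loops from the dog-owner distance series.

    The smoothed distance d(t) is scanned for local maxima with prominence
    >= p_min; each maximum opens a candidate return that ends at the first
    subsequent time d(t) <= d_near.  Candidates that reach the next maximum
    before getting near the owner, or that are cut off by the end of the
    walk, are discarded.
    """
    d = _distance_series(dog, owner)
    d_s = gaussian_smooth_series(d, params.smooth_sd / dt)
    peaks, _ = find_peaks(d_s, prominence=params.p_min)
    events = []
    for p_idx, peak in enumerate(peaks):
        if d_s[peak] <= params.d_near:
            continue
        nxt = peaks[p_idx + 1] if p_idx + 1 < len(peaks) else len(d_s)
        below = np.flatnonzero(d_s[peak:nxt] <= params.d_near)
        if len(below) == 0:
            continue  # never reached the owner before the next excursion / walk end
        end = peak + below[0]
        ev = ReturnEvent(
            dog_id=dog_name,
            t_start=peak * dt,
            t_end=end * dt,
            start_distance=float(d_s[peak]),
            end_distance=float(d_s[end]),
            loop_length=path_length(dog[peak:end + 1]),
        )
        ev.validate()
        events.append(ev)
    return events


def return_period(events: list[ReturnEvent]) -> float:
    """Mean gap between consecutive return-event ends; NaN if < 2 returns."""
    if len(events) < 2:
        return float("nan")
    ends = np.array([e.t_end for e in events])
    return float(np.diff(np.sort(ends)).mean())


def far_from_owner_ratio(dog: np.ndarray, owner: np.ndarray,
                         f: float = 1.0, threshold: float | None = None) -> float:
    """Fraction of time the dog is farther from the owner than a threshold.

    By default the threshold is the dog's own walk-mean distance scaled by
    ``f``; pass ``threshold`` to use a fixed distance instead.
    """
    d = _distance_series(dog, owner)
    theta = float(d.mean()) * f if threshold is None else threshold
    return float(np.mean(d > theta))


def summarize_walk(walk: Walk, cfg: PreprocessConfig = PreprocessConfig(),
                   return_params: ReturnParams = ReturnParams(),
                   far_factor: float = 1.0) -> pd.DataFrame:
    """One row of path characteristics per dog for one (smoothed) walk."""
    motions = derive_motion(walk, cfg)
    owner = walk.positions[walk.owner_id]
    rows = {}
    for d in walk.dog_ids:
        dog = walk.positions[d]
        events = detect_returns(dog, owner, walk.dt, return_params, dog_name=d)
        others = [walk.positions[o] for o in walk.dog_ids if o != d]
        mean_dd = float(np.mean(
            [_distance_series(dog, o) for o in others])) if others else float("nan")
        try:
            pref = preferred_running_speed(motions[d].speed)
        except ValueError:
            pref = float("nan")
        try:
            rel_dist = relative_distance_covered(dog, owner)
        except ValueError:
            rel_dist = float("nan")
        rows[d] = {
            "preferred_running_speed": pref,
            "relative_distance_covered": rel_dist,
            "mean_distance_owner": float(_distance_series(dog, owner).mean()),
            "mean_distance_dogs": mean_dd,
            "return_period": return_period(events),
            "mean_loop_length": float(np.mean([e.loop_length for e in events]))
            if events else float("nan"),
            "n_returns": len(events),
            "far_from_owner_ratio": far_from_owner_ratio(dog, owner, f=far_factor),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "dog_id"
    out.insert(0, "walk_id", walk.walk_id)
    return out


def aggregate_study(summaries: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean +- sd over walks of each per-dog path characteristic."""
    stacked = pd.concat(summaries).drop(columns="walk_id")
    grouped = stacked.groupby(level=0)
    mean, sd = grouped.mean(), grouped.std()
    out = pd.concat({"mean": mean, "sd": sd}, axis=1)
    return out.swaplevel(axis=1).sort_index(axis=1)
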