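"""End-to-end study analysis: walks in, leadership network out.

Ties the stages together the way the field study is analysed: smooth each
walk, derive headings, collect directional-correlation delay events for
every (canonical) dog pair across walks, build per-pair delay histograms,
calibrate the acceptance cutoff on the randomization null, classify pairs
and assemble the leadership network with node scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .delay_correlation import (
    DelayConfig,
    DelayHistogram,
    PairRelation,
    build_delay_histogram,
    classify_pair,
    pair_delay_events,
    randomization_null_sds,
)
from .leadership_network import LeadershipNetwork, build_network, node_scores
from .track_preprocess import PreprocessConfig, Walk, derive_motion, smooth_positions

__all__ = ["StudyResult", "collect_pair_events", "analyze_study"]


def canonical_pairs(dog_ids: list[str]) -> list[tuple[str, str]]:
    dogs = sorted(dog_ids)
    return [(a, b) for i, a in enumerate(dogs) for b in dogs[i + 1:]]


def collect_pair_events(walks: list[Walk], pre_cfg: PreprocessConfig,
                        cfg: DelayConfig) -> dict:
    """pair -> {walk_id -> [CorrelationEvent]} for all canonical dog pairs.

    Only dog-dog pairs enter: the owner's direction changes live on a much
    longer timescale and are excluded by role.
    """
    events: dict = {p: {} for p in canonical_pairs(walks[0].dog_ids)}
    for walk in walks:
        smoothed = smooth_positions(walk, pre_cfg)
        motions = derive_motion(smoothed, pre_cfg)
        for (a, b) in events:
            evs = pair_delay_events(
                motions[a], motions[b], cfg, dt=walk.dt, pair=(a, b),
                walk_id=walk.walk_id, t0=float(walk.t[0]),
                pos_i=smoothed.positions[a], pos_j=smoothed.positions[b])
            events[(a, b)][walk.walk_id] = evs
    return events


@dataclass
class StudyResult:
    histograms: dict[tuple[str, str], DelayHistogram]
    relations: list[PairRelation]
    network: LeadershipNetwork
    cutoff: float
    null_sds: np.ndarray
    events: dict = field(repr=False, default_factory=dict)

    def node_table(self) -> pd.DataFrame:
        return node_scores(self.network)

    def event_frame(self) -> pd.DataFrame:
        rows = [
            {"pair_i": e.pair[0], "pair_j": e.pair[1], "walk_id": e.walk_id,
             "t_center": e.t_center, "tau_star": e.tau_star, "c_max": e.c_max,
             "distance": e.distance}
            for per_walk in self.events.values()
            for evs in per_walk.values()
            for e in evs
        ]
        return pd.DataFrame(rows)


def analyze_study(walks: list[Walk],
                  cfg: DelayConfig = DelayConfig(),
                  pre_cfg: PreprocessConfig = PreprocessConfig(),
                  seed: int = 0) -> StudyResult:
    """Run the full delay-analysis pipeline on a set of walks."""
    events = collect_pair_events(walks, pre_cfg, cfg)
    n_walks = len(walks)
    rng = np.random.default_rng(seed)
    hists = {
        pair: build_delay_histogram(
            [e for evs in per_walk.values() for e in evs], n_walks, cfg, pair=pair)
        for pair, per_walk in events.items()
    }
    null_sds = randomization_null_sds(events, cfg, seed=int(rng.integers(2 ** 31)))
    cutoff = float(np.quantile(null_sds, cfg.null_quantile))
    relations = [
        classify_pair(h, cutoff, cfg, seed=int(rng.integers(2 ** 31)))
        for h in hists.values()
    ]
    dogs = sorted(walks[0].dog_ids)
    network = build_network(relations, nodes=dogs)
    return StudyResult(hists, relations, network, cutoff, null_sds, events)
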