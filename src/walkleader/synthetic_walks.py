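"""Agent-based generator of owner+dogs walks with known leader-follower coupling.

The generator emulates the phenomenology of a group dog walk recorded at
5 Hz: the owner traverses a grassy field along smoothed random waypoints at
roughly constant speed; each dog alternates between running out from the
owner and returning (out-and-back loops at its individual preferred speed,
with occasional near-stationary pauses); and, episodically, an ordered pair
of dogs runs a joint loop during which the follower copies the leader's
heading with a fixed pair-specific time delay.  Positions are finally
perturbed by isotropic GPS noise.

The imposed delays, episode times and directed couplings are returned as a
:class:`GroundTruth`, so every downstream inference stage can be scored
against what actually generated the data.  The coupling lives on headings,
not positions, because the delay-inference method operates on headings.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .track_preprocess import Walk

__all__ = [
    "Coupling",
    "SimConfig",
    "Episode",
    "GroundTruth",
    "generate_walk",
    "generate_study",
    "dog_id",
    "OWNER_ID",
]

OWNER_ID = "O"


def dog_id(k: int) -> str:
    """1-based dog index -> individual id."""
    return f"D{k}"


@dataclass(frozen=True)
class Coupling:
    """One ordered leader->follower coupling.

    delay : s
        Typical time by which the follower's heading lags the leader's (> 0).
    episode_rate : episodes/min
        Poisson rate of joint-loop episodes for this pair.
    episode_length : s
        Duration of each episode.
    lead_share : fraction
        Portion of episodes in which the designated leader actually leads;
        in the remainder the roles are reversed (with the same delay
        magnitude).  Leader and follower roles in real pairs are dynamically
        interchanged, with the longer-term leader ahead in roughly 57-85%
        of interactions; 0.7 emulates that.
    delay_jitter_sd : s
        Sd of the per-episode perturbation of the realized delay, emulating
        the event-to-event scatter of reaction latencies that gives observed
        delay histograms their width.  Set to 0 for an exactly reproducible
        lag.
    """

    delay: float
    episode_rate: float = 1.5
    episode_length: float = 10.0
    lead_share: float = 0.7
    delay_jitter_sd: float = 0.2


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a simulated walk.

    Defaults follow the recorded field study this generator emulates:
    30-40 min walks sampled at 0.2 s, an owner at ~1.1 m/s on a 500x1000 m
    field, dog preferred running speeds spanning 1.4-4.0 m/s, return-loop
    periods of roughly 40-110 s, and 1-2 m GPS noise.
    """

    n_dogs: int = 6
    duration: float = 2100.0  # s, mid 30-40 min
    sample_dt: float = 0.2  # s, 5 Hz
    owner_speed: float = 1.1  # m/s
    preferred_speeds: tuple[float, ...] | None = None  # m/s per dog
    loop_period_mean: tuple[float, ...] | None = None  # s per dog
    coupling: dict[tuple[int, int], Coupling] = field(default_factory=dict)
    heading_noise: float = 0.15  # rad sd per 0.2 s step
    gps_noise_sd: float = 1.5  # m, isotropic
    field_size: tuple[float, float] = (1000.0, 500.0)  # m
    pause_rate: float = 2.0  # pauses/min per dog
    pause_length: float = 3.0  # s mean
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dogs < 1:
            raise ValueError("n_dogs must be >= 1")
        if self.sample_dt <= 0:
            raise ValueError("sample_dt must be > 0")
        n_steps = self.duration / self.sample_dt
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("duration must be a multiple of sample_dt")
        if self.gps_noise_sd < 0:
            raise ValueError("gps_noise_sd must be >= 0")
        for (i, j), c in self.coupling.items():
            if i == j:
                raise ValueError(f"coupling defined for i == j ({i})")
            if not (1 <= i <= self.n_dogs and 1 <= j <= self.n_dogs):
                raise ValueError(f"coupling pair ({i},{j}) outside 1..{self.n_dogs}")
            lag = c.delay / self.sample_dt
            if abs(lag - round(lag)) > 1e-9 or c.delay <= 0:
                raise ValueError(
                    f"coupling delay {c.delay} s must be a positive multiple "
                    f"of sample_dt")

    def speeds(self) -> np.ndarray:
        if self.preferred_speeds is not None:
            if len(self.preferred_speeds) != self.n_dogs:
                raise ValueError("preferred_speeds length must equal n_dogs")
            return np.asarray(self.preferred_speeds, float)
        return np.linspace(1.4, 4.0, self.n_dogs)

    def loop_periods(self) -> np.ndarray:
        if self.loop_period_mean is not None:
            if len(self.loop_period_mean) != self.n_dogs:
                raise ValueError("loop_period_mean length must equal n_dogs")
            return np.asarray(self.loop_period_mean, float)
        return np.linspace(40.0, 108.0, self.n_dogs)


@dataclass(frozen=True)
class Episode:
    walk_id: str
    pair: tuple[str, str]  # (leader, follower) of THIS episode (roles may swap)
    t_start: float
    t_end: float
    lag_s: float = 0.0  # realized heading-copy delay of this episode


@dataclass
class GroundTruth:
    """What the generator imposed: delays, episodes, directed edges."""

    delay_matrix: dict[tuple[str, str], float]  # ordered pair -> s (antisym.)
    episode_log: list[Episode]
    true_directed_edges: set[tuple[str, str]]  # (leader, follower)

    def validate(self) -> None:
        for (i, j), d in self.delay_matrix.items():
            if abs(self.delay_matrix[(j, i)] + d) > 1e-12:
                raise ValueError("delay matrix is not antisymmetric")
        for ep in self.episode_log:
            if ep.pair not in self.delay_matrix:
                raise ValueError(f"episode references unknown pair {ep.pair}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "delay_matrix": {f"{i}->{j}": d for (i, j), d in self.delay_matrix.items()},
            "episodes": [
                {"walk_id": e.walk_id, "leader": e.pair[0], "follower": e.pair[1],
                 "t_start": e.t_start, "t_end": e.t_end}
                for e in self.episode_log
            ],
            "true_directed_edges": sorted(self.true_directed_edges),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _schedule_episodes(cfg: SimConfig, rng: np.random.Generator,
                       walk_id: str) -> list[Episode]:
    """Per-pair Poisson schedules, thinned so that no individual is in two
    episodes at once (a follower's heading would otherwise be over-determined)."""
    dt = cfg.sample_dt
    proposals: list[tuple[float, float, tuple[str, str], float]] = []
    for (i, j), c in sorted(cfg.coupling.items()):
        n_exp = c.episode_rate / 60.0 * cfg.duration
        n_ep = rng.poisson(n_exp)
        lead, foll = dog_id(i), dog_id(j)
        starts = np.sort(rng.uniform(0.0, cfg.duration - c.episode_length,
                                     size=n_ep)) if cfg.duration > c.episode_length else []
        for t0 in starts:
            # per-episode role and reaction latency
            pair = (lead, foll) if rng.random() < c.lead_share else (foll, lead)
            lag = c.delay + (rng.normal(0.0, c.delay_jitter_sd)
                             if c.delay_jitter_sd > 0 else 0.0)
            lag = max(1, round(lag / dt)) * dt
            proposals.append((float(t0), float(t0 + c.episode_length), pair, lag))
    proposals.sort()
    busy_until: dict[str, float] = {}
    kept: list[Episode] = []
    for t0, t1, pair, lag in proposals:
        if max(busy_until.get(pair[0], -1.0), busy_until.get(pair[1], -1.0)) > t0:
            continue
        busy_until[pair[0]] = busy_until[pair[1]] = t1
        kept.append(Episode(walk_id, pair, t0, t1, lag))
    if cfg.coupling and not kept:
        warnings.warn("duration too short to schedule any coupling episode")
    return kept


def _wrap(a: float) -> float:
    return (a + math.pi) % (2 * math.pi) - math.pi


def generate_walk(cfg: SimConfig, seed: int | None = None,
                  walk_id: str = "walk01") -> tuple[Walk, GroundTruth]:
    """Simulate one walk; same (cfg, seed) gives a bit-identical result."""
    if seed is None:
        seed = cfg.seed
    ss = np.random.SeedSequence([cfg.seed, int(seed)])
    rng_sched, rng_dyn, rng_gps = (np.random.default_rng(s) for s in ss.spawn(3))

    dt = cfg.sample_dt
    n = round(cfg.duration / dt)
    t = np.arange(n) * dt
    speeds = cfg.speeds()
    periods = cfg.loop_periods()
    fx, fy = cfg.field_size
    ids = [OWNER_ID] + [dog_id(k + 1) for k in range(cfg.n_dogs)]
    roles = {i: ("owner" if i == OWNER_ID else "dog") for i in ids}

    episodes = _schedule_episodes(cfg, rng_sched, walk_id)
    # per-sample episode lookup: individual -> (role, partner index info)
    lead_of = {i: np.full(n, -1, dtype=int) for i in ids}  # episode idx as leader
    follow_of = {i: np.full(n, -1, dtype=int) for i in ids}
    for e_idx, ep in enumerate(episodes):
        k0, k1 = round(ep.t_start / dt), min(n, round(ep.t_end / dt))
        lead_of[ep.pair[0]][k0:k1] = e_idx
        follow_of[ep.pair[1]][k0:k1] = e_idx
    ep_turn = rng_dyn.uniform(0.3, 0.8, size=max(len(episodes), 1)) * \
        rng_dyn.choice([-1.0, 1.0], size=max(len(episodes), 1))
    ep_lag = [round(ep.lag_s / dt) for ep in episodes]

    # Pause (near-stationary) intervals per dog.
    pause = {i: np.zeros(n, dtype=bool) for i in ids[1:]}
    for d in ids[1:]:
        n_pause = rng_dyn.poisson(cfg.pause_rate / 60.0 * cfg.duration)
        for t0 in rng_dyn.uniform(0, cfg.duration, size=n_pause):
            ln = rng_dyn.exponential(cfg.pause_length)
            k0, k1 = round(t0 / dt), min(n, round((t0 + ln) / dt))
            pause[d][k0:k1] = True

    theta = {i: np.zeros(n) for i in ids}  # true headings (rad)
    spd = {i: np.zeros(n) for i in ids}  # true speeds
    pos = {i: np.zeros((n, 2)) for i in ids}

    # --- owner: smoothed random-waypoint traversal at constant speed -------
    owner_xy = np.array([fx / 2.0, fy / 2.0])
    waypoint = rng_dyn.uniform([0, 0], [fx, fy])
    oth = rng_dyn.uniform(-math.pi, math.pi)
    max_turn_owner = 0.05  # rad per step: slow, smooth direction changes

    # --- dogs: correlated random walk with out-and-back loop state --------
    dog_phase = {d: "out" for d in ids[1:]}
    excursion = {
        dog_id(k + 1): max(8.0, speeds[k] * periods[k] / 4.0)
        for k in range(cfg.n_dogs)
    }
    dth = {d: rng_dyn.uniform(-math.pi, math.pi) for d in ids[1:]}
    dog_xy = {d: owner_xy + rng_dyn.normal(0, 3.0, size=2) for d in ids[1:]}
    log_jitter = 0.15  # lognormal speed jitter around the preferred speed
    run_mu = {dog_id(k + 1): math.log(speeds[k]) + log_jitter ** 2
              for k in range(cfg.n_dogs)}
    pause_mu = math.log(0.25) + 0.4 ** 2  # slow mode ~0.25 m/s

    # Pre-draw per-step noises for speed (vectorized; order is fixed).
    run_speed = {d: np.exp(rng_dyn.normal(run_mu[d], log_jitter, size=n))
                 for d in ids[1:]}
    slow_speed = {d: np.exp(rng_dyn.normal(pause_mu, 0.4, size=n)) for d in ids[1:]}
    h_noise = {d: rng_dyn.normal(0.0, 1.0, size=n) for d in ids[1:]}

    for k in range(n):
        # owner step
        if np.hypot(*(waypoint - owner_xy)) < 15.0:
            waypoint = rng_dyn.uniform([0, 0], [fx, fy])
        target = math.atan2(*(waypoint - owner_xy)[::-1])
        oth += np.clip(_wrap(target - oth), -max_turn_owner, max_turn_owner)
        theta[OWNER_ID][k] = oth
        spd[OWNER_ID][k] = cfg.owner_speed
        pos[OWNER_ID][k] = owner_xy
        owner_xy = owner_xy + cfg.owner_speed * dt * np.array(
            [math.cos(oth), math.sin(oth)])

        for di, d in enumerate(ids[1:]):
            e_f = follow_of[d][k]
            e_l = lead_of[d][k]
            if e_f >= 0:
                # follower: copy the leader's heading, lagged
                lag = ep_lag[e_f]
                leader = episodes[e_f].pair[0]
                src = theta[leader][k - lag] if k - lag >= 0 else theta[leader][0]
                dth[d] = src + cfg.heading_noise * h_noise[d][k]
                s = run_speed[d][k]
            elif e_l >= 0:
                # leader: run a loop with a per-episode constant turn rate
                dth[d] = dth[d] + ep_turn[e_l] * dt + cfg.heading_noise * h_noise[d][k]
                s = run_speed[d][k]
            else:
                rel = dog_xy[d] - pos[OWNER_ID][k]
                dist = float(np.hypot(*rel))
                if dog_phase[d] == "out" and dist > excursion[d]:
                    dog_phase[d] = "in"
                elif dog_phase[d] == "in" and dist < 4.0:
                    dog_phase[d] = "out"
                away = math.atan2(rel[1], rel[0])
                target = away if dog_phase[d] == "out" else away + math.pi
                steer = np.clip(_wrap(target - dth[d]), -0.3, 0.3)
                dth[d] = dth[d] + 0.25 * steer + cfg.heading_noise * h_noise[d][k]
                s = slow_speed[d][k] if pause[d][k] else run_speed[d][k]
            theta[d][k] = dth[d]
            spd[d][k] = s
            pos[d][k] = dog_xy[d]
            dog_xy[d] = dog_xy[d] + s * dt * np.array(
                [math.cos(dth[d]), math.sin(dth[d])])

    positions = {}
    for i in ids:
        noise = rng_gps.normal(0.0, cfg.gps_noise_sd, size=(n, 2)) \
            if cfg.gps_noise_sd > 0 else 0.0
        positions[i] = pos[i] + noise

    walk = Walk(walk_id, t, positions, roles)
    walk.validate()
    truth = _ground_truth(cfg, episodes)
    # stash noise-free state for oracle-style checks
    walk.true_positions = pos  # type: ignore[attr-defined]
    walk.true_headings = theta  # type: ignore[attr-defined]
    walk.true_speeds = spd  # type: ignore[attr-defined]
    return walk, truth


def _ground_truth(cfg: SimConfig, episodes: list[Episode]) -> GroundTruth:
    delay = {}
    edges = set()
    for (i, j), c in cfg.coupling.items():
        li, lj = dog_id(i), dog_id(j)
        delay[(li, lj)] = c.delay
        delay[(lj, li)] = -c.delay
        edges.add((li, lj))
    gt = GroundTruth(delay, episodes, edges)
    gt.validate()
    return gt


def generate_study(cfg: SimConfig, n_walks: int, seed: int | None = None
                   ) -> tuple[list[Walk], GroundTruth]:
    """Independent walks sharing one coupling (fresh noise/episodes per walk)."""
    if n_walks < 1:
        raise ValueError("n_walks must be >= 1")
    if seed is None:
        seed = cfg.seed
    walks = []
    episodes: list[Episode] = []
    truth: GroundTruth | None = None
    for w in range(n_walks):
        walk, gt = generate_walk(cfg, seed=int(seed) * 100_003 % (2 ** 31) + w,
                                 walk_id=f"walk{w + 1:02d}")
        walks.append(walk)
        episodes.extend(gt.episode_log)
        truth = gt
    assert truth is not None
    truth.episode_log = episodes
    return walks, truth
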