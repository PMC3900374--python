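import math

import numpy as np
import pytest

from walkleader.delay_correlation import (
    CorrelationEvent,
    DelayConfig,
    bootstrap_peak_sd,
    build_delay_histogram,
    classify_pair,
    correlation_to_angle,
    leading_ratio,
    pair_delay_events,
    randomization_null_sds,
)
from walkleader.track_preprocess import HeadingSeries


def heading_series(angles, moving=None):
    angles = np.asarray(angles, float)
    u = np.column_stack([np.cos(angles), np.sin(angles)])
    moving = np.ones(len(angles), bool) if moving is None else np.asarray(moving)
    u = np.where(moving[:, None], u, np.nan)
    speed = np.where(moving, 1.0, 0.0)
    return HeadingSeries(u * speed[:, None], speed, u, moving)


def wobble(rng, n, scale=0.6):
    """A smoothly turning heading-angle series (identifiable delays)."""
    return np.cumsum(rng.normal(0, scale * 0.2, size=n)) + \
        0.8 * np.sin(np.arange(n) * 0.07)


def brute_force_events(h_i, h_j, cfg, dt=0.2):
    """Naive full (t, tau) scan with no shortcuts; same window convention:
    a sample pair (s, s+lag) belongs to the window at c iff its midpoint
    s + lag/2 is within t_win/2 of c."""
    u_i, u_j = h_i.heading, h_j.heading
    n = len(u_i)
    taus = cfg.tau_grid()
    lags = np.round(taus / dt).astype(int)
    half = cfg.t_win / 2.0 / dt
    stride = max(1, round(cfg.stride / dt))
    c0 = math.ceil(half + max(abs(lags)) / 2)
    events = []
    for c in range(c0, n - c0, stride):
        best_c, cand = -np.inf, []
        for tau, lag in zip(taus, lags):
            prods, slots = [], 0
            for s in range(n):
                if not 0 <= s + lag < n:
                    continue
                if abs(s + lag / 2.0 - c) <= half + 1e-9:
                    slots += 1
                    p = float(u_i[s] @ u_j[s + lag])
                    if np.isfinite(p):
                        prods.append(p)
            if slots and len(prods) >= max(math.ceil(cfg.min_valid * slots), 1):
                val = float(np.mean(prods))
                if val > best_c + 1e-12:
                    best_c, cand = val, [tau]
                elif abs(val - best_c) <= 1e-12 * max(abs(best_c), 1.0):
                    cand.append(tau)
        if cand and best_c > cfg.c_min:
            tau_star = sorted(cand, key=lambda t: (abs(t), t > 0))[0]
            if abs(tau_star) < cfg.tau_max - 1e-12:
                events.append((c * dt, tau_star, best_c))
    return events


class TestCorrelationToAngle:
    @pytest.mark.parametrize("c, deg", [(0.95, 18.2), (0.99, 8.1), (1.0, 0.0)])
    def test_threshold_angles(self, c, deg):
        assert correlation_to_angle(c) == pytest.approx(deg, abs=0.05)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            correlation_to_angle(1.01)


class TestPairDelayEvents:
    def test_identity_pair_all_zero_delay(self, rng):
        h = heading_series(wobble(rng, 200))
        cfg = DelayConfig(tau_max=2.0)
        events = pair_delay_events(h, h, cfg)
        assert events
        assert all(e.tau_star == 0.0 and e.c_max == pytest.approx(1.0)
                   for e in events)

    def test_constructed_shift_recovered_exactly(self, rng):
        ang = wobble(rng, 300)
        lag = 3
        h_i = heading_series(ang)
        # j's heading at t equals i's at t - 3 samples: i leads by 0.6 s
        h_j = heading_series(np.concatenate([ang[:lag], ang[:-lag]]))
        events = pair_delay_events(h_i, h_j, DelayConfig(tau_max=2.0))
        assert events
        late = [e for e in events if e.t_center > 2.0]
        assert all(e.tau_star == pytest.approx(0.6) for e in late)
        assert all(e.c_max == pytest.approx(1.0) for e in late)

    def test_matches_brute_force_oracle(self, rng):
        ang_i = wobble(rng, 240)
        ang_j = np.concatenate([ang_i[:3], ang_i[:-3]]) + rng.normal(0, 0.1, 240)
        moving_j = rng.random(240) > 0.1  # some undefined headings
        h_i = heading_series(ang_i)
        h_j = heading_series(ang_j, moving_j)
        cfg = DelayConfig(tau_max=2.0, c_min=0.9)
        fast = pair_delay_events(h_i, h_j, cfg)
        slow = brute_force_events(h_i, h_j, cfg)
        assert len(fast) == len(slow)
        for e, (t, tau, c) in zip(fast, slow):
            assert e.t_center == pytest.approx(t)
            assert e.tau_star == pytest.approx(tau)
            assert e.c_max == pytest.approx(c, abs=1e-12)

    def test_mirror_antisymmetry_exact(self, rng):
        ang_i = wobble(rng, 300)
        ang_j = np.concatenate([ang_i[:2], ang_i[:-2]]) + rng.normal(0, 0.15, 300)
        h_i, h_j = heading_series(ang_i), heading_series(ang_j)
        cfg = DelayConfig(tau_max=2.0, c_min=0.9)
        fwd = pair_delay_events(h_i, h_j, cfg, pair=("i", "j"))
        rev = pair_delay_events(h_j, h_i, cfg, pair=("j", "i"))
        assert len(fwd) == len(rev)
        for a, b in zip(fwd, rev):
            assert a.t_center == b.t_center
            assert a.tau_star == -b.tau_star
            assert a.c_max == b.c_max

    def test_mismatched_grids_rejected(self, rng):
        h1 = heading_series(wobble(rng, 100))
        h2 = heading_series(wobble(rng, 120))
        with pytest.raises(ValueError, match="grid"):
            pair_delay_events(h1, h2, DelayConfig())


def events_at(taus, pair=("a", "b")):
    return [CorrelationEvent(pair, "w1", float(i), float(t), 0.99)
            for i, t in enumerate(taus)]


class TestDelayHistogram:
    def test_counts_normalized_by_walks(self):
        h = build_delay_histogram(events_at([0.2] * 30), n_walks=3,
                                  cfg=DelayConfig())
        assert h.counts.sum() == pytest.approx(h.n_events / 3)
        assert h.n_events == 30

    def test_point_mass_at_zero(self):
        h = build_delay_histogram(events_at([0.0] * 50), 1, DelayConfig())
        assert h.tau_mode == 0.0
        np.testing.assert_allclose(h.smoothed, h.smoothed[::-1], atol=1e-12)

    def test_jittered_peak_location(self, rng):
        taus = np.round((0.6 + rng.normal(0, 0.2, 300)) / 0.2) * 0.2
        h = build_delay_histogram(events_at(taus), 1, DelayConfig())
        assert h.tau_mode == pytest.approx(0.6, abs=0.05)

    def test_symmetric_lobes_tie_break_negative_and_wide_fwhm(self):
        h = build_delay_histogram(events_at([1.0] * 40 + [-1.0] * 40), 1,
                                  DelayConfig())
        assert h.tau_mode == -1.0  # ties resolve to the negative side
        assert h.fwhm > 2.0  # spans both lobes

    def test_empty_events(self):
        h = build_delay_histogram([], 5, DelayConfig(), pair=("a", "b"))
        assert h.n_events == 0 and np.isnan(h.tau_mode)


class TestBootstrapPeakSd:
    def test_point_mass_has_zero_sd(self):
        assert bootstrap_peak_sd(events_at([0.4] * 60), 1, DelayConfig(),
                                 seed=1) == pytest.approx(0.0, abs=1e-9)

    def test_too_few_events_flagged(self):
        with pytest.raises(ValueError, match="too few"):
            bootstrap_peak_sd(events_at([0.4] * 5), 1, DelayConfig(), seed=1)

    def test_matches_event_resampling_oracle(self, rng):
        # oracle: literal event resampling with replacement, rebuilding the
        # smoothed histogram each time (independent of the multinomial path)
        cfg = DelayConfig(n_boot=400)
        for taus, label in [
            (rng.uniform(-5, 5, 200), "uniform"),
            (0.6 + rng.normal(0, 0.3, 300), "unimodal"),
        ]:
            taus = np.clip(np.round(taus / 0.2) * 0.2, -5, 5)
            evs = events_at(taus)
            sd = bootstrap_peak_sd(evs, 1, cfg, seed=3)
            args = []
            for _ in range(400):
                sample = [evs[k] for k in rng.integers(0, len(evs), len(evs))]
                args.append(build_delay_histogram(sample, 1, cfg).tau_mode)
            oracle = float(np.std(args, ddof=1))
            if label == "uniform":
                assert sd > 1.0 and oracle > 1.0
                assert sd == pytest.approx(oracle, rel=0.35)
            else:
                assert sd < 0.3
                assert sd == pytest.approx(oracle, abs=0.05)


class TestRandomizationNull:
    def test_identical_zero_peaked_pairs_all_accepted(self):
        # degenerate: every pair has the same histogram spiked at tau = 0,
        # which is mirror-invariant, so all composites are identical
        per_pair = {
            (a, b): {"w1": events_at([0.0] * 40, (a, b)),
                     "w2": events_at([0.0] * 40, (a, b))}
            for a, b in [("A", "B"), ("A", "C"), ("B", "C")]
        }
        cfg = DelayConfig(n_rand=200, n_boot_null=200)
        sds = randomization_null_sds(per_pair, cfg, seed=2)
        assert np.allclose(sds, 0.0)
        cutoff = float(np.quantile(sds, cfg.null_quantile))
        common_sd = bootstrap_peak_sd(per_pair[("A", "B")]["w1"] * 2, 2, cfg, 3)
        assert common_sd <= cutoff + 1e-12  # every pair accepted

    def test_quantile_monotone_in_cutoff_level(self, rng):
        per_pair = {
            (a, b): {"w1": events_at(
                list(np.round(rng.uniform(-5, 5, 80) / 0.2) * 0.2), (a, b))}
            for a, b in [("A", "B"), ("A", "C"), ("B", "C")]
        }
        cfg = DelayConfig(n_rand=300, n_boot_null=100)
        sds = randomization_null_sds(per_pair, cfg, seed=4)
        # raising the acceptance quantile never removes an accepted pair
        assert np.quantile(sds, 0.05) <= np.quantile(sds, 0.25) <= \
            np.quantile(sds, 0.75)

    def test_needs_two_pairs(self):
        with pytest.raises(ValueError, match="2 pairs"):
            randomization_null_sds({("A", "B"): {}}, DelayConfig(), seed=1)


class TestLeadingRatioAndClassification:
    def test_symmetric_histogram_gives_half(self):
        h = build_delay_histogram(
            events_at(list(np.repeat([-0.4, -0.2, 0.0, 0.2, 0.4],
                                     [10, 20, 30, 20, 10]))), 1, DelayConfig())
        assert leading_ratio(h, DelayConfig()) == pytest.approx(0.5, abs=0.02)

    def test_tight_one_sided_mass_saturates(self):
        # a point mass at +0.6 smoothed with the 0.3 s kernel leaves
        # Phi(0.6/0.3) of the fitted Gaussian on the leader's side
        from scipy.stats import norm
        h = build_delay_histogram(events_at([0.6] * 200), 1, DelayConfig())
        ratio = leading_ratio(h, DelayConfig())
        assert ratio == pytest.approx(norm.cdf(2.0), abs=0.01)
        assert ratio > 0.95

    def test_ratio_complementarity_under_mirroring(self, rng):
        taus = np.round((0.5 + rng.normal(0, 0.5, 400)) / 0.2) * 0.2
        taus = np.clip(taus, -5, 5)
        cfg = DelayConfig()
        h = build_delay_histogram(events_at(taus), 1, cfg)
        from walkleader.delay_correlation import _leader_side_mass
        m = _leader_side_mass(h, cfg)
        m_mirror = _leader_side_mass(h.mirrored(), cfg)
        assert m == pytest.approx(m_mirror, abs=0.02)

    def test_flat_histogram_unconnected(self, rng):
        taus = np.round(rng.uniform(-5, 5, 300) / 0.2) * 0.2
        h = build_delay_histogram(events_at(taus), 1, DelayConfig())
        rel = classify_pair(h, cutoff=0.3, cfg=DelayConfig(), seed=5)
        assert rel.status == "unconnected"

    def test_tight_positive_cluster_directed(self, rng):
        taus = np.round((0.6 + rng.normal(0, 0.15, 300)) / 0.2) * 0.2
        h = build_delay_histogram(events_at(taus, ("i", "j")), 1, DelayConfig())
        rel = classify_pair(h, cutoff=0.3, cfg=DelayConfig(), seed=5)
        assert rel.status == "directed" and rel.leader == "i"
        assert rel.leading_ratio > 0.5

    def test_tight_zero_cluster_undirected(self, rng):
        taus = np.round(rng.normal(0, 0.1, 300) / 0.2) * 0.2
        h = build_delay_histogram(events_at(taus, ("i", "j")), 1, DelayConfig())
        rel = classify_pair(h, cutoff=0.3, cfg=DelayConfig(), seed=5)
        assert rel.status == "undirected" and rel.leader is None

    def test_few_events_unconnected_without_bootstrap(self):
        h = build_delay_histogram(events_at([0.4] * 5), 1, DelayConfig())
        rel = classify_pair(h, cutoff=0.3, cfg=DelayConfig(), seed=5)
        assert rel.status == "unconnected"
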