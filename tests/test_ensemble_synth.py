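"""Generator correctness: matchings, mixtures, determinism, geometry."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy.stats import truncnorm

from holoflex import (
    EnsembleConfig,
    TruncatedGaussian,
    cycle_matchings,
    generate_ensemble,
    realize_coordinates,
    sample_pair_assignment,
    sample_radii,
    sample_separations,
)
from holoflex.ensemble_synth import (
    ConfigurationError,
    UsageError,
    particles_to_frame,
    frame_to_particles,
)


def brute_force_matchings(n, k):
    """Independent oracle: enumerate k-subsets of cycle edges directly."""
    edges = [(i, (i + 1) % n) for i in range(n)]
    found = []
    for combo in combinations(edges, k):
        verts = [v for e in combo for v in e]
        if len(set(verts)) == 2 * k:
            found.append(frozenset(combo))
    return found


def matching_count_closed_form(n, k):
    # number of k-matchings of the n-cycle: n/(n-k) * C(n-k, k)
    return n * math.comb(n - k, k) // (n - k)


@pytest.mark.parametrize("n", [12, 14])
def test_cycle_matching_enumeration_matches_oracles(n):
    for k in range(n // 2 + 1):
        ms = cycle_matchings(n, k)
        assert len(ms) == matching_count_closed_form(n, k)
        assert set(ms) == set(brute_force_matchings(n, k))


def test_degenerate_categorical_gives_empty_assignment(rng):
    probs = [1.0] + [0.0] * 6
    assert sample_pair_assignment(12, probs, rng) == frozenset()


def test_six_pair_assignment_uniform_over_two_matchings(rng):
    # the 12-cycle has exactly 2 perfect matchings (alternating edges)
    probs = [0.0] * 6 + [1.0]
    seen = {}
    for _ in range(600):
        m = sample_pair_assignment(12, probs, rng)
        assert len(m) == 6
        seen[m] = seen.get(m, 0) + 1
    assert len(seen) == 2
    for count in seen.values():
        assert 0.4 < count / 600 < 0.6


def test_single_pair_assignment_uniform_over_edges(rng):
    probs = [0.0, 1.0] + [0.0] * 5
    counts = np.zeros(12)
    for _ in range(2400):
        (edge,) = sample_pair_assignment(12, probs, rng)
        counts[edge[0]] += 1
    # each of the 12 edges should get ~200 draws
    assert counts.min() > 120 and counts.max() < 300


def test_assignment_is_always_a_matching(rng):
    cfg = EnsembleConfig()
    for _ in range(200):
        edges = sample_pair_assignment(12, cfg.pair_count_probs, rng)
        verts = [v for e in edges for v in e]
        assert len(verts) == len(set(verts))


def test_invalid_categorical_rejected(rng):
    with pytest.raises(ConfigurationError):
        sample_pair_assignment(12, [0.5, 0.6], rng)
    with pytest.raises(ConfigurationError):
        sample_pair_assignment(12, [-0.1, 1.1], rng)


class TestRadiusSampling:
    def test_pure_compact_stays_below_100(self, rng):
        cfg = EnsembleConfig(p_compact=1.0)
        radii, flags = sample_radii(500, cfg, rng)
        assert flags.all()
        assert (radii >= 77).all() and (radii < 100).all()

    def test_zero_variance_extended_is_constant(self, rng):
        cfg = EnsembleConfig(
            p_compact=0.0,
            radius_extended=TruncatedGaussian(127.0, 0.0, 100.0, 175.0))
        radii, _ = sample_radii(100, cfg, rng)
        assert np.allclose(radii, 127.0)

    def test_large_sample_moments_match_truncnorm_oracle(self, rng):
        cfg = EnsembleConfig()
        radii, _ = sample_radii(100_000, cfg, rng)
        assert (radii >= 77).all() and (radii <= 175).all()

        def tn_stats(spec):
            a = (spec.lo - spec.mean) / spec.sd
            b = (spec.hi - spec.mean) / spec.sd
            return truncnorm.stats(a, b, loc=spec.mean, scale=spec.sd,
                                   moments="mv")
        m_e, v_e = tn_stats(cfg.radius_extended)
        m_c, v_c = tn_stats(cfg.radius_compact)
        p = cfg.p_compact
        mix_mean = (1 - p) * m_e + p * m_c
        mix_var = ((1 - p) * (v_e + m_e**2) + p * (v_c + m_c**2)
                   - mix_mean**2)
        assert abs(radii.mean() - mix_mean) < 0.3
        assert abs(radii.std(ddof=1) - np.sqrt(mix_var)) < 0.3
        # and the calibration reproduces the target statistics
        assert abs(radii.mean() - 127.0) < 1.0
        assert abs(radii.std(ddof=1) - 16.0) < 1.5


class TestSeparationSampling:
    def test_no_pairs_zero_variance(self, rng):
        cfg = EnsembleConfig(
            sep_unpaired=TruncatedGaussian(62.5, 0.0, 45.0, 110.0))
        seps = sample_separations(frozenset(), cfg, rng, 12)
        assert np.allclose(seps, 62.5)

    def test_single_pair_gives_one_short_separation(self, rng):
        cfg = EnsembleConfig()
        seps = sample_separations(frozenset({(3, 4)}), cfg, rng, 12)
        assert (seps < 45).sum() == 1
        assert seps[3] < 45

    def test_mixture_moments_match_analytic_oracle(self, rng):
        cfg = EnsembleConfig()
        probs = np.asarray(cfg.pair_count_probs)
        p_short = (probs * np.arange(len(probs))).sum() / 12  # E[pairs]/12
        vals = []
        for _ in range(10_000):
            edges = sample_pair_assignment(12, cfg.pair_count_probs, rng)
            vals.append(sample_separations(edges, cfg, rng, 12))
        vals = np.concatenate(vals)

        def tn_stats(spec):
            a = (spec.lo - spec.mean) / spec.sd
            b = (spec.hi - spec.mean) / spec.sd
            return truncnorm.stats(a, b, loc=spec.mean, scale=spec.sd,
                                   moments="mv")
        m_p, v_p = tn_stats(cfg.sep_paired)
        m_u, v_u = tn_stats(cfg.sep_unpaired)
        mix_mean = p_short * m_p + (1 - p_short) * m_u
        mix_var = (p_short * (v_p + m_p**2)
                   + (1 - p_short) * (v_u + m_u**2) - mix_mean**2)
        assert abs(vals.mean() - mix_mean) < 0.3
        assert abs(vals.std(ddof=1) - np.sqrt(mix_var)) < 0.3
        assert abs(vals.mean() - 58.0) < 1.0
        assert abs(vals.std(ddof=1) - 15.0) < 1.5

    def test_rejected_in_angular_mode(self, rng):
        cfg = EnsembleConfig(mode="angular")
        with pytest.raises(UsageError):
            sample_separations(frozenset(), cfg, rng, 12)


class TestGenerateEnsemble:
    def test_seed_determinism_both_modes(self):
        for mode in ("separation_explicit", "angular"):
            cfg = EnsembleConfig(n_particles=25, seed=9, mode=mode)
            a = particles_to_frame(generate_ensemble(cfg))
            b = particles_to_frame(generate_ensemble(cfg))
            assert a.equals(b)

    def test_all_dodecamers_without_tetradecamers(self):
        cfg = EnsembleConfig(n_particles=50, seed=1, p_tetradecamer=0.0)
        assert all(p.n_subunits == 12 for p in generate_ensemble(cfg))

    def test_tetradecamer_fraction(self):
        cfg = EnsembleConfig(n_particles=2000, seed=5)
        frac = np.mean([p.n_subunits == 14 for p in generate_ensemble(cfg)])
        assert abs(frac - 0.035) < 0.015

    def test_nonpositive_count_rejected(self):
        with pytest.raises(ConfigurationError):
            EnsembleConfig(n_particles=0)

    def test_threshold_recovers_pair_labels_exactly(self, default_ensemble):
        _, particles = default_ensemble
        for p in particles:
            short = set(np.flatnonzero(p.separations < 45))
            labelled = {i for (i, _) in p.pair_edges}
            assert short == labelled

    def test_compact_flags_match_radius_threshold(self, default_ensemble):
        _, particles = default_ensemble
        for p in particles:
            assert np.array_equal(p.compact_flags, p.radii < 100)

    def test_particle_invariants(self, default_ensemble):
        _, particles = default_ensemble
        for p in particles:
            p.validate()


class TestAngularRealization:
    def test_zero_variance_gives_regular_polygon(self):
        particles = generate_ensemble(
            EnsembleConfig(n_particles=1, seed=0, mode="angular",
                           p_compact=0.0, p_tetradecamer=0.0,
                           pair_count_probs=(1.0,) + (0.0,) * 6,
                           radius_extended=TruncatedGaussian(
                               127.0, 0.0, 100.0, 175.0)))
        p = particles[0]
        # all centre radii equal 104.5; gaps rescale to exactly 30 deg mean
        assert np.allclose(np.hypot(p.coords[:, 0], p.coords[:, 1]), 104.5)
        chord = 2 * 104.5 * np.sin(np.deg2rad(15.0))
        # gaps still jitter, but the mean chord matches the closed form
        assert abs(p.separations.mean() - chord) < 3.0

    def test_gaps_sum_to_full_circle(self, angular_ensemble):
        _, particles = angular_ensemble
        for p in particles[:100]:
            ang = np.degrees(np.arctan2(p.coords[:, 1], p.coords[:, 0]))
            gaps = np.diff(np.concatenate((ang, ang[:1])))
            # clockwise accumulation: each gap is a negative angle step
            total = (-gaps) % 360.0
            assert abs(total.sum() - 360.0) < 1e-6

    def test_separations_obey_law_of_cosines(self, angular_ensemble):
        _, particles = angular_ensemble
        p = particles[0]
        r = np.hypot(p.coords[:, 0], p.coords[:, 1])
        nxt = np.roll(np.arange(p.n_subunits), -1)
        d = np.linalg.norm(p.coords[nxt] - p.coords, axis=1)
        assert np.allclose(d, p.separations)


def test_csv_round_trip(tmp_path, default_ensemble):
    from holoflex import read_particles, write_particles

    cfg, particles = default_ensemble
    path = tmp_path / "particles.csv"
    write_particles(particles[:20], path, cfg=cfg)
    back = read_particles(path)
    assert len(back) == 20
    for a, b in zip(particles[:20], back):
        assert a.n_subunits == b.n_subunits
        assert np.allclose(a.radii, b.radii)
        assert np.allclose(a.separations, b.separations)
        assert a.pair_edges == b.pair_edges
    assert path.with_suffix(".csv.config.json").exists()


def test_frame_round_trip_preserves_pairs(angular_ensemble):
    _, particles = angular_ensemble
    frame = particles_to_frame(particles[:10])
    back = frame_to_particles(frame)
    for a, b in zip(particles[:10], back):
        assert a.pair_edges == b.pair_edges
        assert np.allclose(a.coords, b.coords)


@pytest.mark.parametrize("bad", [
    dict(p_compact=1.5),
    dict(pair_count_probs=(0.5, 0.6)),
    dict(radius_compact=TruncatedGaussian(88, 5, 77, 120)),
    dict(sep_paired=TruncatedGaussian(36, 5, 20, 50)),
    dict(hub_radius=70.0),
])
def test_config_invariants_enforced(bad):
    with pytest.raises(ConfigurationError):
        EnsembleConfig(**bad)
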