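"""Hexagon symmetry metrics against brute-force oracles, and the U test."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from permion import (
    HexSynthSpec,
    angle_series,
    anisotropy_from_eccentricity,
    eccentricity_noiseless,
    eccentricity_series,
    gen_hex_traj,
    hexagon_metrics,
    mann_whitney_u,
    pooled_angles,
    select_frames,
)

from conftest import regular_hexagon, stretched_hexagon


# --- independent oracles -------------------------------------------------

def oracle_metrics(vertices):
    """Brute force: the 3 opposite-vertex distances and explicit vector angles."""
    v = np.asarray(vertices, dtype=float)[:, :2]
    diams = [math.dist(v[i], v[i + 3]) for i in range(3)]
    angles = []
    for i in range(6):
        p, q, r = v[(i - 1) % 6], v[i], v[(i + 1) % 6]
        u1, u2 = p - q, r - q
        cos = np.dot(u1, u2) / (np.linalg.norm(u1) * np.linalg.norm(u2))
        angles.append(math.degrees(math.acos(max(-1.0, min(1.0, cos)))))
    return max(diams), min(diams), max(diams) / min(diams), np.array(angles)


def oracle_mwu_exact_p(a, b):
    """Enumerate all C(n1+n2, n1) rank arrangements of the pooled sample."""
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    n1, n2 = len(a), len(b)

    def u_stat(sample_a, sample_b):
        return sum(1 for x in sample_a for y in sample_b if x > y) + 0.5 * sum(
            1 for x in sample_a for y in sample_b if x == y
        )

    u_obs = u_stat(a, b)
    center = n1 * n2 / 2.0
    count = total = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        sa = [pooled[i] for i in combo]
        sb = [pooled[i] for i in range(n1 + n2) if i not in combo]
        total += 1
        if abs(u_stat(sa, sb) - center) >= abs(u_obs - center) - 1e-12:
            count += 1
    return u_obs, count / total


# --- hexagon metrics -----------------------------------------------------

class TestHexagonMetrics:
    def test_regular_hexagon_is_symmetric(self):
        m = hexagon_metrics(regular_hexagon(radius=2.7, rotation=0.4))
        assert m.E == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(m.angles_deg, 120.0, atol=1e-9)

    def test_worked_stretched_hexagon(self):
        m = hexagon_metrics(stretched_hexagon(1.2))
        assert m.D_max == pytest.approx(2.4, abs=1e-9)
        assert m.d_min == pytest.approx(2.1071, abs=1e-3)
        assert m.E == pytest.approx(1.139, abs=1e-3)
        expected = sorted([110.57, 124.72, 124.72, 110.57, 124.72, 124.72])
        np.testing.assert_allclose(sorted(m.angles_deg), expected, atol=0.01)
        assert m.angles_deg.sum() == pytest.approx(720.0, abs=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = regular_hexagon() + rng.normal(0, 0.15, size=(6, 2))
        m = hexagon_metrics(v)
        D, d, E, angles = oracle_metrics(v)
        assert m.D_max == pytest.approx(D, rel=1e-9)
        assert m.d_min == pytest.approx(d, rel=1e-9)
        assert m.E == pytest.approx(E, rel=1e-9)
        np.testing.assert_allclose(m.angles_deg, angles, atol=1e-7)

    @settings(derandomize=True, max_examples=30)
    @given(
        st.floats(min_value=-3.0, max_value=3.0),
        st.floats(min_value=0.1, max_value=10.0),
        st.floats(min_value=0.0, max_value=6.28),
    )
    def test_similarity_invariance(self, shift, scale, theta):
        v = stretched_hexagon(1.15)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        v2 = scale * (v @ rot.T) + shift
        m1, m2 = hexagon_metrics(v), hexagon_metrics(v2)
        assert m2.E == pytest.approx(m1.E, rel=1e-9)
        np.testing.assert_allclose(np.sort(m2.angles_deg), np.sort(m1.angles_deg), atol=1e-6)

    def test_3d_input_projected_onto_ring_plane(self):
        v = np.column_stack([stretched_hexagon(1.2), np.full(6, 3.3)])
        m = hexagon_metrics(v)
        assert m.E == pytest.approx(1.139, abs=1e-3)

    def test_degenerate_inputs_rejected(self):
        v = regular_hexagon()
        v[1] = v[0]
        with pytest.raises(ValueError, match="coincident"):
            hexagon_metrics(v)

    def test_noiseless_map_and_inverse(self):
        for a in (1.0, 1.05, 1.2, 1.5):
            E = eccentricity_noiseless(a)
            assert hexagon_metrics(stretched_hexagon(a)).E == pytest.approx(E, abs=1e-12)
            assert anisotropy_from_eccentricity(E) == pytest.approx(a, abs=1e-9)


# --- trajectory-level series ---------------------------------------------

class TestEccentricitySeries:
    def test_noiseless_isotropic_series(self):
        traj = gen_hex_traj(HexSynthSpec(n_frames=10, a=1.0, noise_sd=0.0, seed=0))
        res = eccentricity_series(traj, [2, 5, 9])
        assert res["mean"] == pytest.approx(1.0, abs=1e-12)
        assert res["sem"] == pytest.approx(0.0, abs=1e-12)
        assert res["n"] == 10

    def test_noiseless_stretched_series(self):
        traj = gen_hex_traj(HexSynthSpec(n_frames=10, a=1.2, noise_sd=0.0, seed=0))
        res = eccentricity_series(traj, list(range(2, 15)))
        assert res["mean"] == pytest.approx(1.139, abs=1e-3)

    def test_pooled_vs_frame_mean_sample_sizes(self):
        traj = gen_hex_traj(HexSynthSpec(n_frames=20, a=1.1, noise_sd=0.02, seed=1))
        fm = eccentricity_series(traj, list(range(2, 15)), aggregate="frame_mean")
        pooled = eccentricity_series(traj, list(range(2, 15)), aggregate="pooled")
        assert fm["n"] == 20
        assert pooled["n"] == 20 * 13
        assert fm["mean"] == pytest.approx(pooled["mean"], rel=1e-12)

    def test_empty_selection_rejected(self):
        traj = gen_hex_traj(HexSynthSpec(n_frames=5, seed=0))
        with pytest.raises(ValueError):
            eccentricity_series(traj, [])
        with pytest.raises(ValueError):
            eccentricity_series(traj, [2], frames=np.array([], dtype=int))

    def test_select_last_time_span(self):
        traj = gen_hex_traj(HexSynthSpec(n_frames=100, seed=0))  # 0.18 ns spacing
        idx = select_frames(traj, n_frames=50, last_ns=9.0)
        assert len(idx) == 50
        assert traj.times[idx[0]] >= traj.times[-1] - 9.0


class TestAngleSeries:
    def test_regular_rings_give_constant_120(self):
        traj = gen_hex_traj(HexSynthSpec(n_frames=4, a=1.0, noise_sd=0.0, seed=0))
        table = angle_series(traj, 5)
        np.testing.assert_allclose(pooled_angles(table), 120.0, atol=1e-9)

    def test_stretched_rings_give_worked_angles(self):
        traj = gen_hex_traj(HexSynthSpec(n_frames=2, a=1.2, noise_sd=0.0, seed=0))
        table = angle_series(traj, 5)
        vals = np.sort(table.iloc[0, 1:].to_numpy().astype(float))
        np.testing.assert_allclose(vals, sorted([110.57, 124.72, 124.72, 110.57, 124.72, 124.72]), atol=0.01)

    def test_angle_sum_identity_per_frame(self):
        traj = gen_hex_traj(HexSynthSpec(n_frames=50, a=1.1, noise_sd=0.01, seed=2))
        table = angle_series(traj, 7)
        sums = table.filter(like="angle_").sum(axis=1).to_numpy()
        np.testing.assert_allclose(sums, 720.0, atol=1e-6)


# --- Mann-Whitney U -------------------------------------------------------

class TestMannWhitney:
    def test_separated_samples_exact(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.U == 0
        assert res.p_value == pytest.approx(0.1, abs=1e-12)
        assert res.method == "exact"

    def test_identical_samples_p_one(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_swap_symmetry(self):
        a, b = [0.1, 0.9, 2.3, 3.1], [0.5, 1.7, 2.0]
        r1, r2 = mann_whitney_u(a, b), mann_whitney_u(b, a)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)
        assert r2.U == pytest.approx(r1.n1 * r1.n2 - r1.U, abs=1e-12)

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_exact_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=4).round(3)
        b = (rng.normal(size=4) + 0.5).round(3)
        if len(np.unique(np.concatenate([a, b]))) < 8:
            return  # enumeration oracle assumes no ties
        res = mann_whitney_u(a, b)
        u_oracle, p_oracle = oracle_mwu_exact_p(a, b)
        assert res.method == "exact"
        assert res.U == pytest.approx(u_oracle, abs=1e-12)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-9)

    def test_exact_close_to_normal_approximation_at_n20(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=20)
        b = rng.normal(size=20) + 0.4
        p_exact = mann_whitney_u(a, b, mode="exact").p_value
        p_norm = mann_whitney_u(a, b, mode="normal_approx").p_value
        assert abs(p_exact - p_norm) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])
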