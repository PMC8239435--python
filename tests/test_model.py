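import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from togglefate.model import (
    FATE_LABELS,
    ToggleParams,
    assign_attractor,
    basin_map,
    find_fixed_points,
    integrate_ensemble,
    integrate_trajectory,
    jacobian,
    stable_attractors,
    velocity_field,
)

MIRROR = {"immunogenic": "tolerogenic", "tolerogenic": "immunogenic"}


class TestVelocityField:
    @pytest.mark.parametrize(
        "state, expected",
        [
            ((0.0, 0.0), (1.0, 1.0)),  # cross term at full strength, no decay
            ((1.0, 1.0), (0.0, 0.0)),  # diagonal identity: Hill terms sum to 1
            ((0.5, 0.5), (0.5, 0.5)),  # at threshold each Hill term is 1/2
        ],
    )
    def test_analytic_points(self, state, expected):
        assert velocity_field(state) == pytest.approx(expected)

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError):
            velocity_field((-0.1, 0.5))

    @settings(max_examples=50, deadline=None)
    @given(
        i=st.floats(0.0, 2.2),
        t=st.floats(0.0, 2.2),
    )
    def test_swap_symmetry(self, i, t):
        dI, dT = velocity_field((i, t))
        dT2, dI2 = velocity_field((t, i))
        assert dI == pytest.approx(dI2, abs=1e-12)
        assert dT == pytest.approx(dT2, abs=1e-12)

    @pytest.mark.parametrize("state", [(0.3, 1.7), (1.0, 1.0), (2.0, 0.01), (0.6, 0.6)])
    def test_jacobian_matches_finite_differences(self, state):
        p = ToggleParams()
        h = 1e-6
        J = jacobian(state, p)
        for col, axis in enumerate(np.eye(2)):
            plus = np.array(velocity_field(np.asarray(state) + h * axis, p))
            minus = np.array(velocity_field(np.asarray(state) - h * axis, p))
            np.testing.assert_allclose(J[:, col], (plus - minus) / (2 * h), atol=1e-6)


class TestFixedPoints:
    def test_tristable_at_defaults(self, default_fixed_points):
        stable = stable_attractors(default_fixed_points)
        assert len(stable) == 3
        labels = {fp.label for fp in stable}
        assert labels == {"A_immunogenic", "B_tolerogenic", "C_ambivalent"}

    def test_symmetric_attractor_exactly_one_one(self, default_fixed_points):
        (c,) = [fp for fp in default_fixed_points if fp.label == "C_ambivalent"]
        assert c.location.I == pytest.approx(1.0, abs=1e-9)
        assert c.location.T == pytest.approx(1.0, abs=1e-9)
        assert max(c.eigenvalues) < 0

    def test_asymmetric_attractors_mirror(self, default_fixed_points):
        (a,) = [fp for fp in default_fixed_points if fp.label == "A_immunogenic"]
        (b,) = [fp for fp in default_fixed_points if fp.label == "B_tolerogenic"]
        assert a.location.I > a.location.T
        assert b.location.T > b.location.I
        assert a.location.I == pytest.approx(b.location.T, abs=1e-8)
        assert a.location.T == pytest.approx(b.location.I, abs=1e-8)
        # high branch sits near (a+b)/k, low branch near the leaked cross term
        assert a.location.I == pytest.approx(2.0, abs=0.01)
        assert a.location.T == pytest.approx(0.004, abs=0.001)

    def test_saddles_present_and_unused_for_labels(self, default_fixed_points):
        saddles = [fp for fp in default_fixed_points if fp.stability == "saddle"]
        assert len(saddles) == 2
        assert all(fp.label is None for fp in saddles)

    def test_pure_decay_single_origin(self):
        # a=b=0 is outside the positivity contract; tiny a,b approximate pure decay
        p = ToggleParams(a=1e-12, b=1e-12)
        stable = stable_attractors(find_fixed_points(p))
        assert len(stable) == 1
        assert stable[0].location.I == pytest.approx(0.0, abs=1e-6)
        assert stable[0].location.T == pytest.approx(0.0, abs=1e-6)

    def test_velocity_vanishes_at_every_fixed_point(self, default_fixed_points):
        for fp in default_fixed_points:
            speed = np.linalg.norm(velocity_field(fp.location))
            assert speed < 1e-8

    def test_stability_against_perturbation(self, default_fixed_points, default_params):
        rng = np.random.default_rng(0)
        for fp in default_fixed_points:
            for _ in range(3):
                delta = rng.normal(0, 0.01, size=2)
                start = np.maximum(np.asarray(fp.location) + delta, 0.0)
                tr = integrate_trajectory(start, default_params)
                dist = np.linalg.norm(np.asarray(tr.terminal) - np.asarray(fp.location))
                if fp.stability == "stable":
                    assert dist < 0.05
                else:  # saddles repel almost every perturbation
                    assert dist > 0.1


class TestTrajectories:
    def test_start_at_fixed_point_stays(self, default_params):
        tr = integrate_trajectory((1.0, 1.0), default_params)
        assert tr.converged
        assert tr.terminal == pytest.approx((1.0, 1.0), abs=1e-9)

    @pytest.mark.parametrize("c", [0.0, 0.2, 2.0])
    def test_diagonal_closed_form(self, c, default_params):
        """On I=T the system reduces to dx/dt = 1 − x, solved in closed form."""
        tr = integrate_trajectory((c, c), default_params)
        exact = 1.0 - (1.0 - c) * np.exp(-tr.times)
        np.testing.assert_allclose(tr.states[:, 0], exact, atol=1e-6)
        np.testing.assert_allclose(tr.states[:, 1], exact, atol=1e-6)
        assert tr.converged

    def test_polarised_start_reaches_immunogenic_attractor(
        self, default_params, default_attractors
    ):
        (a,) = [fp for fp in default_attractors if fp.label == "A_immunogenic"]
        tr = integrate_trajectory((2.0, 0.05), default_params)
        assert tr.converged
        dist = np.linalg.norm(np.asarray(tr.terminal) - np.asarray(a.location))
        assert dist < default_params.attract_eps

    def test_states_never_negative(self, default_params):
        tr = integrate_trajectory((0.0, 2.2), default_params)
        assert np.all(tr.states >= 0)

    def test_ensemble_matches_single_trajectories(self, default_params):
        starts = np.array([[0.1, 1.9], [1.9, 0.1], [1.2, 1.3], [0.4, 0.4]])
        terminals, converged = integrate_ensemble(starts, default_params)
        assert converged.all()
        for start, terminal in zip(starts, terminals):
            single = integrate_trajectory(start, default_params)
            np.testing.assert_allclose(terminal, np.asarray(single.terminal), atol=1e-5)

    def test_random_starts_end_at_found_fixed_points(self, default_params, default_attractors):
        rng = np.random.default_rng(1)
        starts = rng.uniform(0, default_params.x_max, size=(40, 2))
        terminals, converged = integrate_ensemble(starts, default_params)
        locations = np.array([fp.location for fp in default_attractors])
        for terminal, ok in zip(terminals, converged):
            if ok:
                dists = np.linalg.norm(locations - terminal, axis=1)
                assert dists.min() < default_params.attract_eps


class TestAssignment:
    def test_near_diagonal_is_ambivalent(self, default_attractors):
        assert assign_attractor((1.0001, 0.9999), default_attractors, 0.05) == "ambivalent"

    def test_far_point_unconverged(self, default_attractors, default_params):
        x = default_params.x_max
        assert assign_attractor((x, x), default_attractors, 0.05) == "unconverged"

    def test_exact_attractor_location(self, default_attractors):
        (a,) = [fp for fp in default_attractors if fp.label == "A_immunogenic"]
        assert assign_attractor(a.location, default_attractors, 0.05) == "immunogenic"

    def test_empty_attractor_set(self):
        with pytest.raises(ValueError):
            assign_attractor((1.0, 1.0), [], 0.05)


@pytest.fixture(scope="module")
def basin41():
    return basin_map(ToggleParams(), 41)


class TestBasinMap:
    def test_diagonal_is_ambivalent(self, basin41):
        _, labels = basin41
        assert all(labels[i, i] == "ambivalent" for i in range(labels.shape[0]))

    def test_mirror_symmetry(self, basin41):
        _, labels = basin41
        n = labels.shape[0]
        for i in range(n):
            for j in range(n):
                assert labels[i, j] == MIRROR.get(labels[j, i], labels[j, i])

    def test_nearly_all_points_converge(self, basin41):
        _, labels = basin41
        frac = np.mean(labels != "unconverged")
        assert frac >= 0.99
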