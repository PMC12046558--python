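"""Arm-state classification, label canonicalization and populations."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import paddleface as pf
from paddleface import conformers
from paddleface.conformers import ArmState, canonical_symbols
from paddleface.errors import GeometryError


def _mk_states(symbols):
    out = []
    for s in symbols:
        out.append(
            ArmState(
                side="alpha" if s.startswith("α") else "beta",
                primed=s.endswith("′"),
                theta_deg=0.0,
                delta_theta_deg=90.0 if s.endswith("′") else 0.0,
            )
        )
    return tuple(out)


class TestArmState:
    def test_alpha_unprimed_on_template(self, neutral_template):
        frame, topo = neutral_template
        for a in range(4):
            st_ = pf.arm_state(frame, topo, a)
            assert (st_.side, st_.primed) == ("alpha", False)
            assert st_.delta_theta_deg == pytest.approx(0.0, abs=1e-9)

    def test_midplane_reflection_of_arm_flips_side(self, neutral_template):
        # reflect one arm's imide group through the paddlewheel midplane
        # (z = 0 here), leaving the Rh–Rh axis untouched
        frame, topo = neutral_template
        coords = frame.coords.copy()
        imide = list(topo.arms[0].imide_group)
        coords[imide, 2] *= -1
        flipped = pf.Frame(frame.elements, coords)
        assert pf.arm_state(flipped, topo, 0).side == "beta"
        assert pf.arm_state(flipped, topo, 1).side == "alpha"

    def test_ninety_degree_rotation_is_primed(self, neutral_template):
        # rotating the imide anchor by 90° about the C_carboxylate–C_α bond
        # lands in the primed window
        frame, topo = neutral_template
        coords = frame.coords.copy()
        arm = topo.arms[0]
        j, k = coords[arm.carboxylate_c], coords[arm.alpha_c]
        axis = (k - j) / np.linalg.norm(k - j)
        n_idx = arm.dihedral_quad[3]
        v = coords[n_idx] - k
        c, s = math.cos(math.pi / 2), math.sin(math.pi / 2)
        v_rot = v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c)
        coords[n_idx] = k + v_rot
        st_ = pf.arm_state(pf.Frame(frame.elements, coords), topo, 0)
        assert st_.primed
        assert st_.delta_theta_deg == pytest.approx(90.0, abs=1e-6)

    def test_zero_rh_rh_axis_degenerate(self, neutral_template):
        frame, topo = neutral_template
        coords = frame.coords.copy()
        coords[topo.rh_distal] = coords[topo.rh_carbene]
        with pytest.raises(GeometryError, match="Rh"):
            pf.arm_state(pf.Frame(frame.elements, coords), topo, 0)


class TestCanonicalization:
    def test_rotation_equivalence_pairs(self):
        assert canonical_symbols(["α", "β", "α", "β"]) == "αβαβ"
        assert canonical_symbols(["β", "α", "β", "α"]) == "αβαβ"
        for phase in range(4):
            seq = ["α", "α", "α", "β"]
            rotated = seq[phase:] + seq[:phase]
            assert canonical_symbols(rotated) == "αααβ"

    def test_primed_arm_rotated_to_last_position(self):
        # enumerating all four rotations of (α, α, α′, α) under the ordering
        # α < α′ < β < β′ puts the primed arm last
        assert canonical_symbols(["α", "α", "α′", "α"]) == "αααα′"

    @given(st.lists(st.sampled_from(["α", "α′", "β", "β′"]), min_size=4, max_size=4))
    def test_all_rotations_map_to_one_label(self, seq):
        labels = {
            canonical_symbols(seq[i:] + seq[:i]) for i in range(4)
        }
        assert len(labels) == 1

    @given(st.lists(st.sampled_from(["α", "α′", "β", "β′"]), min_size=4, max_size=4))
    def test_reversal_preserves_chirality_distinction(self, seq):
        rev = seq[::-1]
        rotations = [tuple(seq[i:] + seq[:i]) for i in range(4)]
        if tuple(rev) in rotations:
            assert canonical_symbols(rev) == canonical_symbols(seq)
        else:
            assert canonical_symbols(rev) != canonical_symbols(seq)

    def test_complex_label_uses_arm_states(self, neutral_template):
        frame, topo = neutral_template
        lab = pf.complex_label(frame, topo)
        assert lab.label == "αααα"
        assert len(lab.raw_states) == 4


class TestPopulations:
    def test_single_conformer(self):
        frame, topo = pf.build_template(pf.GeneratorSpec())
        traj = pf.Trajectory(tuple(
            pf.Frame(frame.elements, frame.coords, frame_index=t) for t in range(10)
        ))
        pop = pf.population_table(traj, topo)
        assert pop.fractions == {"αααα": 1.0}
        assert pop.n_frames == 10 and pop.exclusion_fraction == 0.0

    def test_even_mixture_counting(self):
        spec = pf.GeneratorSpec()
        fa, topo = pf.build_template(spec)
        fb, _ = pf.build_template(spec, arm_states=("α", "α", "α", "β"))
        frames = []
        for t in range(10):
            src = fa if t % 2 == 0 else fb
            frames.append(pf.Frame(src.elements, src.coords, frame_index=t))
        pop = pf.population_table(pf.Trajectory(tuple(frames)), topo)
        assert pop.fractions == {"αααα": 0.5, "αααβ": 0.5}

    def test_markov_stationary_recovery_small(self):
        # stationary distribution of [[0.85, 0.15], [0.35, 0.65]] is (0.7, 0.3)
        spec = pf.GeneratorSpec(
            markov_states=(
                pf.MarkovState(("α", "α", "α", "α")),
                pf.MarkovState(("α", "α", "β", "β")),
            ),
            markov_transition=((0.85, 0.15), (0.35, 0.65)),
            n_frames=4000,
            seed=31,
        )
        np.testing.assert_allclose(
            pf.stationary_distribution(spec.markov_transition), [0.7, 0.3], atol=1e-12
        )
        traj, topo = pf.simulate_trajectory(spec)
        pop = pf.population_table(traj, topo)
        assert pop.fractions["αααα"] == pytest.approx(0.7, abs=0.05)
        assert pop.fractions["ααββ"] == pytest.approx(0.3, abs=0.05)

    def test_fractions_sum_to_one(self, two_state_flexible_ensemble):
        _, traj, topo = two_state_flexible_ensemble
        pop = pf.population_table(traj, topo)
        assert sum(pop.fractions.values()) == pytest.approx(1.0, abs=1e-12)


class TestFlexibilityMetrics:
    @pytest.mark.parametrize(
        "fractions, entropy, max_frac",
        [
            ({"αααα": 1.0}, 0.0, 1.0),
            ({"αααα": 0.5, "ααββ": 0.5}, 1.0, 0.5),
            ({"a": 0.25, "b": 0.25, "c": 0.25, "d": 0.25}, 2.0, 0.25),
        ],
    )
    def test_closed_forms(self, fractions, entropy, max_frac):
        pop = conformers.PopulationTable(
            fractions=fractions, n_frames=100, exclusion_fraction=0.0
        )
        m = pf.flexibility_metrics(pop)
        assert m["shannon_entropy_bits"] == pytest.approx(entropy, abs=1e-12)
        assert m["max_fraction"] == max_frac
        assert m["n_states_visited"] == len(fractions)
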