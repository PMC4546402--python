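"""Restraint scoring terms: worked examples, oracles and symmetries."""

import dataclasses

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from tmbundle import RestraintSet, btl_helices, square_bundle
from tmbundle.geometry import HelixSpec, build_ideal_helix, place_helix
from tmbundle.restraints import (
    ContactRestraint,
    InteractionPair,
    hydrophobicity_table,
)


def two_point_coords(separation):
    return {
        "H1": np.array([[0.0, 0.0, 0.0]]),
        "H2": np.array([[separation, 0.0, 0.0]]),
    }


class TestDiameter:
    def test_under_target_is_zero(self):
        assert RestraintSet().diameter_score(two_point_coords(5.0)) == 0.0

    def test_worked_example_30A_midpoints(self):
        # midpoints 30 A apart + 2 * 2.3 A radius, target 26 -> (8.6)^2
        score = RestraintSet().diameter_score(two_point_coords(30.0))
        assert np.isclose(score, 73.96)

    def test_monotone_in_separation(self):
        rs = RestraintSet()
        scores = [rs.diameter_score(two_point_coords(s)) for s in (25, 30, 35, 40)]
        assert all(b >= a for a, b in zip(scores, scores[1:]))


class TestExcludedVolume:
    def test_no_pairs_below_cutoff(self):
        assert RestraintSet().excluded_volume_score(two_point_coords(4.0)) == 0.0

    def test_single_pair_at_3A(self):
        assert np.isclose(
            RestraintSet().excluded_volume_score(two_point_coords(3.0)), 1.0
        )

    def test_superposed_helices_positive(self, specs):
        c = build_ideal_helix(specs[0])
        score = RestraintSet().excluded_volume_score({"A": c, "B": c.copy()})
        assert score > 0


class TestPacking:
    def test_far_apart_is_zero(self):
        assert RestraintSet().packing_score(two_point_coords(11.0)) == 0.0

    def test_matches_brute_force_pair_count(self, rng):
        a = rng.normal(scale=3.0, size=(5, 3))
        b = rng.normal(scale=3.0, size=(5, 3)) + np.array([5.0, 0, 0])
        rs = RestraintSet(packing_weight=2.5)
        count = sum(
            1
            for i in range(5)
            for j in range(5)
            if 4.0 <= np.linalg.norm(a[i] - b[j]) <= 6.5
        )
        assert rs.packing_score({"A": a, "B": b}) == -2.5 * count

    def test_contact_never_raises_score(self):
        # moving a pair into the window adds a negative contribution
        rs = RestraintSet()
        assert rs.packing_score(two_point_coords(5.0)) <= rs.packing_score(
            two_point_coords(11.0)
        )


class TestTiltDepth:
    def test_short_centered_helix_depth_deficit(self):
        # 20 residues -> 28.5 A in a 30 A membrane: 0.75 A deficit on each
        # side, tilt allowance zero (up to the discrete trace's axis wobble)
        spec = HelixSpec("T", "A" * 20, 1, 20)
        rs = RestraintSet()
        score = rs.tilt_depth_score({"T": build_ideal_helix(spec)}, [spec])
        assert np.isclose(score, 2 * 0.75 ** 2, atol=1e-3)

    def test_long_helix_at_tilt_limit_unpenalized(self):
        # 36 A helix in a 30 A membrane may tilt to arccos(30/36) ~ 33.6 deg
        spec = HelixSpec("T", "A" * 25, 1, 25)
        c = build_ideal_helix(spec)
        tilt_max = np.degrees(np.arccos(30.0 / spec.helix_length_A))
        rot = np.deg2rad(tilt_max)
        ry = np.array([
            [np.cos(rot), 0, np.sin(rot)], [0, 1, 0], [-np.sin(rot), 0, np.cos(rot)]
        ])
        score = RestraintSet().tilt_depth_score({"T": c @ ry.T}, [spec])
        assert score < 1e-2

    def test_tilt_beyond_limit_penalized(self):
        spec = HelixSpec("T", "A" * 25, 1, 25)
        c = build_ideal_helix(spec)
        rot = np.deg2rad(50.0)
        ry = np.array([
            [np.cos(rot), 0, np.sin(rot)], [0, 1, 0], [-np.sin(rot), 0, np.cos(rot)]
        ])
        rs = RestraintSet(depth_weight=0.0)
        assert rs.tilt_depth_score({"T": c @ ry.T}, [spec]) > 0


class TestInteraction:
    def _rs(self, **kw):
        defaults = dict(
            interaction_pairs=(InteractionPair("A", "B"),),
            contact_restraints=(),
        )
        defaults.update(kw)
        return RestraintSet(**defaults)

    def _pair(self, separation):
        spec = HelixSpec("X", "A" * 10, 1, 10)
        c = build_ideal_helix(spec)
        specs = (
            dataclasses.replace(spec, name="A"),
            dataclasses.replace(spec, name="B"),
        )
        coords = {"A": c, "B": c + np.array([separation, 0.0, 0.0])}
        return coords, specs

    def test_satisfied_axes_zero(self):
        coords, specs = self._pair(9.0)
        assert self._rs().interaction_score(coords, specs) == 0.0

    def test_violated_axes_worked_example(self):
        coords, specs = self._pair(12.0)
        assert np.isclose(
            self._rs().interaction_score(coords, specs), (12.0 - 10.4) ** 2, atol=1e-6
        )

    def test_contact_penalty_linear_in_certainty(self):
        spec_a = HelixSpec("A", "A" * 5, 1, 5)
        spec_b = HelixSpec("B", "A" * 5, 11, 15)
        coords = {
            "A": build_ideal_helix(spec_a),
            "B": build_ideal_helix(spec_b) + np.array([20.0, 0, 0]),
        }
        scores = []
        for certainty in (0.5, 1.0):
            rs = RestraintSet(
                interaction_pairs=(),
                contact_restraints=(ContactRestraint(3, 13, 8.0, certainty),),
            )
            scores.append(rs.interaction_score(coords, (spec_a, spec_b)))
        assert scores[1] > 0
        assert np.isclose(scores[1] / scores[0], 2.0)

    def test_bad_certainty_rejected(self):
        with pytest.raises(ValueError):
            ContactRestraint(1, 2, certainty=0.0)
        with pytest.raises(ValueError):
            ContactRestraint(1, 2, certainty=1.5)


class TestPairPotential:
    def test_zero_table_gives_zero(self, bundle):
        rs = RestraintSet(pair_potential_table=hydrophobicity_table(prefactor=0.0))
        assert rs.pair_potential_score(bundle.coords, bundle.specs) == 0.0

    def test_single_leu_leu_contact(self):
        spec_a = HelixSpec("A", "L", 1, 1)
        spec_b = HelixSpec("B", "L", 2, 2)
        coords = {"A": np.zeros((1, 3)), "B": np.array([[5.0, 0, 0]])}
        table = hydrophobicity_table(prefactor=0.0)
        table.loc["L", "L"] = -1.0
        rs = RestraintSet(pair_potential_table=table)
        assert rs.pair_potential_score(coords, (spec_a, spec_b)) == -1.0

    def test_matches_brute_force_summation(self, rng):
        spec_a = HelixSpec("A", "LIV", 1, 3)
        spec_b = HelixSpec("B", "GSA", 4, 6)
        a = rng.normal(scale=3.0, size=(3, 3))
        b = rng.normal(scale=3.0, size=(3, 3))
        rs = RestraintSet()
        table = rs.pair_potential_table
        expected = sum(
            table.loc[spec_a.sequence[i], spec_b.sequence[j]]
            for i in range(3)
            for j in range(3)
            if 4.0 <= np.linalg.norm(a[i] - b[j]) <= 6.5
        )
        got = rs.pair_potential_score({"A": a, "B": b}, (spec_a, spec_b))
        assert np.isclose(got, expected)


class TestTotalScore:
    def test_zero_weights_give_zero(self, bundle):
        rs = RestraintSet(
            diameter_weight=0, clash_weight=0, packing_weight=0, tilt_weight=0,
            depth_weight=0, interaction_weight=0, contact_weight=0,
            pair_potential_weight=0,
        )
        assert rs.total_score(bundle) == 0.0

    def test_total_equals_sum_of_terms(self, bundle, restraints):
        bd = restraints.breakdown(bundle)
        parts = sum(v for k, v in bd.items() if k != "total")
        assert abs(bd["total"] - parts) < 1e-9

    def test_deterministic(self, bundle, restraints):
        assert restraints.total_score(bundle) == restraints.total_score(bundle)

    def test_membrane_symmetry_invariance(self, specs, restraints):
        conf = square_bundle(specs, side=9.0)
        coords = conf.coords
        theta = np.deg2rad(73.0)
        rz = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1.0],
        ])
        shift = np.array([4.0, -7.0, 0.0])
        moved = {k: v @ rz.T + shift for k, v in coords.items()}
        a = restraints.breakdown(coords, specs)
        b = restraints.breakdown(moved, specs)
        for key in a:
            assert np.isclose(a[key], b[key], atol=1e-8), key

    def test_penalties_vanish_on_reference_bundle(self, specs):
        # 9 A square, untilted, membrane thin enough for every helix to span;
        # contact restraints need specific rotamer-facing geometry and are
        # exercised separately.
        rs = RestraintSet(membrane_thickness=25.0, contact_restraints=())
        conf = square_bundle(specs, side=9.0)
        bd = rs.breakdown(conf)
        for term in ("diameter", "excluded_volume", "tilt_depth", "interaction"):
            assert bd[term] == pytest.approx(0.0, abs=1e-9), term
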