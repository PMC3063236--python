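import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from tcrstalk.config import GeometryConfig
from tcrstalk.geometry_core import (
    DegenerateInputError,
    PolarAtom,
    detect_clashes,
    detect_hbonds,
    distance,
    probe_gap,
    superpose,
)
from tcrstalk.structure_model import AtomRecord


def brute_force_min_rmsd(mobile, reference, n_zoom=14):
    """Independent superposition oracle: nested Euler-angle grid search.

    Centers both point sets, then minimizes RMSD over rotations by repeatedly
    scanning an 11x11x11 Euler-angle grid and zooming onto the best cell;
    never uses the SVD solution.
    """
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)
    n = mob.shape[0]

    def rmsd_at(angles):
        R = Rotation.from_euler("zyx", angles).as_matrix()
        return np.sqrt(np.sum((mob @ R.T - ref) ** 2) / n)

    center = np.zeros(3)
    half = np.pi
    best = rmsd_at(center)
    for _ in range(n_zoom):
        offsets = np.linspace(-half, half, 11)
        for a in offsets:
            for b in offsets:
                for c in offsets:
                    angles = center + np.array([a, b, c])
                    val = rmsd_at(angles)
                    if val < best:
                        best, center = val, angles
        # grid spacing is half/5; keep the next window larger than one cell
        half *= 0.35
    return best


class TestDistance:
    def test_identity_and_triangle(self):
        assert distance((0, 0, 0), (0, 0, 0)) == 0.0
        assert distance((0, 0, 0), (3, 4, 0)) == pytest.approx(5.0)

    coords = st.lists(st.floats(-100, 100), min_size=3, max_size=3)

    @settings(derandomize=True, max_examples=50)
    @given(p=coords, q=coords, r=coords)
    def test_symmetry_and_triangle_inequality(self, p, q, r):
        assert distance(p, q) == pytest.approx(distance(q, p))
        assert distance(p, r) <= distance(p, q) + distance(q, r) + 1e-9


class TestSuperpose:
    def test_identical_sets_give_zero_rmsd(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        sup = superpose(pts, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_pure_translation_recovered(self):
        pts = np.random.default_rng(1).normal(size=(5, 3))
        shift = np.array([1.0, 2.0, 3.0])
        sup = superpose(pts + shift, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sup.translation, -shift, atol=1e-9)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(2)
        sup = superpose(rng.normal(size=(6, 3)), rng.normal(size=(6, 3)))
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [3, 7, 19])
    def test_matches_brute_force_rotation_grid(self, seed):
        rng = np.random.default_rng(seed)
        mobile = rng.normal(size=(6, 3))
        reference = rng.normal(size=(6, 3))
        sup = superpose(mobile, reference)
        oracle = brute_force_min_rmsd(mobile, reference)
        assert sup.rmsd == pytest.approx(oracle, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_invariant_under_rigid_motion_of_mobile(self, seed):
        rng = np.random.default_rng(seed)
        mobile = rng.normal(size=(8, 3))
        reference = rng.normal(size=(8, 3))
        base = superpose(mobile, reference).rmsd
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.normal(scale=10.0, size=3)
        moved = mobile @ R.T + t
        assert superpose(moved, reference).rmsd == pytest.approx(base, abs=1e-9)

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(DegenerateInputError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(DegenerateInputError):
            superpose(line, line + 1.0)


def _polar(name, element, coord, antecedent=None, backbone=False):
    atom = AtomRecord(name=name, element=element, coord=np.asarray(coord, float))
    return PolarAtom(atom=atom, antecedent=None if antecedent is None
                     else np.asarray(antecedent, float),
                     label=name, is_backbone=backbone)


class TestHBonds:
    def test_beyond_cutoff_gives_no_bond(self):
        pair = [_polar("O1", "O", (0, 0, 0)), _polar("O2", "O", (5, 0, 0))]
        assert detect_hbonds(pair) == []

    def test_good_geometry_gives_exactly_one_bond(self):
        # O...O at 2.8 A with a 150 degree antecedent angle
        ante = np.array([-1.4, 0.7, 0.0])
        pair = [_polar("O1", "O", (0, 0, 0), antecedent=ante),
                _polar("O2", "O", (2.8, 0, 0))]
        bonds = detect_hbonds(pair)
        assert len(bonds) == 1
        assert bonds[0].da_distance == pytest.approx(2.8)

    def test_bad_angle_rejected(self):
        # antecedents of both atoms point at the partner: angles ~0
        a = _polar("O1", "O", (0, 0, 0), antecedent=(1.0, 0, 0))
        b = _polar("O2", "O", (2.8, 0, 0), antecedent=(1.8, 0, 0))
        assert detect_hbonds([a, b]) == []

    def test_too_close_pair_rejected(self):
        pair = [_polar("O1", "O", (0, 0, 0)), _polar("O2", "O", (2.0, 0, 0))]
        assert detect_hbonds(pair) == []

    def test_count_monotone_in_distance_cutoff(self):
        rng = np.random.default_rng(4)
        atoms = [_polar(f"O{i}", "O", rng.uniform(0, 6, size=3)) for i in range(12)]
        counts = [len(detect_hbonds(atoms, GeometryConfig(hb_max=hb)))
                  for hb in (3.5, 3.2, 2.9, 2.6)]
        assert counts == sorted(counts, reverse=True)

    def test_order_invariance(self):
        rng = np.random.default_rng(9)
        atoms = [_polar(f"O{i}", "O", rng.uniform(0, 5, size=3)) for i in range(8)]
        # the bond set is order-invariant as unordered pairs (which atom is
        # called donor is a tie-break when both orientations qualify)
        fwd = {frozenset((b.donor.label, b.acceptor.label))
               for b in detect_hbonds(atoms)}
        rev = {frozenset((b.donor.label, b.acceptor.label))
               for b in detect_hbonds(atoms[::-1])}
        assert fwd == rev


def _atom(element, coord, name="X"):
    return AtomRecord(name=name, element=element, coord=np.asarray(coord, float))


class TestClashes:
    def test_well_separated_carbons_do_not_clash(self):
        report = detect_clashes([_atom("C", (0, 0, 0))], [_atom("C", (4, 0, 0))])
        assert report.count == 0

    def test_overlap_value_matches_hand_computation(self):
        # two carbons 2.0 A apart: overlap = 1.70 + 1.70 - 2.0 - 0.4 = 1.0
        report = detect_clashes([_atom("C", (0, 0, 0))], [_atom("C", (2, 0, 0))])
        assert report.count == 1
        assert report.pairs[0][2] == pytest.approx(1.0)

    def test_count_monotone_in_tolerance(self):
        rng = np.random.default_rng(5)
        placed = [_atom("C", rng.uniform(0, 4, 3)) for _ in range(5)]
        env = [_atom("O", rng.uniform(0, 4, 3)) for _ in range(20)]
        counts = [detect_clashes(placed, env, GeometryConfig(clash_tolerance=t)).count
                  for t in (0.8, 0.4, 0.2, 0.0)]
        assert counts == sorted(counts)


class TestGapProbe:
    def test_far_from_everything_is_a_gap(self):
        probe = probe_gap((0, 0, 0), [_atom("C", (10, 0, 0))])
        assert probe.gap_present and probe.max_free_radius > 8

    def test_center_on_carbon_is_blocked(self):
        probe = probe_gap((0, 0, 0), [_atom("C", (0, 0, 0))])
        assert not probe.gap_present
        assert probe.max_free_radius == pytest.approx(-1.70)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_free_radius_is_lipschitz_in_center(self, seed):
        rng = np.random.default_rng(seed)
        env = [_atom("C", rng.uniform(-5, 5, 3)) for _ in range(30)]
        c1 = rng.uniform(-3, 3, 3)
        delta = rng.normal(scale=0.5, size=3)
        r1 = probe_gap(c1, env).max_free_radius
        r2 = probe_gap(c1 + delta, env).max_free_radius
        assert abs(r1 - r2) <= np.linalg.norm(delta) + 1e-12

    def test_empty_environment_rejected(self):
        from tcrstalk.geometry_core import GeometryError
        with pytest.raises(GeometryError):
            probe_gap((0, 0, 0), [])
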