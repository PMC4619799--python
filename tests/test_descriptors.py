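import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polyqlab import descriptors as desc
from polyqlab import synthetic as syn
from polyqlab.structure import Conformer, Residue

from conftest import random_rotation


def brute_force_contacts(conformer, radii=None, min_separation=3):
    """Exhaustive all-atom-pair scan (oracle for build_contact_map)."""
    radii = radii or desc.RadiiTable()
    pairs = set()
    n = len(conformer)
    for i in range(n):
        for j in range(i + min_separation, n):
            for ai, ci in conformer.residues[i].atoms.items():
                for aj, cj in conformer.residues[j].atoms.items():
                    cutoff = radii.enlargement_factor * (
                        radii.radius_of(ai) + radii.radius_of(aj))
                    if np.linalg.norm(ci - cj) < cutoff:
                        pairs.add((i, j))
    return sorted(pairs)


class TestContactMap:
    def test_far_apart_no_contact(self):
        c = Conformer("x", "QQ", [
            Residue("GLN", {"CA": [0, 0, 0]}),
            Residue("GLN", {"CA": [50.0, 0, 0]}),
        ])
        cmap = desc.build_contact_map(c, min_separation=1)
        assert cmap.contacts == []

    def test_overlapping_spheres_contact(self):
        # two CA carbons 3.0 A apart: 1.24 * (1.88 + 1.88) = 4.66 > 3.0
        c = Conformer("x", "QQ", [
            Residue("GLN", {"CA": [0, 0, 0]}),
            Residue("GLN", {"CA": [3.0, 0, 0]}),
        ])
        cmap = desc.build_contact_map(c, min_separation=1)
        assert cmap.contacts == [(0, 1)]

    @pytest.mark.parametrize("builder, args", [
        (syn.make_ideal, ("hairpin", 16)),
        (syn.make_ideal, ("helix", 20)),
        (syn.make_self_avoiding_coil, (25, 3)),
    ])
    def test_equals_brute_force_oracle(self, builder, args):
        c = builder(*args)
        if set(c.residues[0].atoms) == {"CA"}:
            c = syn.backbone_from_ca(c)
        cmap = desc.build_contact_map(c)
        assert cmap.contacts == brute_force_contacts(c)
        assert all(j - i >= 3 for i, j in cmap.contacts)

    def test_native_distances_are_ca_distances(self, hairpin16):
        cmap = desc.build_contact_map(hairpin16)
        ca = hairpin16.ca_coords()
        for (i, j), d in zip(cmap.contacts, cmap.native_ca_distance):
            assert d == pytest.approx(np.linalg.norm(ca[i] - ca[j]))


class TestRadiusOfGyration:
    def test_single_point(self):
        assert desc.radius_of_gyration(np.array([[1.0, 2, 3]])) == 0.0

    def test_colinear_closed_form(self):
        coords = np.column_stack([3.8 * np.arange(10), np.zeros(10),
                                  np.zeros(10)])
        expected = 3.8 * np.sqrt((100 - 1) / 12)
        assert desc.radius_of_gyration(coords) == pytest.approx(
            expected, abs=1e-6)

    @pytest.mark.parametrize("seed", [1, 2])
    def test_rigid_invariance(self, helix20, seed):
        rot = random_rotation(seed)
        moved = helix20.ca_coords() @ rot.T + 7.0
        assert desc.radius_of_gyration(moved) == pytest.approx(
            desc.radius_of_gyration(helix20), abs=1e-9)


class TestShapeParameter:
    def test_rod_positive_two(self):
        line = np.column_stack([np.linspace(0, 40, 200), np.zeros(200),
                                np.zeros(200)])
        assert desc.shape_parameter_w(line) == pytest.approx(2.0, abs=0.05)

    def test_disk_negative_quarter(self):
        rng = np.random.default_rng(0)
        th = rng.uniform(0, 2 * np.pi, 20000)
        r = np.sqrt(rng.uniform(0, 1, 20000))
        disk = np.column_stack([r * np.cos(th), r * np.sin(th),
                                np.zeros_like(th)])
        assert desc.shape_parameter_w(disk) == pytest.approx(-0.25, abs=0.05)

    def test_sphere_near_zero(self):
        rng = np.random.default_rng(1)
        g = rng.normal(size=(20000, 3))
        g /= np.linalg.norm(g, axis=1)[:, None]
        assert abs(desc.shape_parameter_w(g)) < 0.02

    @pytest.mark.parametrize("seed", [3, 4])
    def test_sign_contract_any_orientation(self, seed):
        rot = random_rotation(seed)
        line = np.column_stack([np.linspace(0, 40, 100), np.zeros(100),
                                np.zeros(100)]) @ rot.T
        assert desc.shape_parameter_w(line) > 0
        rng = np.random.default_rng(seed)
        th = rng.uniform(0, 2 * np.pi, 5000)
        r = np.sqrt(rng.uniform(0, 1, 5000))
        disk = np.column_stack([r * np.cos(th), r * np.sin(th),
                                np.zeros(5000)]) @ rot.T
        assert desc.shape_parameter_w(disk) < 0

    def test_coincident_points_error(self):
        with pytest.raises(ValueError):
            desc.shape_parameter_w(np.zeros((5, 3)))


class TestMeanCoordination:
    def test_chain_only(self):
        cmap = desc.ContactMap(60, [], np.array([]))
        assert desc.mean_coordination(cmap) == pytest.approx(
            2 * 59 / 60, abs=1e-9)

    def test_one_contact_adds_two_over_n(self):
        empty = desc.ContactMap(20, [], np.array([]))
        one = desc.ContactMap(20, [(2, 9)], np.array([8.0]))
        diff = desc.mean_coordination(one) - desc.mean_coordination(empty)
        assert diff == pytest.approx(2 / 20, abs=1e-12)

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_brute_force_tally(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        pairs = set()
        for _ in range(int(rng.integers(0, 15))):
            i = int(rng.integers(0, n - 3))
            j = int(rng.integers(i + 3, n))
            pairs.add((i, j))
        cmap = desc.ContactMap(n, sorted(pairs),
                               np.full(len(pairs), 5.0))
        z = np.zeros(n)
        for i in range(n):
            z[i] = (1 if i in (0, n - 1) else 2)
            z[i] += sum(1 for a, b in pairs if i in (a, b))
        assert desc.mean_coordination(cmap) == pytest.approx(z.mean())
        assert desc.mean_coordination(cmap) >= 2 * (n - 1) / n - 1e-12


class TestContactOrder:
    def test_hand_example_single(self):
        cmap = desc.ContactMap(4, [(0, 3)], np.array([5.0]))
        assert desc.contact_order(cmap) == pytest.approx(0.75)

    def test_hand_example_two(self):
        cmap = desc.ContactMap(10, [(1, 5), (2, 8)], np.array([5.0, 6.0]))
        assert desc.contact_order(cmap) == pytest.approx(0.5)

    def test_no_contacts_errors(self):
        cmap = desc.ContactMap(10, [], np.array([]))
        with pytest.raises(ValueError):
            desc.contact_order(cmap)


class TestSecondaryStructure:
    def test_helix(self, helix20):
        ss = desc.assign_secondary_structure(helix20)
        assert ss.ss_alpha >= 70.0

    def test_hairpin(self, hairpin16):
        ss = desc.assign_secondary_structure(hairpin16)
        assert ss.ss_beta > 0
        assert ss.ss_total >= 30.0

    def test_isolated_strand_has_no_beta(self, extended10):
        ss = desc.assign_secondary_structure(extended10)
        assert ss.ss_beta == 0.0

    def test_missing_backbone_errors(self):
        trace = syn.make_self_avoiding_coil(10, 0)
        with pytest.raises(ValueError, match="backbone"):
            desc.assign_secondary_structure(trace)

    def test_percentages_bounded(self, helix20, hairpin16):
        for c in (helix20, hairpin16):
            ss = desc.assign_secondary_structure(c)
            assert 0 <= ss.ss_alpha and 0 <= ss.ss_beta and 0 <= ss.ss_turn
            assert ss.ss_total <= 100.0


class TestStiffLimit:
    def test_values(self):
        assert desc.stiff_limit(10 ** 9) == pytest.approx(6.0, abs=1e-6)
        assert desc.stiff_limit(60) == pytest.approx(5.8)
        assert desc.stiff_limit(12) == pytest.approx(5.0)

    def test_volatility(self):
        d = dict(n_residues=60, R_g=10.0, w=0.0, ss_alpha=0, ss_beta=0,
                 ss_turn=0, ss_total=0, CO=None, n_contacts=0,
                 contact_mode="backbone")
        assert desc.is_volatile(desc.DescriptorSet(z_mean=5.0, **d))
        assert not desc.is_volatile(desc.DescriptorSet(z_mean=7.67, **d))
        # boundary: exactly at threshold counts as stiff
        assert not desc.is_volatile(desc.DescriptorSet(z_mean=5.8, **d))


class TestComputeDescriptors:
    def test_rigid_invariance_of_bundle(self, hairpin16):
        rot = random_rotation(8)
        moved_res = []
        for res in hairpin16.residues:
            moved_res.append(Residue(res.name, {
                k: rot @ v + np.array([1.0, 2.0, 3.0])
                for k, v in res.atoms.items()}))
        moved = Conformer("m", hairpin16.sequence, moved_res)
        a = desc.compute_descriptors(hairpin16)
        b = desc.compute_descriptors(moved)
        assert b.R_g == pytest.approx(a.R_g, abs=1e-9)
        assert b.w == pytest.approx(a.w, abs=1e-9)
        assert b.z_mean == pytest.approx(a.z_mean)
        assert b.ss_alpha == a.ss_alpha and b.ss_beta == a.ss_beta

    def test_ca_only_gets_backbone_mode(self):
        coil = syn.make_self_avoiding_coil(20, 1)
        d = desc.compute_descriptors(coil)
        assert d.contact_mode == "backbone"
        assert d.z_mean >= 2 * 19 / 20 - 1e-12
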