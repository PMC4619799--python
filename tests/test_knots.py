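import numpy as np
import pytest

from polyqlab import descriptors as desc
from polyqlab import go_model as go
from polyqlab import knots
from polyqlab import synthetic as syn

from conftest import random_rotation


def circle(n=50, r=1.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([r * np.cos(t), r * np.sin(t), np.zeros(n)])


class TestKmtReduce:
    def test_colinear_reduces_to_endpoints(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        assert len(knots.kmt_reduce(pts)) == 2

    def test_idempotent(self):
        c = syn.make_knotted_chain(60, "3_1", (5, 5), 0)
        r1 = knots.kmt_reduce(c.ca_coords())
        r2 = knots.kmt_reduce(r1)
        assert np.array_equal(r1, r2)

    def test_preserves_classification(self):
        c = syn.make_knotted_chain(60, "3_1", (5, 5), 0).ca_coords()
        before, _ = knots.classify_knot(c, n_closures=32, seed=1)
        after, _ = knots.classify_knot(knots.kmt_reduce(c),
                                       n_closures=32, seed=1)
        assert before == after == "3_1"


class TestCloseChain:
    def test_deterministic_per_seed(self):
        c = syn.make_self_avoiding_coil(20, 0).ca_coords()
        a = knots.close_chain(c, 8, seed=3)
        b = knots.close_chain(c, 8, seed=3)
        for la, lb in zip(a, b):
            assert np.array_equal(la, lb)

    def test_near_circle_closures_unknotted(self):
        arc = circle(60)[:-1]  # 1-vertex gap
        for loop in knots.close_chain(arc, 16, seed=0):
            d1, d2 = knots.alexander_invariants(loop, seed=5)
            assert (d1, d2) == (1, 1)

    def test_deep_trefoil_votes(self):
        c = syn.make_knotted_chain(60, "3_1", (5, 5), 0)
        ktype, votes = knots.classify_knot(c, n_closures=64, seed=0)
        assert ktype == "3_1"
        assert votes >= 0.90


class TestAlexanderInvariants:
    def test_unknot_circle(self):
        assert knots.alexander_invariants(circle(), seed=0) == (1, 1)

    @pytest.mark.parametrize("ktype, expected", [
        ("3_1", (3, 7)),     # det(trefoil) = 3; |Delta(-2)| = 7
        ("4_1", (5, 11)),    # figure-eight
        ("5_1", (5, 31)),    # cinquefoil (torus)
        ("5_2", (7, 1)),     # three-twist: |Delta(-2)| = 16, odd part 1
    ])
    def test_closed_parametric_curves(self, ktype, expected):
        curve = syn._parametric_curve(ktype)
        assert knots.alexander_invariants(curve, seed=2) == expected


class TestClassify:
    @pytest.mark.parametrize("ktype", ["0_1", "3_1", "4_1", "5_2"])
    def test_planted_chains(self, ktype):
        c = syn.make_knotted_chain(60, ktype, (5, 5), 0)
        found, votes = knots.classify_knot(c, n_closures=64, seed=0)
        assert found == ktype

    def test_short_coils_are_unknotted(self):
        hits = 0
        for s in range(20):
            coil = syn.make_self_avoiding_coil(20, s)
            t, _ = knots.classify_knot(coil, n_closures=16, seed=s)
            hits += (t == "0_1")
        assert hits == 20

    def test_rigid_scale_reverse_invariance(self):
        pts = syn.make_knotted_chain(60, "3_1", (5, 5), 0).ca_coords()
        rot = random_rotation(4)
        variants = [
            pts @ rot.T + np.array([10.0, -4.0, 2.0]),
            pts * 3.7,
            pts[::-1],
        ]
        for v in variants:
            t, _ = knots.classify_knot(v, n_closures=32, seed=6)
            assert t == "3_1"


class TestKnotCore:
    def test_planted_trefoil_core_recovered(self):
        c = syn.make_knotted_chain(80, "3_1", (19, 25), 0)
        km, kp, dk = knots.knot_core(c, n_closures=32, seed=0)
        span_lo, span_hi = c.planted_span       # non-tail residues, 0-based
        core_lo, core_hi = c.planted_core       # crossing-span ground truth
        assert span_lo + 1 <= km <= kp <= span_hi + 1
        assert abs(km - (core_lo + 1)) <= 3
        assert abs(kp - (core_hi + 1)) <= 3
        assert dk == kp - km + 1
        # the localized core still carries the knot
        sub = c.ca_coords()[km - 1:kp]
        t, _ = knots.classify_knot(sub, n_closures=32, seed=0)
        assert t == "3_1"

    def test_shallow_knot_extends_over_chain(self):
        shallow = syn.make_knotted_chain(60, "3_1", (0, 0), 0)
        _, _, dk_shallow = knots.knot_core(shallow, n_closures=32, seed=0)
        deep = syn.make_knotted_chain(60, "3_1", (13, 13), 0)
        _, _, dk_deep = knots.knot_core(deep, n_closures=32, seed=0)
        assert dk_shallow > dk_deep
        assert dk_shallow >= 40  # extension close to the chain length

    def test_unknotted_input_errors(self):
        coil = syn.make_self_avoiding_coil(20, 3)
        with pytest.raises(ValueError):
            knots.knot_core(coil, n_closures=16, seed=0)


class TestReport:
    def test_report_fields(self):
        c = syn.make_knotted_chain(60, "3_1", (5, 5), 0)
        rep = knots.knot_report(c, n_closures=32, seed=0)
        assert rep.knot_type == "3_1"
        assert rep.delta_k == rep.k_plus - rep.k_minus + 1
        assert 0 < rep.closure_votes <= 1

    def test_unknot_report_has_no_core(self):
        rep = knots.knot_report(circle(30), n_closures=8, seed=0)
        assert rep.knot_type == "0_1"
        assert rep.k_minus is None and rep.delta_k is None


class TestUntying:
    def test_unknotted_start_errors(self, extended10):
        cmap = desc.build_contact_map(extended10)
        model = go.build_go_model(extended10, cmap)
        with pytest.raises(ValueError):
            knots.untying_under_stretch(model, go.GoModelParams(), 2)

    def test_knot_survives_default_pull(self):
        """A deeply planted trefoil stays knotted when fully stretched."""
        c = syn.make_knotted_chain(28, "3_1", (4, 4), 0)
        cmap = desc.build_contact_map(syn.backbone_from_ca(c))
        model = go.build_go_model(c, cmap)
        frac, se, finals = knots.untying_under_stretch(
            model, go.GoModelParams(seed=1), n_seeds=2, n_closures=16)
        assert 0.0 <= frac <= 1.0
        assert len(finals) == 2
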