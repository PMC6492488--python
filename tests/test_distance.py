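"""Minimal-distance strategies: VCPs, tunneled mirrors and the metric properties."""

import numpy as np
import pytest

from s6lattice import (
    UnitCell,
    apply_sym,
    canonical_s6,
    cs6dist,
    dist_euclidean,
    dist_mirror,
    dist_vcp1,
    dist_vcp2,
    distance_matrix_s6,
    edge_transform,
    edge_transforms,
    make_vcp,
    reflection_matrices,
    reflections,
    selling_reduce,
    unreduce_random,
    vcp_candidates,
)
from s6lattice.distance import NotReducedError, projector_axis, projector_perp, random_reduced

from conftest import random_reduced_vectors


def deep_interior_pair(rng, depth=(50.0, 100.0), sep=1.0):
    """Two reduced points far from every boundary and close to each other."""
    base = -rng.uniform(*depth, size=6)
    return base + rng.normal(size=6) * sep, base + rng.normal(size=6) * sep


class TestProjectors:
    def test_axis_plus_perp_is_identity_idempotent_symmetric(self):
        for k in range(1, 7):
            ax, pp = projector_axis(k), projector_perp(k)
            np.testing.assert_array_equal(ax + pp, np.eye(6))
            for m in (ax, pp):
                np.testing.assert_array_equal(m @ m, m)
                np.testing.assert_array_equal(m, m.T)


class TestMakeVcp:
    def test_boundary_point_maps_to_transform_image(self, rng):
        """For p on the boundary the perp term vanishes: VCP = M·p exactly."""
        for k in range(1, 7):
            p = -np.abs(rng.normal(size=6)) * 20
            p[k - 1] = 0.0
            np.testing.assert_allclose(
                make_vcp(p, k), edge_transform(k, 1).matrix.astype(float) @ p, atol=1e-12
            )

    def test_equals_orthogonal_boundary_form(self, rng):
        for k in range(1, 7):
            p = -np.abs(rng.normal(size=6)) * 20
            np.testing.assert_allclose(
                make_vcp(p, k), edge_transform(k, 1).boundary_matrix.astype(float) @ p, atol=1e-12
            )

    def test_reflection_equivariance(self, rng):
        """The 12 boundary forms are permuted among themselves by conjugation
        with any reflection, so reflecting p commutes with VCP construction
        on the permuted boundary."""
        forms = {op.boundary_matrix.tobytes(): op for op in edge_transforms()}
        p = -np.abs(rng.normal(size=6)) * 20
        for op in reflections():
            r = op.matrix.astype(float)
            for k in range(1, 7):
                o = edge_transform(k, 1).boundary_matrix.astype(float)
                conj = (r @ o @ r.T).astype(int)
                assert conj.tobytes() in forms, "conjugated boundary form left the set"
                partner = forms[conj.tobytes()]
                np.testing.assert_allclose(
                    apply_sym(op, make_vcp(p, k)),
                    make_vcp(apply_sym(op, p), partner.boundary_index, partner.variant),
                    atol=1e-10,
                )

    def test_vcp_path_can_undercut_direct_distance(self, rng):
        """Near-boundary construction where crossing beats every reflection."""
        o = edge_transform(1, 1).boundary_matrix.astype(float)
        found = 0
        for _ in range(50):
            x0 = -rng.uniform(40, 100, size=6)
            x0[0] = 0.0
            hp, hq = rng.uniform(0.1, 3.0, size=2)
            p = x0.copy()
            p[0] = -hp
            q = o @ x0
            q[0] = -hq
            direct = dist_euclidean(p, q).distance
            via_vcp = dist_vcp1(p, q).distance
            assert via_vcp <= direct + 1e-12
            if via_vcp < direct - 1e-9:
                found += 1
        assert found > 25, "VCP route almost never undercut the direct distance"


class TestVcp1:
    def test_candidate_count_168(self, rng):
        p = random_reduced_vectors(1, rng)[0]
        cands = vcp_candidates(p)
        assert cands.shape == (168, 6)

    def test_self_distance_zero(self, rng):
        for p in random_reduced_vectors(10, rng):
            assert dist_vcp1(p, p).distance == 0.0

    def test_reflection_images_at_zero_distance(self, rng):
        p = random_reduced_vectors(1, rng)[0]
        for op in reflections():
            q = selling_reduce(apply_sym(op, p)).reduced
            assert dist_vcp1(p, q).distance == pytest.approx(0.0, abs=1e-9)

    def test_interior_point_oracle(self, rng):
        """Deep in the interior no boundary route can be shorter, so vcp1
        equals the min over the 24 reflections of the Euclidean distance."""
        for _ in range(200):
            p, q = deep_interior_pair(rng)
            expected = min(np.linalg.norm(q - r @ p) for r in reflection_matrices())
            assert dist_vcp1(p, q).distance == pytest.approx(expected, rel=1e-12)

    def test_unreduced_input_rejected(self):
        with pytest.raises(NotReducedError):
            dist_vcp1(np.array([1.0, -1, -1, -1, -1, -1]), -np.ones(6))

    def test_variant2_inclusion_never_changes_result(self, rng):
        """With reflections and symmetrisation, adding the 6 variant-2 VCPs
        to the candidate set leaves every distance unchanged."""
        P = random_reduced(200, rng)
        Q = random_reduced(200, rng)
        for p, q in zip(P, Q):
            d1 = dist_vcp1(p, q, variants=(1,)).distance
            d12 = dist_vcp1(p, q, variants=(1, 2)).distance
            assert d12 == pytest.approx(d1, rel=1e-12, abs=1e-12)


class TestVcp2:
    def test_never_exceeds_vcp1(self, rng):
        P = random_reduced(500, rng)
        Q = random_reduced(500, rng)
        improved = 0
        rel_gains = []
        for p, q in zip(P, Q):
            d1 = dist_vcp1(p, q).distance
            d2 = dist_vcp2(p, q).distance
            assert d2 <= d1 + 1e-9
            if d2 < d1 * (1 - 1e-9):
                improved += 1
                rel_gains.append((d1 - d2) / d1)
        # two-boundary improvements are rare and small
        assert improved <= 0.03 * len(P)
        if rel_gains:
            assert np.median(rel_gains) < 0.10

    def test_self_distance_zero(self, rng):
        p = random_reduced_vectors(1, rng)[0]
        assert dist_vcp2(p, p).distance == 0.0


class TestMirror:
    def test_self_distance_zero(self, rng):
        p = random_reduced_vectors(1, rng)[0]
        assert dist_mirror(p, p).distance == 0.0

    def test_never_exceeds_direct(self, rng):
        for p, q in zip(random_reduced(50, rng), random_reduced(50, rng)):
            assert dist_mirror(p, q).distance <= dist_euclidean(p, q).distance + 1e-12

    def test_on_boundary_zero_heights(self, rng):
        """Both points on a boundary: the mirror path degenerates to the
        direct distance through the boundary transforms."""
        p = random_reduced(1, rng)[0]
        q = random_reduced(1, rng)[0]
        p[0] = q[0] = 0.0
        dm = dist_mirror(p, q).distance
        assert dm <= dist_euclidean(p, q).distance + 1e-12
        assert dm == pytest.approx(dist_vcp1(p, q).distance, abs=1e-9)

    def test_agrees_with_vcp1_on_orthogonal_crossings(self, rng):
        """Symmetric instances: perp part invariant under the boundary form
        and both points on the boundary axis line, so any boundary crossing
        is orthogonal; the two algorithms agree to 1e−9."""
        for _ in range(100):
            x0 = -rng.uniform(40, 100, size=6)
            x0[0] = 0.0
            x0[4] = x0[2]  # s3 = s5: invariant under the s1 boundary form
            hp, hq = rng.uniform(0.1, 5.0, size=2)
            p = x0.copy()
            p[0] = -hp
            q = x0.copy()
            q[0] = -hq
            assert dist_mirror(p, q).distance == pytest.approx(
                dist_vcp1(p, q).distance, abs=1e-9
            )


class TestCs6dist:
    def test_unreduce_then_compare_is_zero(self, rng):
        for v in random_reduced_vectors(20, rng):
            u = unreduce_random(v, 3, rng)
            assert cs6dist(u, v).distance == pytest.approx(0.0, abs=1e-7)

    def test_interior_cells_give_euclidean_component_difference(self):
        """(10,12,20,…) vs (10,12,20.1,…): only c·d changes, by 20.1²−20²."""
        d = cs6dist(UnitCell(10, 12, 20, 90, 90, 90), UnitCell(10, 12, 20.1, 90, 90, 90))
        assert d.distance == pytest.approx(20.1**2 - 20.0**2, rel=1e-9)

    def test_symmetry_exact(self, rng):
        for p, q in zip(random_reduced(50, rng), random_reduced(50, rng)):
            for strategy in ("euclidean", "vcp1", "vcp2", "mirror"):
                assert (
                    cs6dist(p, q, strategy=strategy).distance
                    == cs6dist(q, p, strategy=strategy).distance
                )

    def test_upper_bounded_by_canonical_euclidean(self, rng):
        for p, q in zip(random_reduced(50, rng), random_reduced(50, rng)):
            bound = np.linalg.norm(canonical_s6(p) - canonical_s6(q))
            assert cs6dist(p, q).distance <= bound + 1e-9

    def test_nonnegative_and_zero_iff_same_lattice(self, rng):
        p = random_reduced_vectors(1, rng)[0]
        assert cs6dist(p, p).distance == 0.0
        q = random_reduced_vectors(1, rng)[0]
        assert cs6dist(p, q).distance > 0

    def test_reflection_invariance(self, rng):
        p, q = random_reduced(2, rng)
        d0 = cs6dist(p, q).distance
        for op in reflections():
            assert cs6dist(apply_sym(op, p), q).distance == pytest.approx(d0, rel=1e-12)
            assert cs6dist(p, apply_sym(op, q)).distance == pytest.approx(d0, rel=1e-12)

    def test_normalized_mode(self, rng):
        p, q = random_reduced(2, rng)
        d = cs6dist(p, q).distance
        dn = cs6dist(p, q, normalized=True).distance
        assert dn == pytest.approx(d / (np.linalg.norm(p) + np.linalg.norm(q)))


class TestLipschitz:
    def test_one_lipschitz_along_lines(self, rng):
        """All candidate maps are isometries, so each strategy's distance is
        1-Lipschitz in a reduced argument moved along a straight line."""
        e = random_reduced_vectors(1, rng)[0]
        for _ in range(20):
            x = -rng.uniform(1, 100, size=6)
            step = rng.normal(size=6)
            step *= min(1.0, np.min(np.abs(x)) / np.linalg.norm(step)) * 0.5
            y = x + step  # still all-negative, hence reduced
            for dist in (dist_euclidean, dist_vcp1, dist_vcp2):
                dx = dist(x, e).distance
                dy = dist(y, e).distance
                assert abs(dx - dy) <= np.linalg.norm(x - y) * (1 + 1e-12) + 1e-12


class TestDistanceMatrix:
    def test_symmetric_zero_diagonal_nonnegative(self, rng):
        pts = random_reduced(15, rng)
        for strategy in ("vcp1", "vcp2"):
            dm = distance_matrix_s6(pts, strategy=strategy)
            np.testing.assert_array_equal(dm, dm.T)
            np.testing.assert_array_equal(np.diag(dm), np.zeros(15))
            assert np.all(dm >= 0)

    def test_matches_pairwise_calls(self, rng):
        pts = random_reduced(6, rng)
        dm = distance_matrix_s6(pts, strategy="vcp1")
        for i in range(6):
            for j in range(i + 1, 6):
                assert dm[i, j] == pytest.approx(dist_vcp1(pts[i], pts[j]).distance, rel=1e-12)
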