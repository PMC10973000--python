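"""SPD geometry, Karcher mean, MDM and recentering tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dccabci.riemann import (
    MDM,
    AdaptiveReference,
    Recenter,
    airm_distance,
    geodesic,
    karcher_mean,
    rebias,
    shrinkage_scm,
    trace_normalize,
)
from conftest import random_spd, spd_around


class TestGeodesic:
    def test_endpoints(self, random_spd_factory):
        p1, p2 = random_spd_factory(), random_spd_factory()
        assert np.allclose(geodesic(p1, p2, 0.0), p1)
        assert np.allclose(geodesic(p1, p2, 1.0), p2, atol=1e-8)

    def test_constant_path_for_equal_endpoints(self, random_spd_factory):
        p = random_spd_factory()
        for t in (0.0, 0.3, 1.0):
            assert np.allclose(geodesic(p, p, t), p)

    def test_commuting_matrices_elementwise_geometric_mean(self):
        g = geodesic(np.diag([1.0, 1.0]), np.diag([4.0, 4.0]), 0.5)
        assert np.allclose(g, np.diag([2.0, 2.0]))

    def test_no_extrapolation(self, random_spd_factory):
        with pytest.raises(ValueError):
            geodesic(random_spd_factory(), random_spd_factory(), 1.5)

    def test_point_lies_on_path(self, rng):
        p1, p2 = random_spd(rng, 3), random_spd(rng, 3)
        full = airm_distance(p1, p2)
        for t in (0.25, 0.5, 0.75):
            assert airm_distance(p1, geodesic(p1, p2, t)) == pytest.approx(
                t * full, abs=1e-8
            )


class TestAirmDistance:
    def test_self_distance_zero(self, random_spd_factory):
        p = random_spd_factory()
        assert airm_distance(p, p) == pytest.approx(0.0, abs=1e-7)

    def test_closed_form_diagonal(self):
        assert airm_distance(np.eye(2), np.diag([np.e**2, np.e**2])) == pytest.approx(
            2 * np.sqrt(2)
        )

    def test_rejects_non_spd(self, random_spd_factory):
        with pytest.raises(ValueError):
            airm_distance(np.diag([1.0, -1.0]), random_spd_factory(2))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_congruence_invariance(self, seed):
        """delta(W P1 W^T, W P2 W^T) = delta(P1, P2) for invertible W."""
        r = np.random.default_rng(seed)
        p1, p2 = random_spd(r, 3), random_spd(r, 3)
        w = r.standard_normal((3, 3)) + 0.5 * np.eye(3)
        d1 = airm_distance(w @ p1 @ w.T, w @ p2 @ w.T)
        assert d1 == pytest.approx(airm_distance(p1, p2), abs=1e-8, rel=1e-8)


class TestKarcherMean:
    def test_singleton_and_duplicates(self, random_spd_factory):
        p = random_spd_factory()
        assert np.allclose(karcher_mean([p]), p)
        assert np.allclose(karcher_mean([p, p]), p, atol=1e-8)

    def test_two_point_mean_is_geodesic_midpoint(self, rng):
        p1, p2 = random_spd(rng, 3), random_spd(rng, 3)
        assert np.allclose(karcher_mean([p1, p2]), geodesic(p1, p2, 0.5), atol=1e-7)

    def test_commuting_diagonal_closed_form(self):
        mats = [np.diag([1.0, 8.0]), np.diag([4.0, 1.0]), np.diag([2.0, 1.0])]
        expected = np.diag([2.0, 2.0])  # element-wise geometric means
        assert np.allclose(karcher_mean(mats), expected, atol=1e-8)

    def test_minimality_against_random_perturbations(self, rng):
        mats = [random_spd(rng, 3) for _ in range(3)]
        mean = karcher_mean(mats)
        cost = sum(airm_distance(mean, m) ** 2 for m in mats)
        for _ in range(200):
            perturbed = spd_around(rng, mean, dispersion=0.05)
            assert sum(airm_distance(perturbed, m) ** 2 for m in mats) >= cost - 1e-9

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            karcher_mean([])


class TestShrinkageScm:
    def test_large_sample_identity_data(self, rng):
        x = rng.standard_normal((4, 20000))
        c = shrinkage_scm(x)
        assert np.allclose(c, np.cov(x, bias=True), atol=0.02)

    def test_more_channels_than_samples_still_pd(self, rng):
        c = shrinkage_scm(rng.standard_normal((10, 6)))
        assert np.abs(c - c.T).max() < 1e-12
        assert np.linalg.eigvalsh(c)[0] > 0

    def test_single_sample_rejected(self, rng):
        with pytest.raises(ValueError):
            shrinkage_scm(rng.standard_normal((4, 1)))


class TestTraceNormalize:
    def test_examples_and_idempotence(self, random_spd_factory):
        assert np.allclose(trace_normalize(np.diag([2.0, 2.0])), np.diag([0.5, 0.5]))
        p = trace_normalize(random_spd_factory())
        assert np.trace(p) == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(trace_normalize(p), p)


class TestMdm:
    def test_single_example_prototypes(self, random_spd_factory):
        p1, p2 = random_spd_factory(), random_spd_factory()
        m = MDM().fit(np.stack([p1, p2]), ["a", "b"])
        assert np.allclose(m.prototypes_[0], p1)
        assert np.allclose(m.prototypes_[1], p2)
        pred = m.predict(p1[None])
        assert pred[0] == "a"
        assert m.predict_proba(p1[None])[0, 0] > 0.5

    def test_duplicated_training_set_identical_prototypes(self, rng):
        mats = [random_spd(rng, 3) for _ in range(4)]
        y = ["a", "a", "b", "b"]
        m1 = MDM().fit(np.stack(mats), y)
        m2 = MDM().fit(np.stack(mats + mats), y + y)
        assert np.allclose(m1.prototypes_, m2.prototypes_, atol=1e-7)

    def test_equidistant_tie_breaks_to_first_class(self):
        p1, p2 = np.diag([1.0, 4.0]), np.diag([4.0, 1.0])
        m = MDM().fit(np.stack([p1, p2]), ["a", "b"])
        assert m.predict(np.eye(2)[None])[0] == "a"

    def test_well_separated_classes_recovered(self):
        hits = 0
        total = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            protos = {"a": random_spd(r, 4), "b": random_spd(r, 4)}
            X, y = [], []
            for cls, p in protos.items():
                for _ in range(10):
                    X.append(spd_around(r, p, dispersion=0.05))
                    y.append(cls)
            X, y = np.stack(X), np.asarray(y)
            m = MDM().fit(X, y)
            hits += (m.predict(X) == y).sum()
            total += len(y)
        assert hits / total >= 0.95

    def test_probability_monotone_in_distance(self, rng):
        p1, p2 = random_spd(rng, 3), random_spd(rng, 3)
        m = MDM().fit(np.stack([p1, p2]), ["a", "b"])
        probe = spd_around(rng, p1, dispersion=0.02)
        d = m.transform(probe[None])[0]
        proba = m.predict_proba(probe[None])[0]
        assert (d[0] < d[1]) == (proba[0] > 0.5)

    def test_empty_class_rejected(self, random_spd_factory):
        with pytest.raises(ValueError):
            MDM().fit(np.stack([random_spd_factory()]), ["a"])


class TestRebias:
    def test_identity_cases(self, random_spd_factory):
        c = random_spd_factory()
        assert np.allclose(rebias(c, c), np.eye(c.shape[0]), atol=1e-9)
        assert np.allclose(rebias(c, np.eye(c.shape[0])), c)

    def test_recentred_set_has_identity_karcher_mean(self, rng):
        mats = [random_spd(rng, 3) for _ in range(5)]
        ref = karcher_mean(mats)
        recentred = [rebias(m, ref) for m in mats]
        mean = karcher_mean(recentred)
        assert airm_distance(mean, np.eye(3)) < 1e-6

    def test_preserves_pairwise_distances(self, rng):
        c1, c2, r = (random_spd(rng, 3) for _ in range(3))
        assert airm_distance(rebias(c1, r), rebias(c2, r)) == pytest.approx(
            airm_distance(c1, c2), abs=1e-8
        )

    def test_recenter_transformer_roundtrip(self, rng):
        X = np.stack([random_spd(rng, 3) for _ in range(6)])
        rc = Recenter().fit(X)
        out = rc.transform(X)
        assert airm_distance(karcher_mean(list(out)), np.eye(3)) < 1e-6


class TestAdaptiveReference:
    def test_first_matrix_rebiased_with_training_reference(self, rng):
        r_train = random_spd(rng, 3)
        c1 = random_spd(rng, 3)
        for variant in ("reset", "running_mean"):
            state = AdaptiveReference(r_train, variant=variant)
            out = state.step(c1)
            assert np.allclose(out, rebias(c1, r_train))

    def test_as_printed_second_matrix_uses_first(self, rng):
        r_train, c1, c2 = (random_spd(rng, 3) for _ in range(3))
        state = AdaptiveReference(r_train, variant="reset")
        state.step(c1)
        out = state.step(c2)
        assert np.allclose(out, rebias(c2, c1))

    def test_constant_stream_converges_to_identity(self, rng):
        r_train, c = random_spd(rng, 3), random_spd(rng, 3)
        for variant in ("reset", "running_mean"):
            state = AdaptiveReference(r_train, variant=variant)
            for _ in range(30):
                out = state.step(c)
            assert airm_distance(state.reference, c) < 1e-6
            assert np.allclose(out, np.eye(3), atol=1e-6)

    def test_dimension_mismatch(self, rng):
        state = AdaptiveReference(random_spd(rng, 3))
        with pytest.raises(ValueError):
            state.step(random_spd(rng, 4))
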