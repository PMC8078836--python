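import math

import numpy as np
import pytest

import oracles
from mdassoc.data_io import AssociationMatrix, PathwayMembership, SymptomCatalog
from mdassoc.similarity import (
    SimilarityMatrix,
    disease_nmi_similarity,
    gip_bandwidth,
    gip_similarity,
    integrate_similarity,
    integrated_similarities,
    metabolite_hamming_similarity,
    symptom_entropy,
)


class TestMetaboliteHamming:
    def test_tiny_fixture_hand_values(self, tiny):
        _, mp, _ = tiny
        mhs = metabolite_hamming_similarity(mp).values
        expected = np.array(
            [
                [1.00, 0.75, 0.25, 0.25, 0.75, 0.50],
                [0.75, 1.00, 0.50, 0.00, 0.50, 0.25],
                [0.25, 0.50, 1.00, 0.50, 0.00, 0.25],
                [0.25, 0.00, 0.50, 1.00, 0.50, 0.75],
                [0.75, 0.50, 0.00, 0.50, 1.00, 0.75],
                [0.50, 0.25, 0.25, 0.75, 0.75, 1.00],
            ]
        )
        np.testing.assert_allclose(mhs, expected, atol=1e-12)

    def test_identical_columns_give_one(self):
        mp = PathwayMembership(np.array([[1.0, 1.0], [0.0, 0.0]]), ["p1", "p2"], ["m1", "m2"])
        assert metabolite_hamming_similarity(mp).values[0, 1] == 1.0

    def test_matches_bitwise_oracle_on_random_instances(self, rng):
        for _ in range(10):
            MP = (rng.random((rng.integers(1, 8), rng.integers(2, 12))) < 0.4).astype(float)
            mp = PathwayMembership(
                MP,
                [f"p{i}" for i in range(MP.shape[0])],
                [f"m{j}" for j in range(MP.shape[1])],
            )
            got = metabolite_hamming_similarity(mp).values
            np.testing.assert_allclose(got, oracles.hamming_similarity_oracle(MP), atol=1e-12)

    def test_zero_pathways_errors(self):
        mp = PathwayMembership(np.zeros((0, 2)), [], ["m1", "m2"])
        with pytest.raises(ValueError, match="at least one pathway"):
            metabolite_hamming_similarity(mp)


class TestSymptomEntropy:
    def test_tiny_fixture_hand_values(self, tiny):
        _, _, catalog = tiny
        assert catalog.Tn == 10
        assert symptom_entropy("d1", catalog) == pytest.approx(0.7965784284662087, abs=1e-12)
        assert symptom_entropy("d3", catalog) == pytest.approx(0.5210896782498619, abs=1e-12)
        assert symptom_entropy("d4", catalog) == pytest.approx(0.33219280948873625, abs=1e-12)

    def test_whole_catalog_in_one_set_gives_entropy_zero_only_if_single(self):
        cat = SymptomCatalog({"d1": {"s1": 4}})
        assert symptom_entropy("d1", cat) == pytest.approx(0.0, abs=1e-12)

    def test_empty_set_entropy_zero(self, tiny):
        _, _, catalog = tiny
        assert symptom_entropy("not-a-disease", catalog) == 0.0

    def test_matches_oracle(self, rng):
        symptoms = {
            f"d{i}": {f"s{j}": int(rng.integers(1, 5)) for j in rng.choice(8, 3, replace=False)}
            for i in range(4)
        }
        cat = SymptomCatalog(symptoms)
        for d, counts in symptoms.items():
            assert symptom_entropy(d, cat) == pytest.approx(
                oracles.entropy_oracle(list(counts.values()), cat.Tn), abs=1e-12
            )


class TestDiseaseNmi:
    def test_tiny_fixture_hand_values(self, tiny):
        _, _, catalog = tiny
        dnf = disease_nmi_similarity(catalog, ["d1", "d2", "d3", "d4"]).values
        # d1/d2 share s1 (min count 1): 2*0.3321928 / (0.7965784 + 0.7965784)
        assert dnf[0, 1] == pytest.approx(0.4170246112844971, abs=1e-9)
        # d1/d4 share s2 (min count 1): 2*0.3321928 / (0.7965784 + 0.3321928)
        assert dnf[0, 3] == pytest.approx(0.5885919100677789, abs=1e-9)
        # no shared symptoms elsewhere
        for a, b in [(0, 2), (1, 2), (1, 3), (2, 3)]:
            assert dnf[a, b] == 0.0
        np.testing.assert_allclose(np.diag(dnf), 1.0)

    def test_identical_sets_give_one(self):
        cat = SymptomCatalog({"d1": {"s1": 2, "s2": 3}, "d2": {"s1": 2, "s2": 3}})
        dnf = disease_nmi_similarity(cat, ["d1", "d2"]).values
        assert dnf[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_sets_give_zero(self):
        cat = SymptomCatalog({"d1": {"s1": 1}, "d2": {"s2": 1}})
        assert disease_nmi_similarity(cat, ["d1", "d2"]).values[0, 1] == 0.0

    def test_symptomless_disease_diag_zero(self):
        cat = SymptomCatalog({"d1": {"s1": 1}, "d2": {}})
        dnf = disease_nmi_similarity(cat, ["d1", "d2"]).values
        assert dnf[1, 1] == 0.0

    def test_matches_oracle_both_shared_count_modes(self, rng):
        for trial in range(8):
            symptoms = {}
            for i in range(6):
                chosen = rng.choice(10, size=int(rng.integers(0, 5)), replace=False)
                symptoms[f"d{i}"] = {f"s{j}": int(rng.integers(1, 5)) for j in chosen}
            if not any(symptoms.values()):
                continue
            cat = SymptomCatalog(symptoms)
            ids = sorted(symptoms)
            for mode in ("min", "sum"):
                got = disease_nmi_similarity(cat, ids, shared_count=mode).values
                want = oracles.nmi_similarity_oracle(symptoms, ids, shared=mode)
                np.testing.assert_allclose(got, want, atol=1e-12)

    def test_clamped_to_unit_interval(self):
        # large shared counts can push the raw ratio above 1 under "sum"
        cat = SymptomCatalog({"d1": {"s1": 5}, "d2": {"s1": 5}, "d3": {"s2": 1}})
        dnf = disease_nmi_similarity(cat, ["d1", "d2", "d3"], shared_count="sum").values
        assert dnf.max() <= 1.0


class TestGip:
    def test_bandwidth_all_single_entry_profiles(self):
        profiles = np.eye(3)
        assert gip_bandwidth(profiles).omega == pytest.approx(1.0)

    def test_bandwidth_mixed_norms(self):
        profiles = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 1.0, ]])
        # squared norms 2 and 3 -> mean 2.5
        assert gip_bandwidth(profiles).omega == pytest.approx(1 / 2.5)

    def test_bandwidth_zero_profiles_error(self):
        with pytest.raises(ValueError, match="zero"):
            gip_bandwidth(np.zeros((2, 3)))

    def test_tiny_fixture_disease_kernel_hand_values(self, tiny):
        m, _, _ = tiny
        # squared norms 2,2,2,1 -> mean 7/4 -> omega 4/7
        dgs = gip_similarity(m, "disease").values
        assert dgs[0, 1] == pytest.approx(math.exp(-8 / 7), abs=1e-12)
        assert dgs[0, 2] == pytest.approx(math.exp(-16 / 7), abs=1e-12)
        assert dgs[0, 3] == pytest.approx(math.exp(-12 / 7), abs=1e-12)
        np.testing.assert_allclose(np.diag(dgs), 1.0)

    def test_identical_profiles_give_one(self, tiny):
        m, _, _ = tiny
        mgs = gip_similarity(m, "metabolite").values
        # m4 and m5 have identical association columns
        assert mgs[3, 4] == pytest.approx(1.0, abs=1e-12)

    def test_matches_elementwise_oracle(self, rng, tiny):
        m, _, _ = tiny
        for axis, profiles in (("disease", m.M), ("metabolite", m.M.T)):
            got = gip_similarity(m, axis).values
            np.testing.assert_allclose(got, oracles.gip_similarity_oracle(profiles), atol=1e-12)
        M = (rng.random((7, 9)) < 0.3).astype(float)
        M[0, 0] = 1.0  # ensure nonzero profiles exist
        rand_m = AssociationMatrix(M, [f"d{i}" for i in range(7)], [f"m{j}" for j in range(9)])
        got = gip_similarity(rand_m, "disease", omega_prime=2.0).values
        want = oracles.gip_similarity_oracle(M, omega_prime=2.0)
        np.testing.assert_allclose(got, want, atol=1e-12)


class TestIntegration:
    def test_primary_where_nonzero_else_fallback(self, rng):
        labels = [f"x{i}" for i in range(5)]
        p = rng.random((5, 5))
        p = (p + p.T) / 2
        p[p < 0.5] = 0.0
        np.fill_diagonal(p, 1.0)
        f = rng.random((5, 5))
        f = (f + f.T) / 2
        np.fill_diagonal(f, 1.0)
        primary = SimilarityMatrix(p, "disease", "nmi", labels)
        fallback = SimilarityMatrix(f, "disease", "gip", labels)
        got = integrate_similarity(primary, fallback).values
        np.testing.assert_allclose(got, oracles.integrate_oracle(p, f), atol=1e-12)

    def test_axis_mismatch_errors(self, tiny):
        m, mp, catalog = tiny
        dnf = disease_nmi_similarity(catalog, m.disease_ids)
        mhs = metabolite_hamming_similarity(mp)
        with pytest.raises(ValueError, match="different entities"):
            integrate_similarity(dnf, mhs)

    def test_integrated_fills_functional_zeros_with_gip(self, tiny):
        m, mp, catalog = tiny
        ids, ims = integrated_similarities(m, mp, catalog)
        dgs = gip_similarity(m, "disease").values
        mgs = gip_similarity(m, "metabolite").values
        # d1/d3 share no symptoms -> GIP fallback
        assert ids.values[0, 2] == pytest.approx(dgs[0, 2], abs=1e-12)
        # m2/m4 membership columns fully disagree (Hamming 0) -> GIP fallback
        assert ims.values[1, 3] == pytest.approx(mgs[1, 3], abs=1e-12)
        # d1/d2 have functional similarity -> kept
        assert ids.values[0, 1] == pytest.approx(0.4170246112844971, abs=1e-9)

    def test_integration_idempotent(self, tiny):
        m, mp, catalog = tiny
        ids, _ = integrated_similarities(m, mp, catalog)
        again = integrate_similarity(ids, gip_similarity(m, "disease"))
        np.testing.assert_allclose(again.values, ids.values, atol=1e-12)


class TestSimilarityInvariants:
    def test_all_matrices_symmetric_bounded(self, small_planted):
        m, mp, catalog, _ = small_planted
        ids, ims = integrated_similarities(m, mp, catalog)
        for s in (ids, ims):
            assert np.allclose(s.values, s.values.T)
            assert s.values.min() >= 0.0
            assert s.values.max() <= 1.0

    def test_container_rejects_asymmetric(self):
        with pytest.raises(ValueError, match="symmetric"):
            SimilarityMatrix(np.array([[1.0, 0.2], [0.3, 1.0]]), "disease", "x", ["a", "b"])

    def test_container_rejects_out_of_range(self):
        with pytest.raises(ValueError, match="lie in"):
            SimilarityMatrix(np.array([[1.0, 1.2], [1.2, 1.0]]), "disease", "x", ["a", "b"])

    def test_gip_permutation_equivariance(self, tiny):
        m, _, _ = tiny
        perm = [2, 0, 3, 1]
        m2 = AssociationMatrix(
            m.M[perm], [m.disease_ids[i] for i in perm], list(m.metabolite_ids)
        )
        s1 = gip_similarity(m, "disease").values
        s2 = gip_similarity(m2, "disease").values
        np.testing.assert_allclose(s2, s1[np.ix_(perm, perm)], atol=1e-12)
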