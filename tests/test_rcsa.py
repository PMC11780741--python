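"""Saupe-matrix fitting, Q-factors, Monte-Carlo errors, ensembles."""

import numpy as np
import pytest

from cstkit import (
    ConformerEnsemble,
    RCSADataset,
    RCSAObservation,
    SaupeMatrix,
    ShieldingTensor,
    UnderdeterminedError,
    alignment_tensor_cosine,
    back_calculate_rcsa,
    build_design_matrix,
    fit_saupe,
    fit_saupe_ensemble,
    monte_carlo_q,
    q_factor,
)
from cstkit.rcsa import SingularGeometryError
from cstkit.synthetic import (
    ObservationSpec,
    TensorGeneratorSpec,
    generate_rcsa_observations,
    generate_reference_tensors,
    perturb_tensors,
    random_saupe,
)
from cstkit.synthetic import PerturbationSpec

NU = 150.9e6


class TestSaupeMatrix:
    def test_param_round_trip(self, rng):
        p = rng.normal(size=5)
        s = SaupeMatrix.from_params(p)
        assert np.allclose(s.to_params(), p)
        assert np.trace(s.matrix) == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(s.matrix, s.matrix.T)

    def test_alignment_tensor_is_linear_rescaling(self, rng):
        s = random_saupe(1e-3, rng)
        from cstkit.rcsa import ALIGNMENT_SCALE

        assert np.allclose(s.alignment_tensor(), ALIGNMENT_SCALE * s.matrix)

    def test_nonsymmetric_rejected(self):
        with pytest.raises(ValueError):
            SaupeMatrix(np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]]))


class TestBackCalculate:
    def test_zero_saupe_gives_zero(self, random_tensor):
        assert back_calculate_rcsa(SaupeMatrix.zero(), random_tensor, NU) == 0.0

    def test_isotropic_tensor_gives_zero(self, rng):
        s = random_saupe(1e-3, rng)
        iso = ShieldingTensor("m", "C1", 42.0 * np.eye(3))
        assert back_calculate_rcsa(s, iso, NU) == pytest.approx(0.0, abs=1e-12)

    def test_matches_nine_term_loop(self, rng):
        s = random_saupe(1e-3, rng)
        t = ShieldingTensor("m", "C1", rng.normal(scale=50.0, size=(3, 3)))
        sym = 0.5 * (t.matrix + t.matrix.T)
        expected = 0.0
        for i in range(3):
            for j in range(3):
                expected += s.matrix[i, j] * sym[i, j]
        expected *= NU * 1e-6 * (2.0 / 3.0)
        assert back_calculate_rcsa(s, t, NU) == pytest.approx(expected)

    def test_antisymmetric_part_invisible(self, rng):
        s = random_saupe(1e-3, rng)
        m = rng.normal(scale=50.0, size=(3, 3))
        anti = np.array([[0, 3.0, -1.0], [-3.0, 0, 2.0], [1.0, -2.0, 0]])
        a = back_calculate_rcsa(s, ShieldingTensor("m", "C1", m), NU)
        b = back_calculate_rcsa(s, ShieldingTensor("m", "C1", m + anti), NU)
        assert a == pytest.approx(b)


class TestDesignMatrix:
    def test_reference_equal_tensor_gives_zero_row(self, reference_set):
        tmap = {t.nucleus_id: t for t in reference_set}
        tmap["Cdup"] = ShieldingTensor("synthetic", "Cdup", tmap["C1"].matrix)
        design = build_design_matrix(tmap, "C1", NU, ["Cdup", "C2"])
        assert np.allclose(design[0], 0.0)
        assert not np.allclose(design[1], 0.0)

    def test_consistency_with_back_calculation(self, reference_set, rng):
        tmap = {t.nucleus_id: t for t in reference_set}
        ids = [n for n in tmap if n != "C1"]
        design = build_design_matrix(tmap, "C1", NU, ids)
        for _ in range(5):
            s = random_saupe(10 ** rng.uniform(-4, -2), rng)
            direct = np.array(
                [
                    back_calculate_rcsa(s, tmap[n], NU)
                    - back_calculate_rcsa(s, tmap["C1"], NU)
                    for n in ids
                ]
            )
            assert np.allclose(design @ s.to_params(), direct, atol=1e-12)

    def test_missing_nucleus_raises(self, reference_set):
        with pytest.raises(KeyError):
            build_design_matrix(reference_set, "C1", NU, ["C99"])


class TestQFactor:
    def test_perfect_match_zero(self):
        assert q_factor([1.0, -2.0, 3.0], [1.0, -2.0, 3.0]) == 0.0

    def test_zero_prediction_gives_one(self):
        assert q_factor([1.0, 2.0, -3.0], [0.0, 0.0, 0.0]) == pytest.approx(1.0)

    def test_matches_loop_oracle(self, rng):
        obs = rng.normal(size=12)
        calc = rng.normal(size=12)
        num = sum((o - c) ** 2 for o, c in zip(obs, calc))
        den = sum(o**2 for o in obs)
        assert q_factor(obs, calc) == pytest.approx((num / den) ** 0.5)

    def test_all_zero_observed_rejected(self):
        with pytest.raises(ZeroDivisionError):
            q_factor([0.0, 0.0], [1.0, 2.0])


class TestFitSaupe:
    def test_exact_recovery_noiseless(self, noiseless_problem):
        tensors, dataset, truth = noiseless_problem
        fit = fit_saupe(dataset, tensors)
        rel = np.linalg.norm(fit.saupe.matrix - truth.matrix) / np.linalg.norm(
            truth.matrix
        )
        assert rel < 1e-8
        assert fit.q_factor == pytest.approx(0.0, abs=1e-10)
        assert fit.condition_number >= 1.0

    def test_duplicate_observations_leave_fit_unchanged(self, noiseless_problem):
        tensors, dataset, _ = noiseless_problem
        doubled = RCSADataset(
            dataset.observations + dataset.observations,
            dataset.reference_nucleus,
            dataset.larmor_frequency,
        )
        f1 = fit_saupe(dataset, tensors)
        f2 = fit_saupe(doubled, tensors)
        assert np.allclose(f1.saupe.matrix, f2.saupe.matrix, atol=1e-12)

    def test_underdetermined_rejected(self, reference_set):
        obs = tuple(RCSAObservation(f"C{i+2}", 1.0, 0.5) for i in range(4))
        ds = RCSADataset(obs, "C1", NU)
        with pytest.raises(UnderdeterminedError):
            fit_saupe(ds, reference_set)

    def test_rank_deficiency_names_null_direction(self):
        # all tensors axially symmetric about z and diagonal: the design
        # never senses S_xy / S_xz / S_yz
        tensors = {
            f"C{i}": ShieldingTensor("m", f"C{i}", np.diag([a, a, b]))
            for i, (a, b) in enumerate(
                [(10.0, 30.0), (20.0, 80.0), (5.0, 90.0), (15.0, 55.0), (25.0, 60.0), (8.0, 40.0)],
                start=1,
            )
        }
        obs = tuple(RCSAObservation(f"C{i}", 1.0, 0.5) for i in range(2, 7))
        with pytest.raises(SingularGeometryError) as exc:
            fit_saupe(RCSADataset(obs, "C1", NU), tensors)
        assert exc.value.null_direction is not None

    def test_q_grows_with_noise(self, reference_set):
        qs = []
        for sd in [0.1, 1.0, 4.0]:
            reps = []
            for r in range(20):
                ds, _ = generate_rcsa_observations(
                    reference_set, ObservationSpec(noise_sd=sd), seed=1000 * r + int(sd * 10)
                )
                reps.append(fit_saupe(ds, reference_set).q_factor)
            qs.append(np.mean(reps))
        assert qs[0] < qs[1] < qs[2]


class TestMonteCarlo:
    def test_zero_noise_degenerate_distribution(self, noiseless_problem):
        tensors, dataset, _ = noiseless_problem
        mc = monte_carlo_q(dataset, tensors, n_samples=50, noise_sd=0.0, seed=1)
        assert np.allclose(mc.samples, mc.samples[0])
        assert mc.q_sd == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_reproducible(self, noiseless_problem):
        tensors, dataset, _ = noiseless_problem
        a = monte_carlo_q(dataset, tensors, n_samples=100, seed=7)
        b = monte_carlo_q(dataset, tensors, n_samples=100, seed=7)
        assert np.array_equal(a.samples, b.samples)
        assert a.q_mean == b.q_mean

    def test_noise_cannot_improve_perfect_fit(self, noiseless_problem):
        tensors, dataset, _ = noiseless_problem
        q0 = fit_saupe(dataset, tensors).q_factor
        mc = monte_carlo_q(dataset, tensors, n_samples=1000, noise_sd=0.5, seed=3)
        assert mc.q_mean >= q0
        assert mc.n_failed == 0


class TestEnsemble:
    def test_single_conformer_reduces_to_fit_saupe(self, noiseless_problem):
        tensors, dataset, _ = noiseless_problem
        tmap = {t.nucleus_id: t for t in tensors}
        ens = ConformerEnsemble.single(tmap)
        f1 = fit_saupe(dataset, tmap)
        f2 = fit_saupe_ensemble(dataset, ens)
        assert np.allclose(f1.saupe.matrix, f2.saupe.matrix)
        assert f1.q_factor == pytest.approx(f2.q_factor)

    def test_two_identical_conformers_half_weights(self, noiseless_problem):
        tensors, dataset, _ = noiseless_problem
        tmap = {t.nucleus_id: t for t in tensors}
        ens = ConformerEnsemble((("a", tmap, 0.5), ("b", dict(tmap), 0.5)))
        f1 = fit_saupe(dataset, tmap)
        f2 = fit_saupe_ensemble(dataset, ens)
        assert np.allclose(f1.saupe.matrix, f2.saupe.matrix, atol=1e-12)

    def test_mixture_truth_beats_pure_conformers(self, reference_set, rng):
        # conformer B: same eigenvalues, frames rotated by large random angles
        rotated = perturb_tensors(
            reference_set, PerturbationSpec(0.0, 40.0), seed=0
        )
        map_a = {t.nucleus_id: t for t in reference_set}
        map_b = {t.nucleus_id: t for t in rotated}
        ens = ConformerEnsemble((("A", map_a, 0.6), ("B", map_b, 0.4)))
        s = random_saupe(1e-3, rng)
        design = sum(
            w
            * build_design_matrix(tm, "C1", NU, sorted(set(map_a) - {"C1"}))
            for _, tm, w in ens.conformers
        )
        ids = sorted(set(map_a) - {"C1"})
        values = design @ s.to_params()
        ds = RCSADataset(
            tuple(RCSAObservation(n, float(v), 0.5) for n, v in zip(ids, values)),
            "C1",
            NU,
        )
        q_mix = fit_saupe_ensemble(ds, ens).q_factor
        q_a = fit_saupe(ds, map_a).q_factor
        q_b = fit_saupe(ds, map_b).q_factor
        assert q_mix < q_a
        assert q_mix < q_b
        assert q_mix == pytest.approx(0.0, abs=1e-10)

    def test_mismatched_nucleus_sets_raise(self, reference_set):
        map_a = {t.nucleus_id: t for t in reference_set}
        map_b = dict(list(map_a.items())[:-1])
        with pytest.raises(KeyError):
            ConformerEnsemble((("a", map_a, 0.5), ("b", map_b, 0.5)))

    def test_bad_weights_rejected(self, reference_set):
        tmap = {t.nucleus_id: t for t in reference_set}
        with pytest.raises(ValueError):
            ConformerEnsemble((("a", tmap, 0.7), ("b", tmap, 0.7)))


class TestInvariances:
    def test_prefactor_invariance_of_q(self, reference_set):
        ds, _ = generate_rcsa_observations(
            reference_set, ObservationSpec(noise_sd=0.5), seed=21
        )
        q_ref = fit_saupe(ds, reference_set).q_factor
        for scale in [1e-3, 1.0, 17.0, 1e4]:
            q = fit_saupe(ds, reference_set, prefactor=(2.0 / 3.0) * scale).q_factor
            assert abs(q - q_ref) < 1e-12

    def test_isotropic_shift_blindness(self, reference_set):
        # quantize entries to multiples of 2^-10 so adding the exactly
        # representable shift c = 57 is itself exact: the invariance is then
        # bit-level, showing c*I cancels structurally in the differencing
        quantized = [
            ShieldingTensor(
                t.molecule_id, t.nucleus_id, np.round(t.matrix * 1024.0) / 1024.0, t.frame_note
            )
            for t in reference_set
        ]
        ds, _ = generate_rcsa_observations(
            quantized, ObservationSpec(noise_sd=0.5), seed=22
        )
        shifted = [
            ShieldingTensor(t.molecule_id, t.nucleus_id, t.matrix + 57.0 * np.eye(3), t.frame_note)
            for t in quantized
        ]
        reference_set = quantized
        ids = ds.nucleus_ids
        d0 = build_design_matrix(reference_set, "C1", NU, ids)
        d1 = build_design_matrix(shifted, "C1", NU, ids)
        assert np.array_equal(d0, d1)
        f0 = fit_saupe(ds, reference_set)
        f1 = fit_saupe(ds, shifted)
        assert np.array_equal(f0.saupe.matrix, f1.saupe.matrix)
        assert f0.q_factor == f1.q_factor

    def test_unit_consistency_hz_vs_ppb(self, noiseless_problem):
        """Q is unchanged when observations and nu are rescaled consistently."""
        tensors, dataset, _ = noiseless_problem
        noisy = dataset.with_values(dataset.values + 0.3)
        q_hz = fit_saupe(noisy, tensors).q_factor
        scaled = RCSADataset(
            tuple(
                RCSAObservation(o.nucleus_id, o.value * 1000.0, o.error * 1000.0)
                for o in noisy.observations
            ),
            noisy.reference_nucleus,
            noisy.larmor_frequency * 1000.0,
        )
        assert fit_saupe(scaled, tensors).q_factor == pytest.approx(q_hz, abs=1e-12)


class TestAlignmentCosine:
    def test_identity_and_negation(self, rng):
        s = random_saupe(1e-3, rng)
        assert alignment_tensor_cosine(s, s) == pytest.approx(1.0)
        neg = SaupeMatrix(-s.matrix)
        assert alignment_tensor_cosine(s, neg) == pytest.approx(-1.0)

    def test_orthogonal_pair(self):
        a = SaupeMatrix.from_params([1.0, 0.0, 0.0, 0.0, 0.0])
        b = SaupeMatrix.from_params([0.0, 0.0, 1.0, 0.0, 0.0])
        assert alignment_tensor_cosine(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_zero_tensor_rejected(self, rng):
        with pytest.raises(ZeroDivisionError):
            alignment_tensor_cosine(SaupeMatrix.zero(), random_saupe(1e-3, rng))
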