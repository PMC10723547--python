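"""Dose-ensemble generator: mean preservation, shared-error structure, collapsing."""

import numpy as np
import pytest

from sharederr import (
    CohortDesign,
    DoseEnsemble,
    ErrorModel,
    calibrated_group_doses,
    group_mean_doses,
    pairwise_correlation_closed_form,
    replication_rngs,
    shared_dose_correlation,
    simulate_dose_ensemble,
    simulate_surrogate_doses,
    simulate_true_doses,
)


class TestCohortDesign:
    def test_default_matches_study_design(self, design):
        assert design.n_groups == 5
        assert design.n_persons == 3471
        np.testing.assert_allclose(design.central_doses, [0.01, 0.1, 0.5, 1.5, 2.0])
        np.testing.assert_array_equal(design.persons, [2591, 334, 438, 102, 6])
        gi = design.group_index()
        assert gi.size == 3471 and gi[0] == 0 and gi[-1] == 4

    @pytest.mark.parametrize(
        "doses,persons",
        [([0.5, 0.1], [10, 10]), ([0.1, 0.5], [10, 0]), ([-0.1, 0.5], [10, 10])],
    )
    def test_invalid_designs_rejected(self, doses, persons):
        with pytest.raises(ValueError):
            CohortDesign(np.array(doses), np.array(persons))

    def test_file_round_trip(self, tmp_path, design):
        path = tmp_path / "design.tsv"
        design.to_file(path)
        back = CohortDesign.from_file(path)
        np.testing.assert_allclose(back.central_doses, design.central_doses)
        np.testing.assert_array_equal(back.persons, design.persons)


class TestErrorModel:
    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            ErrorModel(sigma_share_berkson=-0.1)


class TestTrueDoses:
    def test_zero_error_degenerates_to_central(self, design, rng):
        ens = simulate_true_doses(design, ErrorModel(), 7, rng)
        expected = design.person_central_doses()[:, None]
        np.testing.assert_array_equal(ens.true_doses, np.broadcast_to(expected, (3471, 7)))

    def test_mean_preservation(self, rng):
        # Lognormal identity E[exp(sigma*Z - sigma^2/2)] = 1: brute-force average.
        one_group = CohortDesign(np.array([0.01]), np.array([4]))
        err = ErrorModel(sigma_share_berkson=0.2, sigma_unshare_berkson=0.2)
        ens = simulate_true_doses(one_group, err, 100_000, rng)
        rep_means = ens.true_doses.mean(axis=0)
        se = rep_means.std(ddof=1) / np.sqrt(rep_means.size)
        assert abs(rep_means.mean() - 0.01) < 3 * se

    def test_shared_draw_common_within_realization(self, design, rng):
        # With no unshared error, all individuals deviate identically per realization.
        err = ErrorModel(sigma_share_berkson=0.5)
        ens = simulate_true_doses(design, err, 20, rng)
        ratio = ens.true_doses / design.person_central_doses()[:, None]
        np.testing.assert_allclose(
            ratio, np.broadcast_to(ratio[0, :], ratio.shape), rtol=1e-12
        )

    def test_shared_component_recoverable_as_mean_log_deviation(self, design, rng):
        err = ErrorModel(sigma_share_berkson=0.4, sigma_unshare_berkson=0.2)
        rng2 = np.random.default_rng(1)
        ens = simulate_true_doses(design, err, 50, rng, rng2)
        logdev = np.log(ens.true_doses / design.person_central_doses()[:, None])
        shared_est = logdev.mean(axis=0)  # averages out the unshared term
        resid = logdev - shared_est[None, :]
        # residual per-realization means are ~0 by construction; spread matches unshared sigma
        assert abs(resid.std() - 0.2) < 0.01

    def test_seeded_determinism(self, design):
        err = ErrorModel(sigma_share_class=0.5, sigma_unshare_class=0.2)
        v1 = simulate_surrogate_doses(design, err, np.random.default_rng(5))
        v2 = simulate_surrogate_doses(design, err, np.random.default_rng(5))
        np.testing.assert_array_equal(v1, v2)

    def test_classical_invariance_of_true_doses(self, design):
        # Same Berkson streams, different classical settings -> identical true doses.
        e1 = ErrorModel(0.2, 0.5, 0.2, 0.2)
        e2 = ErrorModel(0.2, 0.5, 0.5, 0.5)
        ens1 = simulate_dose_ensemble(design, e1, 10, replication_rngs(3, 0))
        ens2 = simulate_dose_ensemble(design, e2, 10, replication_rngs(3, 0))
        np.testing.assert_array_equal(ens1.true_doses, ens2.true_doses)
        assert not np.allclose(ens1.surrogate_doses, ens2.surrogate_doses)


class TestSurrogateDoses:
    def test_zero_error_equals_central(self, design, rng):
        surr = simulate_surrogate_doses(design, ErrorModel(), rng)
        np.testing.assert_array_equal(surr, design.person_central_doses())

    def test_mean_preservation_group3(self, rng):
        # Group-3-like central dose 0.5 Gy, classical GSDs 0.5/0.5.
        grp = CohortDesign(np.array([0.5]), np.array([50]))
        err = ErrorModel(sigma_share_class=0.5, sigma_unshare_class=0.5)
        means = [simulate_surrogate_doses(grp, err, rng).mean() for _ in range(600)]
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(means.size)
        assert abs(means.mean() - 0.5) < 3 * se


class TestGroupMeans:
    def test_simple_mean(self):
        out = group_mean_doses(np.array([0.4, 0.6]), np.array([0, 0]), 1)
        np.testing.assert_allclose(out, [0.5])

    def test_matches_explicit_loop(self, rng):
        gi = np.array([0, 0, 0, 1, 1, 2, 2, 2, 2, 2])
        d = rng.uniform(0.1, 2.0, size=(10, 3))
        out = group_mean_doses(d, gi, 3)
        for g in range(3):
            for r in range(3):
                assert out[g, r] == pytest.approx(d[gi == g, r].mean(), rel=1e-12)

    def test_unsorted_group_index(self, rng):
        gi = np.array([2, 0, 1, 0, 2, 1])
        d = rng.uniform(0.1, 1.0, size=6)
        out = group_mean_doses(d, gi, 3)
        for g in range(3):
            assert out[g] == pytest.approx(d[gi == g].mean(), rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_mean_doses(np.array([1.0, 2.0]), np.array([0, 0]), 2)


class TestCalibratedDoses:
    def test_zero_error_equals_central(self, design, rng):
        ens = simulate_true_doses(design, ErrorModel(), 5, rng)
        np.testing.assert_allclose(calibrated_group_doses(ens), design.central_doses)

    def test_single_realization_equals_group_means(self, design, rng):
        err = ErrorModel(sigma_share_berkson=0.3, sigma_unshare_berkson=0.3)
        ens = simulate_true_doses(design, err, 1, rng)
        np.testing.assert_allclose(
            calibrated_group_doses(ens),
            group_mean_doses(ens.true_doses[:, 0], ens.group_index, 5),
        )

    def test_converges_to_central(self, rng):
        grp = CohortDesign(np.array([0.01]), np.array([8]))
        err = ErrorModel(sigma_share_berkson=0.2, sigma_unshare_berkson=0.2)
        ens = simulate_true_doses(grp, err, 10_000, rng)
        assert calibrated_group_doses(ens)[0] == pytest.approx(0.01, rel=0.02)


class TestSharedDoseCorrelation:
    @pytest.mark.parametrize("s_sh,s_un", [(0.2, 0.2), (0.5, 0.2), (0.2, 0.5), (0.5, 0.5)])
    def test_matches_closed_form(self, design, s_sh, s_un):
        err = ErrorModel(sigma_share_berkson=s_sh, sigma_unshare_berkson=s_un)
        ens = simulate_true_doses(
            design, err, 3000, np.random.default_rng(11), np.random.default_rng(12)
        )
        got = shared_dose_correlation(ens)
        assert got == pytest.approx(pairwise_correlation_closed_form(s_sh, s_un), abs=0.03)

    def test_no_shared_error_uncorrelated(self, design):
        err = ErrorModel(sigma_unshare_berkson=0.5)
        ens = simulate_true_doses(design, err, 2000, np.random.default_rng(2))
        assert abs(shared_dose_correlation(ens)) < 0.03

    def test_degenerate_doses_flagged_nan(self, design, rng):
        ens = simulate_true_doses(design, ErrorModel(), 10, rng)
        assert np.isnan(shared_dose_correlation(ens))


def test_ensemble_export(tmp_path, tiny_design, rng):
    err = ErrorModel(sigma_unshare_berkson=0.2)
    ens = simulate_true_doses(tiny_design, err, 4, rng)
    path = tmp_path / "doses.tsv"
    ens.to_file(path)
    back = np.loadtxt(path, delimiter="\t")
    np.testing.assert_allclose(back, ens.true_doses)
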