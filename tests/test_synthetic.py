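import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from lesionnet import (
    CohortSpec,
    GroundTruthNetwork,
    generate_cohort,
    make_atlas,
    make_hub_recovery_network,
    simulate_ground_truth_network,
    simulate_lesion,
    simulate_motion,
    write_cohort,
)
from lesionnet.synthetic import (
    SyntheticSubject,
    partial_corr_from_precision,
    sample_timeseries,
    simulate_cognition,
)


class TestGroundTruthNetwork:
    def test_precision_is_positive_definite(self, atlas78):
        net = simulate_ground_truth_network(atlas78, n_hubs=8, hub_strength_factor=3,
                                            density=0.1, seed=7)
        assert np.linalg.eigvalsh(net.precision).min() > 0
        assert np.allclose(net.precision, net.precision.T)

    def test_planted_hubs_have_higher_ground_truth_strength(self):
        atlas = make_atlas(15, 4, 1)  # 40 regions
        net = simulate_ground_truth_network(atlas, n_hubs=4, hub_strength_factor=3,
                                            density=0.1, seed=3)
        strength = np.abs(net.partial_corr).sum(axis=1)
        hubs = sorted(net.planted_hubs)
        others = [i for i in range(40) if i not in net.planted_hubs]
        assert strength[hubs].mean() > strength[others].mean()

    def test_determinism_and_seed_sensitivity(self, atlas78):
        a = simulate_ground_truth_network(atlas78, 8, 3.0, 0.1, seed=11)
        b = simulate_ground_truth_network(atlas78, 8, 3.0, 0.1, seed=11)
        c = simulate_ground_truth_network(atlas78, 8, 3.0, 0.1, seed=12)
        assert np.array_equal(a.precision, b.precision)
        assert not np.array_equal((a.precision != 0), (c.precision != 0))

    def test_invalid_arguments_rejected(self, atlas78):
        with pytest.raises(ValueError):
            simulate_ground_truth_network(atlas78, n_hubs=78, hub_strength_factor=3,
                                          density=0.1, seed=0)
        with pytest.raises(ValueError):
            simulate_ground_truth_network(atlas78, 8, 0.5, 0.1, seed=0)
        with pytest.raises(ValueError):
            simulate_ground_truth_network(atlas78, 8, 3.0, 0.0, seed=0)

    def test_partial_corr_definition(self, hub_network):
        p = hub_network.precision
        d = np.sqrt(np.diag(p))
        expected = -p / np.outer(d, d)
        np.fill_diagonal(expected, 0)
        assert np.allclose(hub_network.partial_corr, expected)

    def test_hub_recovery_network_spd_and_hub_contrast(self, hub_network):
        assert np.linalg.eigvalsh(hub_network.precision).min() > 0
        strength = np.abs(hub_network.partial_corr).sum(axis=1)
        hubs = sorted(hub_network.planted_hubs)
        others = [i for i in range(78) if i not in hub_network.planted_hubs]
        assert strength[hubs].min() > strength[others].max()


class TestTimeseries:
    def test_equicorrelation_partial_correlations_recovered(self):
        # 3-node equicorrelation covariance with rho = 0.5: the closed-form
        # inverse gives all pairwise partial correlations equal to 1/3.
        sigma = np.full((3, 3), 0.5)
        np.fill_diagonal(sigma, 1.0)
        precision = np.linalg.inv(sigma)
        net = GroundTruthNetwork(
            precision=precision,
            partial_corr=partial_corr_from_precision(precision),
            planted_hubs=frozenset(),
            seed=0,
        )
        assert np.allclose(net.partial_corr[0, 1], 1 / 3)
        ts, _ = sample_timeseries(net, 50_000, ar_coefficient=0.0, seed=5)
        emp_prec = np.linalg.inv(np.cov(ts, rowvar=False))
        emp = partial_corr_from_precision(emp_prec)
        off = emp[np.triu_indices(3, 1)]
        assert np.all(np.abs(off - 1 / 3) < 0.02)

    def test_identity_precision_gives_independence(self):
        net = GroundTruthNetwork(np.eye(5), np.zeros((5, 5)), frozenset(), 0)
        ts, _ = sample_timeseries(net, 10_000, ar_coefficient=0.0, seed=1)
        emp = partial_corr_from_precision(np.linalg.inv(np.cov(ts, rowvar=False)))
        assert np.abs(emp[np.triu_indices(5, 1)]).max() < 0.05

    def test_ar_smoothing_preserves_partial_structure(self):
        sigma = np.full((3, 3), 0.5)
        np.fill_diagonal(sigma, 1.0)
        precision = np.linalg.inv(sigma)
        net = GroundTruthNetwork(precision, partial_corr_from_precision(precision),
                                 frozenset(), 0)
        ts, _ = sample_timeseries(net, 50_000, ar_coefficient=0.5, seed=2)
        emp = partial_corr_from_precision(np.linalg.inv(np.cov(ts, rowvar=False)))
        assert np.all(np.abs(emp[np.triu_indices(3, 1)] - 1 / 3) < 0.03)

    def test_determinism_bitwise(self, hub_network):
        a, _ = sample_timeseries(hub_network, 100, seed=9)
        b, _ = sample_timeseries(hub_network, 100, seed=9)
        assert np.array_equal(a, b)

    def test_short_series_warns_in_metadata(self, hub_network):
        _, meta = sample_timeseries(hub_network, 50, seed=0)
        assert any("rank-deficient" in w for w in meta["warnings"])

    def test_convergence_to_ground_truth(self):
        atlas = make_atlas(4, 1, 0)  # 10 regions
        net = simulate_ground_truth_network(atlas, 2, 3.0, 0.3, seed=4)
        ts, _ = sample_timeseries(net, 50_000, ar_coefficient=0.0, seed=4)
        emp = partial_corr_from_precision(np.linalg.inv(np.cov(ts, rowvar=False)))
        assert np.abs(emp - net.partial_corr).max() < 0.05


class TestMotion:
    def test_no_spikes_stays_below_limits(self):
        m = simulate_motion(200, spike_rate=0.0, seed=0)
        assert (m["fd"] < 0.5).all()
        assert (m[["trans_x", "trans_y", "trans_z"]].abs() < 1.5).all().all()

    def test_spike_count_matches_binomial_expectation(self):
        m = simulate_motion(450, spike_rate=0.1, seed=1)
        n_spikes = int((m["fd"] > 0.5).sum())
        # Binomial(450, 0.1): mean 45, sd ~6.4; allow 4 sd.
        assert abs(n_spikes - 45) < 26

    def test_determinism(self):
        a = simulate_motion(100, 0.05, seed=3)
        b = simulate_motion(100, 0.05, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestLesion:
    def test_zero_affected_gives_zero_vector(self, atlas78):
        assert simulate_lesion(atlas78, 0, [], seed=0).sum() == 0

    def test_fraction_threshold_count(self, atlas78):
        lesion = simulate_lesion(atlas78, 3, [0.9, 0.6, 0.4], seed=2)
        assert (lesion > 0.5).sum() == 2
        assert (lesion > 0).sum() == 3

    def test_lesion_confined_to_one_hemisphere(self, atlas78):
        lesion = simulate_lesion(atlas78, 10, [0.8] * 10, seed=5)
        left = lesion[atlas78.ids_in_hemisphere("left")]
        right = lesion[atlas78.ids_in_hemisphere("right")]
        assert (left.sum() == 0) != (right.sum() == 0)
        # contiguous by index within the hemisphere
        hit = np.flatnonzero(lesion > 0)
        assert hit.max() - hit.min() == 9

    def test_mismatched_fraction_length_rejected(self, atlas78):
        with pytest.raises(ValueError):
            simulate_lesion(atlas78, 3, [0.9, 0.6], seed=0)


class TestCognition:
    def _subjects(self, n, rng):
        return [
            SyntheticSubject(
                subject_id=f"s{i}",
                group="control",
                age=float(rng.uniform(20, 65)),
                sex="F",
                education=int(rng.integers(1, 8)),
                seed=i,
            )
            for i in range(n)
        ]

    def test_noise_free_scores_are_exact_linear_functions(self, rng):
        subjects = self._subjects(20, rng)
        metrics = pd.DataFrame({"global_clustering": np.zeros(20)},
                               index=[s.subject_id for s in subjects])
        scores, truth = simulate_cognition(subjects, metrics, {}, age_slope=-0.5,
                                           education_slope=2.0, noise_sd=0.0, seed=0)
        expected = np.array([50.0 - 0.5 * s.age + 2.0 * s.education for s in subjects])
        assert np.allclose(scores["verbal_fluency"].to_numpy(), expected)
        # timed tests are stored sign-flipped (lower raw = better)
        assert np.allclose(scores["trails_b"].to_numpy(), -expected)
        assert truth["age_slope"] == -0.5

    def test_metric_linked_score_correlates_with_metric(self, rng):
        subjects = self._subjects(100, rng)
        metric = rng.normal(0.5, 0.1, 100)
        metrics = pd.DataFrame({"global_clustering": metric},
                               index=[s.subject_id for s in subjects])
        link = {"matrix_reasoning": {"global_clustering": 40.0}}
        scores, _ = simulate_cognition(subjects, metrics, link, age_slope=0.0,
                                       education_slope=0.0, noise_sd=1.0, seed=1)
        r = np.corrcoef(scores["matrix_reasoning"], metric)[0, 1]
        assert r > 0.9

    def test_unknown_metric_rejected(self, rng):
        subjects = self._subjects(12, rng)
        metrics = pd.DataFrame({"global_clustering": np.zeros(12)},
                               index=[s.subject_id for s in subjects])
        with pytest.raises(KeyError):
            simulate_cognition(subjects, metrics, {"stroop": {"nope": 1.0}})

    def test_determinism(self, rng):
        subjects = self._subjects(10, rng)
        metrics = pd.DataFrame({"global_clustering": np.zeros(10)},
                               index=[s.subject_id for s in subjects])
        a, _ = simulate_cognition(subjects, metrics, {}, seed=5)
        b, _ = simulate_cognition(subjects, metrics, {}, seed=5)
        pd.testing.assert_frame_equal(a, b)


SMALL_SPEC = CohortSpec(
    n_patients=3,
    n_controls=3,
    n_volumes=40,
    n_hubs=2,
    atlas_args=(5, 2, 1),  # 16 regions
    lesion_n_affected=2,
)


class TestCohort:
    def test_cohort_end_to_end_reproducible(self, tmp_path):
        a = generate_cohort(SMALL_SPEC, master_seed=99)
        b = generate_cohort(SMALL_SPEC, master_seed=99)
        write_cohort(a, tmp_path / "a")
        write_cohort(b, tmp_path / "b")
        files_a = sorted(p.name for p in (tmp_path / "a").iterdir())
        files_b = sorted(p.name for p in (tmp_path / "b").iterdir())
        assert files_a == files_b
        for name in files_a:
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                               shallow=False), name

    def test_cohort_structure(self):
        cohort = generate_cohort(SMALL_SPEC, master_seed=1)
        assert len(cohort.subjects) == 6
        controls = [s for s in cohort.subjects if s.group == "control"]
        patients = [s for s in cohort.subjects if s.group == "patient"]
        assert len(controls) == len(patients) == 3
        for s in controls:
            assert s.lesion.max() == 0
        for s in cohort.subjects:
            assert s.timeseries.shape == (40, 16)
            assert 1 <= s.education <= 7
            assert set(s.raw_cognition) == {
                "verbal_fluency", "verbal_learning", "pegboard", "trails_a",
                "digit_span", "trails_b", "stroop", "digit_symbol",
                "matrix_reasoning",
            }

    def test_controls_matched_on_sex_and_education(self):
        cohort = generate_cohort(SMALL_SPEC, master_seed=2)
        patients = [s for s in cohort.subjects if s.group == "patient"]
        controls = [s for s in cohort.subjects if s.group == "control"]
        for p, c in zip(patients, controls):
            assert p.sex == c.sex
            assert p.education == c.education
            assert abs(p.age - c.age) <= 3.0
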