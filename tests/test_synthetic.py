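import numpy as np
import pytest
from scipy.stats import spearmanr

from plfcs.atlas import extract_roi_timeseries, load_atlas, reference_mean, extract_roi_means
from plfcs.suvr import compute_suvr
from plfcs.synthetic import (
    CohortSpec,
    attenuate_network,
    default_geometry,
    generate_ground_truth_network,
    render_volumes,
    simulate_cohort,
    simulate_subject_timeseries,
    write_cohort_tables,
)


class TestGroundTruthNetwork:
    def test_two_node_symmetry(self):
        net = generate_ground_truth_network(2, hub_exponent=3.0, seed=0)
        r12 = abs(net.correlation[0, 1])
        assert net.hubness == pytest.approx([r12, r12])

    def test_hub_exponent_spreads_strengths(self):
        h0 = generate_ground_truth_network(40, hub_exponent=0.0, seed=5).hubness
        h2 = generate_ground_truth_network(40, hub_exponent=2.0, seed=5).hubness
        cov0 = h0.std() / h0.mean()
        cov2 = h2.std() / h2.mean()
        assert cov0 < cov2

    def test_deterministic_given_seed(self):
        a = generate_ground_truth_network(15, 2.0, seed=9)
        b = generate_ground_truth_network(15, 2.0, seed=9)
        assert np.array_equal(a.covariance, b.covariance)

    def test_rejects_degenerate_size(self):
        with pytest.raises(ValueError, match="at least 2"):
            generate_ground_truth_network(1, 2.0, seed=0)

    def test_attenuation_preserves_psd_and_diagonal(self):
        net = generate_ground_truth_network(25, 2.0, seed=1)
        cov = attenuate_network(net, 0.8)
        np.testing.assert_allclose(np.diagonal(cov), np.diagonal(net.covariance))
        w = np.linalg.eigvalsh(cov)
        assert w.min() >= -1e-10 * w.max()


class TestSubjectTimeseries:
    def test_deterministic_given_seed(self):
        net = generate_ground_truth_network(8, 1.0, seed=2)
        a = simulate_subject_timeseries(net, 50, seed=3)
        b = simulate_subject_timeseries(net, 50, seed=3)
        assert np.array_equal(a.data, b.data)

    def test_diagonal_covariance_gives_independent_columns(self):
        n_t = 4000
        ts = simulate_subject_timeseries(np.eye(5), n_t, seed=4)
        r = np.corrcoef(ts.data, rowvar=False)
        off = r[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 3 / np.sqrt(n_t)

    def test_long_series_recover_ground_truth_correlation(self):
        net = generate_ground_truth_network(6, 2.0, seed=5)
        ts = simulate_subject_timeseries(net, 10000, noise_sd=0.0, seed=5)
        r = np.corrcoef(ts.data, rowvar=False)
        np.fill_diagonal(r, 0.0)
        np.testing.assert_allclose(r, net.correlation, atol=0.05)

    def test_non_psd_covariance_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError, match="positive semi-definite"):
            simulate_subject_timeseries(bad, 10, seed=0)


class TestSimulateCohort:
    def test_no_attenuation_means_no_designed_loss(self):
        spec = CohortSpec(
            n_regions=12,
            n_subjects={"NC": 2, "MCI": 2, "AD": 2},
            n_timepoints=30,
            loss_coefficient={"NC": 0.0, "MCI": 0.0, "AD": 0.0},
            seed=6,
        )
        cohort = simulate_cohort(spec)
        for g in ("NC", "MCI", "AD"):
            np.testing.assert_allclose(cohort.designed_loss(g), 0.0, atol=1e-14)
        for s in cohort.subjects:
            assert np.all(s.designed_loss == 0)

    def test_designed_strength_ordering_follows_loss_coefficients(self, tiny_cohort):
        d = tiny_cohort.designed_strengths
        assert d["NC"].mean() > d["MCI"].mean() > d["AD"].mean()

    def test_uniform_positive_coupling_rank_correlates_loss_and_tau(self):
        spec = CohortSpec(
            n_regions=15,
            n_subjects={"NC": 2, "MCI": 2, "AD": 2},
            n_timepoints=30,
            tau_coupling=np.ones(15),
            seed=7,
        )
        cohort = simulate_cohort(spec)
        rho, _ = spearmanr(cohort.designed_loss("AD"), cohort.designed_tau_mean("AD"))
        assert rho == pytest.approx(1.0)

    def test_clinical_scores_track_disease_burden(self, tiny_cohort):
        m = tiny_cohort.manifest.groupby("group")[["mmse", "cdr_sb"]].mean()
        assert m.loc["NC", "mmse"] > m.loc["MCI", "mmse"] > m.loc["AD", "mmse"]
        assert m.loc["NC", "cdr_sb"] < m.loc["MCI", "cdr_sb"] < m.loc["AD", "cdr_sb"]
        assert tiny_cohort.manifest["mmse"].between(0, 30).all()
        assert tiny_cohort.manifest["cdr_sb"].between(0, 18).all()

    def test_deterministic_given_spec(self):
        spec = dict(
            n_regions=10,
            n_subjects={"NC": 2, "MCI": 2, "AD": 2},
            n_timepoints=20,
            seed=8,
        )
        a = simulate_cohort(CohortSpec(**spec))
        b = simulate_cohort(CohortSpec(**spec))
        for sa, sb in zip(a.subjects, b.subjects):
            assert np.array_equal(sa.timeseries.data, sb.timeseries.data)
            assert np.array_equal(sa.suvr.values, sb.suvr.values)
            assert sa.mmse == sb.mmse

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match=">= 2 subjects"):
            CohortSpec(n_subjects={"NC": 1, "MCI": 2, "AD": 2})
        with pytest.raises(ValueError, match=">= 0"):
            CohortSpec(loss_coefficient={"NC": 0, "MCI": -0.1, "AD": 0.4})
        with pytest.raises(ValueError, match="\\[-1, 1\\]"):
            CohortSpec(n_regions=3, tau_coupling=np.array([0.5, 2.0, 1.0]))


@pytest.fixture(scope="module")
def rendered(tmp_path_factory):
    spec = CohortSpec(
        n_regions=4,
        n_subjects={"NC": 2, "MCI": 2, "AD": 2},
        n_timepoints=12,
        seed=9,
    )
    cohort = simulate_cohort(spec)
    out = tmp_path_factory.mktemp("vols")
    paths = render_volumes(cohort, out, voxel_noise_sd=0.0)
    return cohort, paths


class TestRenderVolumes:
    def test_written_files_reread_with_correct_shapes(self, rendered):
        cohort, paths = rendered
        atlas = load_atlas(paths["atlas"], paths["region_table"])
        assert atlas.n_regions == 4
        assert np.array_equal(atlas.labels, cohort.region_labels)

    def test_functional_round_trip_exact(self, rendered):
        cohort, paths = rendered
        atlas = load_atlas(paths["atlas"], paths["region_table"])
        s = cohort.subjects[0]
        ts = extract_roi_timeseries(paths["func"][s.subject_id], atlas, s.subject_id)
        np.testing.assert_allclose(ts.data, s.timeseries.data, atol=1e-6)

    def test_pet_round_trip_recovers_designed_suvr(self, rendered):
        cohort, paths = rendered
        atlas = load_atlas(paths["atlas"], paths["region_table"])
        s = cohort.subjects[-1]
        means = extract_roi_means(paths["pet"][s.subject_id], atlas)
        ref = reference_mean(paths["pet"][s.subject_id], paths["reference_mask"])
        sv = compute_suvr(means, ref)
        np.testing.assert_allclose(sv.values, s.suvr.values, atol=1e-6)

    def test_region_without_voxels_rejected(self, rendered, tmp_path):
        cohort, _ = rendered
        geom = default_geometry(3)  # one region short
        with pytest.raises(ValueError, match="zero voxels"):
            render_volumes(cohort, tmp_path, geometry=geom)


def test_write_cohort_tables_round_trip(tmp_path, tiny_cohort):
    paths = write_cohort_tables(tiny_cohort, tmp_path)
    import pandas as pd

    suvr = pd.read_csv(paths["suvr"], sep="\t", index_col="subject_id")
    assert suvr.shape == (15, 20)
    first = tiny_cohort.subjects[0]
    np.testing.assert_allclose(
        suvr.loc[first.subject_id].to_numpy(), first.suvr.values, atol=1e-12
    )
    man = pd.read_csv(paths["manifest"], sep="\t")
    assert set(man["group"]) == {"NC", "MCI", "AD"}
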