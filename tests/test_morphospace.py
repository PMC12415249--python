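import numpy as np
import pytest
from sklearn.metrics import silhouette_score

from denscan.data import Group, MeasurementClass, MeasurementMatrix, ReferenceGroup
from denscan.morphospace import (
    filter_missingness,
    fit_reference_pca,
    impute_iterative_pca,
    project_test_subjects,
)
from denscan.simulate import plant_denisovan_like

from conftest import reference_ids


def make_matrix(values, classes=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return MeasurementMatrix(
        [f"S{i}" for i in range(n)], [f"M{j}" for j in range(p)], values, classes
    )


class TestFilterMissingness:
    def test_measurement_over_threshold_dropped(self):
        vals = np.ones((100, 2))
        vals[:21, 0] = np.nan  # 21% missing
        out = filter_missingness(make_matrix(vals))
        assert out.measurement_ids == ["M1"]

    def test_specimen_at_boundary_retained(self):
        vals = np.ones((2, 20))
        vals[0, :3] = np.nan  # exactly 15% missing: "more than" excludes
        out = filter_missingness(make_matrix(vals))
        assert "S0" in out.specimen_ids

    def test_fully_observed_unchanged_either_order(self):
        m = make_matrix(np.arange(12.0).reshape(3, 4))
        for order in ("MEASUREMENTS_FIRST", "SPECIMENS_FIRST"):
            out = filter_missingness(m, order=order)
            assert out == m

    def test_order_changes_outcome(self):
        # S0 is only over the specimen cap while M9 is still present, and M9
        # is over the measurement cap with or without S0 — so the orders
        # disagree about keeping S0
        vals = np.ones((10, 10))
        vals[0, 9] = np.nan
        vals[0, 8] = np.nan  # S0: 20% missing
        vals[1, 9] = np.nan
        vals[2, 9] = np.nan  # M9: 30% missing
        a = filter_missingness(make_matrix(vals), order="MEASUREMENTS_FIRST")
        b = filter_missingness(make_matrix(vals), order="SPECIMENS_FIRST")
        assert "S0" in a.specimen_ids and "M9" not in a.measurement_ids
        assert "S0" not in b.specimen_ids and "M9" not in b.measurement_ids

    def test_nonlinear_only_variant_with_permissive_cap(self, study):
        matrix, _, _ = study
        out = filter_missingness(
            matrix,
            measurement_max_missing=0.30,
            measurement_class=MeasurementClass.NONLINEAR,
        )
        assert all(
            matrix.measurement_class(m) is MeasurementClass.NONLINEAR
            for m in out.measurement_ids
        )

    def test_empty_result_is_an_error(self):
        vals = np.full((4, 3), np.nan)
        vals[0, 0] = 1.0
        with pytest.raises(ValueError):
            filter_missingness(make_matrix(vals))


class TestImputation:
    def test_fully_observed_is_identity(self):
        m = make_matrix(np.arange(20.0).reshape(4, 5))
        out = impute_iterative_pca(m)
        assert np.array_equal(out.values, m.values)

    def test_rank_one_cell_recovered(self):
        rng = np.random.default_rng(3)
        u = rng.uniform(1, 2, size=8)
        v = rng.uniform(1, 3, size=6)
        X = np.outer(u, v)
        truth = X[2, 3]
        X[2, 3] = np.nan
        out = impute_iterative_pca(make_matrix(X), n_components=1, scale=False)
        assert abs(out.values[2, 3] - truth) / abs(truth) < 1e-6

    def test_observed_cells_never_altered(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 7))
        miss = rng.random((12, 7)) < 0.2
        X[miss] = np.nan
        m = make_matrix(X)
        out = impute_iterative_pca(m)
        obs = ~np.isnan(X)
        assert np.array_equal(out.values[obs], X[obs])
        assert not np.isnan(out.values).any()

    def test_all_missing_row_is_precondition_error(self):
        X = np.ones((3, 3))
        X[1, :] = np.nan
        with pytest.raises(ValueError, match="S1"):
            impute_iterative_pca(make_matrix(X))


class TestReferencePCA:
    def test_collinear_references_put_all_variance_on_pc1(self):
        t = np.linspace(0, 1, 10)
        X = np.column_stack([t, 2 * t, -t]) + 5.0
        m = make_matrix(X)
        model = fit_reference_pca(m, m.specimen_ids, scale=False)
        assert model.explained_variance_ratio[0] > 0.999

    def test_duplicated_reference_list_gives_identical_model(self, complete_study):
        matrix, records, _ = complete_study
        refs = [r.specimen_id for r in records if r.group is Group.AMH]
        a = fit_reference_pca(matrix, refs)
        b = fit_reference_pca(matrix, list(refs))
        assert np.allclose(a.loadings, b.loadings)
        assert np.allclose(a.mean, b.mean)

    def test_too_few_reference_rows_rejected(self, complete_study):
        matrix, records, _ = complete_study
        with pytest.raises(ValueError):
            fit_reference_pca(matrix, [matrix.specimen_ids[0]], n_components=2)

    def test_reference_groups_separate_in_pc_space(self, complete_study):
        matrix, records, _ = complete_study
        group_of = {r.specimen_id: r.group for r in records}
        ref_ids = [
            s
            for s in matrix.specimen_ids
            if group_of[s] in (Group.AMH, Group.NEANDERTHAL, Group.H_ERECTUS)
        ]
        model = fit_reference_pca(matrix, ref_ids)
        coords = project_test_subjects(model, matrix, ref_ids)
        labels = [group_of[s].value for s in ref_ids]
        assert silhouette_score(coords, labels) > 0


class TestProjection:
    def test_reference_specimen_reproduces_fitted_score(self, complete_study):
        matrix, records, _ = complete_study
        refs = [r.specimen_id for r in records if r.group is not Group.TEST]
        model = fit_reference_pca(matrix, refs)
        one = refs[3]
        via_project = project_test_subjects(model, matrix, [one])[0]
        direct = model.transform(matrix.row(one)[None, :])[0]
        assert np.allclose(via_project, direct)

    def test_reference_centroid_maps_to_origin(self, complete_study):
        matrix, records, _ = complete_study
        refs = [r.specimen_id for r in records if r.group is not Group.TEST]
        model = fit_reference_pca(matrix, refs)
        centroid = np.mean([matrix.row(s) for s in refs], axis=0)
        assert np.allclose(model.transform(centroid[None, :]), 0.0, atol=1e-9)

    def test_projection_linearity(self, complete_study):
        matrix, records, _ = complete_study
        refs = [r.specimen_id for r in records if r.group is not Group.TEST]
        model = fit_reference_pca(matrix, refs)
        x, y = matrix.row(refs[0]), matrix.row(refs[1])
        a = 0.3
        lhs = model.transform((a * x + (1 - a) * y)[None, :])
        rhs = a * model.transform(x[None, :]) + (1 - a) * model.transform(y[None, :])
        assert np.allclose(lhs, rhs)

    def test_measurement_mismatch_lists_missing(self, complete_study):
        matrix, records, _ = complete_study
        refs = [r.specimen_id for r in records if r.group is not Group.TEST]
        model = fit_reference_pca(matrix, refs)
        sub = matrix.subset(measurement_ids=matrix.measurement_ids[:-1])
        with pytest.raises(ValueError, match=matrix.measurement_ids[-1]):
            project_test_subjects(model, sub, refs[:2])

    def test_planted_subjects_cluster_together(self, complete_study):
        matrix, records, profile = complete_study
        refs_by_group = reference_ids(records)
        m = matrix
        for i in range(3):
            m = plant_denisovan_like(
                m,
                profile,
                2.5,
                refs_by_group[ReferenceGroup.AMH],
                rng=np.random.default_rng(100 + i),
                specimen_id=f"PL{i}",
                reference_group_ids=refs_by_group,
            )
        group_of = {r.specimen_id: r.group for r in records}
        ref_ids = [
            s for s in matrix.specimen_ids if group_of.get(s) is not Group.TEST
        ]
        model = fit_reference_pca(m, ref_ids)
        planted_ids = [f"PL{i}" for i in range(3)]
        planted = project_test_subjects(model, m, planted_ids)
        centroids = []
        for g in (Group.AMH, Group.NEANDERTHAL, Group.H_ERECTUS):
            ids = [s for s in ref_ids if group_of[s] is g]
            centroids.append(project_test_subjects(model, m, ids).mean(axis=0))
        pairwise = [
            np.linalg.norm(planted[i] - planted[j])
            for i in range(3)
            for j in range(i + 1, 3)
        ]
        to_centroids = [
            np.linalg.norm(planted[i] - c) for i in range(3) for c in centroids
        ]
        assert np.mean(pairwise) < np.mean(to_centroids)
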