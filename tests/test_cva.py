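import numpy as np
import pytest

import scalemorph as sm
from scalemorph.clustering import Partition
from scalemorph.cva import mahalanobis_distances
from scalemorph.errors import SchemaError, SingularityError

from conftest import make_table
from oracles import cva_eigenvalues_oracle, mahalanobis_assign_oracle

VARS2 = ("L5", "L6")


def three_group_data(rng, n_per=8, p=2):
    centers = rng.uniform(5, 15, size=(3, p))
    X = np.vstack([rng.normal(c, 1.0, size=(n_per, p)) for c in centers])
    labels = np.repeat([0, 1, 2], n_per)
    return X, labels


def as_partition(labels, table):
    return Partition(
        labels=np.asarray(labels), k=len(np.unique(labels)),
        scale_ids=tuple(table.scale_ids),
    )


def test_two_collinear_groups_single_axis():
    X = np.array([[0.0], [0.0], [0.0], [10.0], [10.0], [10.1]])
    table = make_table(X, ("L6",))
    model = sm.fit_cva(table, np.array([0, 0, 0, 1, 1, 1]), ("L6",))
    assert len(model.eigenvalues) == 1
    assert model.eigenvalues[0] > 0


def test_eigenvalues_match_dense_algebra_oracle(rng):
    for _ in range(20):
        X, labels = three_group_data(rng, p=4)
        table = make_table(X, ("L1", "L3", "L5", "L6"))
        model = sm.fit_cva(table, labels, ("L1", "L3", "L5", "L6"))
        want = cva_eigenvalues_oracle(X, labels)
        assert len(model.eigenvalues) == len(want) <= min(2, 4)
        np.testing.assert_allclose(model.eigenvalues, want, rtol=1e-8, atol=1e-10)


def test_axes_have_unit_pooled_within_variance(rng):
    X, labels = three_group_data(rng, n_per=20, p=3)
    table = make_table(X, ("L1", "L5", "L6"))
    model = sm.fit_cva(table, labels, ("L1", "L5", "L6"))
    A = model.canonical_coefficients
    np.testing.assert_allclose(
        A.T @ model.pooled_within_cov @ A, np.eye(A.shape[1]), atol=1e-8
    )


def test_assignments_match_mahalanobis_oracle(rng):
    for _ in range(10):
        X, labels = three_group_data(rng, p=3)
        table = make_table(X, ("L1", "L5", "L6"))
        model = sm.fit_cva(table, labels, ("L1", "L5", "L6"))
        result = sm.classify(model, table, true_labels=labels)
        want = mahalanobis_assign_oracle(
            X, model.group_means, model.pooled_within_cov, model.groups
        )
        np.testing.assert_array_equal(result.predicted, want)


def test_scale_at_group_mean_assigned_there(rng):
    X, labels = three_group_data(rng, p=2, n_per=10)
    table = make_table(X, VARS2)
    model = sm.fit_cva(table, labels, VARS2)
    probe = make_table(model.group_means, VARS2, ids=["m0", "m1", "m2"])
    result = sm.classify(model, probe)
    np.testing.assert_array_equal(result.predicted, [0, 1, 2])


def test_equidistant_tie_goes_to_lowest_group_id():
    # groups symmetric about x=10; probe exactly between the means
    X = np.array([[8.0, 10.0], [9.0, 11.0], [9.0, 9.0],
                  [12.0, 10.0], [11.0, 11.0], [11.0, 9.0]])
    labels = np.array([0, 0, 0, 1, 1, 1])
    table = make_table(X, VARS2)
    model = sm.fit_cva(table, labels, VARS2)
    probe = make_table([[10.0, 10.0]], VARS2, ids=["probe"])
    d2 = mahalanobis_distances(model, probe.matrix(VARS2))
    assert d2[0, 0] == pytest.approx(d2[0, 1])
    assert sm.classify(model, probe).predicted[0] == 0


def test_label_permutation_within_groups_is_identity(rng):
    X, labels = three_group_data(rng)
    table = make_table(X, VARS2)
    m1 = sm.fit_cva(table, labels, VARS2)
    # permuting rows within the same labelling changes nothing
    perm = rng.permutation(len(labels))
    table_p = make_table(X[perm], VARS2, ids=[f"s{i:03d}" for i in range(len(labels))])
    m2 = sm.fit_cva(table_p, labels[perm], VARS2)
    np.testing.assert_allclose(m1.eigenvalues, m2.eigenvalues, rtol=1e-9)
    np.testing.assert_allclose(m1.group_means, m2.group_means, atol=1e-12)


def test_classification_invariant_under_affine_transforms(rng):
    X, labels = three_group_data(rng, p=3, n_per=12)
    table = make_table(X, ("L1", "L5", "L6"))
    model = sm.fit_cva(table, labels, ("L1", "L5", "L6"))
    base = sm.classify(model, table).predicted
    for _ in range(5):
        # positive transforms keep the lengths non-negative
        A = rng.uniform(0.2, 1.5, size=(3, 3))
        while abs(np.linalg.det(A)) < 0.1:
            A = rng.uniform(0.2, 1.5, size=(3, 3))
        b = rng.uniform(0, 5, size=3)
        Xt = X @ A.T + b
        table_t = make_table(Xt, ("L1", "L5", "L6"))
        model_t = sm.fit_cva(table_t, labels, ("L1", "L5", "L6"))
        np.testing.assert_array_equal(sm.classify(model_t, table_t).predicted, base)


def test_eigenvalue_count_bound(rng):
    for g, p in [(2, 5), (4, 2), (8, 5)]:
        centers = rng.uniform(5, 20, size=(g, p))
        X = np.vstack([rng.normal(c, 1.0, size=(6, p)) for c in centers])
        labels = np.repeat(np.arange(g), 6)
        table = make_table(X, tuple(f"L{i+1}" for i in range(p)))
        model = sm.fit_cva(table, labels, table.variable_names)
        assert len(model.eigenvalues) <= min(g - 1, p)


def test_singular_within_scatter_advises_ridge():
    # within-group variation confined to one direction -> W is rank deficient
    X = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0],
                  [5.0, 9.0], [6.0, 10.0], [7.0, 11.0]])
    labels = np.array([0, 0, 0, 1, 1, 1])
    table = make_table(X, VARS2)
    with pytest.raises(SingularityError, match="ridge"):
        sm.fit_cva(table, labels, VARS2)
    model = sm.fit_cva(table, labels, VARS2, ridge=1e-6)
    assert np.all(np.isfinite(model.eigenvalues))


def test_single_member_group_contributes_mean_only(rng):
    X, labels = three_group_data(rng, n_per=10, p=2)
    X = np.vstack([X, [50.0, 50.0]])
    labels = np.append(labels, 3)
    table = make_table(X, VARS2)
    model = sm.fit_cva(table, labels, VARS2)
    assert model.group_sizes[-1] == 1
    result = sm.classify(model, table, true_labels=labels)
    assert result.predicted[-1] == 3  # far outlier stays in its own group


def test_missing_variable_raises_schema_error(rng):
    X, labels = three_group_data(rng)
    model = sm.fit_cva(make_table(X, VARS2), labels, VARS2)
    with pytest.raises(SchemaError):
        sm.classify(model, make_table(X[:, :1], ("L5",)))


def test_refine_fixpoint_keeps_labels(rng):
    centers = np.array([[5.0, 5.0], [25.0, 5.0], [5.0, 25.0]])
    X = np.vstack([rng.normal(c, 0.5, size=(15, 2)) for c in centers])
    labels = np.repeat([0, 1, 2], 15)
    table = make_table(X, VARS2)
    part = as_partition(labels, table)
    refined, history = sm.refine_labels(table, part, VARS2, max_rounds=3)
    assert history[0].accuracy == pytest.approx(1.0)
    assert len(history) == 1  # fixpoint: zero moves, single round scored
    # canonical renumbering preserves the partition structure
    from scalemorph.metrics import adjusted_rand_index
    assert adjusted_rand_index(refined.labels, part.labels) == pytest.approx(1.0)


def test_refined_labels_equal_previous_predictions(default_sample):
    s = default_sample
    table = s.table
    dendro = sm.agglomerate(table, ("L1", "L3", "L4", "L5", "L6"))
    part = sm.cut_k(dendro, 8)
    refined, history = sm.refine_labels(table, part, ("L1", "L3", "L4", "L5", "L6"))
    from scalemorph.metrics import adjusted_rand_index
    assert adjusted_rand_index(refined.labels, history[0].predicted) == pytest.approx(1.0)
    assert len(history) == 2


def test_confusion_row_sums_are_true_group_sizes(rng):
    X, labels = three_group_data(rng, n_per=12)
    table = make_table(X, VARS2)
    model = sm.fit_cva(table, labels, VARS2)
    result = sm.classify(model, table, true_labels=labels)
    np.testing.assert_array_equal(result.confusion.sum(axis=1), [12, 12, 12])
    assert result.accuracy == pytest.approx(
        np.trace(result.confusion) / 36
    )


def test_agrees_with_sklearn_lda(rng):
    """Independent cross-check: equal-prior LDA assigns like Mahalanobis CVA."""
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    X, labels = three_group_data(rng, n_per=20, p=3)
    table = make_table(X, ("L1", "L5", "L6"))
    model = sm.fit_cva(table, labels, ("L1", "L5", "L6"))
    ours = sm.classify(model, table).predicted
    lda = LinearDiscriminantAnalysis(priors=[1 / 3] * 3).fit(X, labels)
    assert (ours == lda.predict(X)).mean() > 0.97
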