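import itertools

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from gopreclust.ranking import (
    RankedClasses,
    ReferenceTermList,
    compare_rocs,
    label_classes,
    mahalanobis_rank,
    parent_term,
    read_reference_list,
    roc_curve,
    write_roc,
)


def _ranked(distances, labels=None):
    distances = np.asarray(distances, float)
    order = np.argsort(-distances, kind="stable")
    names = labels or [f"GO:{i + 1:07d}" for i in range(len(distances))]
    return RankedClasses(
        class_labels=[names[i] for i in order],
        distances=distances[order],
        center=np.zeros(2),
        covariance=np.eye(2),
    )


class TestMahalanobisRank:
    def test_identity_covariance_reduces_to_euclidean(self, rng):
        # symmetric cloud with empirical covariance ~ I by construction
        base = rng.normal(size=(50, 2))
        base = (base - base.mean(0)) @ np.linalg.inv(np.linalg.cholesky(np.cov(base, rowvar=False))).T
        labels = [f"GO:{i + 1:07d}" for i in range(50)]
        ranked = mahalanobis_rank(base, labels)
        eu = np.linalg.norm(base - base.mean(0), axis=1)
        expected = {lab: d for lab, d in zip(labels, eu)}
        for lab, d in zip(ranked.class_labels, ranked.distances):
            assert d == pytest.approx(expected[lab], abs=1e-8)

    def test_affine_invariance(self, rng):
        X = rng.normal(size=(20, 2))
        labels = [f"GO:{i + 1:07d}" for i in range(20)]
        A = np.array([[2.0, 0.7], [-0.3, 1.4]])
        a = mahalanobis_rank(X, labels)
        b = mahalanobis_rank(X @ A.T + np.array([5.0, -2.0]), labels)
        assert a.class_labels == b.class_labels
        np.testing.assert_allclose(a.distances, b.distances, atol=1e-8)

    def test_hand_points_match_quadratic_form_oracle(self):
        X = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 1.0], [2.0, 3.0]])
        labels = ["GO:0000001", "GO:0000002", "GO:0000003", "GO:0000004"]
        ranked = mahalanobis_rank(X, labels)
        center = X.mean(0)
        S = np.cov(X, rowvar=False)
        det = S[0, 0] * S[1, 1] - S[0, 1] ** 2
        Sinv = np.array([[S[1, 1], -S[0, 1]], [-S[0, 1], S[0, 0]]]) / det
        expected = {
            lab: np.sqrt((x - center) @ Sinv @ (x - center)) for lab, x in zip(labels, X)
        }
        for lab, d in zip(ranked.class_labels, ranked.distances):
            assert d == pytest.approx(expected[lab], abs=1e-10)
        assert (np.diff(ranked.distances) <= 1e-12).all()

    def test_singular_covariance_errors(self):
        X = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.raises(ValueError, match="singular"):
            mahalanobis_rank(X, [f"GO:{i + 1:07d}" for i in range(5)])

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            mahalanobis_rank(np.eye(2), ["GO:0000001", "GO:0000002"])


class TestLabels:
    def test_subclass_inherits_parent_relevance(self):
        ref = ReferenceTermList(frozenset({"GO:0001501"}))
        labs = label_classes(["GO:0001501.3", "GO:0007050", "GO:0001501"], ref)
        np.testing.assert_array_equal(labs, [1, 0, 1])

    def test_empty_reference_all_negative(self):
        ref = ReferenceTermList(frozenset())
        np.testing.assert_array_equal(label_classes(["GO:0001501.3"], ref), [0])

    def test_parent_term_parsing(self):
        assert parent_term("GO:0007047.12") == "GO:0007047"
        assert parent_term("GO:0007047") == "GO:0007047"

    def test_reference_list_io(self, tmp_path):
        p = tmp_path / "ref.txt"
        p.write_text("# relevant terms\nGO:0007050 cell cycle arrest\nGO:0001501\n\n")
        ref = read_reference_list(p)
        assert ref.term_ids == frozenset({"GO:0007050", "GO:0001501"})

    def test_malformed_reference_id(self):
        with pytest.raises(ValueError):
            ReferenceTermList(frozenset({"7047"}))

    def test_packaged_osteogenesis_reference_list(self):
        from gopreclust.ranking import msc_reference_list

        ref = msc_reference_list()
        assert len(ref.term_ids) == 24
        assert "GO:0001501" in ref.term_ids  # skeletal development
        assert "GO:0007050" in ref.term_ids  # cell cycle arrest


def _brute_force_roc(distances, labels):
    """All-thresholds confusion-matrix enumeration (the independent oracle)."""
    distances = np.asarray(distances, float)
    labels = np.asarray(labels, int)
    P, N = labels.sum(), len(labels) - labels.sum()
    pts = {(0.0, 0.0)}
    for thr in np.unique(distances):
        sel = distances >= thr
        tp = (labels[sel] == 1).sum()
        fp = (labels[sel] == 0).sum()
        pts.add((fp / N, tp / P))
    pts = sorted(pts)
    xs, ys = zip(*pts)
    return np.trapezoid(ys, xs)


class TestROC:
    def test_perfect_separation(self):
        ranked = _ranked([4.0, 3.0, 2.0, 1.0])
        curve = roc_curve(ranked, [1, 1, 0, 0])
        assert curve.auc == pytest.approx(1.0)
        assert curve.sensitivity[0] == 0.0 and curve.specificity[0] == 1.0
        assert curve.sensitivity[-1] == 1.0 and curve.specificity[-1] == 0.0

    def test_interleaved_case(self):
        ranked = _ranked([4.0, 3.0, 2.0, 1.0])
        assert roc_curve(ranked, [1, 0, 1, 0]).auc == pytest.approx(0.75)

    def test_matches_exhaustive_oracle_and_sklearn(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 13))
            distances = np.round(rng.uniform(0, 3, n), 1)  # ties likely
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            ranked = _ranked(distances)
            ranked_labels = labels[np.argsort(-distances, kind="stable")]
            curve = roc_curve(ranked, ranked_labels)
            assert curve.auc == pytest.approx(_brute_force_roc(distances, labels), abs=1e-12)
            assert curve.auc == pytest.approx(roc_auc_score(labels, distances), abs=1e-12)

    def test_auc_equals_mann_whitney_probability(self, rng):
        distances = rng.normal(size=40) ** 2
        labels = rng.integers(0, 2, 40)
        ranked = _ranked(distances)
        ranked_labels = labels[np.argsort(-distances, kind="stable")]
        auc = roc_curve(ranked, ranked_labels).auc
        pos = distances[labels == 1]
        neg = distances[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p, n in itertools.product(pos, neg))
        assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_random_labels_auc_near_half(self, rng):
        aucs = []
        for _ in range(1000):
            distances = rng.uniform(size=12)
            labels = rng.permutation([1] * 4 + [0] * 8)
            ranked = _ranked(distances)
            aucs.append(roc_curve(ranked, labels[np.argsort(-distances, kind="stable")]).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.02

    def test_degenerate_labels_error(self):
        ranked = _ranked([2.0, 1.0])
        with pytest.raises(ValueError):
            roc_curve(ranked, [1, 1])

    def test_serialization(self, tmp_path):
        curve = roc_curve(_ranked([3.0, 2.0, 1.0]), [1, 0, 1])
        p = write_roc(curve, tmp_path / "roc.tsv")
        assert p.read_text().startswith("threshold\tsensitivity\tspecificity")


class TestCompareRocs:
    def test_identical_curves(self):
        curve = roc_curve(_ranked([3.0, 2.0, 1.0]), [1, 0, 1])
        out = compare_rocs(curve, curve)
        assert out["delta_auc"] == 0.0
        assert out["dominates"] is True

    def test_perfect_vs_interleaved(self):
        perfect = roc_curve(_ranked([4.0, 3.0, 2.0, 1.0]), [1, 1, 0, 0])
        inter = roc_curve(_ranked([4.0, 3.0, 2.0, 1.0]), [1, 0, 1, 0])
        out = compare_rocs(perfect, inter)
        assert out["delta_auc"] == pytest.approx(0.25)
        assert out["dominates"] is True
        assert compare_rocs(inter, perfect)["dominates"] is False
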