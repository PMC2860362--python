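import numpy as np
import pytest

from gopreclust.io_annotation import ExpressionMatrix, MembershipMatrix
from gopreclust.preclust import (
    PreclustConfig,
    icc,
    icc_scatter_data,
    identity_catalog,
    precluster_catalog,
    precluster_class,
    term_subseed,
    write_catalog,
    write_counts,
)
from gopreclust.synthgen import SyntheticSpec, generate
from gopreclust.io_annotation import build_membership


def sinusoids(phases, n_per, n_cond=24, noise=0.1, seed=0, amplitude=1.0):
    rng = np.random.default_rng(seed)
    t = np.arange(n_cond)
    rows = []
    for ph in phases:
        mean = amplitude * np.sin(2 * np.pi * 2 * t / n_cond + ph)
        rows.append(mean + rng.normal(0, noise, (n_per, n_cond)))
    return np.vstack(rows)


class TestICC:
    def test_identical_rows_give_one(self):
        x = np.sin(np.linspace(0, 7, 10))
        assert icc(np.tile(x, (4, 1))) == pytest.approx(1.0)

    def test_anticorrelated_pair_gives_minus_one(self):
        x = np.array([1.0, 3.0, 2.0, 5.0])
        assert icc(np.vstack([x, -x])) == pytest.approx(-1.0)

    def test_hand_case_minus_one_third(self):
        rows = np.array([[1, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1]], float)
        assert icc(rows) == pytest.approx(-1 / 3)

    def test_matches_brute_force_lower_triangle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 21))
            d = int(rng.integers(3, 25))
            X = rng.normal(size=(n, d))
            vals = []
            for i in range(n):
                for j in range(i):
                    vals.append(np.corrcoef(X[i], X[j])[0, 1])
            assert icc(X) == pytest.approx(np.mean(vals), abs=1e-10)

    def test_invariant_under_positive_affine_rescaling(self, rng):
        X = rng.normal(size=(6, 12))
        slopes = rng.uniform(0.2, 5.0, size=(6, 1))
        shifts = rng.normal(size=(6, 1))
        assert icc(slopes * X + shifts) == pytest.approx(icc(X), abs=1e-10)

    def test_zero_variance_row_names_gene(self):
        X = np.vstack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match="flatgene"):
            icc(X, gene_ids=["flatgene", "g2"])

    def test_too_few_rows_or_conditions(self):
        with pytest.raises(ValueError):
            icc(np.ones((1, 5)))
        with pytest.raises(ValueError):
            icc(np.random.default_rng(0).normal(size=(3, 2)))


class TestPreclusterClass:
    def test_homogeneous_class_left_unsplit(self):
        X = sinusoids([0.3], 10, noise=0.1, seed=2)
        subsets, k = precluster_class(X, [f"g{i}" for i in range(10)], PreclustConfig(seed=2))
        assert k == 1
        assert subsets == [(0, [f"g{i}" for i in range(10)])]

    def test_three_phase_groups_recovered(self):
        genes = [f"g{i}" for i in range(24)]
        X = sinusoids([0, np.pi / 2, np.pi], 8, noise=0.1, seed=3)
        subsets, k = precluster_class(X, genes, PreclustConfig(seed=3))
        assert k == 3
        recovered = sorted(sorted(m) for _, m in subsets)
        planted = sorted(sorted(genes[i * 8 : (i + 1) * 8]) for i in range(3))
        assert recovered == planted

    def test_small_cluster_dropped(self):
        # 7 + 3 genes in two well-separated profile groups; min_size 4 keeps only the 7
        genes = [f"g{i}" for i in range(10)]
        rng = np.random.default_rng(4)
        X = np.vstack([
            np.sin(np.linspace(0, 4 * np.pi, 24)) + rng.normal(0, 0.05, (7, 24)),
            5.0 + rng.normal(0, 0.05, (3, 24)),
        ])
        subsets, k = precluster_class(X, genes, PreclustConfig(seed=4))
        assert k == 2
        assert [m for _, m in subsets] == [genes[:7]]

    def test_class_below_min_size_rejected(self):
        with pytest.raises(ValueError, match="min_size"):
            precluster_class(np.zeros((3, 5)), ["a", "b", "c"], PreclustConfig())


def _benchmark_small(seed=5):
    spec = SyntheticSpec(
        n_conditions=12, n_classes=6, genes_per_class=16, split_classes=[(0, 2)],
        phase_offsets=(0.0, np.pi), noise_sd=0.15, seed=seed,
    )
    expression, annotation, truth = generate(spec)
    membership, expression = build_membership(annotation, expression)
    return expression, membership, truth


class TestCatalog:
    def test_counts_identity_and_membership(self):
        expression, membership, truth = _benchmark_small()
        cat = precluster_catalog(expression, membership, PreclustConfig(seed=5))
        c = cat.counts
        assert c["n_total_out"] == (c["n_classes_in"] - c["n_split"]) + c["n_subclasses_retained"]
        assert c["n_total_out"] == len(cat.entries)
        assert c["n_classes_in"] == 6
        assert c["n_split"] == 1
        # split term appears only as subclasses; members disjoint
        split_entries = [e for e in cat.entries if e.term_id == "GO:0000001"]
        assert all(e.subclass_index >= 1 for e in split_entries)
        members = [g for e in split_entries for g in e.member_gene_ids]
        assert len(members) == len(set(members))
        assert all(len(e.member_gene_ids) >= 4 for e in cat.entries)

    def test_deterministic_and_order_independent(self):
        expression, membership, _ = _benchmark_small()
        cat1 = precluster_catalog(expression, membership, PreclustConfig(seed=5))
        # reversed term order must give the identical catalog (per-term sub-seeds)
        rev = MembershipMatrix(
            membership.gene_ids, membership.term_ids[::-1], membership.values[:, ::-1]
        )
        cat2 = precluster_catalog(expression, rev, PreclustConfig(seed=5))
        as_set = lambda cat: {
            (e.term_id, e.subclass_index, tuple(e.member_gene_ids), round(e.icc, 12))
            for e in cat.entries
        }
        assert as_set(cat1) == as_set(cat2)
        assert cat1.counts == cat2.counts

    def test_single_identical_profile_term(self):
        prof = np.sin(np.linspace(0, 12, 24))
        expression = ExpressionMatrix(
            [f"g{i}" for i in range(4)], [f"t{j}" for j in range(24)], np.tile(prof, (4, 1))
        )
        membership = MembershipMatrix(expression.gene_ids, ["GO:0000001"], np.ones((4, 1), int))
        cat = precluster_catalog(expression, membership, PreclustConfig(seed=1))
        assert len(cat.entries) == 1
        assert cat.entries[0].subclass_index == 0
        assert cat.entries[0].icc == pytest.approx(1.0)

    def test_empty_membership_errors(self):
        expression, membership, _ = _benchmark_small()
        empty = MembershipMatrix(membership.gene_ids, [], np.zeros((len(membership.gene_ids), 0)))
        with pytest.raises(ValueError, match="empty"):
            precluster_catalog(expression, empty)

    def test_identity_catalog_is_unsplit(self):
        expression, membership, _ = _benchmark_small()
        cat = identity_catalog(expression, membership)
        assert cat.counts["n_split"] == 0
        assert cat.counts["n_total_out"] == cat.counts["n_classes_in"]
        assert all(e.subclass_index == 0 for e in cat.entries)

    def test_serialization(self, tmp_path):
        expression, membership, _ = _benchmark_small()
        cat = precluster_catalog(expression, membership, PreclustConfig(seed=5))
        cat_path = write_catalog(cat, tmp_path / "catalog.tsv")
        counts_path = write_counts(cat, tmp_path / "counts.tsv")
        lines = cat_path.read_text().splitlines()
        assert lines[0] == "term_id\tsubclass_index\tn_genes\ticc\tmember_gene_ids"
        assert len(lines) == 1 + len(cat.entries)
        header, row = counts_path.read_text().splitlines()
        assert header.split("\t") == ["# GO cl.", "# split", "# new", "# > min", "total"]
        assert row.split("\t")[0] == "6"


class TestICCScatter:
    def test_unsplit_entries_on_diagonal(self):
        expression, membership, _ = _benchmark_small()
        cat = identity_catalog(expression, membership)
        pts = icc_scatter_data(cat, expression, membership)
        assert len(pts) == len(cat.entries)
        for parent, entry, _, idx in pts:
            assert idx == 0
            assert entry == pytest.approx(parent)

    def test_anticorrelated_split_moves_above_diagonal(self):
        expression, membership, _ = _benchmark_small()
        cat = precluster_catalog(expression, membership, PreclustConfig(seed=5))
        pts = icc_scatter_data(cat, expression, membership)
        split_pts = [p for p in pts if p[2] == "GO:0000001"]
        assert len(split_pts) == 2
        for parent, entry, _, idx in split_pts:
            assert idx >= 1
            assert abs(parent) < 0.3  # anti-correlated halves cancel
            assert entry > 0.8


def test_term_subseed_stable_and_bounded():
    s = term_subseed(42, "GO:0007047")
    assert s == term_subseed(42, "GO:0007047")
    assert 0 <= s < 2**31
    assert s != term_subseed(43, "GO:0007047")
    assert s != term_subseed(42, "GO:0007048")
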