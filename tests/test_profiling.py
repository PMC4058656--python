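"""Density maps, class fractions, enrichment folds, cluster selection."""

import numpy as np
import pytest

from catsom.profiling import (
    EnrichmentUndefinedError,
    background_fractions,
    candidate_pick,
    centroid_reference,
    class_fractions,
    density_map,
    enrichment_factor,
    enrichment_report,
    feature_map,
    read_labels_tsv,
    top_cluster,
    write_labels_tsv,
)
from catsom.som import Assignment, SOMConfig, SOMModel


CFG = SOMConfig(width=4, height=3)


def ref(cid, x, y, dist=1.0):
    return Assignment(compound_id=cid, x=x, y=y, distance=dist, origin="reference")


def lib(cid, x, y, dist=1.0):
    return Assignment(compound_id=cid, x=x, y=y, distance=dist, origin="library")


class TestDensityMap:
    def test_counts_are_conserved(self):
        rng = np.random.default_rng(0)
        assignments = [
            ref(f"c{i}", int(rng.integers(4)), int(rng.integers(3)))
            for i in range(57)
        ]
        grid = density_map(assignments, CFG)
        assert grid.shape == (3, 4)
        assert grid.sum() == 57

    def test_single_occupied_neuron(self):
        grid = density_map([ref(f"c{i}", 2, 1) for i in range(5)], CFG)
        assert grid[1, 2] == 5 and grid.sum() == 5

    def test_origin_filter_separates_collections(self):
        assignments = [ref("r", 0, 0), lib("l", 0, 0), lib("m", 1, 1)]
        assert density_map(assignments, CFG, origin="library").sum() == 2
        assert density_map(assignments, CFG, origin="reference").sum() == 1

    def test_uniform_assignment_is_roughly_flat(self):
        rng = np.random.default_rng(42)
        cfg = SOMConfig(width=5, height=4)
        n = 20_000
        assignments = [
            ref(f"c{i}", int(rng.integers(5)), int(rng.integers(4)))
            for i in range(n)
        ]
        grid = density_map(assignments, cfg)
        assert grid.max() / grid.min() < 1.3


class TestClassFractions:
    def test_worked_distribution(self):
        # 29 compounds on one neuron, 16 kinase-labeled -> 55%
        assignments = [ref(f"c{i}", 1, 1) for i in range(29)]
        labels = {f"c{i}": ["kinase"] if i < 16 else ["other"] for i in range(29)}
        fractions = class_fractions(assignments, labels, (1, 1))
        assert fractions["kinase"] == pytest.approx(16 / 29)
        assert round(fractions["kinase"], 2) == 0.55

    def test_single_compound_single_class(self):
        fractions = class_fractions([ref("a", 0, 0)], {"a": ["gpcr"]}, (0, 0))
        assert fractions == {"gpcr": 1.0}

    def test_absent_class_and_empty_cluster(self):
        fractions = class_fractions([ref("a", 0, 0)], {"a": ["gpcr"]}, (0, 0))
        assert fractions.get("protease", 0.0) == 0.0
        assert class_fractions([ref("a", 0, 0)], {"a": ["gpcr"]}, (3, 2)) == {}

    def test_multilabel_counts_once_per_class(self):
        assignments = [ref("a", 0, 0), ref("b", 0, 0)]
        labels = {"a": ["kinase", "gpcr"], "b": ["kinase"]}
        fractions = class_fractions(assignments, labels, (0, 0))
        assert fractions == {"kinase": 1.0, "gpcr": 0.5}


class TestEnrichmentFactor:
    def test_worked_example_seven_fold(self):
        fold = enrichment_factor(0.55, 0.08)
        assert fold == pytest.approx(6.875)
        assert round(fold) == 7

    def test_small_map_worked_example(self):
        assert enrichment_factor(0.352, 0.08) == pytest.approx(4.4)

    def test_identity_at_equal_fractions(self):
        for x in (0.01, 0.3, 1.0):
            assert enrichment_factor(x, x) == pytest.approx(1.0)

    def test_zero_background_is_undefined_not_infinite(self):
        with pytest.raises(EnrichmentUndefinedError):
            enrichment_factor(0.5, 0.0)


class TestTopCluster:
    def test_concentrated_class_found(self):
        assignments = [ref(f"k{i}", 2, 1) for i in range(10)]
        assignments += [ref(f"o{i}", 0, 0) for i in range(20)]
        labels = {f"k{i}": ["kinase"] for i in range(10)}
        labels.update({f"o{i}": ["other"] for i in range(20)})
        assert top_cluster(assignments, labels, "kinase", CFG) == (2, 1)

    def test_single_member_class(self):
        assert top_cluster([ref("a", 3, 2)], {"a": ["x"]}, "x", CFG) == (3, 2)

    def test_tie_breaks_to_smallest_linear_index(self):
        assignments = [ref("a", 3, 0), ref("b", 1, 2)]
        labels = {"a": ["x"], "b": ["x"]}
        assert top_cluster(assignments, labels, "x", CFG) == (3, 0)

    def test_absent_class_raises_with_name(self):
        with pytest.raises(ValueError, match="proteasome"):
            top_cluster([ref("a", 0, 0)], {"a": ["x"]}, "proteasome", CFG)


class TestCentroidReference:
    def _model(self):
        weights = np.zeros((CFG.n_neurons, 3))
        weights[1 * 4 + 2] = [1.0, 2.0, 3.0]
        return SOMModel(config=CFG, weights=weights, trained=True)

    def test_single_member(self):
        model = self._model()
        assert centroid_reference(model, (2, 1), [ref("only", 2, 1, 0.7)]) == "only"

    def test_zero_distance_member_wins(self):
        model = self._model()
        members = [ref("far", 2, 1, 0.9), ref("exact", 2, 1, 0.0)]
        assert centroid_reference(model, (2, 1), members) == "exact"

    def test_agrees_with_exhaustive_scan(self):
        rng = np.random.default_rng(8)
        model = SOMModel(
            config=CFG, weights=rng.normal(size=(CFG.n_neurons, 5)), trained=True
        )
        target = model.neuron_weight(2, 1)
        vectors = {f"c{i}": rng.normal(size=5) for i in range(20)}
        members = [
            ref(cid, 2, 1, float(np.linalg.norm(v - target)))
            for cid, v in vectors.items()
        ]
        best = min(vectors, key=lambda c: np.linalg.norm(vectors[c] - target))
        assert centroid_reference(model, (2, 1), members) == best

    def test_empty_cluster_raises(self):
        with pytest.raises(ValueError):
            centroid_reference(self._model(), (0, 0), [])


class TestCandidatePick:
    def test_sorted_by_distance_no_duplicates(self):
        members = [lib("b", 1, 1, 0.5), lib("a", 1, 1, 0.1), lib("c", 1, 1, 0.9)]
        others = [lib("d", 0, 0, 0.0), ref("e", 1, 1, 0.0)]
        picks = candidate_pick(members + others, (1, 1))
        assert picks == ["a", "b", "c"]

    def test_empty_cluster(self):
        assert candidate_pick([lib("a", 0, 0)], (2, 2)) == []


class TestFeatureMap:
    def test_weight_plane_is_column_slice(self):
        rng = np.random.default_rng(1)
        from catsom.cats import N_BINS

        model = SOMModel(
            config=CFG, weights=rng.normal(size=(CFG.n_neurons, N_BINS)), trained=True
        )
        plane = feature_map(model, "DA_04")
        idx = 14
        np.testing.assert_array_equal(
            plane, model.weights[:, idx].reshape(3, 4)
        )
        np.testing.assert_array_equal(
            plane, feature_map(model, "HDon-HAcc 4 bonds")
        )

    def test_constant_weights_give_constant_plane(self):
        from catsom.cats import N_BINS

        model = SOMModel(
            config=CFG, weights=np.full((CFG.n_neurons, N_BINS), 0.7), trained=True
        )
        np.testing.assert_allclose(feature_map(model, 0), 0.7)

    def test_mean_mode_averages_assigned_compounds(self):
        import pandas as pd
        from catsom.cats import BIN_NAMES, N_BINS

        model = SOMModel(
            config=CFG, weights=np.zeros((CFG.n_neurons, N_BINS)), trained=True
        )
        table = pd.DataFrame(
            np.arange(2 * N_BINS, dtype=float).reshape(2, N_BINS),
            index=["a", "b"],
            columns=list(BIN_NAMES),
        )
        assignments = [ref("a", 0, 0), ref("b", 0, 0)]
        plane = feature_map(model, 0, mode="mean", assignments=assignments, table=table)
        assert plane[0, 0] == pytest.approx((0 + 150) / 2)
        assert np.isnan(plane[2, 3])

    def test_unknown_bin_rejected(self):
        model = SOMModel(config=CFG, weights=np.zeros((CFG.n_neurons, 150)))
        with pytest.raises(KeyError):
            feature_map(model, "QQ_99")


class TestEnrichmentReport:
    def _setup(self):
        assignments = [ref(f"k{i}", 0, 0) for i in range(6)]
        assignments += [ref(f"g{i}", 1, 0) for i in range(14)]
        labels = {f"k{i}": ["kinase"] for i in range(6)}
        labels.update({f"g{i}": ["gpcr"] for i in range(14)})
        return assignments, labels

    def test_class_totals_conserved_across_neurons(self):
        assignments, labels = self._setup()
        report = enrichment_report(assignments, labels, CFG)
        total_kinase = sum(c.class_counts.get("kinase", 0) for c in report.clusters)
        assert total_kinase == 6

    def test_whole_map_enrichment_is_unity_on_compound_basis(self):
        assignments, labels = self._setup()
        bg = background_fractions(assignments, labels)
        whole_map = class_fractions(
            [ref(a.compound_id, 5, 5) for a in assignments],
            labels,
            (5, 5),
        )
        for cls in bg:
            assert enrichment_factor(whole_map[cls], bg[cls]) == pytest.approx(1.0)

    def test_folds_match_hand_computation(self):
        assignments, labels = self._setup()
        report = enrichment_report(assignments, labels, CFG)
        cluster = report.cluster(0, 0)
        # kinase: fraction 1.0 in cluster vs background 6/20
        assert cluster.folds["kinase"] == pytest.approx(1.0 / (6 / 20))

    def test_target_basis_with_explicit_background(self):
        assignments, labels = self._setup()
        report = enrichment_report(
            assignments, labels, CFG, background={"kinase": 0.08}, basis="target"
        )
        assert report.cluster(0, 0).folds["kinase"] == pytest.approx(1.0 / 0.08)

    def test_report_serializes(self):
        assignments, labels = self._setup()
        d = enrichment_report(assignments, labels, CFG).to_dict()
        assert d["clusters"][0]["label"] == "(0/0)"


class TestLabelsIO:
    def test_roundtrip(self, tmp_path):
        labels = {"a": ["kinase", "gpcr"], "b": ["other"], "c": []}
        path = tmp_path / "labels.tsv"
        write_labels_tsv(labels, path)
        assert read_labels_tsv(path) == labels
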