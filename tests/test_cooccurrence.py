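"""Pan-matrix, co-occurrence statistic, screening and the pattern oracle."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from pancooc.cooccurrence import (
    PanMatrix,
    PhenotypeTable,
    build_pan_matrix,
    enumerate_patterns,
    join_annotations,
    pearson_cooccurrence,
    round_half_away,
    screen,
)

from oracles import pearson_population

#: The six-strain phenotype: maximum NaCl (%, w/v), decreasing.
Y = (10.0, 9.0, 9.0, 5.0, 4.0, 3.0)
STRAINS = ("s1", "s2", "s3", "s4", "s5", "s6")
PHENOTYPE = PhenotypeTable(strains=STRAINS, values=Y)


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.815, 0.82), (-0.815, -0.82), (0.8146, 0.81), (0.9701, 0.97), (0.845, 0.85)],
    )
    def test_half_away_from_zero(self, value, expected):
        assert round_half_away(value, 2) == expected


class TestPearsonCooccurrence:
    @pytest.mark.parametrize(
        "x,expected",
        [
            ((1, 1, 1, 0, 0, 0), 0.97),
            ((1, 1, 1, 1, 0, 0), 0.81),
            ((1, 1, 2, 0, 0, 0), 0.84),
        ],
    )
    def test_printed_values_at_two_decimals(self, x, expected):
        value = pearson_cooccurrence(x, Y)
        assert round_half_away(value, 2) == expected

    def test_perfect_correlation(self):
        assert pearson_cooccurrence(Y, Y) == pytest.approx(1.0)

    def test_constant_abundance_is_undefined(self):
        assert pearson_cooccurrence((1, 1, 1, 1, 1, 1), Y) is None

    def test_matches_scipy_sample_pearson(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.integers(0, 4, size=6).astype(float)
            if x.var() == 0:
                continue
            assert pearson_cooccurrence(x, Y) == pytest.approx(
                stats.pearsonr(x, np.array(Y)).statistic, abs=1e-12
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pearson_cooccurrence((1, 0), Y)

    def test_affine_rescaling_of_phenotype_invariant(self):
        x = (1, 1, 2, 0, 0, 1)
        y2 = tuple(3.5 * v + 2.0 for v in Y)
        assert pearson_cooccurrence(x, Y) == pytest.approx(
            pearson_cooccurrence(x, y2)
        )

    def test_genome_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        x = np.array([1.0, 1, 2, 0, 0, 1])
        y = np.array(Y)
        for _ in range(10):
            perm = rng.permutation(6)
            assert pearson_cooccurrence(x[perm], y[perm]) == pytest.approx(
                pearson_cooccurrence(x, y)
            )


class TestPhenotypeTable:
    def test_constant_phenotype_rejected_at_load(self):
        with pytest.raises(ValueError, match="constant"):
            PhenotypeTable(strains=("a", "b", "c"), values=(5.0, 5.0, 5.0))

    def test_too_few_strains_rejected(self):
        with pytest.raises(ValueError):
            PhenotypeTable(strains=("a", "b"), values=(1.0, 2.0))

    def test_tsv_round_trip(self, tmp_path):
        path = tmp_path / "phenotype.tsv"
        PHENOTYPE.to_tsv(path)
        assert PhenotypeTable.from_tsv(path) == PHENOTYPE


class TestBuildPanMatrix:
    def test_counts_rows(self):
        assignment = {"a1": "Cluster_1", "a2": "Cluster_1", "a3": "Cluster_1"}
        orf_to_genome = {"a1": "s1", "a2": "s2", "a3": "s3"}
        pan = build_pan_matrix(assignment, orf_to_genome, PHENOTYPE)
        assert pan.cluster_ids == ("Cluster_1",)
        np.testing.assert_array_equal(pan.counts, [[1, 1, 1, 0, 0, 0]])

    def test_empty_assignment(self):
        pan = build_pan_matrix({}, {}, PHENOTYPE)
        assert pan.cluster_ids == ()
        assert pan.counts.shape == (0, 6)

    def test_member_conservation(self):
        rng = np.random.default_rng(2)
        assignment, orf_to_genome = {}, {}
        for i in range(40):
            assignment[f"o{i}"] = f"Cluster_{int(rng.integers(1, 8))}"
            orf_to_genome[f"o{i}"] = STRAINS[int(rng.integers(6))]
        pan = build_pan_matrix(assignment, orf_to_genome, PHENOTYPE)
        assert pan.counts.sum() == 40

    def test_unknown_strain_rejected(self):
        with pytest.raises(ValueError, match="unknown strain"):
            build_pan_matrix({"a": "Cluster_1"}, {"a": "nope"}, PHENOTYPE)

    def test_tsv_round_trip(self, tmp_path):
        pan = PanMatrix(
            cluster_ids=("Cluster_1", "Cluster_2"),
            genomes=STRAINS,
            counts=np.array([[1, 1, 1, 0, 0, 0], [0, 1, 2, 0, 1, 0]]),
        )
        path = tmp_path / "pan.tsv"
        pan.to_tsv(path)
        back = PanMatrix.from_tsv(path)
        assert back.cluster_ids == pan.cluster_ids
        np.testing.assert_array_equal(back.counts, pan.counts)


class TestScreen:
    def make_pan(self, rows):
        return PanMatrix(
            cluster_ids=tuple(f"Cluster_{i + 1}" for i in range(len(rows))),
            genomes=STRAINS,
            counts=np.array(rows),
        )

    def test_ordering_and_undefined_side_channel(self):
        pan = self.make_pan(
            [(1, 1, 1, 0, 0, 0), (1, 1, 1, 1, 0, 0), (1, 1, 1, 1, 1, 1)]
        )
        out = screen(pan, PHENOTYPE, threshold=0.8)
        assert [r.value_2dp for r in out.passing] == [0.97, 0.81]
        assert [r.cluster_id for r in out.undefined] == ["Cluster_3"]

    def test_empty_matrix(self):
        pan = build_pan_matrix({}, {}, PHENOTYPE)
        out = screen(pan, PHENOTYPE)
        assert out.passing == () and out.undefined == ()

    def test_high_threshold_empties_pass_list(self):
        pan = self.make_pan([(1, 1, 1, 0, 0, 0), (1, 1, 1, 1, 0, 0)])
        out = screen(pan, PHENOTYPE, threshold=0.999)
        assert out.passing == ()

    def test_threshold_is_strict_on_unrounded_value(self):
        # (1,1,1,1,0,0) -> 0.8146...: passes 0.81, fails 0.82
        pan = self.make_pan([(1, 1, 1, 1, 0, 0)])
        assert screen(pan, PHENOTYPE, threshold=0.81).passing
        assert not screen(pan, PHENOTYPE, threshold=0.82).passing

    def test_negative_correlations_need_absolute_mode(self):
        pan = self.make_pan([(0, 0, 0, 1, 1, 1)])
        assert not screen(pan, PHENOTYPE, threshold=0.8).passing
        out = screen(pan, PHENOTYPE, threshold=0.8, signed=False)
        assert [r.value_2dp for r in out.passing] == [-0.97]

    def test_binary_mode_collapses_copy_number(self):
        pan = self.make_pan([(1, 1, 2, 0, 0, 0)])
        counts_val = screen(pan, PHENOTYPE).passing[0].value_2dp
        binary_val = screen(pan, PHENOTYPE, mode="binary").passing[0].value_2dp
        assert counts_val == 0.84 and binary_val == 0.97

    def test_tie_broken_by_cluster_id(self):
        pan = self.make_pan([(1, 1, 1, 1, 0, 0), (2, 2, 2, 2, 0, 0)])
        out = screen(pan, PHENOTYPE)
        assert [r.cluster_id for r in out.passing] == ["Cluster_1", "Cluster_2"]

    def test_invalid_threshold_rejected(self):
        pan = self.make_pan([(1, 1, 1, 0, 0, 0)])
        with pytest.raises(ValueError):
            screen(pan, PHENOTYPE, threshold=1.0)

    def test_screen_value_matches_enumeration_table(self):
        """Screen/enumeration consistency on every row of a small matrix."""
        rows = [(1, 0, 2, 0, 1, 0), (1, 1, 1, 0, 0, 0), (0, 2, 0, 1, 0, 2)]
        pan = self.make_pan(rows)
        table = enumerate_patterns(Y, max_count=2)
        lookup = {tuple(p): v for p, v in zip(table["pattern"], table["value"])}
        out = screen(pan, PHENOTYPE, threshold=0.0)
        for result in out.all_results:
            row = tuple(pan.row(result.cluster_id))
            assert result.value == pytest.approx(lookup[row])


class TestEnumeratePatterns:
    def test_binary_pattern_space_size(self):
        table = enumerate_patterns(Y, max_count=1)
        assert len(table) == 63

    def test_unique_maximum_is_top3_presence(self):
        """(1,1,1,0,0,0) is the unique best-scoring binary pattern and
        rounds to the printed 0.97."""
        table = enumerate_patterns(Y, max_count=1)
        defined = table.dropna(subset=["value"])
        best = defined.loc[defined["value"].idxmax()]
        assert tuple(best["pattern"]) == (1, 1, 1, 0, 0, 0)
        assert round_half_away(best["value"], 2) == 0.97
        runner_up = defined["value"].nlargest(2).iloc[1]
        assert runner_up < best["value"]

    def test_complement_antisymmetry(self):
        table = enumerate_patterns(Y, max_count=1)
        values = {tuple(p): v for p, v in zip(table["pattern"], table["value"])}
        for pattern, value in values.items():
            complement = tuple(1 - c for c in pattern)
            if not any(complement):
                continue
            other = values[complement]
            if value is None or np.isnan(value):
                assert other is None or np.isnan(other)
            else:
                assert other == pytest.approx(-value)

    def test_three_point_closed_form(self):
        table = enumerate_patterns((1.0, 2.0, 3.0), max_count=1)
        values = {tuple(p): v for p, v in zip(table["pattern"], table["value"])}
        assert values[(0, 0, 1)] == pytest.approx(np.sqrt(3) / 2)
        assert values[(1, 0, 0)] == pytest.approx(-np.sqrt(3) / 2)

    def test_guards(self):
        with pytest.raises(ValueError):
            enumerate_patterns(tuple(range(1, 10)), max_count=1)
        with pytest.raises(ValueError):
            enumerate_patterns(Y, max_count=5)


class TestJoinAnnotations:
    def make_results(self):
        pan = PanMatrix(
            cluster_ids=("Cluster_1", "Cluster_2"),
            genomes=STRAINS,
            counts=np.array([[1, 1, 1, 0, 0, 0], [1, 1, 1, 1, 0, 0]]),
        )
        return screen(pan, PHENOTYPE).passing

    def test_empty_map_defaults_to_hypothetical(self):
        annotated = join_annotations(self.make_results(), {})
        assert all(r.annotation == "hypothetical protein" for r in annotated)

    def test_known_cluster_gets_label_without_reordering(self):
        results = self.make_results()
        annotated = join_annotations(
            results, {"Cluster_1": "TauD/TfdA family dioxygenase"}
        )
        assert [r.cluster_id for r in annotated] == [r.cluster_id for r in results]
        by_id = {r.cluster_id: r.annotation for r in annotated}
        assert by_id["Cluster_1"] == "TauD/TfdA family dioxygenase"

    def test_unknown_cluster_ignored_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="pancooc.cooccurrence"):
            join_annotations(self.make_results(), {"Cluster_99": "x"})
        assert any("unknown cluster" in r.message for r in caplog.records)


class TestSampleVsPopulationNormalisation:
    def test_identical_on_random_vectors(self):
        """The n-1 and n normalisations cancel: both give the same
        correlation on 1000 random abundance/phenotype pairs."""
        rng = np.random.default_rng(12)
        checked = 0
        while checked < 1000:
            x = rng.integers(0, 4, size=6).astype(float)
            y = rng.uniform(1, 12, size=6)
            if x.var() == 0 or y.var() == 0:
                continue
            ours = pearson_cooccurrence(x, y)
            assert ours == pytest.approx(pearson_population(x, y), abs=1e-12)
            checked += 1
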