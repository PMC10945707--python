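import numpy as np
import pandas as pd
import pytest

from arrestome.data_model import (
    AnnotationBundle,
    ComplexDatabase,
    FormatError,
    ProteinComplex,
    ScoredInteraction,
    SpectralCountTable,
    ValidationError,
    ValidationSets,
    collapse_isoforms,
    impute_zero_counts,
    read_complex_edges,
    read_complex_gmt,
    read_scores,
    read_spectral_counts,
    write_scores,
    write_spectral_counts,
)


class TestSpectralCountIO:
    def test_parses_toy_file(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text(
            "bait\tprey\treplicate\tcount\nA\tx\t1\t3\nA\tx\t2\t5\nA\ty\t1\t2\n"
        )
        table = read_spectral_counts(path)
        assert len(table) == 3
        assert table.baits() == ["A"]
        assert table.preys() == ["x", "y"]

    def test_negative_count_names_row(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text("bait\tprey\treplicate\tcount\nA\tx\t1\t3\nA\ty\t1\t-1\n")
        with pytest.raises(ValidationError, match=r"\[1\]"):
            read_spectral_counts(path)

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text("bait\tprey\tcount\nA\tx\t3\n")
        with pytest.raises(FormatError, match="replicate"):
            read_spectral_counts(path)

    def test_duplicate_key_rejected(self):
        df = pd.DataFrame(
            [("A", "x", 1, 3), ("A", "x", 1, 4)],
            columns=["bait", "prey", "replicate", "count"],
        )
        with pytest.raises(ValidationError, match="duplicate"):
            SpectralCountTable(df)

    def test_round_trip_is_lossless(self, toy_counts, tmp_path):
        cpath, ctrl = tmp_path / "c.tsv", tmp_path / "ctrl.tsv"
        write_spectral_counts(toy_counts, cpath, ctrl)
        back = read_spectral_counts(cpath, ctrl, species="toy", n_replicates=2)
        assert back == toy_counts

    def test_missing_cells_are_zero_in_matrix(self, toy_counts):
        mat = toy_counts.matrix("B")
        assert mat.loc["x"].tolist() == [3.0, 0.0]

    def test_control_mean_divides_by_runs(self, toy_counts):
        means = toy_counts.control_mean()
        assert means["x"] == pytest.approx(2.5)  # (2 + 3) / 2 runs
        assert means["y"] == pytest.approx(0.5)  # 1 / 2 runs


class TestScoredInteractions:
    def test_score_range_enforced(self):
        with pytest.raises(ValidationError):
            ScoredInteraction("A", "x", 1.2, 0.0, (1,))

    def test_self_pairs_removed_on_read(self, tmp_path):
        path = tmp_path / "scores.tsv"
        path.write_text(
            "bait\tprey\tscore\tbfdr\tcount_rep1\tcount_rep2\n"
            "A\tA\t0.99\t0.0\t5\t5\nA\tx\t0.9\t0.01\t4\t6\n"
        )
        scored = read_scores(path)
        assert [(s.bait, s.prey) for s in scored] == [("A", "x")]

    def test_round_trip(self, toy_scored, tmp_path):
        path = tmp_path / "scores.tsv"
        write_scores(toy_scored, path)
        assert read_scores(path) == toy_scored

    def test_validation_sets_must_be_disjoint(self):
        with pytest.raises(ValidationError):
            ValidationSets(frozenset({("A", "x")}), frozenset({("A", "x")}))


class TestComplexGmt:
    def test_parses_line(self, tmp_path):
        path = tmp_path / "c.gmt"
        path.write_text("C1\tdesc\tP1\tP2\tP3\n")
        db = read_complex_gmt(path, source_label="src")
        assert db.complexes["C1"].subunits == frozenset({"P1", "P2", "P3"})
        assert db.complexes["C1"].source == "src"

    def test_duplicate_members_collapse(self, tmp_path):
        path = tmp_path / "c.gmt"
        path.write_text("C1\tdesc\tP1\tP1\n")
        assert read_complex_gmt(path).complexes["C1"].subunits == frozenset({"P1"})

    def test_empty_file_gives_empty_db(self, tmp_path):
        path = tmp_path / "c.gmt"
        path.write_text("")
        assert len(read_complex_gmt(path)) == 0

    def test_short_line_is_format_error(self, tmp_path):
        path = tmp_path / "c.gmt"
        path.write_text("C1\tdesc\n")
        with pytest.raises(FormatError, match=":1:"):
            read_complex_gmt(path)

    def test_edges_must_reference_subunits(self, tmp_path):
        gmt = tmp_path / "c.gmt"
        gmt.write_text("C1\tdesc\tP1\tP2\tP3\n")
        edges = tmp_path / "e.tsv"
        edges.write_text("complex_id\tsubunit_a\tsubunit_b\nC1\tP1\tP9\n")
        with pytest.raises(ValidationError):
            read_complex_edges(read_complex_gmt(gmt), edges)

    def test_edges_attach(self, tmp_path):
        gmt = tmp_path / "c.gmt"
        gmt.write_text("C1\tdesc\tP1\tP2\tP3\n")
        edges = tmp_path / "e.tsv"
        edges.write_text("complex_id\tsubunit_a\tsubunit_b\nC1\tP2\tP1\n")
        db = read_complex_edges(read_complex_gmt(gmt), edges)
        assert db.complexes["C1"].edges == frozenset({("P1", "P2")})


class TestCollapseIsoforms:
    def test_sum_reducer_combines_counts(self):
        df = pd.DataFrame(
            [("A", "p1a", 1, 3), ("A", "p1b", 1, 2)],
            columns=["bait", "prey", "replicate", "count"],
        )
        table = SpectralCountTable(df, n_replicates=1)
        out = collapse_isoforms(table, {"p1a": "g1", "p1b": "g1"})
        assert out.counts["count"].tolist() == [5]
        assert out.counts["prey"].tolist() == ["g1"]

    def test_max_reducer(self):
        df = pd.DataFrame(
            [("A", "p1a", 1, 3), ("A", "p1b", 1, 2)],
            columns=["bait", "prey", "replicate", "count"],
        )
        out = collapse_isoforms(SpectralCountTable(df, n_replicates=1),
                                {"p1a": "g1", "p1b": "g1"}, reducer="max")
        assert out.counts["count"].tolist() == [3]

    def test_identity_map_is_noop(self, toy_counts):
        assert collapse_isoforms(toy_counts, {}) == toy_counts

    def test_sum_conserves_total_count(self, toy_counts):
        out = collapse_isoforms(toy_counts, {"x": "g", "y": "g", "z": "g", "w": "g"})
        assert out.counts["count"].sum() == toy_counts.counts["count"].sum()

    def test_empty_table(self):
        empty = SpectralCountTable(
            pd.DataFrame(columns=["bait", "prey", "replicate", "count"])
        )
        assert len(collapse_isoforms(empty, {"a": "b"})) == 0


class TestImputeZeroCounts:
    def test_zero_becomes_floor(self):
        df = pd.DataFrame(
            [("A", "x", 1, 0), ("A", "x", 2, 4)],
            columns=["bait", "prey", "replicate", "count"],
        )
        out = impute_zero_counts(SpectralCountTable(df))
        assert out.counts["count"].tolist() == [0.01, 4.0]

    def test_nonzero_table_unchanged(self, toy_counts):
        # toy_counts has one zero cell implicit (B, x, rep2 missing) but no
        # explicit zero rows; all stored values are positive except none
        df = toy_counts.counts[toy_counts.counts["count"] > 0]
        table = SpectralCountTable(df, toy_counts.controls, "toy", 2)
        out = impute_zero_counts(table)
        assert out.counts["count"].tolist() == [float(c) for c in df["count"]]

    def test_only_zero_entries_change(self, toy_counts):
        out = impute_zero_counts(toy_counts)
        orig = toy_counts.counts["count"].to_numpy(dtype=float)
        new = out.counts["count"].to_numpy()
        changed = orig != new
        assert np.all(orig[changed] == 0)
        assert np.all(new[changed] == 0.01)

    def test_nonpositive_floor_rejected(self, toy_counts):
        with pytest.raises(ValueError):
            impute_zero_counts(toy_counts, floor=0.0)


class TestAnnotationBundle:
    def test_localization_vocabulary_enforced(self):
        with pytest.raises(ValidationError, match="vocabulary"):
            AnnotationBundle(localizations={"p": {"Nucleolus ghost"}})

    def test_complex_edges_validated_at_construction(self):
        with pytest.raises(ValidationError):
            ProteinComplex("c", frozenset({"a", "b"}), frozenset({("a", "z")}))

    def test_pooled_databases_reject_duplicate_ids(self):
        db1, db2 = ComplexDatabase(), ComplexDatabase()
        db1.add(ProteinComplex("c", frozenset({"a"})))
        db2.add(ProteinComplex("c", frozenset({"b"})))
        with pytest.raises(ValidationError):
            ComplexDatabase.pooled([db1, db2])
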