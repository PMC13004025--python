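"""The end-to-end census: filters, window, summary, oracle equivalence."""

from __future__ import annotations

import io

import pytest

from topomotif.census import (
    PatternSpec,
    SearchConfig,
    apply_membrane_filter,
    default_patterns,
    filter_cytoplasmic_tail,
    read_pattern_file,
    run_census,
    scan_proteome,
    summarize_census,
)
from topomotif.patterns import parse_pattern
from topomotif.records import FeatureKind, ProteinRecord, RecordSet, TopoFeature
from topomotif.synth import generate_library, paper_peptide_fixtures
from conftest import make_single_pass, oracle_census_passing


def lxxl() -> PatternSpec:
    return PatternSpec(parse_pattern("L@@L", name="LxxL"), min_membrane_distance=15)


class TestPatternFile:
    def test_packaged_five(self):
        specs = default_patterns()
        assert [s.name for s in specs] == ["LxxL", "NxxY", "FYWxLMV", "PhixFYVxFY", "PDZ"]
        assert specs[0].min_membrane_distance == 15
        assert specs[4].pattern.anchor_cterm
        assert all(not s.pattern.anchor_cterm for s in specs[:4])

    def test_missing_column(self):
        with pytest.raises(ValueError, match="anchor_cterm"):
            read_pattern_file(io.StringIO("pattern\tname\nL@@L\tx\n"))


class TestCytoplasmicTailFilter:
    def test_mixed_set(self):
        records = []
        for i in range(6):
            records.append(make_single_pass(f"C{i}", seq_len=60))
        for i in range(3):
            records.append(make_single_pass(f"E{i}", seq_len=60, cterm_note="Extracellular"))
        records.append(
            ProteinRecord(accession="U0", sequence="A" * 60, features=[])
        )
        rs = RecordSet(records=records)
        kept = filter_cytoplasmic_tail(rs)
        assert sorted(r.accession for r in kept) == [f"C{i}" for i in range(6)]
        assert any("cytoplasmic=6" in p and "extracellular=3" in p for p in kept.provenance)

    def test_empty_set(self):
        assert len(filter_cytoplasmic_tail(RecordSet())) == 0

    def test_all_cytoplasmic_identity(self):
        rs = RecordSet(records=[make_single_pass(f"C{i}", seq_len=60) for i in range(4)])
        assert [r.accession for r in filter_cytoplasmic_tail(rs)] == [
            r.accession for r in rs
        ]


class TestScanProteome:
    def test_planted_tail_motif_passes(self):
        # tail carries LENL 30 residues after the TM end
        tail = "GAS" * 10 + "LENL" + "GAS" * 10
        r = make_single_pass("P1", tail_seq=tail)
        matches = scan_proteome(RecordSet(records=[r]), [lxxl()])
        passing = [m for m in matches if m.passes_filters]
        assert len(passing) == 1
        assert passing[0].matched_seq == "LENL"
        assert passing[0].distance.residues == 30

    def test_match_before_window_not_emitted(self):
        # LENL immediately after the TM, then a 120-residue motif-free tail:
        # the match falls outside the last-100 window
        tail = "LENL" + "GAS" * 40
        r = make_single_pass("P1", tail_seq=tail)
        matches = scan_proteome(RecordSet(records=[r]), [lxxl()], SearchConfig(window_len=100))
        assert matches == []
        full = scan_proteome(RecordSet(records=[r]), [lxxl()], SearchConfig(window_len=None))
        assert len(full) == 1

    def test_extracellular_loop_match_fails_with_reason(self):
        # 3-TM protein, LENL in the extracellular loop within the last 100 aa
        seq = "GAS" * 7 + "A" * 21 + "GASLENLGAS" + "A" * 21 + "GAS" * 4 + "A" * 21 + "GAS" * 10
        feats = [
            TopoFeature(FeatureKind.TOPO_DOM, 1, 21, "Cytoplasmic"),
            TopoFeature(FeatureKind.TRANSMEM, 22, 42),
            TopoFeature(FeatureKind.TOPO_DOM, 43, 52, "Extracellular"),
            TopoFeature(FeatureKind.TRANSMEM, 53, 73),
            TopoFeature(FeatureKind.TOPO_DOM, 74, 85, "Cytoplasmic"),
            TopoFeature(FeatureKind.TRANSMEM, 86, 106),
            TopoFeature(FeatureKind.TOPO_DOM, 107, 136, "Cytoplasmic"),
        ]
        r = ProteinRecord(accession="P1", sequence=seq[:136], features=feats)
        matches = scan_proteome(RecordSet(records=[r]), [lxxl()])
        lenl = [m for m in matches if m.matched_seq == "LENL"]
        assert len(lenl) == 1
        assert not lenl[0].passes_filters
        assert "not cytoplasmic" in lenl[0].fail_reasons

    def test_window_shorter_than_pattern_rejected(self):
        with pytest.raises(ValueError, match="window_len"):
            scan_proteome(RecordSet(), [lxxl()], SearchConfig(window_len=3))


class TestMembraneFilter:
    def test_threshold_fifteen(self):
        tails = {"D14": 14, "D15": 15, "D16": 16}
        records = [
            make_single_pass(acc, tail_seq="GAS" * (d // 3) + ("GA" if d % 3 == 2 else "G" * (d % 3)) + "LENL" + "GASGAS")
            for acc, d in tails.items()
        ]
        matches = [
            m
            for m in scan_proteome(RecordSet(records=records), [lxxl()])
            if m.matched_seq == "LENL"
        ]
        assert {m.accession: m.distance.residues for m in matches} == tails
        kept = apply_membrane_filter(matches, 15)
        assert sorted(m.accession for m in kept) == ["D15", "D16"]

    def test_undefined_distance_kept_and_flagged(self):
        r = ProteinRecord(
            accession="NOTM",
            sequence="GAS" * 20 + "LENLGAS",
            features=[TopoFeature(FeatureKind.TOPO_DOM, 1, 67, "Cytoplasmic")],
        )
        matches = scan_proteome(RecordSet(records=[r]), [lxxl()])
        assert len(matches) == 1
        kept = apply_membrane_filter(matches, 15)
        assert len(kept) == 1
        assert any("undefined" in f for f in kept[0].flags)

    def test_threshold_zero_is_identity(self):
        rs, _ = generate_library(seed=3, n=20)
        matches = scan_proteome(filter_cytoplasmic_tail(rs), default_patterns())
        assert apply_membrane_filter(matches, 0) == matches


class TestSummary:
    def test_counts_and_dedupe(self):
        # one protein with two overlapping LxxL hits, one with a single hit
        r1 = make_single_pass("P1", tail_seq="GAS" * 8 + "LAALAAL" + "GAS" * 6)
        r2 = make_single_pass("P2", tail_seq="GAS" * 8 + "LENL" + "GAS" * 7)
        matches = scan_proteome(RecordSet(records=[r1, r2]), [lxxl()])
        summary = summarize_census(matches, [lxxl()])
        s = summary.per_pattern["LxxL"]
        assert s.n_matches == 3
        assert s.n_unique_proteins == 2
        assert set(s.proteins["accession"]) == {"P1", "P2"}
        # best match per protein is the most C-terminal one
        assert int(s.proteins.set_index("accession").loc["P1", "position"]) == 27 + 27
        assert "protein_class" in s.proteins.columns
        assert (s.proteins["protein_class"] == "").all()

    def test_zero_matches(self):
        summary = summarize_census([], [lxxl()])
        s = summary.per_pattern["LxxL"]
        assert (s.n_matches, s.n_unique_proteins) == (0, 0)
        assert s.proteins.empty

    def test_distance_subparse_counts(self):
        r14 = make_single_pass("D14", tail_seq="GA" + "GAS" * 4 + "LENL" + "GAS" * 4)
        r20 = make_single_pass("D20", tail_seq="GAS" * 6 + "GA" + "LENL" + "GAS" * 4)
        matches = scan_proteome(RecordSet(records=[r14, r20]), [lxxl()])
        summary = summarize_census(matches, [lxxl()])
        s = summary.per_pattern["LxxL"]
        assert s.n_unique_proteins == 2
        assert s.n_unique_proteins_distance_filtered == 1


class TestPipelineProperties:
    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_full_pipeline_matches_oracle(self, seed):
        rs, _ = generate_library(seed=seed, n=60)
        config = SearchConfig(window_len=100, min_membrane_distance=15)
        matches_df, summary, _ = run_census(rs, default_patterns(), config)
        passing = matches_df[matches_df.passes_filters]
        for spec in default_patterns():
            got = sorted(
                (row.accession, row.start, row.end)
                for row in passing[passing.pattern == spec.name].itertuples()
            )
            expected = oracle_census_passing(
                list(rs),
                spec.pattern.source_text,
                spec.pattern.anchor_cterm,
                100,
                True,
                15,
            )
            assert got == expected, spec.name

    def test_filter_monotonicity(self):
        rs, _ = generate_library(seed=21, n=60)
        tails = filter_cytoplasmic_tail(rs)
        patterns = default_patterns()

        def passing_set(config):
            return {
                (m.accession, m.pattern_name, m.start)
                for m in scan_proteome(tails, patterns, config)
                if m.passes_filters
            }

        base = passing_set(SearchConfig(window_len=None, require_cytoplasmic_match=False))
        cyto = passing_set(SearchConfig(window_len=None, require_cytoplasmic_match=True))
        windowed = passing_set(SearchConfig(window_len=100, require_cytoplasmic_match=True))
        small_window = passing_set(SearchConfig(window_len=20, require_cytoplasmic_match=True))
        distanced = passing_set(
            SearchConfig(window_len=100, require_cytoplasmic_match=True, min_membrane_distance=15)
        )
        assert cyto <= base
        assert windowed <= cyto
        assert small_window <= windowed
        assert distanced <= windowed

    def test_window_equivalence_when_longer_than_sequences(self):
        rs, _ = generate_library(seed=22, n=40)
        tails = filter_cytoplasmic_tail(rs)
        patterns = default_patterns()
        max_len = max(len(r) for r in tails)
        a = scan_proteome(tails, patterns, SearchConfig(window_len=None))
        b = scan_proteome(tails, patterns, SearchConfig(window_len=max_len))
        assert a == b

    def test_anchored_pattern_equivalent_to_window_four(self):
        rs, _ = generate_library(seed=23, n=40)
        tails = filter_cytoplasmic_tail(rs)
        pdz = [s for s in default_patterns() if s.name == "PDZ"]
        a = scan_proteome(tails, pdz, SearchConfig(window_len=4))
        b = scan_proteome(tails, pdz, SearchConfig(window_len=100))
        assert a == b

    def test_dedup_equals_accession_cardinality(self):
        rs, _ = generate_library(seed=24, n=60)
        matches_df, summary, _ = run_census(rs)
        passing = matches_df[matches_df.passes_filters]
        for name, s in summary.per_pattern.items():
            assert s.n_unique_proteins == passing[passing.pattern == name].accession.nunique()
            assert s.n_unique_proteins <= s.n_matches or s.n_matches == 0


class TestDeterminism:
    def test_census_outputs_byte_identical(self, tmp_path):
        rs, _ = generate_library(seed=5, n=50)
        out1, out2 = tmp_path / "run1", tmp_path / "run2"
        run_census(rs, out_dir=out1)
        run_census(rs, out_dir=out2)
        files = sorted(p.name for p in out1.iterdir())
        assert files == sorted(p.name for p in out2.iterdir())
        for name in files:
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes(), name

    def test_peptide_fixture_census_lists_planted_carriers(self):
        matches_df, summary, _ = run_census(paper_peptide_fixtures())
        lxxl_carriers = set(summary.per_pattern["LxxL"].proteins["accession"])
        assert lxxl_carriers == {
            "SYNGLUT4",
            "SYNDMT1II",
            "SYNMOR",
            "SYNACY9",
            "SYNS12A7",
            "SYNPLXA1",
        }
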