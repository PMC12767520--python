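"""Interaction parsers (PSI-MI TAB 2.7, BioGRID TAB3, FI TSV) and filtering."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathcurate.fixtures import FixtureConfig, make_interactions, make_knowledgebase, write_psimitab
from pathcurate.interactions import (
    InteractionSet,
    Source,
    filter_ppis_by_fi,
    parse_biogrid_tab3,
    parse_psimitab,
    parse_reactome_fi,
    partners_of,
)

MITAB_COLS = 15


def mitab_row(sym_a, sym_b, pmids=("12345",), tax_a="9606", tax_b="9606"):
    cols = ["-"] * MITAB_COLS
    cols[0] = f"uniprotkb:{sym_a}ACC"
    cols[1] = f"uniprotkb:{sym_b}ACC"
    cols[4] = f"uniprotkb:{sym_a}(gene name)|psi-mi:{sym_a.lower()}(display_short)"
    cols[5] = f"uniprotkb:{sym_b}(gene name)"
    cols[8] = "|".join(f"pubmed:{p}" for p in pmids)
    cols[9] = f"taxid:{tax_a}(host)"
    cols[10] = f"taxid:{tax_b}(host)"
    return "\t".join(cols)


def tab3_file(tmp_path, rows):
    header = "\t".join(
        ["#BioGRID Interaction ID", "Official Symbol Interactor A",
         "Official Symbol Interactor B", "Publication Source",
         "Organism ID Interactor A", "Organism ID Interactor B"]
    )
    path = tmp_path / "bg.tab3.txt"
    path.write_text("\n".join([header] + rows) + "\n")
    return path


class TestPsimitab:
    def test_single_valid_row_field_by_field(self, tmp_path):
        path = tmp_path / "x.mitab"
        path.write_text(mitab_row("TANC1", "PSD95", pmids=("12345",)) + "\n")
        s = parse_psimitab(path)
        assert len(s) == 1
        edge = next(iter(s.edges.values()))
        assert edge.pair == ("PSD95", "TANC1")  # canonical order
        assert edge.pmids == {"12345"}
        assert edge.source is Source.INTACT
        assert edge.score is None
        assert s.report.rows_read == 1 and s.report.edges_kept == 1

    def test_self_edge_dropped(self, tmp_path):
        path = tmp_path / "x.mitab"
        path.write_text(mitab_row("TANC1", "TANC1") + "\n")
        s = parse_psimitab(path)
        assert len(s) == 0 and s.report.rows_skipped == 1

    def test_duplicate_pair_merges_pmids(self, tmp_path):
        path = tmp_path / "x.mitab"
        path.write_text(
            mitab_row("A1", "B1", pmids=("1",)) + "\n" + mitab_row("B1", "A1", pmids=("2",)) + "\n"
        )
        s = parse_psimitab(path)
        assert len(s) == 1
        assert next(iter(s.edges.values())).pmids == {"1", "2"}

    def test_non_human_rows_skipped(self, tmp_path):
        path = tmp_path / "x.mitab"
        path.write_text(
            mitab_row("A1", "B1", tax_b="10090") + "\n" + mitab_row("C1", "D1") + "\n"
        )
        s = parse_psimitab(path)
        assert sorted(e.pair for e in s.edges.values()) == [("C1", "D1")]
        assert s.report.rows_skipped == 1

    def test_row_without_gene_symbols_skipped_not_fatal(self, tmp_path):
        cols = ["-"] * MITAB_COLS
        cols[9] = cols[10] = "taxid:9606(human)"
        path = tmp_path / "x.mitab"
        path.write_text("\t".join(cols) + "\n" + mitab_row("A1", "B1") + "\n")
        s = parse_psimitab(path)
        assert len(s) == 1 and s.report.rows_skipped == 1

    def test_short_rows_rejected(self, tmp_path):
        path = tmp_path / "x.mitab"
        path.write_text("a\tb\tc\n")
        with pytest.raises(ValueError, match="PSI-MI"):
            parse_psimitab(path)


class TestBiogrid:
    def test_minimal_row(self, tmp_path):
        path = tab3_file(tmp_path, ["1\tCHD1\tCHD4\tPUBMED:777\t9606\t9606"])
        s = parse_biogrid_tab3(path)
        assert len(s) == 1
        edge = next(iter(s.edges.values()))
        assert edge.pair == ("CHD1", "CHD4")
        assert edge.pmids == {"777"}
        assert edge.source is Source.BIOGRID

    def test_header_only_file_empty(self, tmp_path):
        s = parse_biogrid_tab3(tab3_file(tmp_path, []))
        assert len(s) == 0 and s.report.rows_read == 0

    def test_duplicate_pair_merging(self, tmp_path):
        path = tab3_file(
            tmp_path,
            ["1\tA1\tB1\tPUBMED:1\t9606\t9606", "2\tB1\tA1\tPUBMED:2\t9606\t9606"],
        )
        s = parse_biogrid_tab3(path)
        assert len(s) == 1
        assert next(iter(s.edges.values())).pmids == {"1", "2"}

    def test_non_human_skipped(self, tmp_path):
        path = tab3_file(tmp_path, ["1\tA1\tB1\tPUBMED:1\t9606\t10090"])
        s = parse_biogrid_tab3(path)
        assert len(s) == 0 and s.report.rows_skipped == 1

    def test_wrong_header_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("colA\tcolB\n1\t2\n")
        with pytest.raises(ValueError, match="TAB3"):
            parse_biogrid_tab3(path)


class TestFiTsv:
    def test_score_parsed(self, tmp_path):
        path = tmp_path / "fi.tsv"
        path.write_text("gene_a\tgene_b\tscore\nA1\tB1\t0.97\n")
        s = parse_reactome_fi(path)
        edge = next(iter(s.edges.values()))
        assert edge.score == pytest.approx(0.97)
        assert edge.source is Source.REACTOME_FI

    def test_score_out_of_range_rejected(self, tmp_path):
        path = tmp_path / "fi.tsv"
        path.write_text("gene_a\tgene_b\tscore\nA1\tB1\t1.5\n")
        with pytest.raises(ValueError, match=r"\[0,1\]"):
            parse_reactome_fi(path)

    @pytest.mark.parametrize("n", [1, 5, 17])
    def test_n_distinct_rows_give_n_edges(self, tmp_path, n):
        rows = [f"G{i}A\tG{i}B\t0.5" for i in range(n)]
        path = tmp_path / "fi.tsv"
        path.write_text("gene_a\tgene_b\tscore\n" + "\n".join(rows) + "\n")
        assert len(parse_reactome_fi(path)) == n


class TestCanonicalization:
    def test_reversed_duplicates_equal_dedup_file(self, tmp_path):
        """A file with every edge duplicated in reverse parses to the same set."""
        pairs = [("A1", "B1"), ("C1", "D1"), ("E1", "F1")]
        dedup = tmp_path / "dedup.mitab"
        doubled = tmp_path / "doubled.mitab"
        dedup.write_text("\n".join(mitab_row(a, b) for a, b in pairs) + "\n")
        doubled.write_text(
            "\n".join(
                [mitab_row(a, b) for a, b in pairs] + [mitab_row(b, a) for a, b in pairs]
            )
            + "\n"
        )
        s1, s2 = parse_psimitab(dedup), parse_psimitab(doubled)
        assert s1.edges.keys() == s2.edges.keys()
        for k in s1.edges:
            assert s1.edges[k].pmids == s2.edges[k].pmids

    def test_max_score_retained_on_merge(self):
        s = InteractionSet()
        s.add("A", "B", Source.REACTOME_FI, score=0.6)
        s.add("B", "A", Source.REACTOME_FI, score=0.9)
        assert next(iter(s.edges.values())).score == pytest.approx(0.9)


class TestFiFilter:
    @staticmethod
    def _sets():
        ppis = InteractionSet()
        for a, b, pm in [("A", "B", "1"), ("C", "D", "2"), ("E", "F", "3")]:
            ppis.add(a, b, Source.INTACT, pmids=frozenset({pm}))
        fis = InteractionSet()
        fis.add("A", "B", Source.REACTOME_FI, score=0.95)
        fis.add("C", "D", Source.REACTOME_FI, score=0.55)
        return ppis, fis

    def test_zero_threshold_with_full_coverage_is_noop(self):
        ppis, _ = self._sets()
        fis = InteractionSet()
        for e in ppis.edges.values():
            fis.add(e.gene_a, e.gene_b, Source.REACTOME_FI, score=0.5)
        out = filter_ppis_by_fi(ppis, fis, 0.0)
        assert out.edges.keys() == ppis.edges.keys()

    def test_empty_fis_gives_empty_output(self):
        ppis, _ = self._sets()
        assert len(filter_ppis_by_fi(ppis, InteractionSet(), 0.0)) == 0

    def test_matches_bruteforce_intersection(self):
        ppis, fis = self._sets()
        out = filter_ppis_by_fi(ppis, fis, 0.9)
        brute = {
            pair
            for pair in ppis.edges
            if pair in fis.edges and fis.edges[pair].score >= 0.9
        }
        assert set(out.edges) == brute == {("A", "B")}
        assert out.edges[("A", "B")].pmids == {"1"}  # PPI pmids preserved

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=6).map(sorted))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_threshold(self, thresholds):
        ppis, fis = self._sets()
        sizes = [len(filter_ppis_by_fi(ppis, fis, t)) for t in thresholds]
        assert sizes == sorted(sizes, reverse=True)


class TestPartners:
    def test_absent_gene_empty(self):
        assert partners_of(InteractionSet(), "NOPE") == set()

    def test_star_graph(self):
        s = InteractionSet()
        for i in range(5):
            s.add("HUB", f"G{i}", Source.INTACT)
        assert {g for g, _ in partners_of(s, "HUB")} == {f"G{i}" for i in range(5)}

    def test_symmetry_on_fixture(self):
        kb = make_knowledgebase(FixtureConfig(seed=3))
        s = make_interactions(FixtureConfig(seed=3), kb)
        genes = s.genes()
        for g in genes:
            for partner, _ in partners_of(s, g):
                assert g in {x for x, _ in partners_of(s, partner)}

    def test_fixture_round_trips_through_mitab_writer(self, tmp_path):
        cfg = FixtureConfig(seed=5)
        s = make_interactions(cfg, make_knowledgebase(cfg))
        path = tmp_path / "rt.mitab"
        write_psimitab(s, path)
        parsed = parse_psimitab(path)
        assert parsed.edges.keys() == s.edges.keys()
        for k in s.edges:
            assert parsed.edges[k].pmids == s.edges[k].pmids
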