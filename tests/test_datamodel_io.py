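"""Readers, writers, domain-type invariants and the retrieval joins."""

import textwrap

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netformula import io
from netformula.datamodel import (
    FormatError,
    HerbCompoundLink,
    Prescription,
    PrescriptionDataset,
    ScoredLink,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(textwrap.dedent(text), encoding="utf-8")
    return p


class TestCompoundTable:
    HEADER = "compound_id,name,MW,ALOGP,HBA,HBD,PSA,ROTB,AROM,ALERTS\n"

    def test_parses_valid_rows(self, tmp_path):
        p = _write(
            tmp_path,
            "c.csv",
            self.HEADER + "C1,alpha,300,2.5,3,1,60,3,2,0\nC2,beta,450,4.0,5,2,90,6,3,1\n",
        )
        recs = io.read_compound_table(p)
        assert [r.compound_id for r in recs] == ["C1", "C2"]
        assert recs[0].MW == 300 and recs[1].ALERTS == 1

    def test_duplicate_id_rejected(self, tmp_path):
        p = _write(
            tmp_path,
            "c.csv",
            self.HEADER + "C1,a,300,2.5,3,1,60,3,2,0\nC1,b,310,2.0,3,1,60,3,2,0\n",
        )
        with pytest.raises(FormatError, match="C1"):
            io.read_compound_table(p)

    def test_non_numeric_cites_row(self, tmp_path):
        p = _write(
            tmp_path,
            "c.csv",
            self.HEADER + "C1,a,abc,2.5,3,1,60,3,2,0\n",
        )
        with pytest.raises(FormatError, match="row 2"):
            io.read_compound_table(p)

    def test_missing_column_named(self, tmp_path):
        p = _write(tmp_path, "c.csv", "compound_id,MW\nC1,300\n")
        with pytest.raises(FormatError, match="ALOGP"):
            io.read_compound_table(p)

    def test_round_trip(self, tmp_path):
        p = _write(
            tmp_path,
            "c.csv",
            self.HEADER + "C1,alpha,300,2.5,3,1,60,3,2,0\n",
        )
        recs = io.read_compound_table(p)
        out = tmp_path / "out.csv"
        io.write_compound_table(recs, out)
        assert io.read_compound_table(out) == recs


class TestLinks:
    def test_missing_score_gets_sentinel(self, tmp_path):
        p = _write(tmp_path, "ct.csv", "compound_id,target,score\nC1,T1,\n")
        links = io.read_links(p, "compound_target")
        assert links == [ScoredLink("C1", "T1", 9999)]

    def test_two_column_table_gets_sentinel(self, tmp_path):
        p = _write(tmp_path, "ct.csv", "compound_id,target\nC1,T1\n")
        assert io.read_links(p, "compound_target")[0].score == 9999

    def test_duplicates_keep_max(self, tmp_path):
        p = _write(
            tmp_path, "ct.csv", "compound_id,target,score\nC1,T1,300\nC1,T1,500\n"
        )
        assert io.read_links(p, "compound_target") == [ScoredLink("C1", "T1", 500)]

    def test_sentinel_outranks_numeric_on_collision(self, tmp_path):
        p = _write(
            tmp_path, "ct.csv", "compound_id,target,score\nC1,T1,900\nC1,T1,\n"
        )
        assert io.read_links(p, "compound_target")[0].score == 9999

    def test_score_out_of_range_rejected(self, tmp_path):
        p = _write(tmp_path, "ct.csv", "compound_id,target,score\nC1,T1,1500\n")
        with pytest.raises(FormatError):
            io.read_links(p, "compound_target")

    def test_herb_compound_pairs(self, tmp_path):
        p = _write(tmp_path, "hc.csv", "herb,compound\nH1,C1\nH1,C2\nH1,C1\n")
        links = io.read_links(p, "herb_compound")
        assert links == [HerbCompoundLink("H1", "C1"), HerbCompoundLink("H1", "C2")]

    def test_empty_file_rejected(self, tmp_path):
        p = _write(tmp_path, "hc.csv", "herb,compound\n")
        with pytest.raises(FormatError):
            io.read_links(p, "herb_compound")

    def test_round_trip(self, tmp_path):
        p = _write(
            tmp_path, "ct.csv", "compound_id,target,score\nC1,T1,300\nC2,T2,\n"
        )
        links = io.read_links(p, "compound_target")
        out = tmp_path / "out.csv"
        io.write_links(links, out)
        assert io.read_links(out, "compound_target") == links


class TestPrescriptions:
    def test_long_format_dedups_within_group(self, tmp_path):
        p = _write(tmp_path, "rx.csv", "Pid,Vid,Herb\np1,v1,a\np1,v1,b\np1,v1,a\n")
        ds = io.read_prescriptions(p)
        assert ds.n_prescriptions == 1 and ds.n_patients == 1
        assert ds.records[0].herbs == frozenset({"a", "b"})

    def test_wide_format_splits_on_delimiter(self, tmp_path):
        p = _write(tmp_path, "rx.csv", "Pid,Vid,Herb\np1,v1,a;b;c\n")
        assert io.read_prescriptions(p).records[0].herbs == frozenset("abc")

    def test_visits_are_distinct_prescriptions(self, tmp_path):
        p = _write(tmp_path, "rx.csv", "Pid,Vid,Herb\np1,v1,a;b\np1,v2,a;c\n")
        ds = io.read_prescriptions(p)
        assert ds.n_prescriptions == 2 and ds.n_patients == 1

    def test_long_and_wide_load_equal(self, tmp_path):
        long = _write(
            tmp_path, "l.csv", "Pid,Vid,Herb\np1,v1,a\np1,v1,b\np2,v1,c\n"
        )
        wide = _write(tmp_path, "w.csv", "Pid,Vid,Herb\np1,v1,a;b\np2,v1,c\n")
        assert io.read_prescriptions(long).records == io.read_prescriptions(wide).records

    def test_herb_names_whitespace_normalized(self, tmp_path):
        p = _write(tmp_path, "rx.csv", "Pid,Vid,Herb\np1,v1, a ;b  c\n")
        assert io.read_prescriptions(p).records[0].herbs == frozenset({"a", "b c"})

    def test_missing_column_rejected(self, tmp_path):
        p = _write(tmp_path, "rx.csv", "Pid,Herb\np1,a\n")
        with pytest.raises(FormatError, match="[Vv]id"):
            io.read_prescriptions(p)

    def test_round_trip(self, tmp_path):
        p = _write(tmp_path, "rx.csv", "Pid,Vid,Herb\np1,v1,a;b\np2,v1,c;d\n")
        ds = io.read_prescriptions(p)
        out = tmp_path / "out.csv"
        io.write_prescriptions(ds, out)
        assert io.read_prescriptions(out).records == ds.records


class TestGeneSets:
    def test_parses_and_dedups(self, tmp_path):
        p = _write(tmp_path, "s.gmt", "T1\tdesc\tg1\tg2\tg1\nT2\tdesc\tg3\n")
        coll = io.read_gene_sets(p)
        assert coll.genes("T1") == frozenset({"g1", "g2"})
        assert coll.universe == frozenset({"g1", "g2", "g3"})

    def test_short_lines_skipped_with_warning(self, tmp_path):
        p = _write(tmp_path, "s.gmt", "T1\tdesc\tg1\nT2\tdesc\n")
        with pytest.warns(UserWarning, match="1 malformed"):
            coll = io.read_gene_sets(p)
        assert coll.n_skipped == 1 and len(coll) == 1

    def test_round_trip(self, tmp_path):
        p = _write(tmp_path, "s.gmt", "T1\tdesc\tg1\tg2\nT2\tother\tg3\n")
        coll = io.read_gene_sets(p)
        out = tmp_path / "out.gmt"
        io.write_gene_sets(coll, out)
        assert io.read_gene_sets(out).sets == coll.sets


class TestPPI:
    def test_self_loops_and_duplicates_collapse(self, tmp_path):
        p = _write(tmp_path, "ppi.csv", "a,b\na,b\nb,a\na,a\n")
        g = io.read_ppi(p)
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 1

    def test_triangle(self, tmp_path):
        p = _write(tmp_path, "ppi.csv", "x,y\na,b\nb,c\nc,a\n")
        g = io.read_ppi(p)
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 3

    def test_tsv_detected(self, tmp_path):
        p = _write(tmp_path, "ppi.tsv", "x\ty\na\tb\n")
        assert io.read_ppi(p).has_edge("a", "b")

    def test_empty_rejected(self, tmp_path):
        p = _write(tmp_path, "ppi.csv", "a,b\n")
        with pytest.raises(FormatError):
            io.read_ppi(p)

    @settings(max_examples=50, deadline=None)
    @given(
        edges=st.lists(
            st.tuples(st.integers(0, 8), st.integers(0, 8)), min_size=1, max_size=30
        )
    )
    def test_simple_graph_invariant_random_edge_lists(self, edges, tmp_path_factory):
        tmp = tmp_path_factory.mktemp("ppi")
        p = tmp / "e.csv"
        p.write_text("a,b\n" + "\n".join(f"n{u},n{v}" for u, v in edges) + "\n")
        try:
            g = io.read_ppi(p)
        except FormatError:
            assert all(u == v for u, v in edges)
            return
        assert not any(u == v for u, v in g.edges)
        assert not g.is_multigraph()

    def test_round_trip_csv(self, tmp_path):
        p = _write(tmp_path, "ppi.csv", "x,y\na,b\nb,c\n")
        g = io.read_ppi(p)
        out = tmp_path / "out.csv"
        io.write_ppi(g, out)
        g2 = io.read_ppi(out)
        assert set(map(frozenset, g.edges)) == set(map(frozenset, g2.edges))


class TestRetrieval:
    LINKS = [
        HerbCompoundLink("H1", "C1"),
        HerbCompoundLink("H1", "C2"),
        HerbCompoundLink("H2", "C2"),
        HerbCompoundLink("H2", "C3"),
        HerbCompoundLink("H1", "ZYGHJZDHTFUPRJ-UHFFFAOYSA-N"),
    ]

    def test_inchikey_lookup(self):
        assert io.lookup_compound("ZYGHJZDHTFUPRJ-UHFFFAOYSA-N", self.LINKS) == {"H1"}

    def test_unknown_valid_key_gives_empty(self):
        assert io.lookup_compound("AAAAAAAAAAAAAA-BBBBBBBBBB-C", self.LINKS) == set()

    def test_malformed_key_rejected(self):
        with pytest.raises(ValueError, match="InChIKey"):
            io.lookup_compound("not-a-key", self.LINKS)

    def test_local_id_accepted(self):
        assert io.lookup_compound("C2", self.LINKS) == {"H1", "H2"}

    def test_union_over_herbs(self):
        fc = io.formula_compounds(["H1", "H2"], self.LINKS)
        assert fc.compound_ids >= {"C1", "C2", "C3"}

    def test_all_unmatched_is_error(self):
        with pytest.raises(ValueError, match="H9"):
            io.formula_compounds(["H9"], self.LINKS)

    def test_partial_match_warns(self):
        with pytest.warns(UserWarning, match="H9"):
            fc = io.formula_compounds(["H1", "H9"], self.LINKS)
        assert fc.unmatched_herbs == ["H9"]
        assert {"C1", "C2"} <= fc.compound_ids


class TestDomainInvariants:
    def test_duplicate_prescription_key_rejected(self):
        with pytest.raises(ValueError):
            PrescriptionDataset(
                [
                    Prescription("p1", "v1", frozenset("a")),
                    Prescription("p1", "v1", frozenset("b")),
                ]
            )

    def test_empty_prescription_rejected(self):
        with pytest.raises(ValueError):
            Prescription("p1", "v1", frozenset())

    def test_score_range_enforced(self):
        with pytest.raises(ValueError):
            ScoredLink("C1", "T1", 1001)
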