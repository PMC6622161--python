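import random

import pytest

from lipoclass import (
    HitFixtureSpec,
    SearchHit,
    TaxonomyRecord,
    expanded_filter,
    load_taxonomy,
    make_hit_fixture,
    origin_check,
    parse_search_hits,
    strict_filter,
    summarize_taxa,
)
from lipoclass.occurrence import (
    expanded_overall_identity_bound_pct,
    strict_overall_identity_bound_pct,
    write_search_hits,
)


def hit(identity=90.0, qcov=90.0, scov=90.0, query_id="q1", subject_id="s1",
        qlen=200, slen=200):
    qspan = round(qcov / 100 * qlen)
    sspan = round(scov / 100 * slen)
    return SearchHit(
        query_id=query_id,
        subject_id=subject_id,
        percent_identity=identity,
        alignment_length=max(qspan, sspan),
        mismatches=0,
        gap_opens=0,
        query_start=1,
        query_end=qspan,
        subject_start=1,
        subject_end=sspan,
        evalue=1e-30,
        bitscore=150.0,
        query_length=qlen,
        subject_length=slen,
    )


class TestParsing:
    def test_well_formed_row_derives_coverage(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "prot1\tgenome1\t85.500\t180\t26\t0\t11\t190\t1\t170\t1e-80\t"
            "311.0\t200\t250\n"
        )
        (h,) = parse_search_hits(path)
        assert h.percent_identity == 85.5
        assert h.query_coverage == pytest.approx(100 * 180 / 200)
        assert h.subject_coverage == pytest.approx(100 * 170 / 250)

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("")
        assert parse_search_hits(path) == []

    def test_twelve_column_row_names_missing_length_columns(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "p\tg\t85.5\t180\t26\t0\t11\t190\t1\t170\t1e-80\t311.0\n"
        )
        with pytest.raises(ValueError, match="query_length and.*subject_length"):
            parse_search_hits(path)

    def test_non_numeric_field_reports_row(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "p\tg\thigh\t180\t26\t0\t11\t190\t1\t170\t1e-80\t311.0\t200\t250\n"
        )
        with pytest.raises(ValueError, match="row 1"):
            parse_search_hits(path)

    def test_coordinates_outside_length_fail(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "p\tg\t85.5\t180\t26\t0\t11\t290\t1\t170\t1e-80\t311.0\t200\t250\n"
        )
        with pytest.raises(ValueError, match="coordinates"):
            parse_search_hits(path)

    def test_round_trip(self, tmp_path):
        hits = make_hit_fixture(HitFixtureSpec(n_hits=10, seed=3)).hits
        path = tmp_path / "hits.tsv"
        write_search_hits(hits, path)
        assert parse_search_hits(path) == hits


class TestFilters:
    @pytest.mark.parametrize(
        "identity,qcov,scov,kept",
        [
            (85, 90, 85, True),
            (85, 70, 90, False),
            (80, 90, 90, False),  # thresholds are exclusive
            (90, 80, 90, False),
            (90, 90, 80, False),
        ],
    )
    def test_strict_rule(self, identity, qcov, scov, kept):
        hits = [hit(identity, qcov, scov)]
        assert (strict_filter(hits) == hits) is kept

    @pytest.mark.parametrize(
        "identity,qcov,scov,kept",
        [
            (65, 85, 10, True),  # subject coverage unconstrained
            (55, 95, 95, False),
            (60, 95, 95, False),  # exclusive
            (65, 80, 95, False),
        ],
    )
    def test_expanded_rule(self, identity, qcov, scov, kept):
        hits = [hit(identity, qcov, scov)]
        assert (expanded_filter(hits) == hits) is kept

    def test_strict_is_subset_of_expanded(self):
        rng = random.Random(23)
        for _ in range(100):
            hits = [
                hit(
                    identity=rng.uniform(0, 100),
                    qcov=rng.uniform(1, 100),
                    scov=rng.uniform(1, 100),
                    query_id=f"q{i}",
                    subject_id=f"s{i}",
                )
                for i in range(20)
            ]
            strict = strict_filter(hits)
            expanded = expanded_filter(hits)
            assert all(h in expanded for h in strict)

    def test_filters_idempotent_and_order_preserving(self):
        hits = make_hit_fixture(HitFixtureSpec(n_hits=30, seed=5)).hits
        for f in (strict_filter, expanded_filter):
            once = f(hits)
            assert f(once) == once
            assert once == [h for h in hits if h in once]

    def test_overall_identity_bounds(self):
        assert strict_overall_identity_bound_pct() == pytest.approx(64.0)
        assert expanded_overall_identity_bound_pct() == pytest.approx(48.0)


class TestTaxaSummary:
    def _taxonomy(self):
        lineages = {
            "g1": "Bacteria;Firmicutes;Bacilli;Bacillales;Bacillaceae;Bacillus",
            "g2": "Bacteria;Firmicutes;Bacilli;Bacillales;Bacillaceae;Geobacillus",
            "g3": "Bacteria;Firmicutes;Bacilli;Bacillales;Bacillaceae;Anoxybacillus",
            "g4": "Bacteria;Firmicutes;Bacilli;Bacillales;Bacillaceae;Parageobacillus",
        }
        return {
            k: TaxonomyRecord(k, tuple(v.split(";"))) for k, v in lineages.items()
        }

    def test_four_genera_one_family(self):
        """Hits in four genera of one family: genus count 4, family count 1."""
        hits = [hit(query_id="Est30", subject_id=f"g{i}") for i in range(1, 5)]
        tax = self._taxonomy()
        by_genus = summarize_taxa(hits, tax, rank="genus")
        assert len(by_genus) == 4
        assert set(by_genus["taxon"]) == {
            "Bacillus", "Geobacillus", "Anoxybacillus", "Parageobacillus"
        }
        by_family = summarize_taxa(hits, tax, rank="family")
        assert len(by_family) == 1
        assert by_family.loc[0, "taxon"] == "Bacillaceae"
        assert by_family.loc[0, "n_subjects"] == 4

    def test_no_hits_empty_summary(self):
        assert summarize_taxa([], self._taxonomy(), rank="genus").empty

    def test_repeated_subject_counts_once(self):
        hits = [hit(query_id="q", subject_id="g1") for _ in range(3)]
        df = summarize_taxa(hits, self._taxonomy(), rank="genus")
        assert df.loc[0, "n_subjects"] == 1
        assert summarize_taxa(hits * 2, self._taxonomy(), rank="genus").equals(df)

    def test_unknown_subject_counted_unresolved(self):
        hits = [hit(query_id="q", subject_id="mystery")]
        df = summarize_taxa(hits, self._taxonomy(), rank="genus")
        assert df.loc[0, "taxon"] == "unresolved"

    def test_taxonomy_tsv_loader(self, tmp_path):
        path = tmp_path / "tax.tsv"
        path.write_text(
            "g1\tBacteria;Firmicutes;Bacilli;Bacillales;Bacillaceae;Bacillus\n"
            "g9\tBacteria;Proteobacteria\n"
        )
        tax = load_taxonomy(path)
        assert tax["g1"].rank("genus") == "Bacillus"
        assert tax["g1"].superkingdom == "Bacteria"
        assert tax["g9"].rank("genus") == ""  # truncated lineage


class TestOriginCheck:
    BACTERIAL = ["Bacteria;Firmicutes"] * 10
    MOSTLY = ["Bacteria;Firmicutes"] * 9 + ["Eukaryota;Ascomycota"]

    def test_strict_match_confirms_regardless_of_top10(self):
        res = origin_check("q", [hit()], self.MOSTLY)
        assert res.decision == "bacterial_confirmed"
        assert res.basis == "strict_genome_match"

    def test_all_top10_bacterial_included(self):
        res = origin_check("q", [], self.BACTERIAL)
        assert res.decision == "included"
        assert res.basis == "top10_all_bacterial"

    def test_one_non_bacterial_lineage_excludes(self):
        res = origin_check("q", [], self.MOSTLY)
        assert res.decision == "excluded"
        assert res.basis == "non_bacterial_in_top10"

    def test_fewer_than_ten_hits_all_examined(self):
        assert origin_check("q", [], ["Bacteria"] * 3).decision == "included"

    def test_only_first_k_hits_examined(self):
        taxa = ["Bacteria"] * 10 + ["Eukaryota"]
        assert origin_check("q", [], taxa, k=10).decision == "included"

    def test_no_evidence_is_indeterminate(self):
        with pytest.raises(ValueError, match="indeterminate"):
            origin_check("q", [], [])
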