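"""Guild annotation of abundance tables and cross-checks with isotopes."""

import pandas as pd
import pytest

from mudgas.biodeg import SecondaryMethaneReport
from mudgas.guilds import (
    GuildLookup,
    GuildRule,
    GuildTable,
    annotate,
    assign_guild,
    consistency_report,
    load_guild_lookup,
    read_abundance_table,
)


@pytest.fixture(scope="module")
def lookup():
    return load_guild_lookup()


def table(data: dict, percent=True, samples=("M1", "M2")) -> GuildTable:
    df = pd.DataFrame(data, index=list(samples)).T
    return GuildTable(df.astype(float), percent)


CONSISTENT = SecondaryMethaneReport(
    True, 15.0, -0.9, 0.9, "consistent with secondary methanogenesis"
)
NOT_CONSISTENT = SecondaryMethaneReport(False, 15.0, 0.1, 0.1, "not consistent")


class TestAssignGuild:
    def test_bare_genus(self, lookup):
        assert assign_guild("Methanoregula", lookup) == "hydrogenotrophic_methanogen"
        assert assign_guild("Geobacter", lookup) == "iron_reducer"

    def test_silva_lineage_family(self, lookup):
        lin = "d__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Betaproteobacteriales;f__Rhodocyclaceae;g__Azoarcus"
        assert assign_guild(lin, lookup) == "nitrate_reducing_alkane_oxidizer"

    def test_most_specific_rank_wins(self, lookup):
        """Geobacter (genus, iron reducer) inside Desulfuromonadales (order,
        sulfate reducer lineage) resolves to the genus rule."""
        lin = "o__Desulfuromonadales;f__Geobacteraceae;g__Geobacter"
        assert assign_guild(lin, lookup) == "iron_reducer"

    def test_order_rule_without_genus_hit(self, lookup):
        lin = "o__Desulfobacterales;f__Desulfobacteraceae;g__SEEP-SRB1"
        assert assign_guild(lin, lookup) == "sulfate_reducer"

    def test_unmatched_is_other(self, lookup):
        assert assign_guild("g__Flavobacterium", lookup) == "other"

    def test_same_rank_conflict_raises(self):
        lk = GuildLookup(
            (
                GuildRule("Methano", "genus", "hydrogenotrophic_methanogen"),
                GuildRule("regula", "genus", "iron_reducer"),
            )
        )
        with pytest.raises(ValueError, match="disambiguate"):
            assign_guild("g__Methanoregula", lk)

    def test_anme_any_rank(self, lookup):
        assert assign_guild("o__ANME-1;g__ANME-1a", lookup) == "ANME"


class TestAnnotate:
    def test_single_match_sums(self, lookup):
        t = table({"Methanoregula": [5.0, 2.0], "Unknownium": [10.0, 10.0]})
        s = annotate(t, lookup)
        assert s.abundance.loc["hydrogenotrophic_methanogen"].tolist() == [5.0, 2.0]
        assert s.abundance.loc["other"].tolist() == [10.0, 10.0]
        assert s.matched["hydrogenotrophic_methanogen"] == ["Methanoregula"]

    def test_empty_lookup_all_other(self):
        t = table({"Methanoregula": [5.0, 2.0]})
        s = annotate(t, GuildLookup(()))
        assert s.abundance.loc["other"].tolist() == [5.0, 2.0]

    def test_anme_presence_pattern(self, lookup):
        t = table({"ANME-2b": [0.5, 0.0]})
        s = annotate(t, lookup)
        anme = s.abundance.loc["ANME"]
        assert anme["M1"] == 0.5 and anme["M2"] == 0.0

    def test_permutation_invariance(self, lookup):
        names = ["Methanoregula", "Geobacter", "Unknownium", "ANME-1"]
        t1 = table({n: [1.0, 2.0] for n in names})
        t2 = table({n: [1.0, 2.0] for n in reversed(names)})
        s1, s2 = annotate(t1, lookup), annotate(t2, lookup)
        pd.testing.assert_frame_equal(s1.abundance, s2.abundance)

    def test_guild_sums_bounded_by_totals(self, lookup):
        t = table({"Methanoregula": [5.0, 2.0], "Geobacter": [1.0, 3.0]})
        s = annotate(t, lookup)
        assert (s.abundance.sum(axis=0) <= t.abundance.sum(axis=0) + 1e-12).all()

    def test_empty_table_rejected(self, lookup):
        with pytest.raises(ValueError):
            annotate(GuildTable(pd.DataFrame(), percent=True), lookup)


class TestReadAbundanceTable:
    def test_wide_taxa_as_rows(self, tmp_path, lookup):
        p = tmp_path / "t.tsv"
        p.write_text("taxon\tM1\tM2\nMethanoregula\t5\t2\nOtherium\t95\t98\n")
        t = read_abundance_table(p, lookup)
        assert t.percent and list(t.abundance.columns) == ["M1", "M2"]

    def test_wide_taxa_as_columns_transposed(self, tmp_path, lookup):
        p = tmp_path / "t.csv"
        p.write_text("sample,Methanoregula,Otherium\nM1,5,95\nM2,2,98\n")
        t = read_abundance_table(p, lookup)
        assert "Methanoregula" in t.abundance.index
        assert list(t.abundance.columns) == ["M1", "M2"]

    def test_long_format(self, tmp_path, lookup):
        p = tmp_path / "t.csv"
        p.write_text(
            "taxon,sample,abundance\nMethanoregula,M1,0.05\nMethanoregula,M2,0.02\n"
            "Otherium,M1,0.95\nOtherium,M2,0.98\n"
        )
        t = read_abundance_table(p, lookup)
        assert not t.percent
        assert t.abundance.loc["Methanoregula", "M1"] == 0.05

    def test_oversum_rejected(self, tmp_path, lookup):
        p = tmp_path / "t.csv"
        p.write_text("taxon,M1\nA,80\nB,60\n")
        with pytest.raises(ValueError, match="exceed"):
            read_abundance_table(p, lookup)


class TestConsistencyReport:
    def test_methanogens_plus_isotopes_support_yes(self, lookup):
        t = table({"Methanoregula": [5.0, 2.0], "Geobacter": [1.0, 0.5], "ANME-1": [0.5, 0.0]})
        rep = consistency_report(annotate(t, lookup), CONSISTENT)
        assert rep.secondary_methanogenesis_support == "yes"
        assert "iron_reducer" in rep.c2plus_oxidizer_candidates
        assert "likely minor" in rep.aom_note

    def test_all_zero_guilds_no_support(self, lookup):
        t = table({"Unknownium": [100.0, 100.0]})
        rep = consistency_report(annotate(t, lookup), NOT_CONSISTENT)
        assert rep.secondary_methanogenesis_support == "no/indeterminate"
        assert rep.c2plus_oxidizer_candidates == ()

    def test_isotope_only_support(self, lookup):
        t = table({"Unknownium": [100.0, 100.0]})
        rep = consistency_report(annotate(t, lookup), CONSISTENT)
        assert rep.secondary_methanogenesis_support == "isotope-only support"

    def test_no_overlapping_samples_warns(self, lookup):
        t = table({"Methanoregula": [5.0, 2.0]})
        rep = consistency_report(
            annotate(t, lookup), CONSISTENT, biodeg_sample_ids=["X1", "X2"]
        )
        assert rep.warnings and rep.overlapping_samples == ()

    def test_anme_above_threshold_noted(self, lookup):
        t = table({"ANME-2a": [5.0, 0.0], "Methanoregula": [1.0, 1.0]})
        rep = consistency_report(annotate(t, lookup), CONSISTENT)
        assert "above the minor threshold" in rep.aom_note
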