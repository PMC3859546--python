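import numpy as np
import pytest

from ovismt.datasets import oylum_ancient_genotypes
from ovismt.haplogroups import (
    DiagnosticTable,
    classify,
    classify_genotype_table,
    classify_observed,
    default_diagnostic_table,
    frequency_table,
    parse_repeats,
    stratify_by_era,
)
from ovismt.seqio import AlignedSeq, CoordinateMap, SeqRecord
from ovismt.synthetic import (
    REF_START,
    default_panel_specs,
    gen_haplogroup_panel,
    synthetic_reference,
)

from conftest import anchor_panel_record


@pytest.fixture(scope="module")
def table() -> DiagnosticTable:
    return default_diagnostic_table()


class TestClassifyObserved:
    @pytest.mark.parametrize(
        "observed, expected",
        [
            # published genotype rows, dot = reference base
            ({15459: "T", 15476: ".", 15484: "A", 15509: ".", 15512: "."}, "A"),
            ({15459: ".", 15476: ".", 15484: ".", 15509: ".", 15512: "."}, "B"),
            ({15459: ".", 15476: "C", 15484: ".", 15509: "G", 15512: "."}, "E"),
            ({15459: ".", 15476: ".", 15484: ".", 15509: "G", 15512: "."}, "C"),
            # complete A signature plus private variants elsewhere
            ({15459: "T", 15476: "T", 15484: "A", 15509: "A", 15512: "T"}, "A"),
            # partial A signature: never resolved to nearest match
            ({15459: "T", 15476: ".", 15484: ".", 15509: ".", 15512: "."}, "unassigned"),
            # matches nothing
            ({15459: "G", 15476: ".", 15484: ".", 15509: ".", 15512: "."}, "unassigned"),
        ],
    )
    def test_signature_matching(self, table, observed, expected):
        call = classify_observed("s", observed, table)
        assert call.haplogroup == expected

    def test_missing_sites_exceed_budget(self, table):
        call = classify_observed(
            "s", {15459: "N", 15476: ".", 15484: ".", 15509: ".", 15512: "."}, table
        )
        assert call.haplogroup == "unassigned" and call.n_missing == 1

    def test_missing_site_allowed_with_budget(self, table):
        call = classify_observed(
            "s",
            {15459: "N", 15476: ".", 15484: ".", 15509: ".", 15512: "."},
            table,
            max_missing=1,
        )
        assert call.haplogroup == "B" and call.n_missing == 1

    def test_shared_signature_rejected(self):
        with pytest.raises(ValueError, match="share"):
            DiagnosticTable(
                {"B": {}, "Y": {15459: "T"}, "Z": {15459: "T"}}
            )


class TestAncientTable:
    def test_frequencies_match_published(self):
        calls = classify_genotype_table(oylum_ancient_genotypes())
        ft = frequency_table(calls).set_index("haplogroup")
        assert ft.loc["A", "count"] == 16 and ft.loc["A", "percent"] == 48.5
        assert ft.loc["B", "count"] == 14 and ft.loc["B", "percent"] == 42.4
        assert ft.loc["C", "count"] == 2 and ft.loc["C", "percent"] == 6.1
        assert ft.loc["E", "count"] == 1 and ft.loc["E", "percent"] == 3.0

    def test_calls_agree_with_published_column(self):
        geno = oylum_ancient_genotypes()
        calls = classify_genotype_table(geno)
        assert [c.haplogroup for c in calls] == list(geno["published_hpg"])

    def test_era_strata_counts(self):
        geno = oylum_ancient_genotypes()
        calls = classify_genotype_table(geno)
        strata = stratify_by_era(geno, [(1800, 1200), (1200, 330)])
        assert len(strata) == 32  # the single 330-30 BCE sample joins neither
        ft = frequency_table(
            [c for c in calls if c.sample_id in strata], strata
        ).set_index(["stratum", "haplogroup"])
        assert ft.loc[("1800-1200 BCE", "A"), "count"] == 8
        assert ft.loc[("1800-1200 BCE", "A"), "n"] == 16
        assert ft.loc[("1200-330 BCE", "A"), "count"] == 8
        assert ft.loc[("1200-330 BCE", "A"), "n"] == 16
        assert ft.loc[("1800-1200 BCE", "B"), "count"] == 7
        assert ft.loc[("1200-330 BCE", "B"), "count"] == 6


class TestClassifySequences:
    def test_round_trip_on_panel(self, panel, syn_ref_aligned):
        """With private mutations kept off the diagnostic sites, every
        synthetic sequence classifies back to its true haplogroup."""
        table = default_diagnostic_table(extra_rules={"X": {15466: "T"}})
        for rec in panel:
            call = classify(
                anchor_panel_record(rec), table, syn_ref_aligned
            )
            assert call.haplogroup == rec.meta["true_hpg"]


class TestRepeats:
    def _aligned(self, rec):
        return anchor_panel_record(rec)

    def test_cluster_i_four_units(self):
        specs = [s for s in default_panel_specs() if s.name == "B"]
        recs = gen_haplogroup_panel(specs, 6, private_mut_rate=0.5, seed=8)
        for rec in recs:
            prof = parse_repeats(self._aligned(rec))
            assert prof.n_units == rec.meta["n_units"]
            assert all(u == 75 for u in prof.unit_lengths)
            assert prof.cluster == "i"

    def test_cluster_ii_five_units(self):
        specs = [s for s in default_panel_specs() if s.name == "C"]
        recs = gen_haplogroup_panel(specs, 30, private_mut_rate=0.5, seed=9)
        five = [r for r in recs if r.meta["n_units"] == 5]
        rec = five[0] if five else recs[0]
        prof = parse_repeats(self._aligned(rec))
        assert prof.unit_lengths[0] == 75
        assert all(u == 76 for u in prof.unit_lengths[1:])
        assert prof.cluster == "ii"

    def test_missing_repeat_region_raises(self):
        rng = np.random.default_rng(0)
        res = "".join(rng.choice(list("ACGT"), size=900))
        rec = SeqRecord("norep", res)
        aln = AlignedSeq(rec, CoordinateMap.identity(REF_START, 900))
        with pytest.raises(ValueError, match="repeat region not found"):
            parse_repeats(aln)

    def test_cluster_consistency_with_haplogroup(self, panel, syn_ref_aligned):
        """Repeat cluster i <=> call in {A,B,D}; ii <=> {C,E,X}."""
        table = default_diagnostic_table(extra_rules={"X": {15466: "T"}})
        for rec in panel:
            aln = anchor_panel_record(rec)
            call = classify(aln, table, syn_ref_aligned)
            prof = parse_repeats(aln)
            if call.haplogroup in {"A", "B", "D"}:
                assert prof.cluster == "i"
            else:
                assert prof.cluster == "ii"


class TestFrequencyTable:
    def test_single_call_is_100_percent(self, table):
        call = classify_observed("s", {p: "." for p in table.positions}, table)
        call.haplogroup = "A"
        ft = frequency_table([call])
        assert ft.loc[0, "percent"] == 100.0

    def test_counts_sum_to_input_size(self):
        calls = classify_genotype_table(oylum_ancient_genotypes())
        ft = frequency_table(calls)
        assert ft["count"].sum() == len(calls)
        assert abs(ft["percent"].sum() - 100.0) < 0.2  # rounding slack

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            frequency_table([])
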