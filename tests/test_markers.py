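"""MLG census, accumulation curves, and the per-locus / per-stratum
diversity index suite."""

import numpy as np
import pytest

from ssrpop.io import MISSING, GenotypeMatrix, LocusInfo
from ssrpop.markers import (
    allele_frequencies,
    genotype_accumulation,
    identify_mlgs,
    locus_indices,
    nm_from_fst,
    per_locus_fst,
    pic,
    private_and_diagnostic_alleles,
    stratum_diversity,
)

from conftest import make_genotypes


class TestMLGs:
    def test_identical_accessions_share_one_mlg(self):
        g = make_genotypes([[(200, 204), (150, 150)], [(204, 200), (150, 150)]])
        assert identify_mlgs(g).n_mlgs == 1

    def test_one_allele_difference_separates(self):
        g = make_genotypes([[(200, 204)], [(200, 206)]])
        assert identify_mlgs(g).n_mlgs == 2

    def test_missing_locus_is_wildcard_with_transitive_closure(self):
        # A2 has L1 missing, matches both A1 and A3 which differ at L1:
        # transitive closure merges all three
        g = make_genotypes(
            [
                [(200, 200), (150, 150)],
                [(MISSING, MISSING), (150, 150)],
                [(204, 204), (150, 150)],
            ]
        )
        assert identify_mlgs(g, "wildcard").n_mlgs == 1
        assert identify_mlgs(g, "strict").n_mlgs == 3

    def test_all_missing_accession_excluded(self):
        g = make_genotypes([[(200, 200)], [(MISSING, MISSING)]])
        with pytest.warns(UserWarning, match="A2"):
            res = identify_mlgs(g)
        assert "A2" not in res.mlg_of


class TestAccumulation:
    def test_monomorphic_panel_flatlines_at_one(self):
        g = make_genotypes([[(200, 200)] * 5] * 4)
        curve = genotype_accumulation(g, n_perm=20, seed=0)
        assert (curve["median_mlgs"] == 1).all()

    def test_median_curve_monotone_nondecreasing(self, small_panel):
        curve = genotype_accumulation(small_panel.genotypes, n_perm=30, seed=1)
        assert (np.diff(curve["median_mlgs"]) >= 0).all()

    def test_discriminating_locus_saturates_and_matches_census(self):
        # locus 1 separates all four accessions; loci 2-5 are monomorphic
        calls = [
            [(200 + 2 * i, 200 + 2 * i)] + [(150, 150)] * 4 for i in range(4)
        ]
        g = make_genotypes(calls)
        curve = genotype_accumulation(g, n_perm=50, seed=2)
        full = identify_mlgs(g).n_mlgs
        assert curve.attrs["full_mlg_count"] == full == 4
        assert curve["max_mlgs"].iloc[0] == 4  # subsets containing locus 1
        assert curve.attrs["saturated"]


class TestAlleleFrequencies:
    def test_single_homozygote(self):
        g = make_genotypes([[(200, 200)]])
        freqs = allele_frequencies(g)
        assert freqs["all"]["L1"] == {200: 1.0}

    def test_three_quarters_one_quarter(self):
        g = make_genotypes([[(200, 204)], [(200, 200)]])
        freqs = allele_frequencies(g)["all"]["L1"]
        assert freqs == {200: 0.75, 204: 0.25}

    def test_frequencies_sum_to_one_everywhere(self, small_panel):
        g = small_panel.genotypes
        strata = {"first": g.accession_ids[:40], "rest": g.accession_ids[40:]}
        table = allele_frequencies(g, strata)
        for label in table:
            for loc, freqs in table[label].items():
                if freqs:
                    assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-12)


class TestPIC:
    @pytest.mark.parametrize(
        "freqs,expected",
        [
            ({200: 1.0}, 0.0),
            ({200: 0.5, 204: 0.5}, 0.5),
            ({1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25}, 0.75),
        ],
    )
    def test_hand_values(self, freqs, expected):
        assert pic(freqs) == pytest.approx(expected, abs=1e-12)


class TestLocusIndices:
    def test_hand_worked_two_allele_locus(self):
        # 7 AA + 3 BB homozygotes: p = (0.7, 0.3)
        g = make_genotypes([[(200, 200)]] * 7 + [[(204, 204)]] * 3)
        idx = locus_indices(g).iloc[0]
        assert idx["Ne"] == pytest.approx(1.0 / 0.58, abs=1e-9)
        assert idx["He"] == pytest.approx(0.42, abs=1e-9)
        assert idx["I"] == pytest.approx(
            -(0.7 * np.log(0.7) + 0.3 * np.log(0.3)), abs=1e-9
        )
        assert idx["Fis"] == 1.0  # Ho = 0 with He > 0

    def test_fixed_alternate_alleles_give_fst_one(self, two_pop_fixed):
        g, strata = two_pop_fixed
        fst = per_locus_fst(g, strata)
        np.testing.assert_allclose(fst.values, 1.0)

    def test_heterozygote_excess_gives_negative_fis(self):
        g = make_genotypes([[(200, 204)], [(200, 204)]])
        idx = locus_indices(g).iloc[0]
        assert idx["Ho"] == 1.0
        assert idx["Fis"] == pytest.approx(-1.0, abs=1e-12)

    def test_he_equals_pic_on_same_frequencies(self, small_panel):
        g = small_panel.genotypes
        idx = locus_indices(g)
        np.testing.assert_allclose(idx["He"].values, idx["PIC"].values, atol=1e-12)

    def test_ne_bounded_by_na_with_equality_iff_equifrequent(self, small_panel):
        idx = locus_indices(small_panel.genotypes)
        assert (idx["Ne"] <= idx["Na"] + 1e-12).all()
        g = make_genotypes([[(200, 200)], [(204, 204)]])
        eq = locus_indices(g).iloc[0]
        assert eq["Ne"] == pytest.approx(eq["Na"], abs=1e-12)


class TestStratumDiversity:
    def test_nm_formula(self):
        assert nm_from_fst(0.2) == pytest.approx(1.0, abs=1e-12)
        assert np.isinf(nm_from_fst(0.0))

    def test_constructed_fst_one_third_gives_nm_half(self):
        # stratum A fixed for allele 200; stratum B at 0.5/0.5:
        # Hs = 0.25, Ht = 0.375, Fst = 1/3, Nm = 0.25*(2/3)/(1/3) = 0.5
        g = make_genotypes(
            [[(200, 200)], [(200, 200)], [(200, 200)], [(204, 204)]]
        )
        strata = {"A": ["A1", "A2"], "B": ["A3", "A4"]}
        table = stratum_diversity(g, strata)
        assert table.attrs["mean_fst"] == pytest.approx(1 / 3, abs=1e-12)
        assert table.attrs["nm"] == pytest.approx(0.5, abs=1e-12)

    def test_cloned_strata_have_zero_fst_infinite_nm(self):
        g = make_genotypes(
            [[(200, 204)], [(208, 208)], [(200, 204)], [(208, 208)]]
        )
        strata = {"A": ["A1", "A2"], "B": ["A3", "A4"]}
        table = stratum_diversity(g, strata)
        assert table.attrs["mean_fst"] == pytest.approx(0.0, abs=1e-12)
        assert np.isinf(table.attrs["nm"])

    def test_fifty_percent_polymorphic(self):
        # exactly 5 of 10 loci variable in the stratum
        calls = []
        for i in range(4):
            row = []
            for j in range(10):
                if j < 5:
                    row.append((200 + 2 * (i % 2), 200 + 2 * (i % 2)))
                else:
                    row.append((150, 150))
            calls.append(row)
        g = make_genotypes(calls)
        table = stratum_diversity(
            g, {"S": ["A1", "A2"], "T": ["A3", "A4"]}
        )
        assert table.loc["S", "percent_polymorphic"] == 50.0

    def test_single_stratum_flags_undefined_fst(self):
        g = make_genotypes([[(200, 204)], [(200, 200)]])
        with pytest.warns(UserWarning, match="single stratum"):
            table = stratum_diversity(g, {"only": ["A1", "A2"]})
        assert np.isnan(table.attrs["mean_fst"])


class TestPrivateDiagnostic:
    def _table(self, fa, fb):
        return {"A": {"L1": fa}, "B": {"L1": fb}}

    def test_private_and_diagnostic(self):
        pa, da = private_and_diagnostic_alleles(
            self._table({1: 0.8, 2: 0.2}, {2: 0.5, 3: 0.5})
        )
        assert pa["A"] == 1  # allele 1 only in A
        assert pa["B"] == 1  # allele 3 only in B
        da_a = da[da["stratum"] == "A"]
        assert len(da_a) == 1 and da_a.iloc[0]["allele"] == 1
        assert da[da["stratum"] == "B"].empty

    def test_shared_frequent_allele_is_neither(self):
        # 0.8 in A but 0.4 in B fails the <30% arm
        pa, da = private_and_diagnostic_alleles(
            self._table({1: 0.8, 2: 0.2}, {1: 0.4, 2: 0.6})
        )
        assert pa["A"] == 0 and pa["B"] == 0
        assert da[da["allele"] == 1].empty

    def test_rare_private_allele_not_diagnostic(self):
        pa, da = private_and_diagnostic_alleles(
            self._table({1: 0.1, 2: 0.9}, {2: 1.0})
        )
        assert pa["A"] == 1
        assert da[da["allele"] == 1].empty
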