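"""Pathogenic-variant stage: filtering, catalog matching, frequencies,
reference correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import brcaness.variants as v
from brcaness.errors import AnalysisError
from brcaness.frequency import FrequencyMatrix, frequency_matrix, correlate_with_references


def make_variants(rows):
    cols = ["Tumor_Sample_Barcode", "Hugo_Symbol", "Chromosome", "Start_Position",
            "Reference_Allele", "Tumor_Seq_Allele2", "Variant_Classification",
            "FILTER", "origin"]
    return pd.DataFrame(rows, columns=cols)


def make_catalog(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "gene",
                                       "clinical_significance", "source"])


class TestFilter:
    def test_toy_counts(self):
        """10 rows: 4 silent, 1 failing filter, 5 passing non-silent -> 5."""
        rows = []
        for i in range(4):
            rows.append((f"S{i}", "ATM", "chr11", 100 + i, "A", "G", "Silent",
                         "PASS", "somatic"))
        rows.append(("S4", "ATM", "chr11", 104, "A", "G", "Missense_Mutation",
                     "artifact", "somatic"))
        for i in range(5):
            rows.append((f"S{5 + i}", "ATM", "chr11", 105 + i, "A", "G",
                         "Missense_Mutation", "PASS", "somatic"))
        out = v.filter_variants(make_variants(rows))
        assert len(out) == 5
        assert (out["Variant_Classification"] == "Missense_Mutation").all()

    def test_unknown_classification_excluded(self):
        rows = [("S0", "ATM", "chr11", 100, "A", "G", "Weird_Class", "PASS", "somatic"),
                ("S1", "ATM", "chr11", 101, "A", "G", "Nonsense_Mutation", "PASS", "somatic")]
        out = v.filter_variants(make_variants(rows))
        assert list(out["Variant_Classification"]) == ["Nonsense_Mutation"]


class TestNormalizeKey:
    @pytest.mark.parametrize("key,expected", [
        (("chr1", 100, "A", "G"), ("chr1", 100, "A", "G")),          # SNV unchanged
        (("chr1", 100, "CT", "CA"), ("chr1", 101, "T", "A")),        # shared prefix
        (("chr1", 100, "AG", "ATG"), ("chr1", 100, "A", "AT")),      # shared suffix
        (("chr1", 99, "CA", "CAT"), ("chr1", 100, "A", "AT")),       # padded insertion
        (("chr1", 100, "ATT", "AT"), ("chr1", 100, "AT", "A")),      # padded deletion
    ])
    def test_parsimony_trimming(self, key, expected):
        assert v.normalize_key(*key) == expected


class TestMatch:
    def test_empty_catalog(self):
        rows = [("S0", "ATM", "chr11", 100, "A", "G", "Missense_Mutation",
                 "PASS", "somatic")]
        out = v.match_plp(make_variants(rows), make_catalog([]))
        assert len(out) == 0

    def test_two_of_five_match(self):
        cat = make_catalog([
            ("chr11", 100, "A", "G", "ATM", "Pathogenic", "clinvar"),
            ("chr11", 200, "C", "T", "ATM", "Likely pathogenic", "clinvar"),
        ])
        rows = [("S0", "ATM", "chr11", 100, "A", "G", "Missense_Mutation", "PASS", "somatic"),
                ("S1", "ATM", "chr11", 200, "C", "T", "Missense_Mutation", "PASS", "somatic"),
                ("S2", "ATM", "chr11", 300, "A", "G", "Missense_Mutation", "PASS", "somatic"),
                ("S3", "ATM", "chr11", 400, "A", "G", "Missense_Mutation", "PASS", "somatic"),
                ("S4", "ATM", "chr11", 500, "A", "G", "Missense_Mutation", "PASS", "somatic")]
        out = v.match_plp(make_variants(rows), cat)
        assert sorted(out["Tumor_Sample_Barcode"]) == ["S0", "S1"]

    def test_matched_once_when_in_both_sources(self):
        cat = make_catalog([
            ("chr11", 100, "A", "G", "ATM", "Pathogenic", "clinvar"),
            ("chr11", 100, "A", "G", "ATM", "Pathogenic", "cosmic"),
        ])
        rows = [("S0", "ATM", "chr11", 100, "A", "G", "Missense_Mutation",
                 "PASS", "somatic")]
        out = v.match_plp(make_variants(rows), cat)
        assert len(out) == 1

    def test_padded_indel_matches_after_normalization(self):
        cat = make_catalog([("chr1", 100, "A", "AT", "ATM", "Pathogenic", "clinvar")])
        rows = [("S0", "ATM", "chr1", 99, "CA", "CAT", "Frame_Shift_Ins",
                 "PASS", "somatic")]
        assert len(v.match_plp(make_variants(rows), cat)) == 1


class TestFrequency:
    def test_three_carriers_among_fifty(self):
        sample_map = pd.Series("LUAD", index=[f"S{i}" for i in range(50)])
        rows = [(f"S{i}", "ATM", "chr11", 100, "A", "G", "Missense_Mutation",
                 "PASS", "somatic") for i in range(3)]
        freq = v.plp_frequency(make_variants(rows), sample_map, ["ATM", "ATR"])
        assert freq.freq.loc["ATM", "LUAD"] == pytest.approx(0.06)
        assert freq.freq.loc["ATR", "LUAD"] == 0.0

    def test_sample_with_two_plps_counted_once(self):
        sample_map = pd.Series("LUAD", index=[f"S{i}" for i in range(10)])
        rows = [("S0", "ATM", "chr11", 100, "A", "G", "Missense_Mutation", "PASS", "somatic"),
                ("S0", "ATM", "chr11", 200, "C", "T", "Missense_Mutation", "PASS", "somatic")]
        freq = v.plp_frequency(make_variants(rows), sample_map, ["ATM"])
        assert freq.numerator.loc["ATM", "LUAD"] == 1

    def test_type_without_samples_is_missing(self):
        sample_map = pd.Series("LUAD", index=["S0", "S1"])
        freq = v.plp_frequency(make_variants([]), sample_map, ["ATM"])
        assert "KIRC" not in freq.freq.columns
        assert freq.freq.reindex(columns=["KIRC"]).isna().all().all()

    def test_matches_brute_force_recount(self, small_cohort):
        bundle, _ = small_cohort
        matched = v.match_plp(v.filter_variants(bundle.variants), bundle.catalog)
        tumors = bundle.tumor_samples()
        freq = v.plp_frequency(matched, tumors, bundle.panel.symbols, origin="somatic")
        som = matched.loc[matched["origin"] == "somatic"]
        for gene in ["ATM", "TP53", "WRN"]:
            for ctype in freq.cancer_types:
                ids = set(tumors.index[tumors == ctype])
                carriers = som.loc[(som["Hugo_Symbol"] == gene)
                                   & som["Tumor_Sample_Barcode"].isin(ids),
                                   "Tumor_Sample_Barcode"].nunique()
                assert freq.numerator.loc[gene, ctype] == carriers
                assert freq.freq.loc[gene, ctype] == pytest.approx(carriers / len(ids))


class TestSummarize:
    def test_per_type_means(self):
        som = make_variants([("S", "A", "1", 1, "A", "G", "x", "PASS", "somatic")] * 4017)
        germ = make_variants([("S", "A", "1", 1, "A", "G", "x", "PASS", "germline")] * 808)
        out = v.summarize_plp(som, germ, n_types=33)
        assert out["germline_mean_rounded"] == 24
        assert out["somatic_mean_rounded"] == 122

    def test_empty_tables(self):
        out = v.summarize_plp(make_variants([]), make_variants([]), n_types=5)
        assert out["somatic_mean"] == 0 and out["germline_mean_rounded"] == 0

    def test_round_half_to_even(self):
        som = make_variants([("S", "A", "1", 1, "A", "G", "x", "PASS", "somatic")] * 10)
        out = v.summarize_plp(som, make_variants([]), n_types=4)
        assert out["somatic_mean"] == pytest.approx(2.5)
        assert out["somatic_mean_rounded"] == 2  # banker's rounding

    def test_zero_types_error(self):
        with pytest.raises(AnalysisError):
            v.summarize_plp(make_variants([]), make_variants([]), n_types=0)


def _freq_from_values(values: dict) -> FrequencyMatrix:
    """FrequencyMatrix with given per-gene frequency vectors (denominator 100)."""
    freq = pd.DataFrame(values).T
    freq.columns = [f"C{i}" for i in range(freq.shape[1])]
    num = (freq * 100).round().astype(int)
    denom = pd.Series(100, index=freq.columns)
    return FrequencyMatrix(freq=num / 100, numerator=num, denominator=denom)


class TestCorrelation:
    def test_identical_vectors_r_one(self, panel):
        vec = [0.01, 0.02, 0.03, 0.04]
        fm = _freq_from_values({g: vec for g in panel.symbols})
        out = correlate_with_references(fm, panel)
        assert np.allclose(out["r"], 1.0)

    def test_hand_computed_r(self, panel):
        values = {g: [0.01, 0.02, 0.03] for g in panel.symbols}
        values["ATM"] = [0.01, 0.02, 0.04]
        fm = _freq_from_values(values)
        out = correlate_with_references(fm, panel)
        atm = out.loc[out["gene"] == "ATM"]
        # closed form for x=(1,2,3), y=(1,2,4): r = 0.9819805...
        assert atm["r"].to_numpy() == pytest.approx(0.981980506, abs=1e-8)

    def test_constant_vector_undefined(self, panel):
        values = {g: [0.01, 0.02, 0.03] for g in panel.symbols}
        values["ATM"] = [0.02, 0.02, 0.02]
        fm = _freq_from_values(values)
        out = correlate_with_references(fm, panel)
        atm = out.loc[out["gene"] == "ATM"]
        assert atm["undefined"].all() and not atm["significant"].any()

    def test_significance_rule_consistency(self, small_cohort):
        """significant <=> p < 0.05 and |r| > threshold, for both cutoffs."""
        bundle, _ = small_cohort
        matched = v.match_plp(v.filter_variants(bundle.variants), bundle.catalog)
        freq = v.plp_frequency(matched, bundle.tumor_samples(),
                               bundle.panel.symbols, origin="somatic")
        for thr in (0.4, 0.5):
            out = correlate_with_references(freq, bundle.panel, threshold=thr)
            ok = out.loc[~out["undefined"]]
            expect = (ok["p"] < 0.05) & (ok["r"].abs() > thr)
            assert (ok["significant"] == expect).all()


@given(st.lists(st.tuples(st.integers(-50, 50), st.integers(-50, 50)),
                min_size=3, max_size=12))
def test_pearson_matches_closed_form(pairs):
    """Pearson r agrees with its closed form to 1e-12."""
    from scipy import stats
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return
    r_lib = stats.pearsonr(x, y)[0]
    xc, yc = x - x.mean(), y - y.mean()
    r_hand = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
    assert r_lib == pytest.approx(r_hand, abs=1e-12)
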