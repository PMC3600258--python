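import math
from fractions import Fraction

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tpmtyper import allele_frequencies, concordance, hwe_exact_test


def cohort_table(panel, n_total, het_719):
    """Long genotype table: het at c.719A>G for the first samples, wild type
    elsewhere."""
    rows = []
    for i in range(n_total):
        for snp_id in panel.snp_ids:
            genotype = "het" if snp_id == "c.719A>G" and i < het_719 else "hom_wt"
            rows.append({"sample_id": f"S{i:04d}", "snp_id": snp_id, "genotype": genotype})
    return pd.DataFrame(rows)


def test_validation_cohort_3c_frequency(panel):
    """10 heterozygous carriers among 244 samples -> 2.05% (10 of 488)."""
    freq = allele_frequencies(cohort_table(panel, 244, 10), panel)
    row = freq.snp_row("c.719A>G")
    assert (row["count"], row["total_alleles"]) == (10, 488)
    assert round(float(row["freq_pct"]), 2) == 2.05
    star = freq.allele_row("*3C")
    assert (star["count"], star["total_alleles"]) == (10, 488)
    assert round(float(star["freq_pct"]), 2) == 2.05
    assert freq.allele_row("*1")["count"] == 478


def test_two_of_eight_hundred_alleles(panel):
    freq = allele_frequencies(cohort_table(panel, 400, 2), panel)
    row = freq.snp_row("c.719A>G")
    assert (row["count"], row["total_alleles"]) == (2, 800)
    assert float(row["freq_pct"]) == pytest.approx(0.25)


def test_all_wild_type_ci_lower_bound_zero(panel):
    freq = allele_frequencies(cohort_table(panel, 50, 0), panel)
    row = freq.snp_row("c.719A>G")
    assert row["freq_pct"] == 0.0
    assert row["ci_lo_pct"] == 0.0
    assert row["ci_hi_pct"] > 0.0


def test_no_call_shrinks_denominator(panel):
    table = cohort_table(panel, 10, 1)
    table.loc[
        (table["sample_id"] == "S0005") & (table["snp_id"] == "c.719A>G"), "genotype"
    ] = "no_call"
    freq = allele_frequencies(table, panel)
    assert freq.snp_row("c.719A>G")["total_alleles"] == 18
    assert freq.snp_row("c.238G>C")["total_alleles"] == 20


def test_sample_subset_restricts_denominator(panel):
    table = cohort_table(panel, 20, 2)
    subset = [f"S{i:04d}" for i in range(10)]
    freq = allele_frequencies(table, panel, samples=subset)
    assert freq.snp_row("c.719A>G")["total_alleles"] == 20


def test_empty_table_is_an_error(panel):
    with pytest.raises(ValueError, match="empty"):
        allele_frequencies(cohort_table(panel, 5, 0), panel, samples=["nope"])


def test_concordance_identical_and_flipped(panel):
    table = cohort_table(panel, 246, 12)
    report = concordance(table, table.copy())
    assert (report.n_samples, report.n_comparable, report.n_concordant) == (246, 246, 246)
    assert report.pct_concordant == 100.0

    flipped = table.copy()
    idx = (flipped["sample_id"] == "S0003") & (flipped["snp_id"] == "c.719A>G")
    flipped.loc[idx, "genotype"] = "hom_wt"
    report = concordance(table, flipped)
    assert report.n_concordant == 245
    assert report.discordant == ["S0003"]


def test_concordance_excludes_no_calls(panel):
    table = cohort_table(panel, 10, 1)
    nocall = table.copy()
    idx = nocall["sample_id"] == "S0002"
    nocall.loc[idx & (nocall["snp_id"] == "c.238G>C"), "genotype"] = "no_call"
    report = concordance(table, nocall)
    assert report.n_comparable == 9
    assert report.excluded == ["S0002"]


def test_concordance_key_mismatch_is_error(panel):
    table = cohort_table(panel, 5, 0)
    missing = table[table["sample_id"] != "S0004"]
    with pytest.raises(ValueError, match="S0004"):
        concordance(table, missing)


def hwe_oracle(n_hom_wt, n_het, n_hom_var):
    """Exact-rational enumeration of the conditional heterozygote
    distribution; independent of the lgamma implementation."""
    n = n_hom_wt + n_het + n_hom_var
    rare = min(2 * n_hom_var + n_het, 2 * n_hom_wt + n_het)
    if rare == 0:
        return 1.0
    probs = {}
    for het in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - het) // 2
        hom_common = n - het - hom_rare
        probs[het] = (
            Fraction(math.factorial(n), math.factorial(hom_rare)
                     * math.factorial(het) * math.factorial(hom_common))
            * Fraction(2) ** het
            * Fraction(
                math.factorial(rare) * math.factorial(2 * n - rare),
                math.factorial(2 * n),
            )
        )
    observed = probs[n_het]
    return float(sum(p for p in probs.values() if p <= observed))


@pytest.mark.parametrize(
    "counts",
    [(234, 10, 0), (25, 50, 25), (100, 0, 0), (0, 0, 100), (5, 0, 5), (1, 1, 1),
     (57, 14, 2), (300, 40, 1)],
)
def test_hwe_matches_exact_enumeration(counts):
    assert hwe_exact_test(*counts) == pytest.approx(hwe_oracle(*counts), abs=1e-9)


def test_hwe_cohort_is_consistent():
    """The validation cohort (10 heterozygotes, no variant homozygotes in
    244) shows no Hardy-Weinberg deviation."""
    assert hwe_exact_test(234, 10, 0) == pytest.approx(1.0, abs=1e-9)


def test_hwe_monomorphic_is_one():
    assert hwe_exact_test(100, 0, 0) == 1.0


@given(
    st.integers(min_value=0, max_value=60),
    st.integers(min_value=0, max_value=25),
    st.integers(min_value=0, max_value=12),
)
def test_hwe_property_vs_oracle(a, b, c):
    """All tables with <= 50 variant alleles agree with the oracle to 1e-9
    and p is a probability."""
    if a + b + c == 0:
        return
    p = hwe_exact_test(a, b, c)
    assert 0.0 <= p <= 1.0
    if 2 * c + b <= 50:
        assert p == pytest.approx(hwe_oracle(a, b, c), abs=1e-9)


def test_self_concordance_property(panel, rng):
    """Concordance of any table with itself is 100%."""
    genotypes = rng.choice(["hom_wt", "het", "hom_var"], size=3 * 30)
    rows = [
        {"sample_id": f"S{i}", "snp_id": snp_id, "genotype": genotypes[3 * i + j]}
        for i in range(30)
        for j, snp_id in enumerate(panel.snp_ids)
    ]
    table = pd.DataFrame(rows)
    report = concordance(table, table.copy())
    assert report.n_concordant == report.n_comparable == 30
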