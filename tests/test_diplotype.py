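from itertools import combinations_with_replacement, product

import pytest

from tpmtyper import (
    diplotype_sample,
    enumerate_diplotypes,
    predict_phenotype,
    resolve_diplotype,
)
from tpmtyper.calling import SnpCall

GENOTYPES = ("hom_wt", "het", "hom_var")
DOSE = {"hom_wt": 0, "het": 1, "hom_var": 2}


def brute_force_pairs(genotypes, panel):
    """Independent oracle: try all unordered allele pairs, re-derive the
    genotype vector of each, keep exact matches."""
    hits = []
    for a, b in combinations_with_replacement(panel.alleles, 2):
        derived = {
            snp_id: GENOTYPES[(snp_id in a.variant_snps) + (snp_id in b.variant_snps)]
            for snp_id in panel.snp_ids
        }
        if derived == genotypes:
            hits.append(tuple(sorted((a.name, b.name))))
    return sorted(hits)


def all_vectors(panel):
    for combo in product(GENOTYPES, repeat=len(panel.snp_ids)):
        yield dict(zip(panel.snp_ids, combo))


def test_soundness_against_oracle_over_all_27_vectors(panel):
    """Candidates match brute force for every genotype vector; every emitted
    pair re-derives the input exactly; inconsistent vectors (those needing a
    haplotype the panel does not declare) raise, matching the oracle."""
    n_consistent = 0
    for genotypes in all_vectors(panel):
        expected = brute_force_pairs(genotypes, panel)
        if not expected:
            with pytest.raises(ValueError, match="no star-allele pair"):
                enumerate_diplotypes(genotypes, panel)
            continue
        n_consistent += 1
        got = enumerate_diplotypes(genotypes, panel)
        assert got == expected
        for pair in got:
            derived = {
                snp_id: GENOTYPES[sum(panel.allele(n).carries(snp_id) for n in pair)]
                for snp_id in panel.snp_ids
            }
            assert derived == genotypes
    assert n_consistent == 14  # 15 pairs, two of which share a dose vector


def test_ambiguity_occurs_exactly_for_the_cis_trans_vector(panel):
    """Only het c.460 + het c.719 (wild type at c.238) has two explanations:
    *1/*3A in cis vs *3B/*3C in trans."""
    ambiguous_vectors = []
    for genotypes in all_vectors(panel):
        candidates = brute_force_pairs(genotypes, panel)
        if not candidates:
            continue
        call = resolve_diplotype(enumerate_diplotypes(genotypes, panel), panel)
        assert call.ambiguous == (len(candidates) > 1)
        if call.ambiguous:
            ambiguous_vectors.append(genotypes)
    assert ambiguous_vectors == [
        {"c.238G>C": "hom_wt", "c.460G>A": "het", "c.719A>G": "het"}
    ]


def test_inconsistent_vector_is_indeterminate_not_fatal(panel):
    calls = [
        SnpCall("S1", snp_id, genotype, None, None, None)
        for snp_id, genotype in zip(panel.snp_ids, ["het", "hom_wt", "hom_var"])
    ]
    result = diplotype_sample(calls, panel)
    assert result.allele_pair is None
    assert result.phenotype == "indeterminate"


@pytest.mark.parametrize(
    "genotypes, expected",
    [
        ({"c.238G>C": "hom_wt", "c.460G>A": "hom_wt", "c.719A>G": "hom_wt"}, [("*1", "*1")]),
        ({"c.238G>C": "hom_wt", "c.460G>A": "hom_wt", "c.719A>G": "het"}, [("*1", "*3C")]),
        (
            {"c.238G>C": "hom_wt", "c.460G>A": "het", "c.719A>G": "het"},
            [("*1", "*3A"), ("*3B", "*3C")],
        ),
        ({"c.238G>C": "hom_wt", "c.460G>A": "hom_wt", "c.719A>G": "hom_var"}, [("*3C", "*3C")]),
    ],
)
def test_enumeration_examples(panel, genotypes, expected):
    assert enumerate_diplotypes(genotypes, panel) == expected


def test_prior_resolution_of_cis_trans_ambiguity(panel):
    """*1/*3A wins over *3B/*3C under Hardy-Weinberg prior products."""
    candidates = [("*1", "*3A"), ("*3B", "*3C")]
    p = {a.name: a.prior_freq for a in panel.alleles}
    score_3a = 2 * p["*1"] * p["*3A"]
    score_trans = 2 * p["*3B"] * p["*3C"]
    call = resolve_diplotype(candidates, panel)
    assert call.allele_pair == ("*1", "*3A")
    assert call.ambiguous
    assert call.phenotype == "intermediate"
    ((alt_pair, alt_score),) = call.alternatives
    assert alt_pair == ("*3B", "*3C")
    assert alt_score == pytest.approx(score_trans / (score_3a + score_trans))
    assert call.alt_phenotype == "poor"


def test_worst_case_policy_reports_poorer_phenotype(panel):
    call = resolve_diplotype([("*1", "*3A"), ("*3B", "*3C")], panel, policy="worst_case")
    assert call.allele_pair == ("*3B", "*3C")
    assert call.phenotype == "poor"
    assert call.ambiguous


@pytest.mark.parametrize(
    "pair, phenotype",
    [
        (("*1", "*1"), "normal"),
        (("*1", "*3C"), "intermediate"),
        (("*3A", "*3C"), "poor"),
        (("*2", "*2"), "poor"),
    ],
)
def test_phenotype_from_nonfunctional_count(panel, pair, phenotype):
    assert predict_phenotype(pair, panel) == phenotype


def test_no_call_gives_indeterminate(panel):
    calls = [
        SnpCall("S1", snp_id, "no_call" if snp_id == "c.460G>A" else "hom_wt", None, None, None)
        for snp_id in panel.snp_ids
    ]
    result = diplotype_sample(calls, panel)
    assert result.allele_pair is None
    assert result.phenotype == "indeterminate"
    assert result.diplotype == "NA"


def test_empty_candidates_is_an_error(panel):
    with pytest.raises(ValueError, match="no diplotype candidates"):
        resolve_diplotype([], panel)
    with pytest.raises(ValueError, match="no-call"):
        enumerate_diplotypes({s: "no_call" for s in panel.snp_ids}, panel)
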