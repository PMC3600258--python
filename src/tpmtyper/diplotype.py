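"""Star-allele diplotype assignment and metabolizer-phenotype prediction.

Per-SNP genotypes are unphased, so a genotype vector can be explained by
more than one pair of star alleles.  The classic TPMT case: heterozygous at
both c.460G>A and c.719A>G is consistent with *1/*3A (both variants in cis)
and with *3B/*3C (in trans) — configurations with different dosing
consequences.  Candidate pairs are enumerated exhaustively; ambiguity is
resolved either by maximizing the Hardy-Weinberg prior product
(``2 p_i p_j`` for i != j, ``p_i^2`` otherwise; policy ``prior``, default)
or by reporting the candidate with the worst phenotype (policy
``worst_case``), with the alternatives always listed.

Phenotype follows the standard activity model: 0 nonfunctional alleles ->
normal, 1 -> intermediate, 2 -> poor metabolizer.  Any no-call SNP makes
the phenotype indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

from .calling import SnpCall
from .panel import Panel, StarAllele

__all__ = [
    "DiplotypeCall",
    "enumerate_diplotypes",
    "resolve_diplotype",
    "predict_phenotype",
    "diplotype_sample",
]

_PHENO_SEVERITY = {"normal": 0, "intermediate": 1, "poor": 2}
_DOSE = {"hom_wt": 0, "het": 1, "hom_var": 2}


@dataclass
class DiplotypeCall:
    """An unordered star-allele pair with ambiguity provenance and phenotype."""

    sample_id: str
    allele_pair: tuple[str, str] | None
    ambiguous: bool = False
    alternatives: list[tuple[tuple[str, str], float]] = field(default_factory=list)
    phenotype: str = "indeterminate"
    alt_phenotype: str | None = None

    @property
    def diplotype(self) -> str:
        if self.allele_pair is None:
            return "NA"
        return "/".join(self.allele_pair)


def _pair_key(a: StarAllele, b: StarAllele) -> tuple[str, str]:
    return tuple(sorted((a.name, b.name)))  # type: ignore[return-value]


def _consistent(pair: tuple[StarAllele, StarAllele], genotypes: dict[str, str]) -> bool:
    for snp_id, genotype in genotypes.items():
        carried = sum(1 for allele in pair if allele.carries(snp_id))
        if carried != _DOSE[genotype]:
            return False
    return True


def enumerate_diplotypes(
    genotypes: dict[str, str] | list[SnpCall], panel: Panel
) -> list[tuple[str, str]]:
    """All unordered star-allele pairs consistent with the genotype vector.

    A pair is consistent iff, for every panel SNP, the number of pair
    members carrying its variant equals the variant dose of the genotype
    (hom_wt 0, het 1, hom_var 2).  Raises if any SNP is a no-call or if no
    pair explains the genotypes.
    """
    if not isinstance(genotypes, dict):
        genotypes = {call.snp_id: call.genotype for call in genotypes}
    unknown = set(genotypes) - set(panel.snp_ids)
    if unknown:
        raise ValueError(f"genotypes reference unknown SNP(s): {sorted(unknown)}")
    if any(g == "no_call" for g in genotypes.values()):
        raise ValueError("cannot enumerate diplotypes with no-call genotypes")
    pairs = [
        _pair_key(a, b)
        for a, b in combinations_with_replacement(panel.alleles, 2)
        if _consistent((a, b), genotypes)
    ]
    if not pairs:
        raise ValueError(f"no star-allele pair explains genotypes {genotypes}")
    return sorted(pairs)


def _hwe_prior(pair: tuple[str, str], panel: Panel) -> float:
    p1 = panel.allele(pair[0]).prior_freq
    p2 = panel.allele(pair[1]).prior_freq
    return (2.0 if pair[0] != pair[1] else 1.0) * p1 * p2


def predict_phenotype(pair: tuple[str, str], panel: Panel) -> str:
    """Metabolizer phenotype from the count of nonfunctional alleles."""
    n_nonfunctional = sum(
        1 for name in pair if panel.allele(name).functional == "nonfunctional"
    )
    return panel.phenotype(n_nonfunctional)


def resolve_diplotype(
    candidates: list[tuple[str, str]],
    panel: Panel,
    sample_id: str = "",
    policy: str = "prior",
) -> DiplotypeCall:
    """Pick one diplotype among the consistent candidates.

    ``prior``: maximize the Hardy-Weinberg prior product; ``worst_case``:
    pick the candidate with the most severe phenotype (prior as tie-break).
    With multiple candidates the call is flagged ambiguous and every
    candidate is reported with its normalized prior score.
    """
    if not candidates:
        raise ValueError("no diplotype candidates to resolve")
    scored = [(pair, _hwe_prior(pair, panel)) for pair in candidates]
    total = sum(s for _, s in scored) or 1.0
    scored = [(pair, s / total) for pair, s in scored]
    if policy == "prior":
        best = max(scored, key=lambda item: item[1])[0]
    elif policy == "worst_case":
        best = max(
            scored,
            key=lambda item: (_PHENO_SEVERITY[predict_phenotype(item[0], panel)], item[1]),
        )[0]
    else:
        raise ValueError(f"unknown ambiguity policy {policy!r}")
    alternatives = sorted(
        (item for item in scored if item[0] != best), key=lambda item: -item[1]
    )
    phenotype = predict_phenotype(best, panel)
    alt_phenotype = None
    if alternatives:
        alt_phenotype = predict_phenotype(alternatives[0][0], panel)
    return DiplotypeCall(
        sample_id=sample_id,
        allele_pair=best,
        ambiguous=len(candidates) > 1,
        alternatives=alternatives,
        phenotype=phenotype,
        alt_phenotype=alt_phenotype,
    )


def diplotype_sample(
    snp_calls: list[SnpCall], panel: Panel, policy: str = "prior"
) -> DiplotypeCall:
    """Full per-sample resolution.

    No-call SNPs, and genotype vectors no declared star-allele pair can
    explain (which would indicate a novel haplotype), both yield an
    indeterminate call rather than an error: a plate run must not abort on
    one problematic sample.
    """
    sample_id = snp_calls[0].sample_id if snp_calls else ""
    if any(call.genotype == "no_call" for call in snp_calls):
        return DiplotypeCall(sample_id=sample_id, allele_pair=None)
    try:
        candidates = enumerate_diplotypes(snp_calls, panel)
    except ValueError:
        return DiplotypeCall(sample_id=sample_id, allele_pair=None)
    return resolve_diplotype(candidates, panel, sample_id=sample_id, policy=policy)
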