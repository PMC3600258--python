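"""Assay validation statistics.

Allele frequencies with exact (Clopper-Pearson) confidence intervals,
per-sample genotype concordance against a reference method, and an exact
conditional Hardy-Weinberg test.  The HWE test enumerates every possible
heterozygote count given the observed allele counts and sums the
probabilities of configurations no more likely than the observed one — the
chi-square approximation is useless at the allele frequencies seen in
pharmacogene panels (a handful of variant alleles in a few hundred
chromosomes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .diplotype import enumerate_diplotypes, resolve_diplotype
from .panel import Panel

__all__ = [
    "FrequencyReport",
    "ConcordanceReport",
    "allele_frequencies",
    "concordance",
    "hwe_exact_test",
]

GENOTYPE_DOSE = {"hom_wt": 0, "het": 1, "hom_var": 2}


def round_pct(x: float, ndigits: int = 2) -> float:
    """Round-half-even percent formatting (10/488 -> 2.05)."""
    return round(x, ndigits)


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial CI for k successes in n trials, as proportions."""
    if n == 0:
        return (0.0, 1.0)
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


@dataclass
class FrequencyReport:
    """Variant-allele frequencies per SNP and per star allele."""

    per_snp: pd.DataFrame  # snp_id, n_samples, count, total_alleles, freq_pct, ci_lo/hi_pct
    per_allele: pd.DataFrame  # allele, count, total_alleles, freq_pct, ci_lo/hi_pct
    n_samples: int = 0

    def snp_row(self, snp_id: str) -> pd.Series:
        return self.per_snp.set_index("snp_id").loc[snp_id]

    def allele_row(self, name: str) -> pd.Series:
        return self.per_allele.set_index("allele").loc[name]


@dataclass
class ConcordanceReport:
    """Sample-level agreement between this assay and a reference method."""

    n_samples: int
    n_comparable: int
    n_concordant: int
    per_snp: pd.DataFrame  # snp_id, n_comparable, n_concordant
    discordant: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)  # samples with any no_call

    @property
    def pct_concordant(self) -> float:
        if self.n_comparable == 0:
            return float("nan")
        return 100.0 * self.n_concordant / self.n_comparable


def _check_genotype_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "snp_id", "genotype"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"genotype table missing columns: {sorted(missing)}")
    bad = set(table["genotype"]) - set(GENOTYPE_DOSE) - {"no_call"}
    if bad:
        raise ValueError(f"unknown genotype labels: {sorted(bad)}")
    if table.duplicated(["sample_id", "snp_id"]).any():
        raise ValueError("duplicate (sample_id, snp_id) rows in genotype table")
    return table


def allele_frequencies(
    genotypes: pd.DataFrame,
    panel: Panel,
    samples: list[str] | None = None,
    conf: float = 0.95,
) -> FrequencyReport:
    """Variant and star-allele frequencies from a long genotype table.

    ``samples`` restricts the denominator (e.g. patients only, excluding
    spiked-in controls).  Per SNP, the variant allele count is
    2 x hom_var + het over called samples; no-calls are dropped from that
    SNP's denominator.  Star-allele counts come from per-sample diplotype
    resolution and use only samples fully called at every panel SNP.
    """
    genotypes = _check_genotype_table(genotypes)
    if samples is not None:
        genotypes = genotypes[genotypes["sample_id"].isin(set(samples))]
    if genotypes.empty:
        raise ValueError("empty genotype table")
    n_samples = genotypes["sample_id"].nunique()

    snp_rows = []
    for snp in panel.snps:
        sub = genotypes[(genotypes["snp_id"] == snp.snp_id) & (genotypes["genotype"] != "no_call")]
        total = 2 * len(sub)
        count = int(sum(GENOTYPE_DOSE[g] for g in sub["genotype"]))
        freq = 100.0 * count / total if total else float("nan")
        lo, hi = clopper_pearson(count, total, conf)
        snp_rows.append(
            {
                "snp_id": snp.snp_id,
                "n_samples": len(sub),
                "count": count,
                "total_alleles": total,
                "freq_pct": freq,
                "ci_lo_pct": 100.0 * lo,
                "ci_hi_pct": 100.0 * hi,
            }
        )

    # star alleles: resolve a diplotype per fully-called sample
    wide = genotypes.pivot(index="sample_id", columns="snp_id", values="genotype")
    wide = wide.reindex(columns=panel.snp_ids)
    complete = wide.dropna()
    complete = complete[(complete != "no_call").all(axis=1)]
    counts = {a.name: 0 for a in panel.alleles}
    for _, row in complete.iterrows():
        call = resolve_diplotype(
            enumerate_diplotypes(row.to_dict(), panel), panel
        )
        for name in call.allele_pair:
            counts[name] += 1
    total_star = 2 * len(complete)
    allele_rows = []
    for allele in panel.alleles:
        k = counts[allele.name]
        freq = 100.0 * k / total_star if total_star else float("nan")
        lo, hi = clopper_pearson(k, total_star, conf)
        allele_rows.append(
            {
                "allele": allele.name,
                "count": k,
                "total_alleles": total_star,
                "freq_pct": freq,
                "ci_lo_pct": 100.0 * lo,
                "ci_hi_pct": 100.0 * hi,
            }
        )
    return FrequencyReport(
        per_snp=pd.DataFrame(snp_rows),
        per_allele=pd.DataFrame(allele_rows),
        n_samples=n_samples,
    )


def concordance(calls: pd.DataFrame, reference: pd.DataFrame) -> ConcordanceReport:
    """Per-sample exact genotype concordance against a reference method.

    A sample is concordant iff every one of its SNPs matches exactly.
    Samples with a no-call in either method are excluded from the
    comparable set and listed separately.  Key mismatches (samples or SNPs
    present in only one table) are an error.
    """
    calls = _check_genotype_table(calls)
    reference = _check_genotype_table(reference)
    left = set(map(tuple, calls[["sample_id", "snp_id"]].itertuples(index=False)))
    right = set(map(tuple, reference[["sample_id", "snp_id"]].itertuples(index=False)))
    if left != right:
        only_calls = sorted({s for s, _ in left - right})
        only_ref = sorted({s for s, _ in right - left})
        raise ValueError(
            f"genotype tables do not share keys (calls-only samples: {only_calls}, "
            f"reference-only samples: {only_ref})"
        )
    merged = calls.merge(
        reference, on=["sample_id", "snp_id"], suffixes=("_call", "_ref")
    )
    n_samples = merged["sample_id"].nunique()
    merged["no_call"] = (merged["genotype_call"] == "no_call") | (
        merged["genotype_ref"] == "no_call"
    )
    excluded = sorted(merged.loc[merged["no_call"], "sample_id"].unique())
    usable = merged[~merged["sample_id"].isin(excluded)]
    usable = usable.assign(match=usable["genotype_call"] == usable["genotype_ref"])
    by_sample = usable.groupby("sample_id")["match"].all()
    discordant = sorted(by_sample.index[~by_sample])
    per_snp = (
        usable.groupby("snp_id")["match"]
        .agg(n_comparable="size", n_concordant="sum")
        .reset_index()
    )
    return ConcordanceReport(
        n_samples=n_samples,
        n_comparable=int(by_sample.size),
        n_concordant=int(by_sample.sum()),
        per_snp=per_snp,
        discordant=list(discordant),
        excluded=list(excluded),
    )


def hwe_exact_test(n_hom_wt: int, n_het: int, n_hom_var: int) -> float:
    """Exact conditional Hardy-Weinberg test for one biallelic SNP.

    Enumerates every heterozygote count compatible with the observed allele
    counts and returns the summed probability of all configurations no more
    probable than the observed one (two-sided).  Monomorphic data give 1.
    """
    if min(n_hom_wt, n_het, n_hom_var) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_wt + n_het + n_hom_var
    if n == 0:
        raise ValueError("genotype counts are all zero")
    n_var = 2 * n_hom_var + n_het  # copies of the rarer-coded allele
    n_wt = 2 * n_hom_wt + n_het
    rare = min(n_var, n_wt)
    if rare == 0:
        return 1.0

    def log_prob(het: int) -> float:
        hom_rare = (rare - het) // 2
        hom_common = n - het - hom_rare
        return (
            math.lgamma(n + 1)
            - math.lgamma(hom_rare + 1)
            - math.lgamma(het + 1)
            - math.lgamma(hom_common + 1)
            + het * math.log(2.0)
            + math.lgamma(rare + 1)
            + math.lgamma(2 * n - rare + 1)
            - math.lgamma(2 * n + 1)
        )

    hets = range(rare % 2, rare + 1, 2)
    logs = {h: log_prob(h) for h in hets}
    observed = logs[n_het]
    # sum configurations with probability <= observed (tolerance for ties)
    p = sum(math.exp(lp) for lp in logs.values() if lp <= observed + 1e-12)
    return min(1.0, p)
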