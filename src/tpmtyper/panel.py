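"""Genotyping panel definitions.

A :class:`Panel` declares everything downstream modules need to know about
the assay: which SNPs are interrogated, which star alleles (named haplotypes)
exist over those SNPs, population priors used to rank phase-ambiguous
diplotypes, and the map from the number of nonfunctional alleles to the
metabolizer phenotype.  The clinically used TPMT panel (c.238G>C, c.460G>A,
c.719A>G defining *2/*3A/*3B/*3C) ships as a data file, so the panel is
configuration, not code.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import IO, Mapping

import yaml

__all__ = [
    "PanelError",
    "SnpDef",
    "StarAllele",
    "Panel",
    "load_panel",
    "serialize_panel",
    "default_panel",
]

_PHENOTYPES = ("normal", "intermediate", "poor")
_FUNCTIONAL = ("normal", "nonfunctional")
_PRIOR_TOL = 1e-9


class PanelError(ValueError):
    """Raised when a panel definition is malformed or inconsistent."""


@dataclass(frozen=True)
class SnpDef:
    """A biallelic SNP interrogated by one wild-type and one variant reaction."""

    snp_id: str
    rsid: str
    wt_base: str
    var_base: str
    protein_change: str = ""

    def __post_init__(self) -> None:
        for base_name in ("wt_base", "var_base"):
            base = getattr(self, base_name)
            if base not in ("A", "C", "G", "T"):
                raise PanelError(f"{self.snp_id}: {base_name} {base!r} is not a nucleotide")
        if self.wt_base == self.var_base:
            raise PanelError(f"{self.snp_id}: wt_base equals var_base ({self.wt_base})")


@dataclass(frozen=True)
class StarAllele:
    """A named haplotype defined by the set of panel SNPs it carries.

    ``prior_freq`` is a population prior used only to resolve phase-ambiguous
    diplotypes; it is configuration, not a measurement.
    """

    name: str
    variant_snps: frozenset[str]
    prior_freq: float
    functional: str

    def __post_init__(self) -> None:
        if self.functional not in _FUNCTIONAL:
            raise PanelError(f"allele {self.name}: functional must be one of {_FUNCTIONAL}")
        if not 0.0 <= self.prior_freq <= 1.0:
            raise PanelError(f"allele {self.name}: prior_freq {self.prior_freq} outside [0, 1]")

    def carries(self, snp_id: str) -> bool:
        return snp_id in self.variant_snps


@dataclass
class Panel:
    """A validated genotyping panel: SNPs, star alleles, phenotype map."""

    snps: list[SnpDef]
    alleles: list[StarAllele]
    phenotype_map: dict[int, str] = field(
        default_factory=lambda: {0: "normal", 1: "intermediate", 2: "poor"}
    )
    name: str = "panel"

    def __post_init__(self) -> None:
        snp_ids = [s.snp_id for s in self.snps]
        if len(set(snp_ids)) != len(snp_ids):
            raise PanelError("duplicate snp_id in panel")
        allele_names = [a.name for a in self.alleles]
        if len(set(allele_names)) != len(allele_names):
            raise PanelError("duplicate allele name in panel")
        known = set(snp_ids)
        for allele in self.alleles:
            unknown = allele.variant_snps - known
            if unknown:
                raise PanelError(
                    f"allele {allele.name} references unknown SNP(s): {sorted(unknown)}"
                )
        ref = self.reference_allele  # raises if *1 missing/malformed
        if ref.functional != "normal":
            raise PanelError("reference allele *1 must be functional=normal")
        total = sum(a.prior_freq for a in self.alleles)
        if abs(total - 1.0) > _PRIOR_TOL:
            raise PanelError(f"allele priors sum to {total!r}, expected 1")
        for count in (0, 1, 2):
            pheno = self.phenotype_map.get(count)
            if pheno not in _PHENOTYPES:
                raise PanelError(f"phenotype_map[{count}] = {pheno!r} invalid")
        expected = {0: "normal", 1: "intermediate", 2: "poor"}
        if {k: self.phenotype_map[k] for k in (0, 1, 2)} != expected:
            raise PanelError(f"phenotype_map must be {expected}")

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def reference_allele(self) -> StarAllele:
        for allele in self.alleles:
            if allele.name == "*1":
                if allele.variant_snps:
                    raise PanelError("*1 must carry no variant SNPs")
                return allele
        raise PanelError("panel must declare the reference allele *1")

    def snp(self, snp_id: str) -> SnpDef:
        for s in self.snps:
            if s.snp_id == snp_id:
                return s
        raise KeyError(snp_id)

    def allele(self, name: str) -> StarAllele:
        for a in self.alleles:
            if a.name == name:
                return a
        raise KeyError(name)

    def phenotype(self, n_nonfunctional: int) -> str:
        return self.phenotype_map[n_nonfunctional]


def _as_mapping(doc: object) -> Mapping:
    if not isinstance(doc, Mapping):
        raise PanelError("panel file must be a mapping at top level")
    return doc


def load_panel(source: str | IO[str]) -> Panel:
    """Load and validate a panel from a YAML file path or open stream."""
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = yaml.safe_load(source)
    doc = _as_mapping(doc)
    version = doc.get("schema_version")
    if version != 1:
        raise PanelError(f"unsupported panel schema_version: {version!r}")
    try:
        snps = [SnpDef(**entry) for entry in doc.get("snps", [])]
        alleles = [
            StarAllele(
                name=entry["name"],
                variant_snps=frozenset(entry.get("variant_snps", [])),
                prior_freq=float(entry["prior_freq"]),
                functional=entry["functional"],
            )
            for entry in doc.get("alleles", [])
        ]
    except (TypeError, KeyError) as exc:
        raise PanelError(f"malformed panel entry: {exc}") from exc
    phenotype_map = {int(k): v for k, v in doc.get(
        "phenotype_map", {0: "normal", 1: "intermediate", 2: "poor"}
    ).items()}
    return Panel(
        snps=snps,
        alleles=alleles,
        phenotype_map=phenotype_map,
        name=str(doc.get("name", "panel")),
    )


def serialize_panel(panel: Panel) -> str:
    """Serialize a panel back to its YAML document (round-trips load_panel)."""
    doc = {
        "schema_version": 1,
        "name": panel.name,
        "snps": [
            {
                "snp_id": s.snp_id,
                "rsid": s.rsid,
                "wt_base": s.wt_base,
                "var_base": s.var_base,
                "protein_change": s.protein_change,
            }
            for s in panel.snps
        ],
        "alleles": [
            {
                "name": a.name,
                "variant_snps": sorted(a.variant_snps),
                "prior_freq": a.prior_freq,
                "functional": a.functional,
            }
            for a in panel.alleles
        ],
        "phenotype_map": dict(panel.phenotype_map),
    }
    return yaml.safe_dump(doc, sort_keys=False)


def default_panel() -> Panel:
    """The shipped three-SNP TPMT panel (*1, *2, *3A, *3B, *3C)."""
    import io

    ref = importlib.resources.files("tpmtyper.data").joinpath("tpmt_panel.yaml")
    return load_panel(io.StringIO(ref.read_text(encoding="utf-8")))
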