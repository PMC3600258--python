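"""Automatic interpretation of duplex allele-specific qPCR reactions.

Each SNP of each sample is assayed in two wells — one with a wild-type-
specific primer, one with a variant-specific primer — each co-amplifying a
GAPDH internal positive control (IPC).  Interpretation is two-staged:

* **QC gate**: a reaction counts only if its IPC amplified with Ct strictly
  below ``ipc_max_ct`` (default 30).  An IPC failure in either of a SNP's
  two wells voids that SNP (no-call), not the whole sample, because the IPC
  verifies each individual reaction.

* **delta-Ct call**: with both target Cts defined, |Ct_wt - Ct_var| below
  the threshold (default 2 cycles) means both alleles amplified equally
  well (heterozygote); at or above it, the allele with the *smaller* Ct is
  the one present (homozygote).  A delta-Ct of 2 with amplification
  efficiency 2 already corresponds to a >= 4-fold template imbalance, so
  the boundary itself is called homozygous.  One-sided amplification is the
  limiting case of a large delta-Ct and is called homozygous for the
  amplified allele, with delta-Ct recorded as (max_cycle - Ct), floored at
  the threshold.  No amplification on either side is a no-call.

Calling is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .curves import CtResult
from .panel import Panel

__all__ = ["CallingConfig", "SnpCall", "qc_ipc", "call_snp", "call_sample"]

GENOTYPES = ("hom_wt", "het", "hom_var", "no_call")

# QC flags
IPC_FAIL_WT_WELL = "IPC_FAIL_WT_WELL"
IPC_FAIL_VAR_WELL = "IPC_FAIL_VAR_WELL"
NO_AMPLIFICATION = "NO_AMPLIFICATION"
LOW_INPUT = "LOW_INPUT"
LOW_INPUT_UNKNOWN = "LOW_INPUT_UNKNOWN"


@dataclass(frozen=True)
class CallingConfig:
    """Interpretation thresholds (assay protocol constants)."""

    delta_ct_threshold: float = 2.0
    ipc_max_ct: float = 30.0
    max_cycle: float = 45.0
    min_input_ng_per_ul: float = 5.0
    ambiguity_policy: str = "prior"

    def __post_init__(self) -> None:
        if min(self.delta_ct_threshold, self.ipc_max_ct, self.max_cycle,
               self.min_input_ng_per_ul) <= 0:
            raise ValueError("all thresholds must be positive")
        if self.ambiguity_policy not in ("prior", "worst_case"):
            raise ValueError("ambiguity_policy must be 'prior' or 'worst_case'")


@dataclass
class SnpCall:
    """Genotype call for one SNP of one sample, with QC provenance."""

    sample_id: str
    snp_id: str
    genotype: str
    ct_wt: CtResult | None
    ct_var: CtResult | None
    delta_ct: float | None  # None = not applicable (no-call)
    qc_flags: set[str] = field(default_factory=set)


def qc_ipc(ipc_ct: CtResult, ipc_max_ct: float = 30.0) -> bool:
    """A reaction passes QC iff its IPC Ct is defined and strictly < the cap."""
    return ipc_ct.determined and ipc_ct.ct < ipc_max_ct


def call_snp(
    ct_wt: CtResult,
    ct_var: CtResult,
    delta_threshold: float = 2.0,
    max_cycle: float = 45.0,
) -> tuple[str, float | None]:
    """Delta-Ct genotype call from the two allele-specific target Cts.

    Returns ``(genotype, delta_ct)``; assumes both wells already passed the
    IPC gate (QC no-calls are decided upstream).
    """
    if ct_wt.determined and ct_var.determined:
        delta = abs(ct_wt.ct - ct_var.ct)
        if delta < delta_threshold:
            return "het", delta
        return ("hom_wt" if ct_wt.ct < ct_var.ct else "hom_var"), delta
    if ct_wt.determined or ct_var.determined:
        defined = ct_wt if ct_wt.determined else ct_var
        delta = max(max_cycle - defined.ct, delta_threshold)
        return ("hom_wt" if ct_wt.determined else "hom_var"), delta
    return "no_call", None


def call_sample(
    wells: list,
    panel: Panel,
    dna_conc_ng_per_ul: float | None = None,
    config: CallingConfig = CallingConfig(),
    cts: dict[tuple[str, str], CtResult] | None = None,
) -> list[SnpCall]:
    """Interpret one sample's wells (two per panel SNP) into per-SNP calls.

    ``wells`` are :class:`tpmtyper.io.WellRecord` for a single sample.
    ``cts`` maps (well_id, channel) to precomputed :class:`CtResult`; when
    omitted, each well must carry curves and Cts are computed here.
    """
    from .curves import compute_ct  # local import to avoid cycle at module load

    by_snp: dict[str, dict[str, object]] = {}
    sample_ids = {w.sample_id for w in wells}
    if len(sample_ids) != 1:
        raise ValueError(f"wells span multiple samples: {sorted(sample_ids)}")
    sample_id = sample_ids.pop()
    for w in wells:
        slot = by_snp.setdefault(w.snp_id, {})
        if w.primer_allele in slot:
            raise ValueError(
                f"duplicate {w.primer_allele} well for sample {sample_id} SNP {w.snp_id}"
            )
        slot[w.primer_allele] = w

    input_flags: set[str] = set()
    if dna_conc_ng_per_ul is None:
        input_flags.add(LOW_INPUT_UNKNOWN)
    elif dna_conc_ng_per_ul < config.min_input_ng_per_ul:
        input_flags.add(LOW_INPUT)

    def well_ct(well, channel: str) -> CtResult:
        if cts is not None:
            try:
                return cts[(well.well_id, channel)]
            except KeyError:
                raise ValueError(f"no Ct for well {well.well_id} channel {channel}")
        return compute_ct(well.curves[channel])

    calls: list[SnpCall] = []
    for snp in panel.snps:
        slot = by_snp.get(snp.snp_id, {})
        if set(slot) != {"wt", "var"}:
            raise ValueError(
                f"sample {sample_id}: SNP {snp.snp_id} needs one wt and one var well"
            )
        flags = set(input_flags)
        if not qc_ipc(well_ct(slot["wt"], "IPC"), config.ipc_max_ct):
            flags.add(IPC_FAIL_WT_WELL)
        if not qc_ipc(well_ct(slot["var"], "IPC"), config.ipc_max_ct):
            flags.add(IPC_FAIL_VAR_WELL)
        ct_wt = well_ct(slot["wt"], "TARGET")
        ct_var = well_ct(slot["var"], "TARGET")
        if flags & {IPC_FAIL_WT_WELL, IPC_FAIL_VAR_WELL}:
            genotype, delta = "no_call", None
        else:
            genotype, delta = call_snp(
                ct_wt, ct_var, config.delta_ct_threshold, config.max_cycle
            )
            if genotype == "no_call":
                flags.add(NO_AMPLIFICATION)
        calls.append(
            SnpCall(sample_id, snp.snp_id, genotype, ct_wt, ct_var, delta, flags)
        )
    return calls
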