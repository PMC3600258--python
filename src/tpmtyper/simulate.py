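"""Generative model of the duplex allele-specific qPCR assay.

Every upstream module is testable without instrument data because this
module simulates the whole measurement chain: a diplotype and a DNA input
amount become per-well threshold cycles and, optionally, full 45-cycle
fluorescence curves in the package's own file dialects.

The core model is the textbook exponential-amplification relation

    Ct = A - log_E(copies) [+ mismatch penalty]

with efficiency ``E`` (default 2: perfect doubling, under which a 4-fold
template difference is exactly a delta-Ct of 2), intercept ``A`` = Ct of a
single matched template copy, and a fixed Ct penalty for a primer whose 3'
end mismatches the template (allele specificity).  Stochasticity enters in
three places:

* template sampling: the number of effectively detected template copies is
  Poisson(p x copies) with per-copy detection efficiency ``p``; zero
  detected copies on every route means no amplification, which is what
  makes the limit of detection finite;
* cycle noise: Normal jitter on each well's Ct;
* fluorescence noise on each rendered curve point.

Curves are rendered as baseline + linear drift + a logistic sigmoid placed
so that the noise-free curve crosses the nominal fluorescence threshold
exactly at the well's Ct, which gives downstream Ct estimation an analytic
oracle.  The ng-to-copies conversion (1 ng/uL = 1000 copies/uL) and the
5 uL template volume per reaction follow the assay's published
characterization.

All randomness flows from a single seeded generator; the same seed yields
bit-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from string import ascii_uppercase

import numpy as np
import pandas as pd

from .curves import AmplificationCurve
from .io import SampleMeta, WellRecord, atomic_write_text
from .panel import Panel, default_panel

__all__ = [
    "SimParams",
    "Stratum",
    "SimulatedPlate",
    "LodResult",
    "ct_from_copies",
    "simulate_well",
    "simulate_panel",
    "paper_panel_strata",
    "estimate_lod",
    "copies_per_reaction",
]


@dataclass(frozen=True)
class SimParams:
    """Constants of the generative assay model (defaults = validated assay).

    ``detection_eff`` is calibrated so the default limit of detection lands
    at 1e2 copies/reaction; the per-SNP override for c.719A>G is lower so
    its LOD is 1e3 copies/reaction, matching the assay characterization.
    These are calibration targets, not measurements.
    """

    efficiency: float = 2.0          # amplification factor per cycle, (1, 2]
    ct_intercept: float = 38.0       # Ct of one matched template copy
    mismatch_penalty: float = 12.0   # extra cycles for a 3'-mismatched primer
    ct_noise_sd: float = 0.15        # cycle jitter per well
    ipc_ct_mean: float = 24.0
    ipc_ct_sd: float = 0.3
    copies_per_ng_ul: float = 1000.0  # copies/uL per ng/uL of genomic DNA
    template_volume_ul: float = 5.0   # template volume per reaction
    detection_eff: float = 0.05       # per-copy detection probability
    detection_eff_by_snp: dict = field(
        default_factory=lambda: {"c.719A>G": 0.01}
    )
    max_cycle: int = 45
    # curve rendering
    fmax: float = 3.0                # plateau fluorescence, a.u.
    slope: float = 1.8               # logistic rate per cycle
    baseline_level: float = 0.05
    baseline_drift: float = 0.002    # a.u. per cycle
    fluor_noise_sd: float = 0.01
    curve_threshold: float = 0.1     # fluorescence at which the clean curve crosses at Ct
    seed: int = 17

    def __post_init__(self) -> None:
        if not 1.0 < self.efficiency <= 2.0:
            raise ValueError("efficiency must be in (1, 2]")
        if not 0.0 < self.detection_eff <= 1.0:
            raise ValueError("detection_eff must be in (0, 1]")
        for name in ("ct_intercept", "mismatch_penalty", "copies_per_ng_ul",
                     "template_volume_ul", "fmax", "slope", "curve_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def detection_eff_for(self, snp_id: str | None) -> float:
        if snp_id is None:
            return self.detection_eff
        return self.detection_eff_by_snp.get(snp_id, self.detection_eff)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def copies_per_reaction(conc_ng_per_ul: float, params: SimParams) -> float:
    """Template copies loaded per reaction for a DNA concentration."""
    return conc_ng_per_ul * params.copies_per_ng_ul * params.template_volume_ul


def ct_from_copies(copies: float, matched: bool, params: SimParams) -> float:
    """Deterministic Ct for a template amount; may exceed the run length
    (meaning the curve never crosses within the run)."""
    if copies <= 0:
        raise ValueError("copies must be positive (zero copies are handled by sampling)")
    ct = params.ct_intercept - math.log(copies) / math.log(params.efficiency)
    if not matched:
        ct += params.mismatch_penalty
    return ct


_MATCHED_FRACTION = {  # fraction of template matching the primer's allele
    ("hom_wt", "wt"): 1.0, ("hom_wt", "var"): 0.0,
    ("het", "wt"): 0.5, ("het", "var"): 0.5,
    ("hom_var", "wt"): 0.0, ("hom_var", "var"): 1.0,
}


@dataclass
class SimulatedWell:
    """Ground truth for one reaction: analytic Cts before curve rendering."""

    target_ct: float | None  # true Ct; may exceed max_cycle (=> undetermined)
    ipc_ct: float

    def target_ct_visible(self, max_cycle: float) -> float | None:
        if self.target_ct is None or self.target_ct > max_cycle:
            return None
        return self.target_ct


def simulate_well(
    genotype: str,
    primer_allele: str,
    total_copies: float,
    params: SimParams,
    rng: np.random.Generator,
    snp_id: str | None = None,
) -> SimulatedWell:
    """Draw the true target and IPC Cts for one allele-specific reaction.

    The matched fraction of template is 1 for a matching homozygote, 0.5
    for a heterozygote and 0 for the opposite homozygote; the mismatched
    remainder amplifies with the mismatch penalty.  Each route detects
    Poisson(p x copies) effective copies; the well's Ct is the earlier of
    the two routes, or no amplification if both detect zero.
    """
    if total_copies < 0:
        raise ValueError("total_copies must be non-negative")
    frac = _MATCHED_FRACTION[(genotype, primer_allele)]
    p = params.detection_eff_for(snp_id)
    cts: list[float] = []
    for copies, matched in ((total_copies * frac, True),
                            (total_copies * (1.0 - frac), False)):
        detected = int(rng.poisson(p * copies)) if copies > 0 else 0
        if detected > 0:
            ct = ct_from_copies(detected / p, matched, params)
            cts.append(ct + rng.normal(0.0, params.ct_noise_sd))
    target_ct = min(cts) if cts else None
    ipc_ct = float(rng.normal(params.ipc_ct_mean, params.ipc_ct_sd))
    return SimulatedWell(target_ct, ipc_ct)


def sigmoid_midpoint(ct: float, params: SimParams) -> float:
    """Logistic midpoint placing the clean curve's threshold crossing at ct."""
    return ct + math.log(params.fmax / params.curve_threshold - 1.0) / params.slope


def render_curve(
    ct: float | None, params: SimParams, rng: np.random.Generator
) -> AmplificationCurve:
    """Render a raw fluorescence curve for a well with true Ct ``ct``."""
    cycles = np.arange(1, params.max_cycle + 1)
    fluor = params.baseline_level + params.baseline_drift * cycles
    if ct is not None:
        m = sigmoid_midpoint(ct, params)
        fluor = fluor + params.fmax / (1.0 + np.exp(-params.slope * (cycles - m)))
    if params.fluor_noise_sd > 0:
        fluor = fluor + rng.normal(0.0, params.fluor_noise_sd, size=len(cycles))
    return AmplificationCurve(cycles, np.maximum(fluor, 0.0))


@dataclass(frozen=True)
class Stratum:
    """One homogeneous group of simulated samples."""

    diplotype: str               # e.g. "*1/*3C"
    n: int
    dna_conc_ng_per_ul: float
    sample_ids: tuple[str, ...] | None = None
    group: str = "patient"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"stratum {self.diplotype!r}: n must be >= 1")
        if self.sample_ids is not None and len(self.sample_ids) != self.n:
            raise ValueError("sample_ids length must equal n")


def paper_panel_strata() -> list[Stratum]:
    """The validation-cohort preset: 244 patients (234 *1/*1 + 10 *1/*3C)
    plus the two Coriell heterozygote controls (NA09301 *3B, NA03579 *3C)."""
    return [
        Stratum("*1/*1", 234, 10.0),
        Stratum("*1/*3C", 10, 10.0),
        Stratum("*1/*3B", 1, 10.0, sample_ids=("NA09301",), group="control"),
        Stratum("*1/*3C", 1, 10.0, sample_ids=("NA03579",), group="control"),
    ]


def _well_id(index: int) -> str:
    plate, pos = divmod(index, 96)
    row, col = divmod(pos, 12)
    return f"P{plate + 1}-{ascii_uppercase[row]}{col + 1}"


def _genotype_from_pair(pair: tuple[str, str], snp_id: str, panel: Panel) -> str:
    dose = sum(1 for name in pair if panel.allele(name).carries(snp_id))
    return ("hom_wt", "het", "hom_var")[dose]


@dataclass
class SimulatedPlate:
    """A simulated run: wells, sample metadata, truth, and true Cts."""

    wells: list[WellRecord]
    metas: list[SampleMeta]
    truth_genotypes: pd.DataFrame   # sample_id, snp_id, genotype
    truth_samples: pd.DataFrame     # sample_id, diplotype, group, dna_conc_ng_per_ul
    true_cts: dict[tuple[str, str], float | None]  # (well_id, channel) -> Ct
    params: SimParams

    def write(self, out_dir: str, curves: bool = True) -> dict[str, str]:
        """Write layout/curves-or-Cts/samples/truth files; returns paths."""
        import os

        paths = {
            "layout": os.path.join(out_dir, "layout.csv"),
            "samples": os.path.join(out_dir, "samples.csv"),
            "truth_genotypes": os.path.join(out_dir, "truth.tsv"),
            "truth_samples": os.path.join(out_dir, "truth_diplotypes.tsv"),
        }
        layout_lines = ["well_id,sample_id,snp_id,primer_allele"]
        for w in self.wells:
            layout_lines.append(f"{w.well_id},{w.sample_id},{w.snp_id},{w.primer_allele}")
        atomic_write_text(paths["layout"], "\n".join(layout_lines) + "\n")
        sample_lines = ["sample_id,dna_conc_ng_per_ul"]
        for m in self.metas:
            conc = "" if m.dna_conc_ng_per_ul is None else repr(m.dna_conc_ng_per_ul)
            sample_lines.append(f"{m.sample_id},{conc}")
        atomic_write_text(paths["samples"], "\n".join(sample_lines) + "\n")
        atomic_write_text(paths["truth_genotypes"], self.truth_genotypes.to_csv(sep="\t", index=False))
        atomic_write_text(paths["truth_samples"], self.truth_samples.to_csv(sep="\t", index=False))
        if curves:
            paths["curves"] = os.path.join(out_dir, "curves.csv")
            lines = ["well_id,channel,cycle,fluorescence"]
            for w in self.wells:
                for channel in ("TARGET", "IPC"):
                    curve = w.curves[channel]
                    for c, f in zip(curve.cycles, curve.fluorescence):
                        lines.append(f"{w.well_id},{channel},{c},{f:.6f}")
            atomic_write_text(paths["curves"], "\n".join(lines) + "\n")
        else:
            paths["cts"] = os.path.join(out_dir, "cts.csv")
            lines = ["well_id,channel,ct"]
            max_cycle = float(self.params.max_cycle)
            for (well_id, channel), ct in self.true_cts.items():
                token = "UNDETERMINED" if ct is None or ct > max_cycle else f"{ct:.4f}"
                lines.append(f"{well_id},{channel},{token}")
            atomic_write_text(paths["cts"], "\n".join(lines) + "\n")
        return paths


def simulate_panel(
    strata: list[Stratum],
    panel: Panel | None = None,
    params: SimParams = SimParams(),
    curves: bool = True,
    rng: np.random.Generator | None = None,
) -> SimulatedPlate:
    """Simulate a whole validation run: two wells per SNP per sample."""
    panel = panel or default_panel()
    rng = rng if rng is not None else params.rng()
    wells: list[WellRecord] = []
    metas: list[SampleMeta] = []
    truth_rows: list[dict] = []
    sample_rows: list[dict] = []
    true_cts: dict[tuple[str, str], float | None] = {}

    next_auto = 1
    well_index = 0
    for stratum in strata:
        pair = tuple(sorted(stratum.diplotype.split("/")))
        if len(pair) != 2:
            raise ValueError(f"bad diplotype spec {stratum.diplotype!r}")
        for name in pair:
            panel.allele(name)  # raises KeyError for unknown alleles
        for i in range(stratum.n):
            if stratum.sample_ids is not None:
                sample_id = stratum.sample_ids[i]
            else:
                sample_id = f"S{next_auto:04d}"
                next_auto += 1
            metas.append(SampleMeta(sample_id, stratum.dna_conc_ng_per_ul))
            sample_rows.append(
                {
                    "sample_id": sample_id,
                    "diplotype": "/".join(pair),
                    "group": stratum.group,
                    "dna_conc_ng_per_ul": stratum.dna_conc_ng_per_ul,
                }
            )
            total_copies = copies_per_reaction(stratum.dna_conc_ng_per_ul, params)
            for snp in panel.snps:
                genotype = _genotype_from_pair(pair, snp.snp_id, panel)
                truth_rows.append(
                    {"sample_id": sample_id, "snp_id": snp.snp_id, "genotype": genotype}
                )
                for primer_allele in ("wt", "var"):
                    sim = simulate_well(
                        genotype, primer_allele, total_copies, params, rng, snp.snp_id
                    )
                    well_id = _well_id(well_index)
                    well_index += 1
                    record = WellRecord(
                        well_id, sample_id, snp.snp_id, primer_allele, {}
                    )
                    if curves:
                        record.curves["TARGET"] = render_curve(sim.target_ct, params, rng)
                        record.curves["IPC"] = render_curve(sim.ipc_ct, params, rng)
                    wells.append(record)
                    true_cts[(well_id, "TARGET")] = sim.target_ct
                    true_cts[(well_id, "IPC")] = sim.ipc_ct
    return SimulatedPlate(
        wells=wells,
        metas=metas,
        truth_genotypes=pd.DataFrame(truth_rows),
        truth_samples=pd.DataFrame(sample_rows),
        true_cts=true_cts,
        params=params,
    )


@dataclass
class LodResult:
    """Dilution-series outcome: LOD and the per-concentration call table."""

    lod_copies_per_reaction: float | None
    table: pd.DataFrame  # copies_per_reaction, n_correct, n_replicates, fraction_correct


def estimate_lod(
    snp_id: str | None = None,
    grid: tuple[float, ...] = (1e7, 1e6, 1e5, 1e4, 1e3, 1e2),
    replicates: int = 20,
    params: SimParams = SimParams(),
    rng: np.random.Generator | None = None,
    min_fraction: float = 0.95,
) -> LodResult:
    """Limit of detection from a simulated dilution series of homozygous
    variant template.

    For each concentration (copies/reaction, decreasing powers of ten) the
    two allele-specific reactions are simulated ``replicates`` times and
    interpreted with the delta-Ct rule; the LOD is the smallest
    concentration at which at least ``min_fraction`` of replicates (and all
    larger concentrations) yield the correct homozygous-variant call.
    """
    from .calling import call_snp
    from .curves import CtResult

    if replicates < 4:
        raise ValueError("replicates must be >= 4 (assay used quadruplicates)")
    if list(grid) != sorted(grid, reverse=True):
        raise ValueError("grid must be decreasing")
    rng = rng if rng is not None else params.rng()
    rows = []
    lod: float | None = None
    chain_intact = True
    for copies in grid:
        n_correct = 0
        for _ in range(replicates):
            sim_wt = simulate_well("hom_var", "wt", copies, params, rng, snp_id)
            sim_var = simulate_well("hom_var", "var", copies, params, rng, snp_id)
            ct_wt = CtResult(sim_wt.target_ct_visible(params.max_cycle), 0.0)
            ct_var = CtResult(sim_var.target_ct_visible(params.max_cycle), 0.0)
            genotype, _ = call_snp(ct_wt, ct_var, max_cycle=float(params.max_cycle))
            n_correct += genotype == "hom_var"
        fraction = n_correct / replicates
        rows.append(
            {
                "copies_per_reaction": copies,
                "n_correct": n_correct,
                "n_replicates": replicates,
                "fraction_correct": fraction,
            }
        )
        if chain_intact and fraction >= min_fraction:
            lod = copies
        else:
            chain_intact = False
    return LodResult(lod, pd.DataFrame(rows))
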