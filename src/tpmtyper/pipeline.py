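"""End-to-end interpretation of one plate: curves (or a Ct table) in,
per-sample genotype calls, diplotypes and phenotypes out."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import CallingConfig, SnpCall, call_sample
from .curves import CtResult, baseline_correct, compute_ct, pooled_threshold
from .diplotype import DiplotypeCall, diplotype_sample
from .io import SampleMeta, WellRecord
from .panel import Panel

__all__ = ["SampleResult", "compute_plate_cts", "process_plate", "results_to_genotype_table"]


@dataclass
class SampleResult:
    sample_id: str
    snp_calls: list[SnpCall]
    diplotype_call: DiplotypeCall


def compute_plate_cts(
    wells: list[WellRecord], config: CallingConfig = CallingConfig()
) -> dict[tuple[str, str], CtResult]:
    """Estimate the Ct of every well/channel on a plate.

    Baseline-corrects all curves first so the auto-threshold floor can use
    the plate-wide maximum corrected fluorescence.
    """
    corrected: dict[tuple[str, str], object] = {}
    for well in wells:
        for channel, curve in well.curves.items():
            corrected[(well.well_id, channel)] = baseline_correct(curve)
    if not corrected:
        return {}
    # one threshold per channel, pooled across the plate (instrument practice)
    thresholds = {
        channel: pooled_threshold(
            [c for (_, ch), c in corrected.items() if ch == channel]
        )
        for channel in {ch for _, ch in corrected}
    }
    return {
        key: compute_ct(curve, mode="fixed", fixed_threshold=thresholds[key[1]])
        for key, curve in corrected.items()
    }


def process_plate(
    wells: list[WellRecord],
    metas: list[SampleMeta],
    panel: Panel,
    config: CallingConfig = CallingConfig(),
    cts: dict[tuple[str, str], CtResult] | None = None,
) -> list[SampleResult]:
    """Interpret a whole plate; sample order follows first appearance in
    the layout.  ``cts`` bypasses curve processing (pre-computed Ct table)."""
    if cts is None:
        cts = compute_plate_cts(wells, config)
    conc = {m.sample_id: m.dna_conc_ng_per_ul for m in metas}
    by_sample: dict[str, list[WellRecord]] = {}
    for well in wells:
        by_sample.setdefault(well.sample_id, []).append(well)
    results = []
    for sample_id, sample_wells in by_sample.items():
        snp_calls = call_sample(
            sample_wells,
            panel,
            dna_conc_ng_per_ul=conc.get(sample_id),
            config=config,
            cts=cts,
        )
        dip = diplotype_sample(snp_calls, panel, policy=config.ambiguity_policy)
        results.append(SampleResult(sample_id, snp_calls, dip))
    return results


def results_to_genotype_table(results: list[SampleResult]) -> pd.DataFrame:
    """Long genotype table (sample_id, snp_id, genotype) from plate results."""
    rows = [
        {"sample_id": r.sample_id, "snp_id": c.snp_id, "genotype": c.genotype}
        for r in results
        for c in r.snp_calls
    ]
    return pd.DataFrame(rows)
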