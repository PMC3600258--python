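"""Readers and writers for plate layouts, amplification curves, Ct tables,
reference genotype tables, and result reports.

All dialects are plain text, chosen as the simplest superset of common
instrument exports (real instruments vary and RDML import is a non-goal):

* layout CSV: ``well_id,sample_id,snp_id,primer_allele``
* curve CSV (long): ``well_id,channel,cycle,fluorescence`` with channels
  ``TARGET`` and ``IPC``, cycles 1-based and contiguous
* Ct CSV: ``well_id,channel,ct`` with ``UNDETERMINED`` for no crossing
* samples CSV (optional): ``sample_id,dna_conc_ng_per_ul``
* genotype TSV: ``sample_id,snp_id,genotype``
* reports: one TSV row per sample plus a JSON document with full
  provenance (thresholds, per-well Cts, software version, seed)

All file writes are atomic (temp file + rename).
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .curves import AmplificationCurve, CtResult

__all__ = [
    "InputError",
    "WellRecord",
    "SampleMeta",
    "read_layout",
    "read_curves",
    "read_ct_table",
    "write_ct_table",
    "read_genotype_table",
    "write_genotype_table",
    "write_report",
    "atomic_write_text",
]

CHANNELS = ("TARGET", "IPC")
UNDETERMINED_TOKEN = "UNDETERMINED"


class InputError(ValueError):
    """Raised when an input file is malformed or inconsistent."""


@dataclass
class WellRecord:
    """One reaction well: sample x SNP x allele-specific primer, with curves."""

    well_id: str
    sample_id: str
    snp_id: str
    primer_allele: str  # "wt" | "var"
    curves: dict[str, AmplificationCurve] = field(default_factory=dict)


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    dna_conc_ng_per_ul: float | None = None

    def __post_init__(self) -> None:
        conc = self.dna_conc_ng_per_ul
        if conc is not None and conc < 0:
            raise InputError(f"sample {self.sample_id}: negative DNA concentration")


def _read_csv(source, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(source, dtype=str, **kw)
    except Exception as exc:  # pragma: no cover - message wrapper
        raise InputError(f"cannot parse CSV input: {exc}") from exc


def _require_columns(df: pd.DataFrame, columns: Iterable[str], what: str) -> None:
    missing = set(columns) - set(df.columns)
    if missing:
        raise InputError(f"{what} missing columns: {sorted(missing)}")


def read_layout(source) -> pd.DataFrame:
    """Read and validate a plate layout CSV."""
    layout = _read_csv(source)
    _require_columns(layout, ["well_id", "sample_id", "snp_id", "primer_allele"], "layout")
    bad = set(layout["primer_allele"]) - {"wt", "var"}
    if bad:
        raise InputError(f"layout primer_allele must be wt/var, got {sorted(bad)}")
    if layout["well_id"].duplicated().any():
        dups = sorted(layout.loc[layout["well_id"].duplicated(), "well_id"])
        raise InputError(f"duplicate well_id in layout: {dups}")
    key = ["sample_id", "snp_id", "primer_allele"]
    if layout.duplicated(key).any():
        dups = layout[layout.duplicated(key, keep=False)].sort_values(key)
        raise InputError(
            "duplicate (sample_id, snp_id, primer_allele) in layout: "
            + ", ".join(map(str, dups[key].drop_duplicates().itertuples(index=False)))
        )
    return layout


def read_samples(source) -> list[SampleMeta]:
    """Read the optional per-sample metadata CSV."""
    df = _read_csv(source)
    _require_columns(df, ["sample_id", "dna_conc_ng_per_ul"], "samples table")
    metas = []
    for row in df.itertuples(index=False):
        raw = row.dna_conc_ng_per_ul
        conc = None if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "" \
            else float(raw)
        metas.append(SampleMeta(str(row.sample_id), conc))
    return metas


def read_curves(
    layout_source, curve_source, samples_source=None
) -> tuple[list[WellRecord], list[SampleMeta]]:
    """Join a plate layout with a long-format curve CSV into WellRecords.

    Every layout well must have both a TARGET and an IPC curve with
    contiguous 1-based cycles; anything else is an :class:`InputError`
    naming the offending well.
    """
    layout = read_layout(layout_source)
    curves = _read_csv(curve_source)
    _require_columns(curves, ["well_id", "channel", "cycle", "fluorescence"], "curve file")
    bad_channels = set(curves["channel"]) - set(CHANNELS)
    if bad_channels:
        raise InputError(f"unknown channels in curve file: {sorted(bad_channels)}")
    curves = curves.assign(
        cycle=curves["cycle"].astype(int),
        fluorescence=curves["fluorescence"].astype(float),
    )
    if curves.duplicated(["well_id", "channel", "cycle"]).any():
        dup = curves[curves.duplicated(["well_id", "channel", "cycle"])].iloc[0]
        raise InputError(
            f"duplicate curve row for well {dup['well_id']} channel {dup['channel']} "
            f"cycle {dup['cycle']}"
        )

    grouped = {
        key: grp.sort_values("cycle")
        for key, grp in curves.groupby(["well_id", "channel"], sort=False)
    }
    records: list[WellRecord] = []
    for row in layout.itertuples(index=False):
        well_curves: dict[str, AmplificationCurve] = {}
        for channel in CHANNELS:
            grp = grouped.get((row.well_id, channel))
            if grp is None:
                raise InputError(f"well {row.well_id}: no {channel} curve rows")
            cycles = grp["cycle"].to_numpy()
            if cycles[0] != 1 or not np.all(np.diff(cycles) == 1):
                raise InputError(
                    f"well {row.well_id} channel {channel}: cycles must be contiguous from 1"
                )
            try:
                well_curves[channel] = AmplificationCurve(
                    cycles, grp["fluorescence"].to_numpy()
                )
            except ValueError as exc:
                raise InputError(f"well {row.well_id} channel {channel}: {exc}") from exc
        records.append(
            WellRecord(row.well_id, row.sample_id, row.snp_id, row.primer_allele, well_curves)
        )

    if samples_source is not None:
        metas = read_samples(samples_source)
    else:
        seen = dict.fromkeys(layout["sample_id"])
        metas = [SampleMeta(sample_id) for sample_id in seen]
    return records, metas


def read_ct_table(source, max_cycle: float = 45.0) -> dict[tuple[str, str], CtResult]:
    """Read a pre-computed Ct CSV (instrument export bypassing curves)."""
    df = _read_csv(source)
    _require_columns(df, ["well_id", "channel", "ct"], "Ct table")
    out: dict[tuple[str, str], CtResult] = {}
    for row in df.itertuples(index=False):
        if row.channel not in CHANNELS:
            raise InputError(f"well {row.well_id}: unknown channel {row.channel!r}")
        key = (str(row.well_id), str(row.channel))
        if key in out:
            raise InputError(f"duplicate Ct row for well {key[0]} channel {key[1]}")
        token = str(row.ct).strip()
        if token == UNDETERMINED_TOKEN:
            out[key] = CtResult(None, threshold=float("nan"))
            continue
        ct = float(token)
        if not 0.0 < ct <= max_cycle:
            raise InputError(
                f"well {row.well_id} channel {row.channel}: Ct {ct} outside (0, {max_cycle}]"
            )
        out[key] = CtResult(ct, threshold=float("nan"))
    return out


def write_ct_table(cts: dict[tuple[str, str], CtResult], path: str) -> None:
    lines = ["well_id,channel,ct"]
    for (well_id, channel), res in cts.items():
        token = UNDETERMINED_TOKEN if res.ct is None else repr(float(res.ct))
        lines.append(f"{well_id},{channel},{token}")
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_genotype_table(source) -> pd.DataFrame:
    """Read a genotype TSV (``sample_id, snp_id, genotype``)."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    _require_columns(df, ["sample_id", "snp_id", "genotype"], "genotype table")
    allowed = {"hom_wt", "het", "hom_var", "no_call"}
    bad = set(df["genotype"]) - allowed
    if bad:
        raise InputError(f"unknown genotype labels: {sorted(bad)}")
    if df.duplicated(["sample_id", "snp_id"]).any():
        raise InputError("duplicate (sample_id, snp_id) rows in genotype table")
    return df[["sample_id", "snp_id", "genotype"]]


def write_genotype_table(df: pd.DataFrame, path: str) -> None:
    atomic_write_text(path, df.to_csv(sep="\t", index=False))


def atomic_write_text(path: str, text: str) -> None:
    """Write text to ``path`` atomically (temp file in same dir + rename)."""
    directory = os.path.dirname(os.path.abspath(path))
    os.makedirs(directory, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=directory, prefix=".tmp-", text=True)
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _ct_repr(res: CtResult | None) -> str:
    if res is None or res.ct is None:
        return UNDETERMINED_TOKEN
    return f"{res.ct:.2f}"


def write_report(
    sample_results: list,
    panel,
    tsv_path: str | None = None,
    json_path: str | None = None,
    config=None,
    seed: int | None = None,
) -> tuple[str, str]:
    """Render per-sample results as a one-row-per-sample TSV plus a JSON
    document with full provenance; returns the two texts (and writes them
    when paths are given).

    ``sample_results`` are :class:`tpmtyper.pipeline.SampleResult`.
    """
    from . import __version__

    snp_ids = panel.snp_ids
    header = ["sample_id"]
    for snp_id in snp_ids:
        header += [f"genotype:{snp_id}", f"delta_ct:{snp_id}"]
    header += ["diplotype", "ambiguous", "alternatives", "phenotype", "alt_phenotype", "qc_flags"]
    lines = ["\t".join(header)]
    json_samples = []
    for res in sample_results:
        calls = {c.snp_id: c for c in res.snp_calls}
        row = [res.sample_id]
        flags: set[str] = set()
        for snp_id in snp_ids:
            call = calls[snp_id]
            flags |= call.qc_flags
            delta = "NA" if call.delta_ct is None else f"{call.delta_ct:.2f}"
            row += [call.genotype, delta]
        dip = res.diplotype_call
        alternatives = ";".join(
            f"{'/'.join(pair)}({score:.3g})" for pair, score in dip.alternatives
        )
        row += [
            dip.diplotype,
            str(dip.ambiguous).lower(),
            alternatives or "NA",
            dip.phenotype,
            dip.alt_phenotype or "NA",
            ",".join(sorted(flags)) or "PASS",
        ]
        lines.append("\t".join(row))
        json_samples.append(
            {
                "sample_id": res.sample_id,
                "snps": {
                    snp_id: {
                        "genotype": calls[snp_id].genotype,
                        "delta_ct": calls[snp_id].delta_ct,
                        "ct_wt": None if not calls[snp_id].ct_wt.determined else calls[snp_id].ct_wt.ct,
                        "ct_var": None if not calls[snp_id].ct_var.determined else calls[snp_id].ct_var.ct,
                        "threshold_wt": calls[snp_id].ct_wt.threshold,
                        "threshold_var": calls[snp_id].ct_var.threshold,
                        "qc_flags": sorted(calls[snp_id].qc_flags),
                    }
                    for snp_id in snp_ids
                },
                "diplotype": dip.diplotype,
                "ambiguous": dip.ambiguous,
                "alternatives": [
                    {"diplotype": "/".join(pair), "score": score}
                    for pair, score in dip.alternatives
                ],
                "phenotype": dip.phenotype,
                "alt_phenotype": dip.alt_phenotype,
            }
        )
    tsv_text = "\n".join(lines) + "\n"
    doc = {
        "software": {"name": "tpmtyper", "version": __version__},
        "panel": panel.name,
        "config": None if config is None else {
            "delta_ct_threshold": config.delta_ct_threshold,
            "ipc_max_ct": config.ipc_max_ct,
            "max_cycle": config.max_cycle,
            "min_input_ng_per_ul": config.min_input_ng_per_ul,
            "ambiguity_policy": config.ambiguity_policy,
        },
        "seed": seed,
        "n_samples": len(sample_results),
        "samples": json_samples,
    }
    json_text = json.dumps(doc, indent=2) + "\n"
    if tsv_path:
        atomic_write_text(tsv_path, tsv_text)
    if json_path:
        atomic_write_text(json_path, json_text)
    return tsv_text, json_text
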