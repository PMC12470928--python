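"""Quantitative methylation calling from Sanger bisulfite electropherograms.

Sanger bisulfite sequencing is traditionally qualitative: peak amplitudes
depend strongly on the local nucleotide context, so the raw T-channel signal
at a converted CpG cannot be read as a methylation fraction. The procedure
implemented here makes it quantitative:

1. **context correction** — each CpG's T-channel amplitude is divided by the
   median amplitude of nearby invariant (non-CpG, non-variable) peaks, which
   absorbs trace-wide and local intensity fluctuations;
2. **calibration** — "model amplicons", produced by amplifying the target
   first and bisulfite-converting the PCR product afterwards, contain only
   unmethylated cytosines and hence define the 0%-methylation signal; the
   per-site scaling coefficient is ``scale = 100 / median(corrected model
   signal)``;
3. **measurement** — a sample's methylation at a CpG is
   ``100 - scale * corrected_T_signal``, clamped to [0, 100].

Sites without a resolvable T peak or without calibration propagate as
missing (NaN), never as 0 — electropherogram dropout is a known feature of
this assay and is handled downstream by missing-aware modelling.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TraceBundle",
    "CalibrationScale",
    "correct_signal",
    "build_calibration",
    "methylation_from_trace",
    "quantify_traces",
    "write_traces_tsv",
    "read_traces_tsv",
]

PEAK_COLUMNS = ["slot", "kind", "genomic_position", "channel", "amplitude"]


@dataclass
class TraceBundle:
    """Peak amplitudes extracted from one trace (one sample, one amplicon).

    ``peaks`` has columns ``slot`` (0-based base position along the insert),
    ``kind`` ("cpg" for the variable CpG cytosine slot, "flank" for invariant
    context peaks), ``genomic_position`` (hg19 position for CpG slots, -1 for
    flanks), ``channel`` (A/C/G/T) and ``amplitude`` (non-negative).
    A CpG slot may carry both a C and a T peak; a site dropped by the
    instrument simply has no peaks at its slot.
    """

    sample_id: str
    locus_id: str
    peaks: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(PEAK_COLUMNS) - set(self.peaks.columns)
        if missing:
            raise ValueError(f"peaks missing columns: {sorted(missing)}")
        if (self.peaks["amplitude"] < 0).any():
            raise ValueError("peak amplitudes must be non-negative")
        cpg = self.peaks[self.peaks["kind"] == "cpg"]
        if cpg.duplicated(["genomic_position", "channel"]).any():
            raise ValueError("duplicate CpG peak for one channel")

    def cpg_positions(self) -> list[int]:
        pos = self.peaks.loc[self.peaks["kind"] == "cpg", "genomic_position"]
        return sorted(set(int(p) for p in pos))

    def resolved(self, positions: Iterable[int]) -> dict[int, bool]:
        """Whether each requested CpG position has any peak in this trace."""
        present = set(self.cpg_positions())
        return {int(p): int(p) in present for p in positions}


@dataclass
class CalibrationScale:
    """Per-CpG scaling derived from fully-unmethylated model amplicons.

    ``scale[p] == 100 / median_unmethylated_signal[p]`` by construction.
    Sites whose corrected signal was missing in every model trace, or whose
    median is zero, are listed in ``uncalibratable``.
    """

    median_unmethylated_signal: dict[int, float] = field(default_factory=dict)
    scale: dict[int, float] = field(default_factory=dict)
    uncalibratable: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        for p, med in self.median_unmethylated_signal.items():
            if not math.isclose(self.scale[p] * med, 100.0, rel_tol=1e-12):
                raise ValueError(f"scale/median inconsistent at {p}")


def correct_signal(
    trace: TraceBundle,
    window: int = 5,
    positions: Sequence[int] | None = None,
    channel: str = "T",
) -> dict[int, float]:
    """Context-corrected signal per CpG: T amplitude / median flank amplitude.

    Flank peaks are the invariant peaks within ``window`` slots on either
    side of the CpG slot. A dropped CpG (no peak in any channel at its slot)
    or one with no flank peaks in the window maps to NaN. A resolved CpG
    whose requested channel carries no peak has signal 0 — e.g. a fully
    methylated site shows a C peak but no T peak.
    """
    peaks = trace.peaks
    cpg = peaks[peaks["kind"] == "cpg"]
    flank = peaks[peaks["kind"] == "flank"]
    flank_slots = flank["slot"].to_numpy()
    flank_amp = flank["amplitude"].to_numpy(dtype=float)

    if positions is None:
        positions = trace.cpg_positions()

    out: dict[int, float] = {}
    for p in positions:
        p = int(p)
        site = cpg[cpg["genomic_position"] == p]
        if site.empty:
            out[p] = float("nan")
            continue
        rows = site[site["channel"] == channel]
        amplitude = float(rows["amplitude"].iloc[0]) if not rows.empty else 0.0
        slot = int(site["slot"].iloc[0])
        in_window = np.abs(flank_slots - slot) <= window
        if not in_window.any():
            out[p] = float("nan")
            continue
        out[p] = amplitude / float(np.median(flank_amp[in_window]))
    return out


def build_calibration(
    model_traces: Sequence[TraceBundle],
    window: int = 5,
    positions: Sequence[int] | None = None,
) -> CalibrationScale:
    """Median corrected signal of unmethylated model amplicons, per CpG.

    At least one model trace is required; three or more replicates make the
    median robust to single-trace artefacts.
    """
    if not model_traces:
        raise ValueError("at least one model trace is required")
    per_site: dict[int, list[float]] = {}
    if positions is not None:
        for p in positions:
            per_site[int(p)] = []
    for trace in model_traces:
        for p, v in correct_signal(trace, window=window, positions=positions).items():
            per_site.setdefault(p, []).append(v)

    calib = CalibrationScale()
    for p, values in per_site.items():
        finite = [v for v in values if math.isfinite(v)]
        if not finite:
            calib.uncalibratable.add(p)
            continue
        med = float(np.median(finite))
        if med <= 0:
            calib.uncalibratable.add(p)
            continue
        calib.median_unmethylated_signal[p] = med
        calib.scale[p] = 100.0 / med
    return calib


def methylation_from_trace(
    trace: TraceBundle,
    calib: CalibrationScale,
    window: int = 5,
    positions: Sequence[int] | None = None,
    clamp: bool = True,
    composite: bool = False,
) -> dict[int, float]:
    """Per-CpG methylation percent: ``100 - scale * corrected_T_signal``.

    The corrected T signal measures the *converted* (unmethylated) fraction,
    so a signal equal to the model median reads 0% and an absent T peak with
    a present C peak reads 100%. Values are clamped to [0, 100] unless
    ``clamp=False`` (raw values are useful diagnostics: noise can push the
    linear estimate slightly outside the scale).

    ``composite=True`` switches to the alternative amplitude-ratio estimator
    ``100 * C / (C + T)`` computed from the two channel amplitudes at the
    CpG slot; it needs no calibration but ignores context correction.
    """
    if composite:
        return _composite_estimate(trace, positions)

    corrected = correct_signal(trace, window=window, positions=positions)
    out: dict[int, float] = {}
    for p, signal in corrected.items():
        if not math.isfinite(signal) or p in calib.uncalibratable or p not in calib.scale:
            out[p] = float("nan")
            continue
        value = 100.0 - calib.scale[p] * signal
        out[p] = min(100.0, max(0.0, value)) if clamp else value
    return out


def _composite_estimate(
    trace: TraceBundle, positions: Sequence[int] | None
) -> dict[int, float]:
    cpg = trace.peaks[trace.peaks["kind"] == "cpg"]
    if positions is None:
        positions = trace.cpg_positions()
    out: dict[int, float] = {}
    for p in positions:
        p = int(p)
        rows = cpg[cpg["genomic_position"] == p]
        if rows.empty:
            out[p] = float("nan")
            continue
        amp = {ch: 0.0 for ch in "ACGT"}
        for _, r in rows.iterrows():
            amp[r["channel"]] = float(r["amplitude"])
        total = amp["C"] + amp["T"]
        out[p] = 100.0 * amp["C"] / total if total > 0 else float("nan")
    return out


def quantify_traces(
    traces_by_sample: Mapping[str, Sequence[TraceBundle]],
    calib: CalibrationScale,
    position_names: Mapping[int, str],
    window: int = 5,
    composite: bool = False,
) -> pd.DataFrame:
    """Assemble a samples x CpG-features methylation matrix (percent, NaN
    for missing) from per-sample trace bundles."""
    records: dict[str, dict[str, float]] = {}
    for sample_id, traces in traces_by_sample.items():
        row: dict[str, float] = {}
        for trace in traces:
            est = methylation_from_trace(
                trace, calib, window=window, composite=composite
            )
            for p, v in est.items():
                if p in position_names:
                    row[position_names[p]] = v
        records[sample_id] = row
    df = pd.DataFrame.from_dict(records, orient="index")
    # sites dropped in every trace still appear, as all-missing columns
    return df.reindex(columns=list(position_names.values()))


# ---------------------------------------------------------------------------
# TSV round trip for trace bundles


def write_traces_tsv(traces: Sequence[TraceBundle], path: str | Path) -> None:
    frames = []
    for t in traces:
        df = t.peaks.copy()
        df.insert(0, "locus", t.locus_id)
        df.insert(0, "sample", t.sample_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_traces_tsv(path: str | Path) -> list[TraceBundle]:
    df = pd.read_csv(path, sep="\t", na_values="NA", keep_default_na=False)
    out = []
    for (sample, locus), grp in df.groupby(["sample", "locus"], sort=False):
        peaks = grp[PEAK_COLUMNS].reset_index(drop=True)
        out.append(TraceBundle(sample_id=str(sample), locus_id=str(locus), peaks=peaks))
    return out
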