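"""Synthetic case/control cohorts for the targeted methylation pipeline.

The study design this package supports — deep targeted bisulfite sequencing
plus calibrated quantitative Sanger sequencing of a four-amplicon panel —
cannot ship its patient DNA. This module generates cohorts with the same
statistical structure so every downstream stage is exercisable end to end:

* per-sample, per-CpG *true* methylation: controls centred at a high
  baseline, cases (and VUS carriers, who behave like cases) shifted down by
  the episignature delta-betas, with per-sample biological noise; samples
  from phenotypically overlapping syndromes are drawn from the control
  distribution;
* bisulfite amplicon reads at deep (default 8000x) coverage with imperfect
  conversion and uniform substitution error;
* four-channel Sanger trace bundles with context-dependent peak amplitudes,
  multiplicative trace noise, replicate fully-unmethylated model-amplicon
  traces for calibration, and the structured site-dropout pattern Sanger
  bisulfite sequencing exhibits on this panel.

Everything is deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import AmpliconDesign, load_episignature, load_panel, merged_feature_name
from .sanger import PEAK_COLUMNS, TraceBundle

__all__ = [
    "SyntheticConfig",
    "SampleTruth",
    "default_config",
    "generate_cohort",
    "synthetic_references",
    "simulate_reads",
    "simulate_traces",
    "simulate_model_traces",
    "reads_to_fastq",
    "truth_matrix",
    "labels_series",
    "SANGER_MISSING_DEFAULTS",
]

# Structured dropout of Sanger bisulfite sequencing on this panel: sites the
# chemistry/trace never resolves (rate 1.0), sites resolved only in a limited
# fraction of samples, and sites with occasional loss.
SANGER_MISSING_DEFAULTS: dict[int, float] = {
    # never assessed
    10555905: 1.0,
    10556174: 1.0,
    10556244: 1.0,
    206628415: 1.0,
    206628592: 1.0,
    206628606: 1.0,
    206628609: 1.0,
    # assessed in a limited number of samples
    10555808: 0.7,
    10556052: 0.7,
    10556107: 0.7,
    10556147: 0.7,
    10556199: 0.7,
    206628553: 0.7,
    # occasional loss
    10555881: 0.1,
    10556204: 0.1,
    206628525: 0.1,
    206628529: 0.1,
    206628531: 0.1,
    206628539: 0.1,
    206628625: 0.1,
    206628645: 0.1,
    206628747: 0.1,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = (int(b) for b in _BASES)
# base byte -> index in _BASES (255 = not a base)
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _BASE_INDEX[_b] = _i

_REFERENCE_SEED = 190925  # fixed: synthetic references are a panel artefact


@dataclass(frozen=True)
class SampleTruth:
    """Ground-truth methylation of one synthetic sample (percent scale)."""

    sample_id: str
    label: str  # control | rts1 | vus | overlap
    true_methylation: dict[int, float]

    def __post_init__(self) -> None:
        if self.label not in {"control", "rts1", "vus", "overlap"}:
            raise ValueError(f"unknown label {self.label!r}")
        for p, v in self.true_methylation.items():
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"methylation out of [0, 100] at {p}: {v}")


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the synthetic study, with the cohort composition and
    effect sizes of the emulated study as defaults.

    ``control_baseline`` and ``case_delta`` are percent / percentage-point
    maps keyed by genomic position; the case centre at a site is
    ``baseline + delta`` (deltas are negative: cases are hypomethylated).
    ``context_amplitude`` is the site-specific Sanger peak-amplitude factor
    relative to invariant flank peaks. ``sanger_missing_rate`` is the
    per-site probability that a sample trace drops the site entirely.
    """

    n_control: int = 30
    n_case: int = 60
    n_vus: int = 5
    n_overlap: int = 4
    control_baseline: dict[int, float] = field(default_factory=dict)
    case_delta: dict[int, float] = field(default_factory=dict)
    biological_sd: float = 5.0
    coverage: int = 8000
    conversion_efficiency: float = 0.995
    seq_error_rate: float = 0.002
    trace_noise_cv: float = 0.05
    context_amplitude: dict[int, float] = field(default_factory=dict)
    sanger_missing_rate: dict[int, float] = field(default_factory=dict)
    n_model_traces: int = 3
    noise_model: str = "normal"  # or "beta" (moment-matched)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_control", "n_case", "n_vus", "n_overlap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.coverage < 1:
            raise ValueError("coverage must be >= 1")
        for name in ("conversion_efficiency", "seq_error_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for p, r in self.sanger_missing_rate.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"sanger_missing_rate[{p}] out of [0, 1]")
        if self.noise_model not in {"normal", "beta"}:
            raise ValueError("noise_model must be 'normal' or 'beta'")

    @property
    def n_total(self) -> int:
        return self.n_control + self.n_case + self.n_vus + self.n_overlap


def default_config(
    panel: Sequence[AmpliconDesign] | None = None,
    control_baseline: float = 92.0,
    seed: int = 0,
    **overrides,
) -> SyntheticConfig:
    """Config reproducing the emulated study conditions on the shipped panel.

    Controls sit at a high promoter-CpG-island-shore baseline (92% at every
    panel site — an assumption, chosen so the case and control classes
    straddle the mid-80s% cut-off region given ~-20 pp case deltas); case
    deltas come from the episignature table (array delta-beta x 100), with
    flanking CpGs lacking a probe taking their locus' mean delta. Sanger
    context-amplitude factors are fixed site-specific values in [0.6, 1.4].
    """
    if panel is None:
        panel = load_panel()
    episig = load_episignature()
    by_locus: dict[str, list[float]] = {}
    delta_by_pos: dict[int, float] = {}
    locus_of_pos: dict[int, str] = {}
    for c in episig:
        locus_of_pos[c.position] = c.locus
        if c.delta_beta is not None:
            by_locus.setdefault(c.locus, []).append(c.delta_beta * 100.0)
            delta_by_pos[c.position] = c.delta_beta * 100.0
    locus_mean = {loc: float(np.mean(v)) for loc, v in by_locus.items()}

    positions = sorted(p for a in panel for p in a.encompassed_cpgs)
    baseline = {p: control_baseline for p in positions}
    delta = {}
    for p in positions:
        if p in delta_by_pos:
            delta[p] = delta_by_pos[p]
        else:
            delta[p] = locus_mean.get(locus_of_pos.get(p, ""), -20.0)

    ctx_rng = np.random.default_rng(_REFERENCE_SEED)
    context = {p: float(a) for p, a in zip(positions, ctx_rng.uniform(0.6, 1.4, len(positions)))}
    missing = {p: SANGER_MISSING_DEFAULTS.get(p, 0.0) for p in positions}

    return SyntheticConfig(
        control_baseline=baseline,
        case_delta=delta,
        context_amplitude=context,
        sanger_missing_rate=missing,
        seed=seed,
        **overrides,
    )


# ---------------------------------------------------------------------------
# cohort truths


def generate_cohort(config: SyntheticConfig) -> list[SampleTruth]:
    """Draw per-sample true methylation for the configured cohort.

    Controls and overlapping-syndrome samples are centred at the control
    baseline; cases and VUS carriers at baseline + delta. Noise is a clamped
    normal with sd ``biological_sd`` (or a moment-matched beta when
    ``noise_model='beta'``). Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    positions = sorted(config.control_baseline)
    if not positions:
        raise ValueError("config.control_baseline is empty")
    base = np.array([config.control_baseline[p] for p in positions])
    delta = np.array([config.case_delta.get(p, 0.0) for p in positions])

    groups = [
        ("control", "C", config.n_control, base),
        ("rts1", "R", config.n_case, base + delta),
        ("vus", "V", config.n_vus, base + delta),
        ("overlap", "O", config.n_overlap, base),
    ]
    cohort: list[SampleTruth] = []
    for label, prefix, n, centre in groups:
        centre = np.clip(centre, 0.0, 100.0)
        for i in range(n):
            values = _draw_truth(rng, centre, config.biological_sd, config.noise_model)
            cohort.append(
                SampleTruth(
                    sample_id=f"{prefix}{i + 1:03d}",
                    label=label,
                    true_methylation={p: float(v) for p, v in zip(positions, values)},
                )
            )
    return cohort


def _draw_truth(
    rng: np.random.Generator, centre: np.ndarray, sd: float, model: str
) -> np.ndarray:
    if sd == 0:
        return centre.copy()
    if model == "normal":
        return np.clip(centre + sd * rng.standard_normal(centre.shape), 0.0, 100.0)
    # beta with matched mean/sd on the [0,1] scale; falls back to clamped
    # normal where the moment match is infeasible (variance too large)
    m = centre / 100.0
    s = sd / 100.0
    nu = m * (1 - m) / s**2 - 1
    values = np.empty_like(centre)
    for i, (mi, nui) in enumerate(zip(m, nu)):
        if nui > 0 and 0 < mi < 1:
            values[i] = 100.0 * rng.beta(mi * nui, (1 - mi) * nui)
        else:
            values[i] = np.clip(centre[i] + sd * rng.standard_normal(), 0.0, 100.0)
    return values


def labels_series(cohort: Sequence[SampleTruth]) -> pd.Series:
    return pd.Series({s.sample_id: s.label for s in cohort}, name="label")


def truth_matrix(
    cohort: Sequence[SampleTruth], panel: Sequence[AmpliconDesign] | None = None
) -> pd.DataFrame:
    """Samples x features matrix of *true* methylation (plus merged-pair
    features when a panel is given) — the noiseless reference for what the
    quantification backends estimate."""
    rows = {s.sample_id: s.true_methylation for s in cohort}
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)
    chrom_of = {}
    if panel is not None:
        for a in panel:
            for p in a.encompassed_cpgs:
                chrom_of[p] = a.insert_chrom
        df.columns = [f"{chrom_of.get(p, 'chr?')}:{p}" for p in df.columns]
        for a in panel:
            for x, y in a.merged_pairs:
                name = merged_feature_name(a.insert_chrom, x, y)
                df[name] = df[[f"{a.insert_chrom}:{x}", f"{a.insert_chrom}:{y}"]].mean(axis=1)
    return df


# ---------------------------------------------------------------------------
# reference sequences


def synthetic_references(
    panel: Sequence[AmpliconDesign], seed: int = _REFERENCE_SEED
) -> dict[str, str]:
    """Deterministic synthetic insert sequences with a CpG at every
    encompassed position and no other CpG dinucleotide.

    These stand in for the hg19 inserts so that no genome download is
    needed; read simulation and read matching only require that CpG and
    non-CpG cytosines sit at known offsets.
    """
    rng = np.random.default_rng(seed)
    refs: dict[str, str] = {}
    for a in panel:
        length = a.insert_length
        seq = rng.choice(_BASES, size=length).astype(np.uint8)
        for off in a.cpg_offsets():
            if off + 1 >= length:
                raise ValueError(f"CpG at insert edge in {a.locus_id}")
            seq[off] = _C
            seq[off + 1] = _G
        cpg_off = set(a.cpg_offsets())
        # break accidental CpGs so every CG dinucleotide is a designed site
        for i in range(length - 1):
            if seq[i] == _C and seq[i + 1] == _G and i not in cpg_off:
                seq[i + 1] = _A
        refs[a.locus_id] = seq.tobytes().decode()
    return refs


def non_cpg_c_offsets(ref: str, cpg_offsets: Sequence[int]) -> np.ndarray:
    arr = np.frombuffer(ref.encode(), dtype=np.uint8)
    mask = arr == _C
    mask[list(cpg_offsets)] = False
    return np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(
    truth: SampleTruth,
    panel: Sequence[AmpliconDesign],
    insert_seqs: Mapping[str, str],
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    max_read_len: int = 260,
) -> dict[str, np.ndarray]:
    """Simulate bisulfite amplicon reads for one sample.

    Returns per locus a (coverage x read_length) uint8 array of base bytes
    (use :func:`reads_to_fastq` for FASTQ). Per read and CpG, the cytosine
    is methylated (protected) with probability truth/100; unmethylated CpG
    cytosines and all non-CpG cytosines convert to T with probability
    ``conversion_efficiency``; substitution errors are uniform at
    ``seq_error_rate``. Reads are the full insert, truncated to
    ``max_read_len``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out: dict[str, np.ndarray] = {}
    for a in panel:
        if a.locus_id not in insert_seqs:
            raise KeyError(f"no reference sequence for locus {a.locus_id}")
        ref = insert_seqs[a.locus_id]
        arr = np.frombuffer(ref.encode(), dtype=np.uint8)
        n = config.coverage
        reads = np.tile(arr, (n, 1))

        cpg_off = np.array(a.cpg_offsets())
        m = np.array([truth.true_methylation[p] for p in a.encompassed_cpgs]) / 100.0
        methylated = rng.random((n, cpg_off.size)) < m
        converts = rng.random((n, cpg_off.size)) < config.conversion_efficiency
        reads[:, cpg_off] = np.where(~methylated & converts, _T, _C).astype(np.uint8)

        nc = non_cpg_c_offsets(ref, a.cpg_offsets())
        if nc.size:
            conv = rng.random((n, nc.size)) < config.conversion_efficiency
            reads[:, nc] = np.where(conv, _T, _C).astype(np.uint8)

        if config.seq_error_rate > 0:
            err = rng.random(reads.shape) < config.seq_error_rate
            k = int(err.sum())
            if k:
                cur = _BASE_INDEX[reads[err]]
                reads[err] = _BASES[(cur + rng.integers(1, 4, size=k)) % 4]

        out[a.locus_id] = reads[:, :max_read_len]
    return out


def reads_to_fastq(
    reads: np.ndarray, sample_id: str, locus_id: str, quality: int = 30
):
    """Wrap a read array as Biopython SeqRecords (constant base quality)."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = []
    length = reads.shape[1]
    for i, row in enumerate(reads):
        rec = SeqRecord(
            Seq(row.tobytes().decode()),
            id=f"{sample_id}|{locus_id}|{i}",
            description="",
        )
        rec.letter_annotations["phred_quality"] = [quality] * length
        records.append(rec)
    return records


def write_fastq(records, path: str | Path) -> None:
    from Bio import SeqIO

    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


# ---------------------------------------------------------------------------
# trace simulation


def simulate_traces(
    truth: SampleTruth,
    panel: Sequence[AmpliconDesign],
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    insert_seqs: Mapping[str, str] | None = None,
    window: int = 5,
    apply_missing: bool = True,
) -> list[TraceBundle]:
    """Simulate one sample's Sanger trace bundle per amplicon.

    At each CpG slot the T peak carries the converted (unmethylated)
    fraction and the C peak the protected fraction, both scaled by the
    site's context amplitude and multiplicative noise; invariant flank peaks
    (amplitude ~= 1 x noise) surround each CpG for context correction.
    Sites drop out entirely with their configured missing rate.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if insert_seqs is None:
        insert_seqs = synthetic_references(panel)

    bundles = []
    for a in panel:
        ref = insert_seqs[a.locus_id]
        cpg_off = a.cpg_offsets()
        cpg_set = set(cpg_off)
        rows: list[tuple] = []
        for p, off in zip(a.encompassed_cpgs, cpg_off):
            if apply_missing and rng.random() < config.sanger_missing_rate.get(p, 0.0):
                continue
            ctx = config.context_amplitude.get(p, 1.0)
            frac = truth.true_methylation[p] / 100.0
            t_amp = ctx * (1.0 - frac) * _noise(rng, config.trace_noise_cv)
            c_amp = ctx * frac * _noise(rng, config.trace_noise_cv)
            rows.append((off, "cpg", p, "T", t_amp))
            rows.append((off, "cpg", p, "C", c_amp))
        flank_slots = sorted(
            {
                s
                for off in cpg_off
                for s in range(max(0, off - window), min(len(ref), off + window + 1))
                if s not in cpg_set and s - 1 not in cpg_set  # skip CpG C and G slots
            }
        )
        for s in flank_slots:
            channel = "T" if ref[s] == "C" else ref[s]  # converted reference base
            rows.append((s, "flank", -1, channel, _noise(rng, config.trace_noise_cv)))
        peaks = pd.DataFrame(rows, columns=PEAK_COLUMNS).sort_values("slot", kind="stable")
        bundles.append(
            TraceBundle(sample_id=truth.sample_id, locus_id=a.locus_id, peaks=peaks.reset_index(drop=True))
        )
    return bundles


def _noise(rng: np.random.Generator, cv: float) -> float:
    return max(0.0, 1.0 + cv * rng.standard_normal())


def simulate_model_traces(
    panel: Sequence[AmpliconDesign],
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    insert_seqs: Mapping[str, str] | None = None,
    window: int = 5,
) -> list[TraceBundle]:
    """Replicate traces of fully-unmethylated model amplicons (the 0%
    calibration reference). Only structurally unassessable sites (missing
    rate 1.0) drop out of model traces: the model amplicon is resequenced
    until resolved everywhere the assay can resolve at all."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    positions = [p for a in panel for p in a.encompassed_cpgs]
    zero = SampleTruth(
        sample_id="model",
        label="control",
        true_methylation={p: 0.0 for p in positions},
    )
    structural = {
        p: (1.0 if config.sanger_missing_rate.get(p, 0.0) >= 1.0 else 0.0)
        for p in positions
    }
    model_cfg = replace(config, sanger_missing_rate=structural)
    traces: list[TraceBundle] = []
    for i in range(config.n_model_traces):
        rep = replace(zero, sample_id=f"model_{i + 1}")
        traces.extend(
            simulate_traces(
                rep, panel, model_cfg, rng=rng, insert_seqs=insert_seqs, window=window
            )
        )
    return traces
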