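"""Targeted panel design from an episignature CpG table.

An episignature is a disorder-specific genome-wide DNA methylation pattern.
This module reduces such a signature — a table of differentially methylated
CpG dinucleotides with case-minus-control beta differences — to a small set
of amplifiable target loci suitable for bisulfite PCR and sequencing:

1. keep CpGs whose absolute delta-beta meets a threshold;
2. group retained CpGs into loci short enough for one amplicon;
3. optionally unite neighbouring CpGs with similar behaviour into merged
   two-CpG features (their mean methylation), while keeping the individual
   CpGs as features as well;
4. validate concrete amplicon designs (insert length, CpG content, primers).

Coordinates are hg19, 1-based, inclusive; a CpG is addressed by the position
of its forward-strand cytosine. The shipped fixtures describe a four-amplicon
panel over the GCNT2 promoter region (chr6) and a chr2 region that together
recapitulate the CREBBP-related Rubinstein-Taybi syndrome (RTS1) episignature.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "EpisignatureCpG",
    "TargetLocus",
    "AmpliconDesign",
    "ValidationReport",
    "select_cpgs",
    "group_into_loci",
    "define_merged_pairs",
    "bisulfite_convert",
    "validate_amplicon",
    "merged_feature_name",
    "feature_name",
    "load_episignature",
    "load_panel",
    "panel_to_bed",
    "read_episignature_tsv",
    "read_panel_json",
    "write_panel_bed",
]

_DNA = set("ACGTN")


@dataclass(frozen=True)
class EpisignatureCpG:
    """A single CpG from an episignature table.

    ``probe_id`` is the methylation-array probe identifier, or "" for CpGs
    that flank array probes inside a designed amplicon but are absent from
    the array design. ``delta_beta`` is the case-minus-control methylation
    difference on the beta (0-1) scale, or None when unknown (flanking CpGs).
    """

    chrom: str
    position: int
    probe_id: str = ""
    delta_beta: float | None = None
    locus: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.position <= 0:
            raise ValueError(f"position must be positive, got {self.position}")
        if self.delta_beta is not None:
            if not math.isfinite(self.delta_beta):
                raise ValueError(f"non-finite delta_beta for {self.chrom}:{self.position}")
            if not -1.0 <= self.delta_beta <= 1.0:
                raise ValueError(f"delta_beta out of [-1, 1]: {self.delta_beta}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.position}"


@dataclass(frozen=True)
class TargetLocus:
    """A group of CpGs close enough to be covered by one amplicon.

    ``merged_pairs`` lists position pairs treated additionally as single
    mean-methylation features. ``flags`` records design warnings, e.g. a
    locus holding a single CpG (which violates the two-CpG design rule but
    is reported rather than silently dropped).
    """

    locus_id: str
    cpgs: tuple[EpisignatureCpG, ...]
    merged_pairs: tuple[tuple[int, int], ...] = ()
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.cpgs:
            raise ValueError("locus needs at least one CpG")
        chroms = {c.chrom for c in self.cpgs}
        if len(chroms) != 1:
            raise ValueError(f"locus {self.locus_id} spans chromosomes {sorted(chroms)}")
        positions = [c.position for c in self.cpgs]
        if positions != sorted(positions):
            raise ValueError(f"locus {self.locus_id} CpGs not sorted by position")
        pos_set = set(positions)
        for a, b in self.merged_pairs:
            if a == b or a not in pos_set or b not in pos_set:
                raise ValueError(f"merged pair ({a}, {b}) not a pair of distinct locus CpGs")

    @property
    def chrom(self) -> str:
        return self.cpgs[0].chrom

    @property
    def span_bp(self) -> int:
        """Bases an insert must cover: from the first CpG's C through the
        last CpG's G (position + 1)."""
        return self.cpgs[-1].position + 1 - self.cpgs[0].position + 1

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(c.position for c in self.cpgs)


@dataclass(frozen=True)
class AmpliconDesign:
    """A bisulfite-PCR amplicon: primers plus the insert it amplifies.

    Primer sequences are stored as printed in the design, i.e. already
    matching the bisulfite-converted template strand.
    """

    locus_id: str
    primer_f: str
    primer_r: str
    insert_chrom: str
    insert_start: int
    insert_end: int
    encompassed_cpgs: tuple[int, ...]
    merged_pairs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.insert_start > self.insert_end:
            raise ValueError("insert_start must be <= insert_end")
        for primer in (self.primer_f, self.primer_r):
            if not primer or set(primer) - set("ACGT"):
                raise ValueError(f"primer must be nonempty over ACGT: {primer!r}")

    @property
    def insert_length(self) -> int:
        return self.insert_end - self.insert_start + 1

    def cpg_offsets(self) -> tuple[int, ...]:
        """0-based offsets of the CpG cytosines within the insert."""
        return tuple(p - self.insert_start for p in self.encompassed_cpgs)


@dataclass
class ValidationReport:
    """Per-criterion pass/fail outcome of an amplicon design check."""

    locus_id: str
    checks: dict[str, bool] = field(default_factory=dict)
    details: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(self.checks.values())


def select_cpgs(
    cpgs: Sequence[EpisignatureCpG],
    min_abs_delta: float = 0.20,
    keep_unknown: bool = False,
) -> list[EpisignatureCpG]:
    """Keep CpGs whose |delta-beta| meets the threshold, preserving order.

    CpGs with unknown delta-beta (flanking sites without array probes) are
    dropped unless ``keep_unknown`` — they only enter a panel because they
    fall inside an insert designed around retained CpGs.
    """
    if not 0.0 <= min_abs_delta <= 1.0:
        raise ValueError("min_abs_delta must be in [0, 1]")
    out = []
    for c in cpgs:
        if c.delta_beta is None:
            if keep_unknown:
                out.append(c)
        elif abs(c.delta_beta) >= min_abs_delta:
            out.append(c)
    return out


def group_into_loci(
    cpgs: Sequence[EpisignatureCpG],
    max_span_bp: int = 300,
) -> list[TargetLocus]:
    """Greedy left-to-right grouping of CpGs into amplifiable loci.

    Within each chromosome, CpGs are taken in coordinate order and added to
    the open locus while the bases an insert must cover — from the first
    CpG's C through the last CpG's G — stay within ``max_span_bp``;
    otherwise a new locus starts. Single-CpG loci are flagged
    ``single_cpg`` because one amplicon should interrogate at least two CpG
    dinucleotides.
    """
    if max_span_bp <= 0:
        raise ValueError("max_span_bp must be positive")
    by_chrom: dict[str, list[EpisignatureCpG]] = {}
    for c in cpgs:
        by_chrom.setdefault(c.chrom, []).append(c)

    loci: list[TargetLocus] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda c: c.position)
        group: list[EpisignatureCpG] = []
        for c in ordered:
            if group and c.position + 2 - group[0].position > max_span_bp:
                loci.append(_make_locus(group, len(loci) + 1))
                group = []
            group.append(c)
        if group:
            loci.append(_make_locus(group, len(loci) + 1))
    return loci


def _make_locus(group: list[EpisignatureCpG], index: int) -> TargetLocus:
    flags = ("single_cpg",) if len(group) == 1 else ()
    locus_id = group[0].locus or f"{group[0].chrom}:{group[0].position}-{group[-1].position}"
    return TargetLocus(locus_id=locus_id, cpgs=tuple(group), flags=flags)


def define_merged_pairs(
    locus: TargetLocus, pairs: Iterable[tuple[int, int]]
) -> TargetLocus:
    """Record neighbour-CpG pairs to be treated as single mean features.

    Downstream feature extraction emits both the merged feature (named by
    :func:`merged_feature_name`) and the individual per-CpG features.
    """
    pos_set = set(locus.positions)
    norm = []
    for a, b in pairs:
        if a not in pos_set or b not in pos_set:
            raise ValueError(f"pair position not in locus {locus.locus_id}: ({a}, {b})")
        if a == b:
            raise ValueError(f"merged pair must join two distinct CpGs, got ({a}, {b})")
        norm.append((min(a, b), max(a, b)))
    return replace(locus, merged_pairs=locus.merged_pairs + tuple(norm))


def feature_name(chrom: str, position: int) -> str:
    return f"{chrom}:{position}"


def merged_feature_name(chrom: str, a: int, b: int) -> str:
    """Canonical name of a merged two-CpG feature, lower coordinate first."""
    a, b = sorted((a, b))
    return f"{chrom}:{a}_{chrom}:{b}"


def bisulfite_convert(seq: str, methylated_positions: Iterable[int] = ()) -> str:
    """Apply in-silico bisulfite conversion to a forward-strand sequence.

    Unmethylated cytosine deaminates to uracil and is read as thymine;
    5-methylcytosine is protected. ``methylated_positions`` are 0-based
    offsets of protected cytosines.
    """
    if set(seq) - _DNA:
        raise ValueError("sequence must be over {A,C,G,T,N}")
    protected = set(methylated_positions)
    for off in protected:
        if not 0 <= off < len(seq):
            raise ValueError(f"methylated offset out of range: {off}")
    return "".join(
        "T" if (base == "C" and i not in protected) else base
        for i, base in enumerate(seq)
    )


def validate_amplicon(
    design: AmpliconDesign,
    max_insert_bp: int = 300,
    min_cpgs: int = 2,
) -> ValidationReport:
    """Check an amplicon design against the panel design rules.

    Hard criteria: insert length within ``max_insert_bp``; at least
    ``min_cpgs`` encompassed CpGs; every encompassed CpG inside the insert.
    Primers containing a CpG dinucleotide (whose conversion state is
    methylation-dependent and would bias amplification) raise a warning only.
    """
    report = ValidationReport(locus_id=design.locus_id)

    length = design.insert_length
    report.checks["insert_length"] = length <= max_insert_bp
    report.details["insert_length"] = f"{length} bp (max {max_insert_bp})"

    n = len(design.encompassed_cpgs)
    report.checks["min_cpgs"] = n >= min_cpgs
    report.details["min_cpgs"] = f"{n} CpGs (min {min_cpgs})"

    inside = all(
        design.insert_start <= p <= design.insert_end for p in design.encompassed_cpgs
    )
    report.checks["cpgs_inside_insert"] = inside
    report.details["cpgs_inside_insert"] = "all inside" if inside else "CpG outside insert"

    for name, primer in (("primer_f", design.primer_f), ("primer_r", design.primer_r)):
        if "CG" in primer:
            report.warnings.append(f"{name} contains a CpG dinucleotide")

    return report


# ---------------------------------------------------------------------------
# fixture and format I/O


def read_episignature_tsv(path: str | Path) -> list[EpisignatureCpG]:
    """Read an episignature table (TSV: locus, probe_id, chrom, position,
    delta_beta; delta_beta empty for CpGs absent from the array design)."""
    cpgs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")

            def col(name: str) -> str:
                i = idx[name]
                return f[i] if i < len(f) else ""

            delta = col("delta_beta")
            cpgs.append(
                EpisignatureCpG(
                    chrom=col("chrom"),
                    position=int(col("position")),
                    probe_id=col("probe_id"),
                    delta_beta=float(delta) if delta else None,
                    locus=col("locus"),
                )
            )
    return cpgs


def read_panel_json(path: str | Path) -> list[AmpliconDesign]:
    with open(path) as fh:
        doc = json.load(fh)
    return [
        AmpliconDesign(
            locus_id=a["locus_id"],
            primer_f=a["primer_f"],
            primer_r=a["primer_r"],
            insert_chrom=a["insert_chrom"],
            insert_start=a["insert_start"],
            insert_end=a["insert_end"],
            encompassed_cpgs=tuple(sorted(a["encompassed_cpgs"])),
            merged_pairs=tuple((min(p), max(p)) for p in a.get("merged_pairs", [])),
        )
        for a in doc["amplicons"]
    ]


def panel_to_bed(panel: Sequence[AmpliconDesign]) -> list[tuple[str, int, int, str]]:
    """Convert 1-based inclusive inserts to BED (0-based, half-open) rows."""
    return [
        (a.insert_chrom, a.insert_start - 1, a.insert_end, a.locus_id) for a in panel
    ]


def write_panel_bed(panel: Sequence[AmpliconDesign], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name in panel_to_bed(panel):
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def _data_path(name: str) -> Path:
    return Path(str(resources.files("epitarget").joinpath("data", name)))


def load_episignature() -> list[EpisignatureCpG]:
    """The shipped RTS1 episignature CpG table (array probes + flanking CpGs)."""
    return read_episignature_tsv(_data_path("episignature_cpgs.tsv"))


def load_panel() -> list[AmpliconDesign]:
    """The shipped four-amplicon RTS1 panel with merged neighbour pairs."""
    return read_panel_json(_data_path("panel.json"))
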