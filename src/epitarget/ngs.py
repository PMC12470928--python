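"""Per-CpG methylation from targeted bisulfite amplicon reads.

Deep amplicon bisulfite sequencing measures methylation as the abundance of
cytosine versus thymine at each CpG target site: after bisulfite conversion
an unmethylated C reads as T, a methylated C stays C. Because the reads come
from a known four-amplicon panel rather than the whole genome, full
bisulfite alignment is unnecessary; reads are matched directly against the
amplicon references under an asymmetric bisulfite match rule (a read T is
compatible with a reference C or T; a read C only with a reference C).

Stages: length filtering -> reference matching -> per-site C/T counting ->
percent methylation with a coverage floor -> merged-pair feature assembly.
A conversion-efficiency QC from non-CpG cytosines (which should convert
completely) flags incompletely converted samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import AmpliconDesign, merged_feature_name
from .cohort import non_cpg_c_offsets, _BASES, _C, _T

logger = logging.getLogger(__name__)

__all__ = [
    "SiteCounts",
    "length_filter",
    "match_read",
    "match_reads",
    "count_states",
    "methylation_from_counts",
    "conversion_qc",
    "merge_features",
    "quantify_sample",
    "quantify_cohort",
    "matrix_to_tsv",
    "matrix_from_tsv",
]


@dataclass
class SiteCounts:
    """Base tallies at one CpG position across matched reads."""

    position: int
    c_count: int = 0
    t_count: int = 0
    other_count: int = 0

    def __post_init__(self) -> None:
        if min(self.c_count, self.t_count, self.other_count) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def coverage(self) -> int:
        return self.c_count + self.t_count + self.other_count


def _as_array(read) -> np.ndarray:
    if isinstance(read, np.ndarray):
        return read.astype(np.uint8, copy=False)
    seq = str(read.seq) if hasattr(read, "seq") else str(read)
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def length_filter(reads: Iterable, min_len: int = 100, max_len: int = 260) -> list:
    """Keep reads with min_len <= length <= max_len (bounds inclusive)."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    kept, discarded = [], 0
    for r in reads:
        n = len(r.seq) if hasattr(r, "seq") else len(r)
        if min_len <= n <= max_len:
            kept.append(r)
        else:
            discarded += 1
    if discarded:
        logger.info("length_filter discarded %d read(s)", discarded)
    return kept


def _bisulfite_identity(reads: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Fraction of positions compatible under the asymmetric bisulfite rule:
    read base equals reference, or read T over reference C (converted)."""
    match = (reads == ref) | ((reads == _T) & (ref == _C))
    return match.mean(axis=1)


def match_read(
    read,
    panel: Sequence[AmpliconDesign],
    insert_seqs: Mapping[str, str],
    min_identity: float = 0.9,
) -> tuple[str, int] | None:
    """Assign a read to the amplicon it fits best; None if unmatched.

    Amplicon reads are fixed-template, so no indel alignment is attempted:
    the read is slid over each reference (offset 0 when lengths agree) and
    scored by bisulfite identity over the overlap. The best hit must reach
    ``min_identity``; a tie between amplicons is unmatched.
    """
    arr = _as_array(read)
    best: tuple[float, str, int] | None = None
    tied = False
    for a in panel:
        ref = np.frombuffer(insert_seqs[a.locus_id].encode(), dtype=np.uint8)
        offsets = range(0, max(1, ref.size - arr.size + 1))
        for off in offsets:
            overlap = min(arr.size, ref.size - off)
            if overlap <= 0:
                continue
            ident = float(
                _bisulfite_identity(arr[None, :overlap], ref[off : off + overlap])[0]
            )
            if best is None or ident > best[0]:
                best, tied = (ident, a.locus_id, off), False
            elif ident == best[0] and (a.locus_id, off) != best[1:]:
                tied = True
    if best is None or tied or best[0] < min_identity:
        return None
    return best[1], best[2]


def match_reads(
    reads: np.ndarray,
    panel: Sequence[AmpliconDesign],
    insert_seqs: Mapping[str, str],
    min_identity: float = 0.9,
) -> tuple[str | None, np.ndarray]:
    """Vectorised bulk matcher for a batch of equal-length reads at offset 0.

    Returns the winning locus (None when no amplicon wins) and the boolean
    mask of reads that individually reach ``min_identity`` against it. Used
    on simulator output where every read spans its full amplicon.
    """
    identities: dict[str, np.ndarray] = {}
    for a in panel:
        ref = np.frombuffer(insert_seqs[a.locus_id].encode(), dtype=np.uint8)
        overlap = min(reads.shape[1], ref.size)
        identities[a.locus_id] = _bisulfite_identity(reads[:, :overlap], ref[:overlap])
    mean_ident = {loc: i.mean() for loc, i in identities.items()}
    winner = max(mean_ident, key=mean_ident.get)
    ok = identities[winner] >= min_identity
    if not ok.any():
        return None, ok
    return winner, ok


def count_states(
    reads: np.ndarray, cpg_offsets: Sequence[int], positions: Sequence[int]
) -> list[SiteCounts]:
    """Tally C/T/other per CpG column over matched, offset-aligned reads."""
    out = []
    for off, pos in zip(cpg_offsets, positions):
        if off >= reads.shape[1]:
            out.append(SiteCounts(position=pos))  # site beyond read end
            continue
        col = reads[:, off]
        c = int((col == _C).sum())
        t = int((col == _T).sum())
        out.append(SiteCounts(position=pos, c_count=c, t_count=t,
                              other_count=int(col.size - c - t)))
    return out


def methylation_from_counts(counts: SiteCounts, min_coverage: int = 100) -> float:
    """Percent methylation 100*C/(C+T); NaN below the coverage floor.

    Bases other than C or T are sequencing error and stay out of the
    denominator.
    """
    informative = counts.c_count + counts.t_count
    if informative < min_coverage or informative == 0:
        return float("nan")
    return 100.0 * counts.c_count / informative


def conversion_qc(
    reads: np.ndarray, non_cpg_c: Sequence[int], threshold: float = 0.02
) -> tuple[float | None, bool]:
    """Retained-C fraction at non-CpG cytosines (~ 1 - conversion
    efficiency) and whether it exceeds the failure threshold.

    Returns (None, False) when the panel offers no non-CpG cytosines.
    """
    offs = [o for o in non_cpg_c if o < reads.shape[1]]
    if not offs:
        return None, False
    block = reads[:, offs]
    retained = float((block == _C).mean())
    return retained, retained > threshold


def merge_features(
    matrix: pd.DataFrame,
    merged_pairs: Sequence[tuple[str, int, int]],
    policy: str = "use_present",
) -> tuple[pd.DataFrame, list[str]]:
    """Append merged two-CpG mean features to a per-CpG matrix.

    ``merged_pairs`` entries are (chrom, pos_a, pos_b). When exactly one
    member is present the default policy uses it alone (and reports the
    feature in the returned flag list); policy "strict" leaves it missing.
    Per-CpG columns are retained alongside the merged ones.
    """
    if policy not in {"use_present", "strict"}:
        raise ValueError("policy must be 'use_present' or 'strict'")
    out = matrix.copy()
    flagged: list[str] = []
    for chrom, a, b in merged_pairs:
        ca, cb = f"{chrom}:{a}", f"{chrom}:{b}"
        if ca not in out.columns or cb not in out.columns:
            raise KeyError(f"merged pair member missing from matrix: {ca}, {cb}")
        name = merged_feature_name(chrom, a, b)
        pair = out[[ca, cb]]
        if policy == "use_present":
            merged = pair.mean(axis=1)  # mean of available members
            if (pair.isna().sum(axis=1) == 1).any():
                flagged.append(name)
        else:
            merged = pair.mean(axis=1)
            merged[pair.isna().any(axis=1)] = np.nan
        out[name] = merged
    return out, flagged


def panel_merged_pairs(panel: Sequence[AmpliconDesign]) -> list[tuple[str, int, int]]:
    return [(a.insert_chrom, x, y) for a in panel for x, y in a.merged_pairs]


def quantify_sample(
    reads_by_locus: Mapping[str, np.ndarray] | Sequence,
    panel: Sequence[AmpliconDesign],
    insert_seqs: Mapping[str, str],
    min_coverage: int = 100,
    min_identity: float = 0.9,
    min_len: int = 100,
    max_len: int = 260,
) -> tuple[dict[str, float], dict[str, float | None]]:
    """Full per-sample NGS pipeline: filter, match, count, call.

    Accepts either pre-batched read arrays keyed by locus (simulator
    output; matching is still performed, the keys are not trusted) or a
    flat iterable of reads/SeqRecords. Returns (feature -> percent, locus ->
    conversion-QC retained-C fraction).
    """
    if isinstance(reads_by_locus, Mapping):
        batches = list(reads_by_locus.values())
    else:
        flat = length_filter(list(reads_by_locus), min_len, max_len)
        by_len: dict[int, list[np.ndarray]] = {}
        for r in flat:
            arr = _as_array(r)
            by_len.setdefault(arr.size, []).append(arr)
        batches = [np.vstack(group) for group in by_len.values()]

    designs = {a.locus_id: a for a in panel}
    methylation: dict[str, float] = {}
    qc: dict[str, float | None] = {}
    counts_by_locus: dict[str, list[SiteCounts]] = {}
    for batch in batches:
        if isinstance(batch, np.ndarray) and batch.ndim == 2:
            n = batch.shape[1]
            if not (min_len <= n <= max_len):
                batch = batch[:, :max_len]
                if batch.shape[1] < min_len:
                    continue
            locus, ok = match_reads(batch, panel, insert_seqs, min_identity)
            if locus is None:
                continue
            matched = batch[ok]
            a = designs[locus]
            offs = [o for o in a.cpg_offsets() if o < matched.shape[1]]
            pos = [p for p, o in zip(a.encompassed_cpgs, a.cpg_offsets()) if o < matched.shape[1]]
            counts_by_locus.setdefault(locus, [])
            counts_by_locus[locus] = _accumulate(
                counts_by_locus[locus], count_states(matched, offs, pos)
            )
            nc = non_cpg_c_offsets(insert_seqs[locus], a.cpg_offsets())
            qc[locus], _ = conversion_qc(matched, nc)

    for a in panel:
        for sc in counts_by_locus.get(a.locus_id, []):
            methylation[f"{a.insert_chrom}:{sc.position}"] = methylation_from_counts(
                sc, min_coverage
            )
        for p in a.encompassed_cpgs:
            methylation.setdefault(f"{a.insert_chrom}:{p}", float("nan"))
    return methylation, qc


def _accumulate(acc: list[SiteCounts], new: list[SiteCounts]) -> list[SiteCounts]:
    if not acc:
        return new
    by_pos = {sc.position: sc for sc in acc}
    for sc in new:
        if sc.position in by_pos:
            old = by_pos[sc.position]
            old.c_count += sc.c_count
            old.t_count += sc.t_count
            old.other_count += sc.other_count
        else:
            acc.append(sc)
    return acc


def quantify_cohort(
    reads_by_sample: Mapping[str, Mapping[str, np.ndarray]],
    panel: Sequence[AmpliconDesign],
    insert_seqs: Mapping[str, str],
    min_coverage: int = 100,
    with_merged: bool = True,
) -> pd.DataFrame:
    """Samples x features percent-methylation matrix from per-sample reads."""
    rows = {}
    for sample_id, reads in reads_by_sample.items():
        methylation, _ = quantify_sample(reads, panel, insert_seqs, min_coverage)
        rows[sample_id] = methylation
    order = [f"{a.insert_chrom}:{p}" for a in panel for p in a.encompassed_cpgs]
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=order)
    if with_merged:
        df, _ = merge_features(df, panel_merged_pairs(panel))
    return df


def matrix_to_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="sample", na_rep="NA")


def matrix_from_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample", na_values="NA")
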