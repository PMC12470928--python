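# Methods

## Scope and model

`epitarget` implements the desk side of a targeted episignature assay for
CREBBP-related Rubinstein–Taybi syndrome (RTS1): reducing a genome-wide
differential-methylation signature to four bisulfite-PCR amplicons (35 CpGs,
six merged neighbour pairs), quantifying per-CpG methylation from either
deep amplicon sequencing or calibrated Sanger traces, and deriving a linear
decision rule — ultimately a single raw-scale cut-off on the merged
`chr6:10556199_chr6:10556204` locus, below which a sample is called RTS1.
The wet-lab stages (DNA extraction, bisulfite conversion, library
preparation, sequencing) are outside scope and are emulated by the
synthetic-cohort module.

Coordinates are hg19, 1-based; a CpG is addressed by its forward-strand
cytosine. Only the forward bisulfite strand is modelled: the amplicons are
strand-specific by primer design, so reverse-strand (G/A) calling never
arises. External tables are percent scale (0–100) with `NA` for missing;
fractions appear only internally.

## Panel design

CpGs are filtered on |Δβ| ≥ `min_abs_delta` (default 0.20). The shipped
episignature fixture is reproduced verbatim even though three of its array
probes fall slightly under that threshold — the fixture records the panel as
designed, while the filter stays honest and configurable. CpGs flanking
array probes inside a designed insert carry no Δβ; they are dropped by the
filter unless explicitly kept and enter the panel only through the insert
that covers them.

Grouping into loci is greedy left-to-right per chromosome. The span
constraint counts the bases an insert must cover, from the first CpG's C
through the last CpG's G (`max + 1 − min + 1 ≤ max_span_bp`, default 300).
With the plain `max − min + 1` definition, chr6:10556107 would join the
first chr6 locus at a span of exactly 300 bp, which no 300 bp insert
covering full dinucleotides can realise; the dinucleotide-aware definition
reproduces the published 1.1 / 1.2 split. Single-CpG loci are flagged, not
dropped. The published loci on chr2 reflect primer-placement constraints
beyond pure span grouping; the grouper makes no attempt to reproduce them
and the shipped panel fixture is authoritative.

Merged neighbour-pair features (six pairs, e.g. chr6:10556199 +
chr6:10556204) are the arithmetic mean of their members and are always
emitted *alongside* the per-CpG features, so model search can consider both.
Merged-feature names are canonicalised with the lower coordinate first.

## Synthetic cohorts

The generator emulates the study conditions: 30 controls, 60 cases, 5 VUS
carriers and 4 overlapping-syndrome samples (99 total). Per sample and CpG,
true methylation is drawn from a normal distribution clamped to [0, 100]
(a moment-matched beta is available behind `noise_model="beta"`), sd
`biological_sd` = 5 percentage points. Case and VUS centres are the control
baseline plus the episignature Δβ × 100 (≈ −17 to −27 pp; flanking CpGs
without an array probe take their locus' mean Δβ); overlapping-syndrome
samples are drawn from the control distribution, reflecting their observed
behaviour.

The control baseline defaults to 92% at every panel site. This is an
assumption, not a published value: the study never states the controls'
absolute level, but its case/control cut-offs (84.45% NGS, 80.99% Sanger)
must fall between the class centres, which a 92% baseline with ~−20 pp
deltas achieves. Synthetic cut-offs land in the low-to-mid 80s; that
agreement is a consequence of this choice and must not be read as a
reproduction of the published cut-offs, which depend on unpublished patient
data.

Reads: each amplicon read is its full insert (209–256 bp, inside the
100–260 nt bounds). Per read and CpG, the cytosine is methylated with
probability truth/100; unmethylated CpG cytosines and all non-CpG cytosines
convert to T with probability `conversion_efficiency` (default 0.995);
uniform substitution errors at `seq_error_rate` (default 0.002). Quality
scores are a constant Q30; indels and PCR duplicates are not modelled.
Reference inserts are generated deterministically with a CG at every
designed offset and nowhere else, so no genome download is needed; real
hg19 inserts can be substituted wherever a `locus → sequence` mapping is
accepted.

Sanger traces: at each CpG slot the T peak carries the converted fraction
and the C peak the protected fraction, both scaled by a fixed site-specific
context amplitude (drawn once, uniform in [0.6, 1.4]) and multiplicative
noise `1 + N(0, trace_noise_cv)` truncated at zero; invariant flank peaks of
unit expected amplitude surround each CpG. Site dropout follows the assay's
observed structure: seven panel CpGs are never resolvable (rate 1.0), six
are resolved only in a minority of samples (rate 0.7), nine drop
occasionally (rate 0.1). Model-amplicon replicates (default 3) are fully
unmethylated; only the structurally unresolvable sites drop out of model
traces — a calibration reference is resequenced until it is readable
wherever the assay can read at all.

What passing tests on this simulator do **not** show: array-to-sequencing
platform offsets, PCR amplification bias between alleles, real
electropherogram baseline drift or dye blobs, and any cohort structure
(age, sex, batch) are absent, so performance numbers here bound only the
statistical pipeline, not the wet assay.

## NGS quantification

Reads are length-filtered (100–260 nt inclusive), then matched against the
amplicon references under the asymmetric bisulfite rule (read T matches
reference C or T; read C matches only reference C), best amplicon wins at
identity ≥ 0.9 over the overlap, ties are unmatched. Amplicon reads are
fixed-template, so there is no indel alignment. Methylation is
100·C/(C+T) per CpG; bases other than C/T are treated as sequencing error
and excluded from the denominator. Sites under `min_coverage` (default 100,
a floor that protects degenerate simulations well below the nominal 8000×)
are missing, never 0. The retained-C fraction at non-CpG cytosines
estimates 1 − conversion efficiency; samples above 2% are flagged.

## Sanger quantification

The corrected signal of a CpG is its T-channel amplitude divided by the
median amplitude of invariant flank peaks within ±`window` slots (default
5). This flank-median normalisation is this package's concrete definition
of context correction — the underlying idea (peak amplitude depends on
local context, so it must be normalised locally) admits several
realisations and the choice is documented here as an interpretation. A CpG
slot with no peak in any channel is missing; a resolved slot without a T
peak has signal 0 (fully methylated). Calibration: per site, the median
corrected signal over model traces; `scale = 100 / median`; sites with no
finite model signal or zero median are uncalibratable and propagate as
missing. Methylation is `100 − scale × signal`, clamped to [0, 100]
(noise can push the linear estimate slightly outside; the unclamped value
is available for diagnostics). The formula uses the T channel alone, as
specified; a `composite=True` flag provides the 100·C/(C+T) amplitude-ratio
alternative for comparison.

## Classification

Split: stratified 70:30, each class contributing `round(n·0.7)` training
samples (30+60 → 21+42 / 9+18); implemented directly rather than via
scikit-learn's splitter, whose floating-point floor gives 62/28 on this
cohort. Missing data: features missing in > 50% of training samples are
dropped; the rest are filled with the training median; the mask is kept for
reporting. Z parameters (mean, sample sd) are always frozen on the training
set and reused for test/VUS/overlap samples — the alternative (refitting on
test) leaks information.

Shadow-feature selection appends a row-shuffled copy of every feature each
iteration, fits a random forest, and scores a hit when a real feature's
impurity importance exceeds the best shadow's. Hits over `n_iter`
iterations are tested against Binomial(n_iter, ½), two-sided, with
Bonferroni adjustment across features (the standard all-relevant wrapper's
default); significant-high is important, significant-low rejected,
otherwise tentative. Note the null is approximate: with fixed data, hits
are dependent across iterations, so a feature spuriously correlated with
(even permuted) labels can be flagged — the false-positive *rate* is
controlled near α per feature set, but zero false positives are not
guaranteed.

Combination search fits a linear SVM (C = 1.0, no kernel — the decision
rule is linear by design) with stratified CV on every feature subset up to
`max_k` (default 2: the useful models here are one- and two-feature, and
enumeration over all important features is exponential), ranking by
accuracy with ties broken toward fewer features. For a single feature the
boundary `w·z + b = 0` is solved to `cutoff_z = −b/w` and back-transformed
exactly (`cutoff_raw = mean + sd·cutoff_z`). A value exactly at the cut-off
goes to the control side and is flagged borderline; a sample missing its
feature value is unclassifiable, never silently imputed at predict time.
Evaluation reports sensitivity/specificity/accuracy with RTS1 as the
positive class, a ROC swept over the scalar decision score with trapezoidal
AUC, and stratified CV that refits the model within folds.

## Problem sizes and tolerances

Defaults mirror the study (8000× coverage, 30+60+5+4 cohort). The
end-to-end experiment and its tests run at reduced coverage (500× positive,
300× null control): with a ~20 pp effect against 5 pp biological sd, the
binomial quantification noise at 500× (≤ ~2.2 pp sd) is negligible next to
biological noise, and nothing downstream depends on depth beyond it. Boruta
runs 30 iterations with 60-tree forests at these sizes. Binomial-recovery
checks run at the full 8000× with ideal conversion and zero sequencing
error so the 4σ binomial bound is the exact oracle; imperfect conversion
adds a known upward bias of (1−m)·(1−ce) — at most ~0.5 pp at 5%
methylation with the default efficiency — which is a chemistry property
surfaced by the conversion QC, not estimator error.

Numerical conventions: Z-scores use sample sd (ddof = 1); the cut-off
round-trip is exact to 1e-9 relative; Sanger clamping happens after the
linear formula; merged pairs with exactly one present member use it and are
flagged (strict propagation available); all randomness flows through
explicit integer seeds and fixed-seed runs are bit-identical.

## Known limitations

The published cut-offs (0.5690 ↔ 84.45%; 0.581809 ↔ 80.99%) and
misclassification counts are functions of the unpublished patient cohort
and are deliberately not targets. The simulator's Sanger context model is
multiplicative and site-independent; real trace context effects are
sequence-driven and autocorrelated. Reverse-strand bisulfite calling,
variant screening at CpG sites (C>T SNVs masquerading as unmethylated
cytosines), and multi-panel multiplexing are out of scope.
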