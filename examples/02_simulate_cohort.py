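"""Generate a synthetic study cohort with reads and Sanger traces.

The default configuration mirrors the emulated study: 30 controls at a 92%
baseline, 60 cases hypomethylated by the episignature delta-betas (~ -17 to
-27 percentage points), 5 VUS carriers (case-distributed) and 4
overlapping-syndrome samples (control-distributed).
"""

import numpy as np

import epitarget as et

config = et.default_config(seed=7, coverage=2000)
cohort = et.generate_cohort(config)
labels = et.labels_series(cohort)
print("cohort:", {k: int(v) for k, v in labels.value_counts().items()})

site = 10556199  # one CpG of the target locus
controls = [s.true_methylation[site] for s in cohort if s.label == "control"]
cases = [s.true_methylation[site] for s in cohort if s.label == "rts1"]
print(f"true methylation at chr6:{site}: "
      f"controls {np.mean(controls):.1f}% +/- {np.std(controls):.1f}, "
      f"cases {np.mean(cases):.1f}% +/- {np.std(cases):.1f}")

panel = et.load_panel()
refs = et.synthetic_references(panel)
rng = np.random.default_rng(7)
reads = et.simulate_reads(cohort[0], panel, refs, config, rng=rng)
for locus, arr in reads.items():
    print(f"  locus {locus}: {arr.shape[0]} reads x {arr.shape[1]} bp")

traces = et.simulate_traces(cohort[0], panel, config, rng=rng, insert_seqs=refs)
resolved = sum(len(t.cpg_positions()) for t in traces)
total = sum(len(a.encompassed_cpgs) for a in panel)
print(f"Sanger traces for {cohort[0].sample_id}: {resolved}/{total} CpGs "
      f"resolved (structured dropout mirrors the assay)")
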