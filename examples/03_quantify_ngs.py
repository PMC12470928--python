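"""Call per-CpG methylation from deep bisulfite amplicon reads.

Simulates one sample at 8000x coverage, runs the full calling path
(length filter -> bisulfite-aware matching -> C/T counting -> percent with
coverage floor) and compares the estimates with the simulated truth.
"""

import numpy as np

import epitarget as et

panel = et.load_panel()
refs = et.synthetic_references(panel)
config = et.default_config(seed=3, coverage=8000)
sample = et.generate_cohort(config)[0]

reads = et.simulate_reads(sample, panel, refs, config, rng=np.random.default_rng(3))
methylation, qc = et.quantify_sample(reads, panel, refs, min_coverage=100)

print(f"sample {sample.sample_id} ({sample.label}), coverage {config.coverage}x")
print(f"{'site':>16} {'truth':>7} {'called':>7} {'error':>6}")
for a in panel:
    for p in a.encompassed_cpgs[:3]:  # first three CpGs per amplicon
        name = f"{a.insert_chrom}:{p}"
        t, c = sample.true_methylation[p], methylation[name]
        print(f"{name:>16} {t:7.2f} {c:7.2f} {c - t:+6.2f}")

print("\nconversion QC (retained non-CpG C fraction; ~1 - efficiency):")
for locus, frac in qc.items():
    print(f"  {locus}: {frac:.4f}")
# Errors stay within a fraction of a percentage point at this depth: the
# binomial sampling sd at 8000x is at most ~0.6 pp.
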