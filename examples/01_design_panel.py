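"""Reduce an episignature CpG table to validated amplicon targets.

Loads the shipped RTS1 episignature (array probes plus flanking CpGs),
applies the |delta-beta| >= 20% filter, groups CpGs into amplifiable loci
and validates the four shipped amplicon designs.
"""

import epitarget as et

episig = et.load_episignature()
probed = [c for c in episig if c.probe_id]
print(f"episignature table: {len(episig)} CpGs ({len(probed)} with array probes)")

kept = et.select_cpgs(probed, min_abs_delta=0.20)
print(f"probes with |delta-beta| >= 0.20: {len(kept)} of {len(probed)}")

loci = et.group_into_loci(probed, max_span_bp=300)
for locus in loci:
    flag = " (single CpG — needs a partner)" if locus.flags else ""
    print(f"  locus {locus.locus_id}: {len(locus.cpgs)} CpGs, "
          f"span {locus.span_bp} bp{flag}")

print("\namplicon validation (insert <= 300 bp, >= 2 CpGs):")
for amplicon in et.load_panel():
    report = et.validate_amplicon(amplicon)
    print(f"  {amplicon.locus_id}: insert {amplicon.insert_length} bp, "
          f"{len(amplicon.encompassed_cpgs)} CpGs -> "
          f"{'PASS' if report.passed else 'FAIL'}")

# The loci printed above come from the greedy grouper applied to the array
# probes alone; the shipped panel additionally pulls in neighbouring CpGs
# that fall inside each insert but are absent from the array design.
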