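"""Metaprofile of a repressive histone mark along an ERV consensus.

Simulates wild-type and knockout ChIP libraries over a toy genome carrying
three diverged copies of a 2 kb LTR-flanked consensus, aligns the reads back
to the consensus, resolves multi-mappers and compares the two RPKM
metaprofiles.  Scaled down from the standard study for a quick run.
"""

from ervprofiler.pipeline import consensus_study

study = consensus_study(seed=0, n_reads=40_000, genome_length=60_000)

wt, ko = study.profiles["wt"], study.profiles["ko"]
print(f"consensus length: {wt.length} bp, bin width {wt.bin_width} bp")
print(f"reads profiled:   wt {wt.n_reads_used}, ko {ko.n_reads_used}")
print(f"mean RPKM:        wt {study.comparison.mean_a:.1f}, ko {study.comparison.mean_b:.1f}")
print(f"wt/ko mean body signal ratio: {study.comparison.mean_ratio:.2f} "
      f"(closed-form expectation {study.expected_ratio:.2f})")
print(f"shape correlation with the planted enrichment profile: "
      f"{study.shape_correlation:.3f}")
print()
print("The ratio > 1 shows the knockout losing the mark over element bodies;")
print("the shape correlation shows the nonuniform within-element profile is")
print("recovered despite 2% copy divergence and LTR multi-mapping.")
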