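"""Bisulphite clone analysis: calling, conversion QC and four-bin report.

Simulates clone sets from a densely methylated wild-type line and a
partially demethylated knockout line, calls per-CpG methylation against the
unconverted reference, applies the strict >98% conversion filter, and bins
clones into methylated-fraction quartiles.
"""

from ervprofiler.pipeline import methylation_study

study = methylation_study(seed=0, n_clones=50)

print(f"amplicon: {len(study.reference)} bp")
print(f"clones passing conversion QC: {study.n_clones}")
print()
print("percentage of clones per methylation bin (columns = methylated fraction):")
print(study.binning.percentages.round(1).to_string())
print()
print(f"conversion QC batch (true rate 0.95, strict >0.98 filter): "
      f"{study.qc_removed}/{study.qc_total} clones removed")
print()
print("The knockout's clones shift out of the top (76-100% methylated) bin,")
print("the signature of partial demethylation at individual molecules.")
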