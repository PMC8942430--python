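"""Fraction of the microbiota carrying a KEGG module or CAZy family.

Profiles MSPs, then computes for each module the summed abundance of MSPs
whose restricted gene content (detected genes plus core genes) covers more
than 90% of the module's KO set; a CAZy family is carried by any MSP with
at least one annotated gene.
"""

import fibrascope as fs
from fibrascope.functional import ModuleDefinition

catalog = fs.generate_catalog(n_genes=2000, n_msp=15, ko_density=0.8,
                              cazy_density=0.3, seed=7)
design, composition = fs.generate_cohort(catalog, n_subjects=4, seed=8)
alignments = fs.simulate_alignments(composition, catalog, depth=20_000, seed=9)
raw = fs.attribute_reads(alignments, catalog)
downsized, _ = fs.downsize(raw, 15_000, seed=10)
freqs = fs.normalize_frequencies(downsized, catalog)
msp = fs.msp_abundance(freqs, catalog, renormalize=True)

# one KO-set module drawn from the core genes of the dominant MSP (so that
# MSP can plausibly carry it), plus two CAZy-family modules
top_msp = msp[msp.columns[0]].idxmax()
core_kos = sorted({k for g in catalog.core_of(top_msp)
                   for k in catalog.frame.at[g, "ko_ids"]})[:4]
modules = [ModuleDefinition("demo_module", "kegg", frozenset(core_kos)),
           ModuleDefinition("GH43_8", "cazy", frozenset({"GH43_8"})),
           ModuleDefinition("GH76", "cazy", frozenset({"GH76"}))]

profile, provenance = fs.functional_profile(msp, freqs, modules, catalog)
sample = profile.columns[0]
print(f"module carriage in {sample}:")
print(profile[sample].round(4).to_string())
carriers = provenance.query("sample_id == @sample and module_id == 'GH43_8'")
print(f"MSPs carrying GH43_8 in {sample}: {', '.join(carriers['msp_id']) or 'none'}")
print("-> each value is the summed relative abundance of the MSPs that")
print("   carry the function, i.e. the fraction of the microbiota with it.")
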