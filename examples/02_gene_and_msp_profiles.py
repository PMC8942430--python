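"""From alignment records to gene counts, frequencies and MSP abundances.

Simulates read-to-gene alignments (with 15% shared reads), attributes them
to genes, downsizes every sample to a common mapped-read depth, normalizes
to FPKM-style frequencies, and profiles MSPs from their marker genes.
"""

import fibrascope as fs

catalog = fs.generate_catalog(n_genes=2000, n_msp=15, seed=3)
design, composition = fs.generate_cohort(catalog, n_subjects=6, seed=4)

alignments = fs.simulate_alignments(composition, catalog, depth=20_000,
                                    shared_fraction=0.15, seed=5)
raw = fs.attribute_reads(alignments, catalog)
print(f"raw counts: {raw.data.shape[0]} genes x {raw.data.shape[1]} samples, "
      f"column sums all {raw.mapped_reads.iloc[0]:.0f} (reads conserved)")

downsized, excluded = fs.downsize(raw, target=15_000, seed=6)
print(f"downsized to 15,000 mapped reads; excluded samples: {excluded or 'none'}")

freqs = fs.normalize_frequencies(downsized, catalog)
msp = fs.msp_abundance(freqs, catalog, renormalize=True)
gene_rich = fs.gene_richness(downsized)
msp_rich = fs.msp_richness(msp)
sample = msp.columns[0]
print(f"sample {sample}: gene richness {gene_rich[sample]}, "
      f"MSP richness {msp_rich[sample]}")
print(f"top-3 MSP abundances in {sample}:")
print(msp[sample].nlargest(3).round(4).to_string())
print("-> MSP abundance is the mean frequency of its 100 marker genes;")
print("   an MSP with fewer than 10 detected markers is set to zero.")
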