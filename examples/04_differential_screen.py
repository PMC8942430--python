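"""Rank-based longitudinal screen for bread-responsive features.

Runs the full pipeline on a cohort with one planted differential species,
then screens all MSPs: ANOVA-type interaction test (bread x visit), BH
correction at q <= 0.1, and per-bread Wilcoxon + graded Cliff's delta.
"""

import fibrascope as fs

catalog = fs.generate_catalog(n_genes=4000, n_msp=40, seed=11)
design, composition = fs.generate_cohort(
    catalog, n_subjects=39,
    effects=(fs.PlantedEffect("msp_0012", cliffs_delta_target=0.72),), seed=12)
alignments = fs.simulate_alignments(composition, catalog, depth=20_000,
                                    shared_fraction=0.1, seed=13)
raw = fs.attribute_reads(alignments, catalog)
downsized, _ = fs.downsize(raw, 15_000, seed=14)
freqs = fs.normalize_frequencies(downsized, catalog)
msp = fs.msp_abundance(freqs, catalog)

results, excluded = fs.differential_screen(msp, design)
hits = results[results["significant"]]
print(f"{len(results)} MSPs tested, {len(excluded)} degenerate, "
      f"{len(hits)} significant at q<=0.1:")
cols = ["feature_id", "p_interaction", "q_value",
        "cliffs_delta_mf", "grade_mf", "cliffs_delta_ctl", "grade_ctl"]
print(hits[cols].round(4).to_string(index=False))

shift = fs.intra_individual_dissimilarity(msp, design)
print("mean intra-individual Bray-Curtis shift (pre -> post): "
      f"MF {shift['multi_fiber'].mean():.3f} vs CTL {shift['control'].mean():.3f}")
print("-> the planted species is recovered with a large multi-fiber effect")
print("   and a near-zero control effect; the Bray-Curtis shift is larger")
print("   in the arm whose composition actually moved.")
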