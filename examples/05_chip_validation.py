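"""Validate a TF's predicted module against ChIP-seq style peak data.

Peaks are filtered (FDR < 0.01 and >= 10 reads in >= 2 samples), assigned to
genes whose TSS lies within 10 kb of the peak summit, and genes are ranked
by peak count (> mean + 2 SD = top targets).  Concordance between ChIP
target genes and the TF's network module is a Fisher test; differential
occupancy between genotypes reuses the NB count test.
"""

import numpy as np

import trnkit as tk

study = tk.simulate_study(tk.SimulationConfig(seed=1))
iv = study.intervals
print(f"ChIP table for {iv.chip_tf}: {len(iv.peaks)} called peaks")

peaks = tk.filter_peaks(iv.peaks)
print(f"after retention rules (FDR < 0.01, >= 10 reads in >= 2 samples): {len(peaks)}")

dist = tk.distance_to_nearest_tss(peaks, iv.annotations)
print(f"median summit-to-TSS distance: {np.nanmedian(dist):.0f} bp")

pm = tk.map_peaks_to_genes(peaks, iv.annotations, window_bp=10_000)
print(f"genes with >= 1 peak within 10 kb: {len(pm.peak_positive_genes())}; "
      f"top targets (> mean + 2 SD): {len(pm.top_targets())}")

module = set(study.truth.targets_of(iv.chip_tf))
overlap, odds, p = tk.module_chip_concordance(
    module, pm, universe=set(study.truth.gene_ids)
)
print(f"module / ChIP concordance: overlap {overlap} of {len(module)}, "
      f"OR = {odds:.1f}, P = {p:.2e} (low P = module matches binding)")

occ = tk.differential_occupancy(peaks, "mutant")
n_sig = int((occ['fdr'] < 0.05).sum())
print(f"differential occupancy mutant vs wildtype: {n_sig} peaks at FDR < 5%, "
      f"{occ.attrs['frac_weaker']:.0%} of peaks weaker in the mutant")
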