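"""Predict and sample STR amplification-stutter read histograms.

The stutter model is a per-cycle slippage Markov chain: over 17 effective
amplification cycles a read can drift away from its template allele by
+/-1 repeat unit per cycle.  The DP prediction gives the exact read-length
distribution; sampling draws a finite-coverage histogram from it.
"""

from strlineage.stutter import StutterModel, predict_histogram, sample_histogram

model = StutterModel(cycles=17)
dist = predict_histogram(model, allele=13, unit="AC")
print("predicted read-length distribution for an (AC)x13 allele:")
for length, p in dist.as_dict(1e-4).items():
    print(f"  {length:>3} repeats: {p:.4f}")
# ~91% of reads keep 13 repeats; ~6% lose one unit (the classic n-1
# stutter band), smaller mass further out.

h = sample_histogram(model, 13, n_reads=30, rng=0)
print("\none 30-read histogram sampled from that allele:", h.counts)
# This is what the genotyper sees for a single cell-locus at 30x coverage.
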