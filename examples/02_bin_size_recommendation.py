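"""Pick an analysis bin size from a panel's off-target read yield.

A 75-gene panel yields ~3 million reads per sample with roughly half
falling outside the targets; those off-target reads spread over the whole
genome and the bin size must be large enough that each bin collects ~100
of them.
"""

import depthcnv as dc

stats = dc.OffTargetStats(
    sample_ids=["panel_sample"],
    total_reads=[3_000_000],
    off_target_reads=[1_500_000],
    mean_read_length=100.0,
    off_target_span=3_000_000_000,
)
print(f"off-target fraction: {stats.off_target_fraction[0]:.2f}")
print(f"mean off-target depth: {stats.mean_off_target_depth[0]:.3f}x")

bin_size = dc.recommend_bin_size(stats, genome_size=3_000_000_000)
reads_per_bin = stats.off_target_reads[0] * bin_size / 3_000_000_000
print(f"recommended bin size: {bin_size // 1000} kb "
      f"(~{reads_per_bin:.0f} expected off-target reads per bin)")
print("(~100 reads/bin keeps the Poisson noise floor of the relative "
      "dosage near 10%, enough to separate 0.5/1.0/1.5 over a few bins)")
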