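"""Generate a synthetic peak landscape and look at what was planted.

The generator lays 200 genes on 4 chromosomes, plants 20 target genes
with co-binding of all 3 factors at an active promoter and high
target-cell expression, and writes everything (BED/TSV/JSON) plus a
truth manifest.
"""

from regscreen import SyntheticConfig, generate

config = SyntheticConfig(seed=1)
dataset = generate(config)

print(f"genes: {len(dataset.genes)}  planted targets: {len(dataset.truth.planted_targets)}")
print(f"first targets: {dataset.truth.planted_targets[:5]}")
for label, peaks in dataset.peaks_by_factor.items():
    print(f"{label}: {len(peaks)} peaks "
          f"({config.n_targets} at planted promoters + "
          f"{config.background_peaks_per_factor} background)")
print(f"replicates of factor1: {len(dataset.factor1_rep1)} / {len(dataset.factor1_rep2)} peaks")
for mark, peaks in dataset.mark_peaks.items():
    print(f"{mark}: {len(peaks)} peaks")

g = dataset.truth.planted_targets[0]
print(f"\n{g}: intended state {dataset.truth.planted_states[f'promoter:{g}']}, "
      f"expression class {dataset.truth.planted_expression_class[g]} in "
      f"{config.cell_types[0]}")
print("Every planted target has factor peaks over an H3K4me3+H3K27ac promoter")
print("and medium/high target-cell expression, so the screen should find all 20.")

paths = dataset.write("scratch/example_landscape")
print(f"\nwrote {len(paths)} files to scratch/example_landscape/")
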