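"""One-call reproducible pipeline run: simulate, process, measure, analyze.

Writes the HDF5 spectrum container, CSV reports and a JSON summary (all
stamped with the seed and a configuration hash) into ./scratch/demo_run,
then prints the headline numbers.  Rerunning with the same configuration
reproduces every artifact bit for bit.
"""

from pathlib import Path

from ftms2d.pipeline import RunConfig, run_pipeline

config = RunConfig(preset="nb4k", n_increments=1024, detect_points=4096, seed=7)
result = run_pipeline(config, Path("scratch/demo_run"))

print(f"config hash {config.hash()}  seed {config.seed}")
print(f"coverage:            {result.coverage}")
print(f"site fractions:      { {k: round(v, 3) for k, v in result.site_fractions.items()} }")
print(f"correlation gap:     {result.mean_difference_hz:.2f} Hz  (true 2.69 Hz)")
print(f"decay rate:          {result.decay_rate:.1f} 1/s  (true 20)")
print("\nartifacts:")
for name, path in result.files.items():
    print(f"  {name:12s} {path}")
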