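"""One reproducible end-to-end run producing the full report bundle.

Equivalent to the CLI `microniche run-all --seed 1 --out bundle/`; two
runs with the same configuration produce byte-identical CSVs.
"""

from microniche import RunConfig, run_pipeline

cfg = RunConfig(simulate=True, seed=1, n_resamples=99, out_dir="bundle")
artifacts = run_pipeline(cfg)

print("report bundle:")
for name, path in artifacts.items():
    print(f"  {name:<22} {path}")
print("\noverlap null summary:")
print((artifacts["overlap_null_summary"]).read_text())
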