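"""One-call pipeline: synthesize -> split -> tune -> impute -> evaluate.

Equivalent to `transpute run --out-dir run_demo --seed 5` on the shell;
every stage's outputs land in the run directory with a manifest.
"""

import json
import tempfile
from pathlib import Path

from transpute import RunConfig, SynthConfig, run_pipeline

out_dir = Path(tempfile.mkdtemp()) / "run_demo"
config = RunConfig(
    out_dir=str(out_dir),
    seed=5,
    method="sample-lasso",
    synth=SynthConfig(n_tissues=4, samples_per_tissue=30,
                      datasets_per_tissue=3, n_genes=200, seed=5),
    fractions=(0.6, 0.2, 0.2),
    tune=True,
)
manifest = run_pipeline(config)

for stage in manifest["stages"]:
    extras = {k: v for k, v in stage.items() if k not in ("stage", "seconds")}
    print(f"stage {stage['stage']:10s} {stage['seconds']:6.2f}s  {extras}")
print(f"\nrun artifacts in {out_dir}:")
for f in sorted(out_dir.iterdir()):
    print(f"  {f.name}")
print(json.dumps({"median_nrmse":
                  manifest["stages"][-1]["median_nrmse"]}, indent=2))
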