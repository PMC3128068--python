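"""The whole workflow in one call: simulate -> call -> filter -> anchor ->
catalog -> design/sharing -> population structure.

Equivalent to `spudsnp run-all --seed 1 --outdir spudsnp_demo`; every
output file carries the tool version, config hash and seed, and the
manifest's counts satisfy the conservation ledgers at every stage.
"""

import json

from spudsnp.config import RunConfig
from spudsnp.pipeline import run_pipeline

config = RunConfig(seed=1, outdir="scratch/spudsnp_demo")
config.simulate.n_genes = 6
config.simulate.cultivars = ["Atlantic", "PremierRusset", "Snowden"]

manifest = run_pipeline(config)
print(json.dumps(manifest.counts, indent=2, sort_keys=True))
# raw_calls = filtered_calls + failed_calls per cultivar;
# filtered_calls = anchored + anchor drops; the high-confidence count is
# the biallelic subset of unique genome positions, and design_accepted +
# design_rejected partitions it.
print("\noutputs:")
for key, path in sorted(manifest.outputs.items()):
    print(f"  {key}: {path}")
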