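"""The complete inference chain on one simulated study.

filter -> relatedness -> ancestry -> mtDNA -> maternity -> paternal
partitioning -> strategy classification -> population rates, compared
against the generator's ground truth.
"""

import json

from nestkin.pipeline import PipelineConfig, run_pipeline
from nestkin.synthgen import SimConfig

res = run_pipeline(PipelineConfig(simulate=SimConfig(seed=5), seed=5))

truth = dict(zip(res.sim.truth.nests.nest_id, res.sim.truth.nests.strategy))
got = res.calls_by_nest()
print("nest  called                 truth                  ok")
for nest in sorted(truth):
    print(f"{nest}  {got[nest]:22s} {truth[nest]:22s} "
          f"{'yes' if got[nest] == truth[nest] else 'NO'}")

print("\npopulation rates (count / denominator):")
print(json.dumps(res.rates, indent=1, default=str))
# multi_paternal_nests counts nests with >= 2 paternal lineages among
# the hen's own eggs; parasitic clutches are separate maternal lineages.
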