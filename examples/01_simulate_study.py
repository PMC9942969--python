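"""Generate a synthetic nesting study and look at its ground truth.

The generator emulates a coastal black duck brood study: three reference
panels (black duck, wild mallard, game-farm mallard) at low nuclear
divergence, 19 nests with clutches of 5-13 eggs, extra-pair eggs,
parasitized nests, a renesting hen and a shared father.
"""

from nestkin.synthgen import SimConfig, simulate_study

sim = simulate_study(SimConfig(seed=1))

print(f"genotypes: {sim.genotypes.n_sites} SNPs x "
      f"{sim.genotypes.n_samples} samples "
      f"({len(sim.panel_labels)} reference, "
      f"{len(sim.focal_ids)} focal hens+eggs)")
print(f"mtDNA pool: {len(sim.mtdna_pool.sequences)} haplotypes "
      f"({sum(1 for v in sim.mtdna_pool.haplogroups.values() if v == 'OW-A')}"
      " in the Old World A haplogroup)")
print("\ntrue nest strategies:")
print(sim.truth.nests.to_string(index=False))
# each nest's strategy is the label the pipeline should recover: e.g. a
# multi_paternal_EPC nest holds exactly one egg from a second father.
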