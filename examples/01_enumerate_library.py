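"""Enumerate a small combinatorial library by hydrogen-handle linking.

Three building blocks (methane, benzene, thiophene) are grown for three
generations with constraints disabled; every product arises from deleting
one hydrogen on each partner and bonding the heavy-atom neighbours.
"""

from densiscreen import BuildingBlock, LibraryConfig, enumerate_library

blocks = [
    BuildingBlock("Me", "C", "methane", 4),
    BuildingBlock("Bz", "c1ccccc1", "benzene", 6),
    BuildingBlock("Th", "c1ccsc1", "thiophene", 4),
]

library = enumerate_library(blocks, LibraryConfig.unconstrained(max_generations=3))
print(f"{len(library)} unique structures from {len(blocks)} blocks, 3 generations")

by_gen = {}
for cand in library.candidates:
    by_gen.setdefault(cand.generation, []).append(cand)
for gen in sorted(by_gen):
    print(f"  generation {gen}: {len(by_gen[gen])} molecules, e.g. "
          f"{by_gen[gen][0].smiles_canonical}")

# With the default constraints (150-400 Da, <=4 rings) light candidates are
# only intermediates: they grow but are not emitted.
constrained = enumerate_library(blocks, LibraryConfig(max_generations=3))
print(f"{len(constrained)} candidates survive the 150-400 Da / 4-ring window")
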