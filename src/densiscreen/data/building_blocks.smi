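# Default 15-building-block set for combinatorial library generation.
# Format: <smiles> <id> [<name>]
# Linker blocks (B1-B3) are represented by their saturated parent molecules
# (methane, hydrogen sulfide, water); their hydrogens are the linker handles.
# Blocks marked "placeholder" are generic organic-materials moieties standing
# in for unnamed members of the original 15-block set (not source-exact).
C B1 methylene linker (methane parent)
S B2 sulfide linker (hydrogen sulfide parent)
O B3 ether linker (water parent)
c1ccccc1 B4 benzene (placeholder)
C1CCCCC1 B5 cyclohexane (placeholder)
c1ccoc1 B6 furan (placeholder)
c1nncs1 B7 1,3,4-thiadiazole
C1CCC1 B8 cyclobutane (placeholder)
C1CCCC1 B9 cyclopentane
c1cc[nH]c1 B10 pyrrole (placeholder)
c1ccncc1 B11 pyridine (placeholder)
c1cnsn1 B12 1,2,5-thiadiazole
c1cscn1 B13 thiazole
c1ocnc1 B14 oxazole (placeholder)
C1CC1 B15 cyclopropane (placeholder)
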