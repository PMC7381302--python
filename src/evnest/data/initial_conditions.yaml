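# Default initial copy numbers (molecules per cell) for the 16 species of the
# reduced extrinsic-apoptosis model that start at nonzero abundance.
#
# FADD, pC8 (procaspase-8), pC3 (procaspase-3, 21,000) and Smac (100,000) are
# fixed by the modeling conditions this package reproduces; the remaining
# values are literature-typical abundances for Type II (HeLa/Jurkat-like)
# cells from the extrinsic-apoptosis modeling literature and are configurable.
Ligand: 3000          # death ligand (TRAIL/FasL scale)
Receptor: 200         # death receptor
FADD: 130000          # DISC adapter (high-DISC condition)
pC8: 130000           # procaspase-8 (high-DISC condition)
pC3: 21000            # procaspase-3
pC6: 10000            # procaspase-6
Bid: 40000            # BH3-only MOMP activator
Bax: 80000            # pore-forming effector
Bcl2: 28000           # anti-apoptotic MOMP inhibitor
Bad: 25000            # sensitizer (inhibits Bcl-2)
CytoC_mito: 500000    # mitochondrial cytochrome c
Smac_mito: 100000     # mitochondrial Smac/DIABLO
Apaf: 100000          # Apaf-1
pC9: 100000           # procaspase-9
XIAP: 100000          # X-linked inhibitor of apoptosis
PARP: 1000000         # caspase-3 substrate; cleavage is the death proxy
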