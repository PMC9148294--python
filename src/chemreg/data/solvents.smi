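# Seed solvent dictionary for solvate stripping, one SMILES per line.
O           # water
CO          # methanol
CCO         # ethanol
CC(C)O      # isopropanol
CC(C)=O     # acetone
CS(C)=O     # DMSO
CN(C)C=O    # DMF
C1CCOC1     # THF
COCCOC      # DME
CC#N        # acetonitrile
ClCCl       # DCM
ClC(Cl)Cl   # chloroform
CCOCC       # diethyl ether
CCOC(C)=O   # ethyl acetate
Cc1ccccc1   # toluene
c1ccccc1    # benzene
CCCCCC      # hexane
C1CCCCC1    # cyclohexane
OCCO        # ethylene glycol
CC(=O)N(C)C # DMA
O=C1CCCN1C  # NMP
OCC(O)CO    # glycerol
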