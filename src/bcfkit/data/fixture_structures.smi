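# Curated toy structures for exercising fragment rules and the AD battery.
# SMILES<TAB>ID
c1ccccc1	benzene
Clc1c(Cl)c(Cl)c(Cl)c(Cl)c1Cl	hexachlorobenzene
Oc1c(Cl)c(Cl)c(Cl)c(Cl)c1Cl	pentachlorophenol
COc1c(Cl)cc(Cl)cc1Cl	246-trichloroanisole
Oc1c(Cl)cc(Cl)cc1Cl	246-trichlorophenol
S=C=S	carbon-disulfide
C[Si]1(C)O[Si](C)(C)O[Si](C)(C)O[Si](C)(C)O1	octamethylcyclotetrasiloxane
CCCCCCCCCCCCO	dodecanol
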