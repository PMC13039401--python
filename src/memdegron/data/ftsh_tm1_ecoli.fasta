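>FtsH_Ecoli_TM1 region residues 6-23 (numbering +3 vs UniProt); polar caps K6,N7 cytosolic and Q23 periplasmic
KNLILWLVIAVVLMSVFQ
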