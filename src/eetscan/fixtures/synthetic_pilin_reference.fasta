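>synthetic_pilin_ref synthetic strict e-pilin reference (simulated, not a database accession)
MKKLQGFLRLEVMVLILLQPMPNRAMMAPWQRWQNRVFAVMVPTMAKIDPSKPDTFRDAI
NIYTIRV
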