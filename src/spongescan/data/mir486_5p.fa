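>hsa-miR-486-5p mature sequence, miRBase v22 MIMAT0002177
UCCUGUACUGAGCUGCCCCGAG
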