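chr6	10555690	10555946	1.1
chr6	10556023	10556275	1.2
chr2	206628379	206628588	2.1
chr2	206628566	206628809	2.2
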