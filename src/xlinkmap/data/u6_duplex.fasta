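>U6_probe_duplex_non_template psea_offset=31 promoter=U6
GCTATGACCATGATTACGAATTCATTCTTATAATTCTCAACTGCTCTTTCCGGTACCGCCATGGAAAGGTATGGGATC
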