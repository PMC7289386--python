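edge_type	count
guided	662
undetermined	127
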