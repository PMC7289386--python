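component_id	n_nodes	main_function
Component 23	23	Membrane and mitochondria
Component 18	18	Cytoskeleton
Component 17	17	RNA binding
Component 15	15	Extracellular exosome
Component 13	13	Extracellular matrix
Component 12	12	RNA binding and translation
Component 11	11	Proliferation and oxphos
Component 10	10	Extracellular exosome
Component 9	9	RNA binding and splicing
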