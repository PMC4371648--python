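word	frequency
bath	35.0
best	95.5
coal	18.0
cold	120.0
drank	22.0
floor	88.0
pin	27.5
plate	41.0
pound	33.0
tend	19.5
third	64.0
this	980.0
told	210.0
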