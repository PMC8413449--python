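name	start	end
MT-OHR	110	441
MT-CSB1	213	235
MT-CSB2	299	315
MT-CSB3	346	363
MT-LSP	392	445
MT-HSP1	545	567
MT-TAS	16157	16172
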