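id	name	formula	excluded
glucose	D-glucose	C6H12O6	0
histidine	L-histidine	C6H9N3O2	0
maltose	maltose	C12H22O11	0
ocdca	octadecanoate	C18H36O2	0
serine	L-serine	C3H7NO3	0
trehalose	trehalose	C12H22O11	0
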