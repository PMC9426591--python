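# Observed responses in atrazine-treated soil: 1 = the genus showed a
# significant increase in relative abundance under the supplement
# (Welch test, BH-FDR p < 0.05), 0 = no significant increase.
# Transcribed for the four focal degrader genera; genera whose abundance
# decreased count as 0.
supplement	species	increased
glucose	Arthrobacter	0
glucose	Clostridium	1
glucose	Geobacter	1
glucose	Pseudomonas	0
histidine	Arthrobacter	0
histidine	Clostridium	0
histidine	Geobacter	0
histidine	Pseudomonas	1
maltose	Arthrobacter	1
maltose	Clostridium	1
maltose	Geobacter	1
maltose	Pseudomonas	0
ocdca	Arthrobacter	0
ocdca	Clostridium	0
ocdca	Geobacter	0
ocdca	Pseudomonas	0
serine	Arthrobacter	0
serine	Clostridium	0
serine	Geobacter	0
serine	Pseudomonas	0
trehalose	Arthrobacter	1
trehalose	Clostridium	0
trehalose	Geobacter	0
trehalose	Pseudomonas	0
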