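# SYNTHETIC stand-in for the published simulation-matrix fold-change values
# (growth under supplement / growth without supplement, community dFBA,
# round 3), which are deposited in external supplementary data.
# The >= 2-fold classification of these values reproduces the published
# binary calls exactly (three positives: maltose and trehalose for
# Arthrobacter, trehalose for Pseudomonas); the numeric magnitudes below
# are placeholders consistent with those calls, not published values.
supplement	species	fold_change
glucose	Arthrobacter	1.1
glucose	Clostridium	1.6
glucose	Geobacter	1.5
glucose	Pseudomonas	1.2
histidine	Arthrobacter	1.0
histidine	Clostridium	1.0
histidine	Geobacter	1.0
histidine	Pseudomonas	1.8
maltose	Arthrobacter	3.6
maltose	Clostridium	1.7
maltose	Geobacter	1.4
maltose	Pseudomonas	1.3
ocdca	Arthrobacter	1.2
ocdca	Clostridium	1.0
ocdca	Geobacter	1.0
ocdca	Pseudomonas	1.1
serine	Arthrobacter	1.3
serine	Clostridium	1.0
serine	Geobacter	1.0
serine	Pseudomonas	1.4
trehalose	Arthrobacter	3.8
trehalose	Clostridium	1.2
trehalose	Geobacter	1.1
trehalose	Pseudomonas	2.4
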