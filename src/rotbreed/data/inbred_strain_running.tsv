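strain	best_distance_m
DA	840
PVG	718
AUG	699
SR	533
F344	469
ACI	450
LEW	442
WKY	414
BUF	373
MNS	308
COP	298
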