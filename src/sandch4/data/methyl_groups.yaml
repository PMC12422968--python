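# Methyl groups available to methylotrophic methanogens, per molecule.
# Extend freely (e.g. further osmolytes); keys are case-insensitive.
tma: 3               # trimethylamine
tmao: 3              # trimethylamine N-oxide
choline: 3
glycine-betaine: 3
dmsp: 2              # dimethylsulfoniopropionate
dms: 2               # dimethylsulfide
methylamine: 1
methanol: 1
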