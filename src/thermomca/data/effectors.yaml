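# Literature-derived regulatory metabolites per reaction. Anthranilate
# feed-forward-inhibits indole-3-glycerol-phosphate synthase; entries are
# filtered to the reactions present in the active network (the toy lumps
# IGPS with tryptophan synthase). Extend per reaction as
#   <reaction-id>: [{metabolite: <id>, role: activator|inhibitor}, ...]
effectors:
  igps:
    - {metabolite: anth, role: inhibitor}
  igps_trps:
    - {metabolite: anth, role: inhibitor}
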