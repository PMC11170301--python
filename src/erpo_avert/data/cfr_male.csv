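# units=fraction
# method-specific case fatality ratios, male stratum (ED-visit based)
method,cfr
firearm,0.904
poisoning_drugs,0.025
poisoning_other_solid_liquid,0.016
poisoning_gases_vapors,0.342
hanging,0.559
drowning,0.62
cutting,0.013
jumping_height,0.306
jumping_moving_object,0.307
other_unspecified,0.02
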