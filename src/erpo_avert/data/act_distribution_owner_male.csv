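# units=percent
# estimated method distribution of suicidal acts, male handgun owners
method,proportion
firearm,28
poisoning_drugs,54
poisoning_other_solid_liquid,2
poisoning_gases_vapors,1
hanging,3
drowning,0
cutting,9
jumping_height,1
jumping_moving_object,1
other_unspecified,1
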