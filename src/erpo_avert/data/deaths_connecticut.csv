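# units=count
# method-specific suicide deaths among the 762 Connecticut ERPO respondents, 1999-2013
method,deaths
firearm,6
poisoning_drugs,2
poisoning_other_solid_liquid,0
poisoning_gases_vapors,2
hanging,10
drowning,0
cutting,1
jumping_height,0
jumping_moving_object,0
other_unspecified,0
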