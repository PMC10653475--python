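code_prefix,category
NCE,new_chemical_entity
NP,new_product
NC,new_combination
NPP,new_patient_population
NR,new_route
NDF,new_indication_or_dosing
I,new_indication_or_dosing
D,new_indication_or_dosing
PED,pediatric
M,new_indication_or_dosing
ODE,other
GAIN,other
PC,other
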