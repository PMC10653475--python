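brand,ingredients,insulin_class,first_approval,n_products,n_drug_device,manufacturer
Admelog,lispro,rapid,12/11/2017,3,1,Sanofi
Myxredlin,human,rapid,6/20/2019,1,0,Baxter
Basaglar,glargine,long,12/16/2015,1,1,Eli Lilly
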