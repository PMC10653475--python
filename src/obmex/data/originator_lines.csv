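brand,ingredients,insulin_class,first_approval,n_products,n_drug_device,manufacturer
Humalog,lispro,rapid,6/14/1996,4,3,Eli Lilly
Velosulin BR,human,rapid,7/19/1999,1,0,Novo Nordisk
Novolog,aspart,rapid,6/7/2000,5,3,Novo Nordisk
Apidra,glulisine,rapid,4/16/2004,3,1,Sanofi
Exubera,human,rapid,1/27/2006,2,2,Pfizer
Afrezza,human,rapid,6/27/2014,3,3,MannKind
Fiasp,aspart,rapid,9/29/2017,3,1,Novo Nordisk
Humulin BR,regular,short,4/28/1986,1,0,Eli Lilly
Humulin U,regular,short,6/10/1987,2,0,Eli Lilly
Novolin L,regular,short,6/25/1991,1,0,Novo Nordisk
Novolin R,regular,short,6/25/1991,1,1,Novo Nordisk
Novolin N,NPH,intermediate,7/1/1991,1,1,Novo Nordisk
Lantus,glargine,long,4/20/2000,2,1,Sanofi
Levemir,detemir,long,6/16/2005,5,4,Novo Nordisk
Toujeo,glargine,long,2/25/2015,2,2,Sanofi
Tresiba,degludec,long,9/25/2015,3,1,Novo Nordisk
Xultophy 100/3.6,glargine/lixisenatide,mixture_long_incretin,11/21/2016,1,1,Novo Nordisk
Soliquo 100/33,glargine/lixisenatide,mixture_long_incretin,11/21/2016,1,1,Sanofi
Humalog 50/50,lispro protamine/lispro,mixture_intermediate_rapid,12/22/1999,3,2,Eli Lilly
Humalog 75/25,lispro protamine/lispro,mixture_intermediate_rapid,12/22/1999,3,2,Eli Lilly
Novolog 70/30,aspart protamine/aspart,mixture_intermediate_rapid,11/1/2001,4,1,Novo Nordisk
Ryzodeg 70/30,degludec/aspart,mixture_intermediate_rapid,9/25/2015,1,1,Novo Nordisk
Humulin 70/30,NPH/regular,mixture_intermediate_short,4/25/1989,2,1,Eli Lilly
Novolin 70/30,NPH/regular,mixture_intermediate_short,6/25/1991,1,1,Novo Nordisk
Humulin 50/50,NPH/regular,mixture_intermediate_short,4/29/1992,1,0,Eli Lilly
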