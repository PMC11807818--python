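component,direction
vegetables_g,beneficial
legumes_g,beneficial
fruits_nuts_g,beneficial
cereals_g,beneficial
fish_g,beneficial
mufa_sfa_ratio,beneficial
meat_g,detrimental
dairy_g,detrimental
alcohol_g,range
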