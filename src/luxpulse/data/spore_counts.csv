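label,viable_per_ml,spores_12h,spores_24h,spores_48h
wild_type,7.8e7,1.1e7,1.2e7,1.6e7
sigH,4.0e6,0,0,0
codY,3.3e8,3.7e6,5.8e6,7.1e6
relA,1.3e8,9.4e5,1.1e6,1.0e6
relA_yjbM_ywaC,1.0e8,1.0e5,2.6e5,3.6e5
relA_yjbM_ywaC_codY,1.5e8,0,0,0
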