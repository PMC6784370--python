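sample_label	nominal_class	concentration_per_mL	coating	counts_per_mL
1e5 NS1	positive	1e5	anti-CD138	12123,14700,10367
3e4 NS1	positive	3e4	anti-CD138	3463,5173,6180,5070
1e4 NS1	positive	1e4	anti-CD138	2867,1223,1927,1597
3e3 NS1	positive	3e3	anti-CD138	467,630,517,607
1e3 NS1	positive	1e3	anti-CD138	500,977,280,353
1e5 NS1 IpaD315	negative		IpaD315	895,60,660,637,723,313,520
1e5 CHO	negative		anti-CD138	690,380,367
beads only	negative		anti-CD138	1665,375,2213,310
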