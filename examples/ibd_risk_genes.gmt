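ibd_risk_example	example fixture; substitute a curated risk-gene list for real analyses	gene0066	gene0473	gene0444	gene0525	gene0370	gene0411	gene0303	gene0392	gene0042	gene0494	gene0152	gene0040	gene0438	gene0290	gene0274	gene0530	gene0122	gene0268	gene0397	gene0342	gene0077	gene0096	gene0075	gene0049	gene0422	gene0014	gene0553	gene0159	gene0153	gene0188	gene0073	gene0211	gene0023	gene0576	gene0131	gene0520	gene0505	gene0179	gene0222	gene0341
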