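# Committed truth for filter_fixture.tsv: rows that survive the default rules
# (tumor_vaf > 0.05 strict, normal_vaf < 0.01 strict, alt_fwd >= 2 and
# alt_rev >= 2, position outside blacklist 513-525 / 3105-3109).
sample_id
F01
F03
F08
F11
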