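# Circuit-only run with the optimized interface parameters and the
# in-silico tandem tissue load; reproduces the ~12 V end-of-plateau
# electrode potential from a 20 V drive.

[run]
name = "tandem_load"

[circuit]
r_tissue_ohm = 522.0

[pulse]
amplitude_v = 20.0
width_ms = 50.0
rise_time_ms = 1.0
fall_time_ms = 1.0
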