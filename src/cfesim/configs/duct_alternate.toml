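# Synthetic cochlear duct, alternate configuration (anodes and cathodes
# interleaved along the array), full coupled pipeline at default resolution.

[run]
name = "duct_alternate"
target_surface = "basilar_membrane"

[geometry]
kind = "duct"
mesh_size_um = 100.0

[electrodes]
configuration = "alternate"
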