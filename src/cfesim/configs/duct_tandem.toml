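# Synthetic cochlear duct, tandem configuration (four ganged anodes then
# four ganged cathodes), full coupled pipeline at default resolution.

[run]
name = "duct_tandem"
target_surface = "basilar_membrane"

[geometry]
kind = "duct"
mesh_size_um = 100.0

[electrodes]
configuration = "tandem"
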