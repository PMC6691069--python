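# Analytic slab fixture: 1 mm cube of perilymph-like fluid with a mid-plane
# membrane, plate electrodes on opposite faces, driven by the standard
# 20 V / 50 ms pulse.  Small and fast; the resistances have closed forms.

[run]
name = "slab_demo"
target_surface = "basilar_membrane"

[geometry]
kind = "slab"
mesh_size_um = 125.0
slab_dims_mm = [1.0, 1.0, 1.0]
slab_membrane = true

[electrodes]
configuration = ["anode", "cathode", "floating", "floating", "floating", "floating", "floating", "floating"]

[circuit]
r_tissue_ohm = 976.6
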