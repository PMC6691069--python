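# cfesim

Coupled circuit / finite-element simulation of **close-field electroporation
(CFE)**: gene electrotransfer driven by a cochlear-implant electrode array.

Array-driven electroporation delivers plasmid DNA to mesenchymal cells lining
the scala tympani by pulsing the implant's own electrodes.  Transfection
efficacy tracks the electric field strength reached at the target tissue
(the basilar membrane), which cannot be measured in situ.  `cfesim` predicts
those fields by chaining three models:

1. **Electrode-electrolyte interface.**  EIS spectra of platinum cochlear
   electrodes are fit by a constant phase element (CPE) in series with a
   spreading resistance, `Z(f) = R_s + K/(j 2πf)^m` with `m = θ_CPE / 90°`.
   For time-domain work the CPE is synthesized as `n` parallel series-RC
   branches whose capacitances grow by the density factor `k` per branch
   (θ_CPE = 65.3°, k = 1.18, n = 61, R_s = 297 Ω for the 8-channel array
   studied).  Faradaic redox currents at electroporation voltages are added
   as an anti-parallel pair of diode–memristor branches,
   `V = n·V_T ln(1 + I/I_s) + M(q)·I`, with memristance
   `M(q) = max(M_min, M_0 / (1 + |q|/q_0))` decreasing as charge is
   delivered.
2. **Volume conductor.**  The quasi-static conduction equation
   `∇·(−σ∇V) = 0` is solved with linear tetrahedral finite elements on a
   labelled mesh of the cochlear duct (body-fluid scalae σ = 1.5 S/m,
   soft-tissue surround 0.25092, nerve-tissue partition 0.017126).  The
   basilar and Reissner's membranes are zero-thickness contact-impedance
   sheets carrying `n̂·J = (σ_m/d_s)(V₁ − V₂)` with σ_m = 0.2904 S/m and
   numerical thicknesses 90 µm and 20 µm.
3. **Coupling and field mapping.**  The tissue load is extracted from a 1 V
   stationary solve, the interface circuit is integrated against that load,
   and the delivered electrode potential V(t) scales a unit field solution
   (superposition; a brute-force per-sample mode serves as the oracle).
   Per-element |E| on the basilar membrane is binned into field levels
   (default edges 4, 8, 20, 100, 500, 1000 V/cm) and the areas per level are
   compared between the **alternate** (A,C,A,C,…) and **tandem**
   (A,A,A,A,C,C,C,C) electrode configurations.

The MRI-derived guinea-pig geometry of the original study is not
distributed; `cfesim` ships a parametric synthetic duct that preserves the
topology (three scalae, two membranes, nerve core, soft-tissue surround,
8-electrode array of 350 µm diameter / 300 µm length / 300 µm spacing in the
scala tympani, helicotrema at the apex) but not the spiral anatomy.  Gmsh
MSH 4.1 meshes with the same label vocabulary can be imported instead.

## Worked example

Reproduce the delivered-voltage calculation for the tandem configuration
(in-silico tissue load 522 Ω, single 20 V / 50 ms pulse with 1 ms ramps):

```sh
cfesim simulate-circuit --config src/cfesim/configs/tandem_load.toml --out resp.csv
```

```
[cfesim] R_tissue = 522 ohm; end-of-plateau V_out = 12.057 V, I = 23.10 mA, q = 1.123 mC
```

Of the 20 V drive, 12.06 V survives the electrode-tissue interface at the
end of the plateau — the `±12 V` applied at the electrode boundaries in the
tandem field simulations; with the alternate load (174 Ω, `--r-tissue 174`)
the same circuit delivers 6.93 V.  The delivered charge (1.12 mC) has
reduced the Faradaic memristance to roughly half its initial value, which is
why the plateau sits far above the purely capacitive (non-Faradaic)
response.

The full coupled pipeline on the synthetic duct:

```sh
cfesim analyze --config src/cfesim/configs/duct_tandem.toml --out out/
```

```
[cfesim] tissue R = 442.5 ohm, plateau potential = 11.30 V
```

writes the circuit response CSV, VTU field snapshots (`V` nodal,
`E_mag_V_per_m` per element), and the basilar-membrane field-area report
(CSV + JSON).  `cfesim demo --out demo/` runs the slab fixture plus the duct
tandem/alternate comparison end-to-end; `--fast` uses a coarse scaled-down
duct.  `cfesim compare --config-a … --config-b …` emits per-bin
tandem/alternate area ratios.

Label vocabulary for imported meshes: regions `scala_tympani`,
`scala_media`, `scala_vestibuli`, `soft_tissue`, `partition`; surfaces
`electrode_1` … `electrode_8`, `outer`, and membrane sides
`basilar_membrane:side1/:side2`, `reissner_membrane:side1/:side2`.

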