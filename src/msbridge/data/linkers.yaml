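# Built-in cross-linker and platinum-adduct chemistry.
# Bridge formulas are the compositions ADDED by a bridging cross-link
# (diacid spacer minus two waters); "D" denotes deuterium.
crosslinkers:
  - name: DSG
    light_bridge: {C: 5, H: 4, O: 2}
    heavy_bridge: {C: 5, D: 4, O: 2}
    reactive_residues: [K, S]
    reacts_n_term: true
    span: 20.5
    span_tol: 3.0
  - name: DSS
    light_bridge: {C: 8, H: 10, O: 2}
    heavy_bridge: {C: 8, H: 6, D: 4, O: 2}
    reactive_residues: [K, S]
    reacts_n_term: true
    span: 24.2
    span_tol: 3.0
pt_adducts:
  - name: transplatin
    protein_reactive: [C, M, H, T]
    reacts_protein_termini: false
    dna_reactive: [G]
    pt_isotope: Pt
    # Donor-heteroatom span of a trans Pt(NH3)2 bridge; not a literature
    # calibration, see docs/methods.md.
    span: 5.0
    span_tol: 2.0
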