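# Modification table, v1 — histone H3 tail middle-down search chemistry.
# delta_mass must agree with the elemental composition within 1e-4 Da;
# compositions use heavy-isotope symbols 13C / 15N where the label chemistry
# requires them.  Users may extend this file and load it with
# midtail.chem_core.load_modifications().
version: 1
modifications:
  - name: Methyl
    abbrev: me1
    delta_mass: 14.015650
    composition: {C: 1, H: 2}
    targets: [K, R]
    max_per_peptide: 3
  - name: Dimethyl
    abbrev: me2
    delta_mass: 28.031300
    composition: {C: 2, H: 4}
    targets: [K, R]
    max_per_peptide: 3
  - name: Trimethyl
    abbrev: me3
    delta_mass: 42.046950
    composition: {C: 3, H: 6}
    targets: [K]
    max_per_peptide: 3
  - name: Phospho
    abbrev: ph
    delta_mass: 79.966331
    composition: {H: 1, P: 1, O: 3}
    targets: [S, T]
    max_per_peptide: 2
  - name: Acetyl
    abbrev: ac
    delta_mass: 42.010565
    composition: {C: 2, H: 2, O: 1}
    targets: [K]
    max_per_peptide: 5
  - name: Propionyl
    abbrev: pr
    delta_mass: 56.026215
    composition: {C: 3, H: 4, O: 1}
    targets: [K]
    max_per_peptide: 1
  - name: TMT6plex
    abbrev: TMT6plex
    delta_mass: 229.162932
    composition: {C: 8, 13C: 4, H: 20, N: 1, 15N: 1, O: 2}
    targets: [H]
    max_per_peptide: 0
    fixed: true
  - name: SortaseCterm
    abbrev: cterm
    delta_mass: 76.1001
    composition: null
    targets: []
    max_per_peptide: 0
    fixed: true
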