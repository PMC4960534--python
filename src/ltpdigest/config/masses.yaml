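# Residue-level mass tables and protease specificity rules.
# Average and monoisotopic residue masses derived from IUPAC standard
# atomic masses via the standard amino-acid residue compositions
# (identical to the Expasy/Unimod reference tables).
residue_masses:
  average:
    A: 71.07802
    C: 103.14281
    D: 115.08757
    E: 129.11418
    F: 147.17420
    G: 57.05140
    H: 137.13952
    I: 113.15787
    K: 128.17252
    L: 113.15787
    M: 131.19604
    N: 114.10280
    P: 97.11537
    Q: 128.12942
    R: 156.18592
    S: 87.07742
    T: 101.10404
    V: 99.13125
    W: 186.21031
    Y: 163.17360
  monoisotopic:
    A: 71.03711
    C: 103.00918
    D: 115.02694
    E: 129.04259
    F: 147.06841
    G: 57.02146
    H: 137.05891
    I: 113.08406
    K: 128.09496
    L: 113.08406
    M: 131.04048
    N: 114.04293
    P: 97.05276
    Q: 128.05858
    R: 156.10111
    S: 87.03203
    T: 101.04768
    V: 99.06841
    W: 186.07931
    Y: 163.06333
constants:
  water_average: 18.01529
  water_monoisotopic: 18.01056
  # loss of two hydrogens per disulfide bridge
  disulfide_average: 2.01588
  disulfide_monoisotopic: 2.01565
  # carbamidomethyl (iodoacetamide) adduct per free cysteine, C2H3NO
  carbamidomethyl_average: 57.05140
  carbamidomethyl_monoisotopic: 57.02146
proteases:
  trypsin:
    cleaves_after: [K, R]
    blocked_by_next: [P]
  chymotrypsin:
    cleaves_after: [F, Y, W, L]
    blocked_by_next: [P]
  # high-specificity convention at pH <= 2; LTPs are pepsin-resistant and the
  # gastric stage contributes no cuts by default
  pepsin:
    cleaves_after: [F, L, W, Y]
    blocked_by_next: []
# van der Waals radii (Angstrom), Bondi (1964) element-based set
vdw_radii:
  id: bondi-1964
  H: 1.20
  C: 1.70
  N: 1.55
  O: 1.52
  S: 1.80
  P: 1.80
  default: 1.70
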