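# 24-variant eye/hair-colour panel definition.
#
# assay_index is the column order of the multiplex assay (and of the bundled
# genotype fixture): positions 1-11 are the eleven MC1R variants, positions
# 12-24 the remaining pigmentation markers.  Allele letters follow the assay
# read-out strand exactly as reported by the genotyping chemistry; no strand
# flipping is performed anywhere in the package.
#
# effect_allele is the allele counted as the model dosage (0/1/2).
# effect_allele_freq is the default European-like frequency used by the
# synthetic reference-panel generator.
# red_penetrant marks MC1R variants with high penetrance for red hair; the
# missing-marker policy attaches a "red hair cannot be excluded" caveat when
# one of these is missing but hair is still predicted.
# dropout_sensitivity is the relative fragility weight used by the
# degradation simulator (the insertion probe is the most fragile, rs4959270
# second, all others baseline).
#
# hair_excluded: the hair/shade models use 22 of the 24 markers.  Which two
# are excluded is a configuration choice (overridable); the default excludes
# the two OCA2/SLC24A4 variants whose predictive value is specific to eye
# colour.

markers:
  - {marker_id: N29insA,    gene: MC1R,    assay_index: 1,  alleles: [C, A], effect_allele: A, effect_allele_freq: 0.002, red_penetrant: true,  dropout_sensitivity: 3.0}
  - {marker_id: rs11547464, gene: MC1R,    assay_index: 2,  alleles: [G, A], effect_allele: A, effect_allele_freq: 0.01,  red_penetrant: true}
  - {marker_id: rs885479,   gene: MC1R,    assay_index: 3,  alleles: [C, T], effect_allele: T, effect_allele_freq: 0.08}
  - {marker_id: rs1805008,  gene: MC1R,    assay_index: 4,  alleles: [C, T], effect_allele: T, effect_allele_freq: 0.07,  red_penetrant: true}
  - {marker_id: rs1805005,  gene: MC1R,    assay_index: 5,  alleles: [G, T], effect_allele: T, effect_allele_freq: 0.09}
  - {marker_id: rs1805006,  gene: MC1R,    assay_index: 6,  alleles: [C, A], effect_allele: A, effect_allele_freq: 0.01,  red_penetrant: true}
  - {marker_id: rs1805007,  gene: MC1R,    assay_index: 7,  alleles: [C, T], effect_allele: T, effect_allele_freq: 0.06,  red_penetrant: true}
  - {marker_id: rs1805009,  gene: MC1R,    assay_index: 8,  alleles: [G, C], effect_allele: C, effect_allele_freq: 0.02,  red_penetrant: true}
  - {marker_id: Y152OCH,    gene: MC1R,    assay_index: 9,  alleles: [C, A], effect_allele: A, effect_allele_freq: 0.003, red_penetrant: true}
  - {marker_id: rs2228479,  gene: MC1R,    assay_index: 10, alleles: [G, A], effect_allele: A, effect_allele_freq: 0.10}
  - {marker_id: rs1110400,  gene: MC1R,    assay_index: 11, alleles: [T, C], effect_allele: C, effect_allele_freq: 0.01}
  - {marker_id: rs28777,    gene: SLC45A2, assay_index: 12, alleles: [A, C], effect_allele: C, effect_allele_freq: 0.12}
  - {marker_id: rs16891982, gene: SLC45A2, assay_index: 13, alleles: [G, C], effect_allele: C, effect_allele_freq: 0.15, in_eye_model: true}
  - {marker_id: rs12821256, gene: KITLG,   assay_index: 14, alleles: [A, G], effect_allele: G, effect_allele_freq: 0.15}
  - {marker_id: rs4959270,  gene: EXOC2,   assay_index: 15, alleles: [C, A], effect_allele: A, effect_allele_freq: 0.40, dropout_sensitivity: 2.0}
  - {marker_id: rs12203592, gene: IRF4,    assay_index: 16, alleles: [C, T], effect_allele: T, effect_allele_freq: 0.15, in_eye_model: true}
  - {marker_id: rs1042602,  gene: TYR,     assay_index: 17, alleles: [G, T], effect_allele: T, effect_allele_freq: 0.35}
  - {marker_id: rs1800407,  gene: OCA2,    assay_index: 18, alleles: [G, A], effect_allele: A, effect_allele_freq: 0.07, in_eye_model: true}
  - {marker_id: rs2402130,  gene: SLC24A4, assay_index: 19, alleles: [A, G], effect_allele: G, effect_allele_freq: 0.20}
  - {marker_id: rs12913832, gene: HERC2,   assay_index: 20, alleles: [T, C], effect_allele: C, effect_allele_freq: 0.70, in_eye_model: true}
  - {marker_id: rs2378249,  gene: ASIP,    assay_index: 21, alleles: [T, C], effect_allele: C, effect_allele_freq: 0.12}
  - {marker_id: rs12896399, gene: SLC24A4, assay_index: 22, alleles: [G, T], effect_allele: G, effect_allele_freq: 0.45, in_eye_model: true}
  - {marker_id: rs1393350,  gene: TYR,     assay_index: 23, alleles: [C, T], effect_allele: T, effect_allele_freq: 0.25, in_eye_model: true}
  - {marker_id: rs683,      gene: TYRP1,   assay_index: 24, alleles: [T, G], effect_allele: G, effect_allele_freq: 0.45}

hair_excluded: [rs1800407, rs12896399]
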