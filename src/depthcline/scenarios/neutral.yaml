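name: neutral
# Panmixia: no genetic structure, no trait divergence; every downstream
# signal should sit at its null expectation.
n_groups: 3
group_sizes: [83, 217, 71]
n_loci: 18
alleles_per_locus: [3, 20]
target_fst: 0.0
structure_model: island
depth_per_group: [40.0, 75.0, 120.0]
missing_rate: 0.0
lmax_decline: 0.0
growth_decline: 0.0
seed: 0
trait_specs:
  - {name: buoyancy, sigma2_between: 0.0, sigma2_within: 4.0, additive: true, allometric_exponent: 0.0}
  - {name: CPD, sigma2_between: 0.0, sigma2_within: 0.01, allometric_exponent: 1.0}
  - {name: CPL, sigma2_between: 0.0, sigma2_within: 0.01, allometric_exponent: 1.0}
  - {name: HLL, sigma2_between: 0.0, sigma2_within: 0.01, allometric_exponent: 1.0}
  - {name: MXL, sigma2_between: 0.0, sigma2_within: 0.01, allometric_exponent: 1.0}
  - {name: OOL, sigma2_between: 0.0, sigma2_within: 0.01, allometric_exponent: 1.0}
  - {name: PCL, sigma2_between: 0.0, sigma2_within: 0.01, allometric_exponent: 1.0}
  - {name: PVL, sigma2_between: 0.0, sigma2_within: 0.01, allometric_exponent: 1.0}
  - {name: POL, sigma2_between: 0.0, sigma2_within: 0.01, allometric_exponent: 1.0}
  - {name: body_PC1, sigma2_between: 0.0, sigma2_within: 1.0, additive: true, allometric_exponent: 0.0}
  - {name: head_PC1, sigma2_between: 0.0, sigma2_within: 1.0, additive: true, allometric_exponent: 0.0}
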