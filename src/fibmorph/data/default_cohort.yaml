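# Default cohort parameters.
#
# Group means/SDs, group sizes and age ranges are study-derived defaults for a
# 7T MRI fibular morphometry cohort (107 adults, four sex x age-group cells);
# they describe the population the simulator emulates, not ground truth any
# analysis is expected to reproduce. Age slopes and the BMI/SFT/MFI
# distributions are the package's own realistic choices (see docs/methods.md).
#
# Units: BT mm, BA mm^2, g dimensionless, MPI dimensionless, age years,
# BMI kg/m^2, SFT mm.

groups:
  "F<=50":
    n: 17
    age_range: [15, 50]
    bt: {mean: 2.9, sd: 0.5}
    ba: {mean: 67.9, sd: 12.6}
    g: {mean: 0.37, sd: 0.13}
    mpi: {mean: 0.12, sd: 0.04}
    mfi_probs: {normal: 0.6, mild: 0.3, moderate: 0.1}
  "M<=50":
    n: 13
    age_range: [11, 50]
    bt: {mean: 2.9, sd: 0.5}
    ba: {mean: 71.7, sd: 7.7}
    g: {mean: 0.42, sd: 0.16}
    mpi: {mean: 0.12, sd: 0.04}
    mfi_probs: {normal: 0.6, mild: 0.3, moderate: 0.1}
  "F>50":
    n: 26
    age_range: [51, 78]
    bt: {mean: 2.0, sd: 0.5}
    ba: {mean: 58.6, sd: 15.0}
    g: {mean: 0.61, sd: 0.13}
    mpi: {mean: 0.17, sd: 0.05}
    mfi_probs: {normal: 0.3, mild: 0.4, moderate: 0.3}
  "M>50":
    n: 51
    age_range: [51, 79]
    bt: {mean: 2.9, sd: 0.6}
    ba: {mean: 85.1, sd: 16.9}
    g: {mean: 0.49, sd: 0.11}
    mpi: {mean: 0.12, sd: 0.05}
    mfi_probs: {normal: 0.3, mild: 0.4, moderate: 0.3}

# per-sex linear age effects, centered on each group's age midpoint
bt_age_slope: {F: -0.015, M: 0.0}     # mm / year
mpi_age_slope: {F: 0.001, M: 0.0}     # 1 / year

bmi_distribution:
  F: {mean: 30.3, sd: 5.7}
  M: {mean: 28.4, sd: 4.4}

sft_distribution: {mean: 5.0, sd: 2.0}

seed: 0
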