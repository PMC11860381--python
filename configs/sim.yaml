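# Simulation parameters for `nirseed simulate --config configs/sim.yaml`.
# Every key is optional; omitted keys fall back to the package defaults
# shown here.  Amplitudes are absorbance units, widths/centres cm^-1,
# dispersions are standard deviations.

scans_per_bag: 6

# Gaussian absorption bands (C-H 2nd overtone, N-H 1st, S-H 1st,
# O-H/HOH combination, C-H combination, C-H/CH2 combination).
band_centers: [8230.0, 6824.0, 5736.0, 5176.0, 4776.0, 4304.0]
band_widths: [220.0, 180.0, 140.0, 120.0, 130.0, 110.0]
base_amplitudes: [0.45, 0.25, 0.35, 0.60, 0.40, 0.30]
baseline_level: 0.35

# Scan-level artefacts, one per pre-processing operator:
scatter_slope_sd: 0.05    # multiplicative scatter (MSC / SNV)
scatter_offset_sd: 0.02   # additive offset (mean centring, derivatives)
tilt_sd: 0.01             # linear baseline tilt (detrend)
noise_sd: 0.003           # white per-point noise (Savitzky-Golay)

# Between-bag amplitude jitter, shared by the six scans of a bag:
bag_sd: 0.0008

# Per-strain amplitude jitter (0 = strain identity has no spectral effect):
strain_jitter_sd: 0.0

# Class effects (cultivar_effect / endophyte_effect) default to the
# calibrated offsets on bands 1 (8230), 5 (4776) and 3 (5736) described in
# docs/methods.md; override them here as {cultivar: [6 amplitudes]} and
# [6 amplitudes] respectively.
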