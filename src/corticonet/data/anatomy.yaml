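# Anatomical parameter tables for the published network configuration.
# All sections are plain data so that a new census can be swapped in.
#
# densities: excitatory neuron density [neurons/mm^3] for the four areas with
#   direct measurements; the remaining areas use the per-layer average.
# voxel_counts: number of (10 um)^3 voxels per region.
# interlaminar_widths_cat: Gaussian connection widths [um] measured in cat V1,
#   source layer -> target layer.
# interlaminar_d75: pairwise connection probability at 75 um horizontal offset,
#   source layer -> target layer.
# surface_areas: flat-map convex-hull surface area [mm^2] per region.

dlgn_count: 21200

densities:
  VISp:  {L4: 106114.7, "L2/3": 86668.2, L5: 86643.4}
  VISal: {L4: 93176.9,  "L2/3": 79070.6, L5: 78540.9}
  VISl:  {L4: 86559.9,  "L2/3": 73937.9, L5: 66215.6}
  VISpl: {L4: 106783.0, "L2/3": 87368.3, L5: 82538.1}

averaged_areas: [VISrl, VISli, VISpor]

voxel_counts:
  VISp:   {L4: 1023640, "L2/3": 1999040, L5: 1552688}
  VISal:  {L4: 104152,  "L2/3": 199314,  L5: 202942}
  VISl:   {L4: 179084,  "L2/3": 301588,  L5: 314522}
  VISpl:  {L4: 36638,   "L2/3": 205150,  L5: 242812}
  VISrl:  {L4: 146294,  "L2/3": 276390,  L5: 244294}
  VISli:  {L4: 57256,   "L2/3": 117252,  L5: 147946}
  VISpor: {L4: 60632,   "L2/3": 373972,  L5: 385168}

interlaminar_widths_cat:
  "L2/3": {"L2/3": 225, L4: 50,  L5: 100}
  L4:     {"L2/3": 220, L4: 180, L5: 140}
  L5:     {"L2/3": 150, L4: 100, L5: 210}

# Reference pair anchoring the cat -> mouse width scaling: L4->L4 is 114 um in
# mouse auditory cortex and 180 um in cat V1.
width_scaling: {mouse_um: 114.0, cat_um: 180.0}

interlaminar_d75:
  "L2/3": {"L2/3": 0.160, L4: 0.016, L5: 0.083}
  L4:     {"L2/3": 0.140, L4: 0.243, L5: 0.104}
  L5:     {"L2/3": 0.021, L4: 0.007, L5: 0.116}

d75_offset_um: 75.0

surface_areas:
  VISp:   {L4: 4.3271, "L2/3": 4.7406, L5: 4.2511}
  VISal:  {L4: 0.4909, "L2/3": 0.5477, L5: 0.4972}
  VISl:   {L4: 0.8793, "L2/3": 0.9279, L5: 0.8651}
  VISli:  {L4: 0.3355, "L2/3": 0.4356, L5: 0.4039}
  VISpl:  {L4: 0.2865, "L2/3": 0.6659, L5: 0.6785}
  VISrl:  {L4: 0.6182, "L2/3": 0.6980, L5: 0.6748}
  VISpor: {L4: 0.5264, "L2/3": 1.3937, L5: 1.2445}

# Extrinsic in-degree: assumed number of interareal inputs per neuron.
in_degree: 1000

# Subcortical kernel sizes from receptive-field sizes at 1 pixel/degree acuity:
# 9 degrees in dLGN; dLGN->VISp4 then 3x3 for an 11x11 VISp receptive field.
dlgn_rf_degrees: 9.0
acuity_pixels_per_degree: 1.0
dlgn_to_visp_kernel: 3
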