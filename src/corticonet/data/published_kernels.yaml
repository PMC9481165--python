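# As-published conv kernel sizes, one entry per edge ("source->target" -> k).
# Interareal kernels have no closed-form re-derivation without the voxel-model
# connectome, so the published values are frozen here.  The two interlaminar
# entries VISli4->VISli2/3 (17) and VISpl4->VISpl2/3 (19) disagree with the
# width-to-pixels formula applied to the shipped surface areas (which gives 15
# and 17); they are kept verbatim and flagged by the generator.
input->dLGN: 9
dLGN->VISp4: 3
VISp4->VISp2/3: 9
VISp4->VISal4: 17
VISp4->VISl4: 19
VISp4->VISli4: 19
VISp4->VISpl4: 19
VISp4->VISrl4: 19
VISp4->VISpor4: 17
VISp2/3->VISp5: 3
VISp2/3->VISal4: 15
VISp2/3->VISl4: 19
VISp2/3->VISli4: 17
VISp2/3->VISpl4: 17
VISp2/3->VISrl4: 21
VISp2/3->VISpor4: 19
VISp5->VISal4: 15
VISp5->VISl4: 19
VISp5->VISli4: 19
VISp5->VISpl4: 17
VISp5->VISrl4: 19
VISp5->VISpor4: 19
VISpor4->VISpor2/3: 13
VISpor2/3->VISpor5: 3
VISal4->VISal2/3: 13
VISal4->VISpor4: 3
VISal2/3->VISal5: 5
VISal2/3->VISpor4: 1
VISal5->VISpor4: 1
VISl4->VISl2/3: 9
VISl4->VISpor4: 15
VISl2/3->VISl5: 5
VISl2/3->VISpor4: 15
VISl5->VISpor4: 15
VISli4->VISli2/3: 17
VISli4->VISpor4: 17
VISli2/3->VISli5: 7
VISli2/3->VISpor4: 17
VISli5->VISpor4: 15
VISpl4->VISpl2/3: 19
VISpl4->VISpor4: 3
VISpl2/3->VISpl5: 5
VISpl2/3->VISpor4: 5
VISpl5->VISpor4: 5
VISrl4->VISrl2/3: 11
VISrl4->VISpor4: 7
VISrl2/3->VISrl5: 5
VISrl2/3->VISpor4: 9
VISrl5->VISpor4: 9
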