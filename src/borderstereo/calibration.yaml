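# Versioned calibration constants for the experiment presets.
#
# Each value is a reference group mean (crossings per measurement line)
# that the generator is calibrated to reproduce through the Buffon
# inversion rho = pi * mean / (2 * L).  Group keys name the line
# placement they calibrate.  Changing a target changes only the scene
# densities, never the measurement code.
version: 1
presets:
  barrel_layer4:
    line_length: 375.0
    astrocyte:
      septal: 3.78
      core: 11.02
    capillary:
      septal: 2.64
      core: 2.97
  barrel_layer3_5:
    line_length: 375.0
    astrocyte_layer3:
      septal: 11.2
      core: 16.2
    astrocyte_layer5:
      septal: 9.4
      core: 14.3
    capillary_layer3:
      septal: 1.66
      core: 1.69
    capillary_layer5:
      septal: 2.46
      core: 1.73
  auditory_A1A2:
    line_length: 50.0
    astrocyte:
      A1: 14.1
      A2: 7.4
    reference_200um:
      A1: 13.96
      A2: 7.18
  human_IIIaIIIb:
    line_length: 375.0
    astrocyte:
      IIIa: 27.2
      IIIb: 13.3
    reference_200um:
      IIIa: 28.5
      IIIb: 12.4
  human_blobs:
    line_length: 500.0
    astrocyte:
      blob: 5.25
      interblob: 11.25
    reference_margin:
      interblob-margin: 12.1
  thickness_4v8:
    line_length: 375.0
    astrocyte:
      septal: 3.78
      core: 11.02
    thin_retention: 0.65
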