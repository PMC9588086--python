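# Reconstructed width-programmed dilution network for the two-stage MCGG:
# merging equal 150 um dye/buffer feeds gives the 1/2 rung; a 50 um dye feed
# against a 150 um buffer feed gives the 1/4 rung.  Weights are feed widths
# (flow proportional to width at equal length/height).
inlets:
  dye: 1.0
  buffer: 0.0
merges:
  - name: half
    streams: [[dye, 150.0], [buffer, 150.0]]
  - name: quarter
    streams: [[dye, 50.0], [buffer, 150.0]]
outputs: [dye, half, quarter, buffer]
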