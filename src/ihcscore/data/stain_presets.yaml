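# Stain absorbance presets: per-stain RGB optical-density vectors.
# Vectors are unit-normalized on load; order defines the channel order of
# the unmixed output.  The "hdab" entry carries the canonical published
# constants for brightfield H&E + DAB deconvolution.
hdab:
  description: Hematoxylin, eosin and DAB for chromogenic IHC with hematoxylin counterstain
  stains:
    hematoxylin: [0.650, 0.704, 0.286]
    eosin: [0.072, 0.990, 0.105]
    dab: [0.268, 0.570, 0.776]
he:
  description: Hematoxylin and eosin only (third channel completed orthogonally)
  stains:
    hematoxylin: [0.644211, 0.716556, 0.266844]
    eosin: [0.092789, 0.954111, 0.283111]
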