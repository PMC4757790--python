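# Provenance of the bundled reference curves
blood_absorption.tsv:
  quantity: absorption coefficient of undiluted whole blood, mm^-1
  anchors:
    - {wavelength_nm: 425, source: inversion of the packaged 1%-blood
       24-um coefficient 0.413 mm^-1 (van Veen relation)}
    - {wavelength_nm: 561, source: inversion of 0.153 mm^-1}
    - {wavelength_nm: 576, source: inversion of 0.206 mm^-1}
    - {wavelength_nm: 593, source: inversion of 0.056 mm^-1}
  between_anchors: standard ~96%-oxygenated whole-blood shape,
    monotone log-space interpolation through literature-scale points
znpp_emission.tsv:
  quantity: unit-peak ZnPP emission template
  shape: Gaussian, peak 593 nm, FWHM 25 nm (parametric stand-in)
ppix_emission.tsv:
  quantity: unit-peak PPIX emission template
  shape: Gaussians at 635 nm (1.0, FWHM 25) and 705 nm (0.3, FWHM 40)
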