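# znpp — non-invasive erythrocyte zinc protoporphyrin quantitation

Iron deficiency raises the zinc protoporphyrin (ZnPP) content of red blood
cells: when iron is scarce, zinc is inserted into protoporphyrin IX instead,
and the ZnPP/haem ratio (µmol ZnPP per mol haem) becomes a blood-free-stable
biomarker of functional iron deficiency.  ZnPP fluoresces under blue
excitation, so it can in principle be read *through the skin of the lower
lip*, where a thin epithelium overlies blood-filled capillaries — except
that tissue autofluorescence is ~100× brighter than the ZnPP signal.

This package implements the full computational chain of a fibre-probe
instrument that solves that problem, for researchers in biomedical optics
and clinical-method evaluation:

- **Dual-wavelength difference spectroscopy** (`znpp.quantify`): emission
  spectra are acquired at 425 nm (ZnPP excitation maximum) and 407 nm
  (equal blood absorption, ~78% weaker ZnPP excitation).  Normalising the
  407-nm spectrum to the 425-nm one over 520–525 nm and subtracting cancels
  >90% of the background while retaining most of the ZnPP fluorescence.
- **Second-derivative spectral fitting**: the difference spectrum *D* is
  decomposed by finding amplitudes (a, z, p) such that

      B(λ) = (D(λ) − z·F_ZnPP(λ) − p·F_PPIX(λ)) / exp(−a·µ_a(λ))

  has the smoothest possible residual background *B* over 560–750 nm
  (minimal summed squared second derivative).  Here µ_a is the whole-blood
  absorption spectrum, F_ZnPP and F_PPIX are unit-peak emission templates
  (593 nm and 635/705 nm), z is the ZnPP amplitude reported per cycle, and
  a is an effective haemoglobin path length (mm).
- **Blood-absorption-index site qualification**: the depth of the
  haemoglobin dip around 576 nm on the 407-nm spectrum, solved from three
  bands (562/576/593 nm), maps to the instrument's LED zones; only *green*
  sites (index ≥ 0.70 × 10⁻²) are quantified.
- **Vessel-packaging correction** (`znpp.references`): blood confined in
  vessels of diameter d absorbs less than evenly distributed haemoglobin,
  by the factor C = (1 − e^(−µd))/(µd); forward and inverse maps with the
  bundled whole-blood absorption curve and emission templates.
- **Layered Monte Carlo fluorescence transport** (`znpp.mc_fluor`):
  MCML-style photon transport (Henyey–Greenstein scattering, Fresnel
  boundaries, survival roulette) with fibre launch/detection geometry
  (NA 0.22, reflecting ferrule) and weighted-direct-emission fluorescence,
  with exact per-run energy ledgers.
- **Method-comparison statistics** (`znpp.stats`): robust zero-offset
  scaling to HPLC units, Bland–Altman limits of agreement from the
  Maronna–Zamar τ-scale (1.96·τ) with percentile-bootstrap CIs, Youden
  ROC cutpoints, and contingency diagnostics at the >50 µmol/mol
  iron-deficiency threshold.
- **Synthetic fixtures** (`znpp.synthetic`): seeded generators for
  spectra, full sessions (10 sites × 10 cycles) and 56-subject cohorts
  with the statistical structure the method assumes, so everything above
  is testable without any instrument data.

## Worked example

```python
from znpp.quantify import quantify_subject
from znpp.references import load_reference_library
from znpp.synthetic import SpectrumGenSpec, generate_session

refs = load_reference_library()
session = generate_session(
    SpectrumGenSpec(znpp_amplitude=2.0, ppix_amplitude=0.5, seed=42), refs
)
result = quantify_subject(session, refs)
print(result.n_cycles, result.mean_z, result.sem_z)
```

prints

```
cycles quantified : 100
mean ZnPP amplitude: 1.550 counts/ms
s.e.m.             : 0.018 counts/ms
```

The generator embedded 2.0 counts/ms of ZnPP in every 425-nm spectrum; the
difference spectrum retains a fraction (1 − 0.22) of it, so the recovered
mean sits at ~1.56 counts/ms, with the subject-level precision given by the
s.e.m. over the 100 cycles.  More narrative scripts live in `examples/`
(one per capability: session quantitation, blood index, vessel packaging,
Monte Carlo, agreement statistics); each prints what it computes and what
the numbers mean.

A thin CLI wraps the same library calls:

```bash
znpp simulate session --seed 7 --out runs/s7
znpp quantify runs/s7/session.json --out runs/s7/q
znpp stats agree --paired runs/cohort.tsv --boot 2000 --seed 1 --out runs/agree
znpp mc --photons 20000 --seed 3 --out runs/mc
```

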