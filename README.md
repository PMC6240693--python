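# dropfreeze

Analysis of droplet-freezing assays for microalgal ice nucleation: from
frozen-well counts on cooled well plates to per-cell ice-nucleating-particle
(INP) spectra, strain-level ice-nucleation-activity (INA) classification,
treatment-contrast inference of the active compound's nature, and panel-level
diversity/survival summaries — plus a full simulator of the experiment for
validation and power analysis.

It is written for aerobiologists, limnologists and atmospheric scientists who
phenotype microbial strains (here: airborne and aquatic microalgae) with
immersion-freezing well-plate assays: suspensions are cooled stepwise from
−2 to −28 °C with 30-minute holds, and the number of frozen wells is recorded
per temperature setpoint against a PBS buffer control.

## The model

The frozen fraction at setpoint T is FF(T) = (frozen wells)/(total wells).
After background correction against the buffer control, the cumulative INP
concentration per cell follows the Vali relation under the singular
(time-independent) freezing approximation:

```
N(T) = −ln(1 − [FF_sample(T) − FF_control(T)]) / (c · V)
```

with c the cell concentration (cells µL⁻¹) and V the droplet volume (µL).
Cell-free plates (controls, 0.22 µm filtrates) are normalised per droplet
(divide by V only). Setpoints where the control out-freezes the sample are
removed, fully frozen plates are reported as saturation lower bounds with
FF = (n − ½)/n, and Clopper–Pearson 95 % intervals on the frozen-well counts
are propagated through the same monotone map. Ten-fold dilution series are
merged per setpoint over the dilutions inside the plate's detection limits,
and a strain is kept only when all three biological replicates show activity
above the lower detection limit −ln(1 − 1/n)/(cV).

Strain decisions follow the assay conventions: a screen is positive when at
least 50 % of wells are frozen at −24 °C, activity is confirmed when every
repeated screen is positive, the onset temperature is the warmest setpoint
active in all replicates, and onsets bin into warm (≥ −6 °C), mid, cool and
cold classes down to −24 °C. The nature of the INA compound is inferred from
heat (100 °C, denatures proteins) and filtration (removes cells) contrasts
with a Kruskal–Wallis gate and Dunn pairwise post-hoc tests, implemented in
`dropfreeze.stats` together with the two-sample proportion test with
continuity correction.

## Worked example

```python
import dropfreeze as df

protocol = df.TemperatureProtocol.default()           # -2 … -28 °C, 2 °C steps
droplet = df.DropletSpec(volume_ul=20, cells_per_ul=100)
truth = df.SpectrumModel(
    components=(df.SpectrumComponent("proteinaceous", "particulate",
                                     onset_t=-8.0, amplitude_a=1e-3,
                                     slope_gamma=0.5),),
    background_per_droplet=df.default_background(),
)
plate = df.simulate_plate(truth, droplet, protocol, n_wells=32, seed=11)
control = df.simulate_plate(
    df.SpectrumModel(background_per_droplet=df.default_background()),
    df.DropletSpec(volume_ul=20), protocol, n_wells=32, seed=12,
    treatment="control")
spectrum = df.estimate_spectrum(plate, control)
for t, v, lo, hi, fl in zip(spectrum.setpoints, spectrum.values,
                            spectrum.ci_low, spectrum.ci_high, spectrum.flags):
    print(f"{t:6.1f} °C  {v:10.3e}  [{lo:9.3e}, {hi:9.3e}]  {fl}")
```

prints

```
  -2.0 °C   0.000e+00  [0.000e+00, 5.764e-05]  below_detection
  -4.0 °C   0.000e+00  [0.000e+00, 5.764e-05]  below_detection
  -6.0 °C   0.000e+00  [0.000e+00, 5.764e-05]  below_detection
  -8.0 °C   1.040e-03  [6.190e-04, 1.674e-03]  ok
 -10.0 °C   2.079e-03  [1.109e-03,       inf]  saturated
 ...
```

The plate froze 28/32 wells at −8 °C (the component's onset), giving an
estimate of 1.04 × 10⁻³ INP cell⁻¹ whose interval covers the true
K(−8 °C) = 10⁻³; colder setpoints are fully frozen, so only the saturation
lower bound 2.08 × 10⁻³ cell⁻¹ = −ln(1 − 63/64)/(cV) is resolvable there (a
dilution series extends the range; see `merge_dilutions`).

The same workflow is available from the shell:

```
dropfreeze simulate --seed 1 --out sim/          # plates.csv, strains.tsv, truth.json
dropfreeze spectrum --plates sim/plates.csv --out spectra/
dropfreeze classify --spectra spectra/spectra.json --out decisions.csv
dropfreeze summary  --strains sim/strains.tsv --out summaries/
dropfreeze run      --seed 1 --out results/      # everything, with a manifest
```

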