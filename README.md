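# thermotee

Estimation of total energy expenditure (TEE) in pediatric intensive-care
patients from low-resolution radiometric thermography.

Bedside long-wave infrared cameras deliver 160×120 frames of absolute skin
temperature. From such a frame, this package (i) segments the patient from the
background, ventilatory tubes and monitor screens, (ii) isolates bare skin
from blanket-covered regions by clustering temperatures, (iii) recovers the
skin temperature beneath textiles through a thermal-resistance model, and
(iv) converts the mean skin temperature into radiative power and a daily
energy expenditure, classified against an age/sex reference. It is aimed at
researchers prototyping non-invasive metabolic monitoring; because clinical
thermography databases are rarely shareable, the package ships a phantom
generator that produces realistic frames **with exact ground truth**, used for
training, validation and all tests.

## The model

For a patient of weight $W$ (kg) with mean bare-skin temperature $T$ (°C) in a
room at $T_a$ (°C):

- net radiative power per unit area (Stefan–Boltzmann),
  $P = \varepsilon\,\sigma\,\big[(T+273.15)^4 - (T_a+273.15)^4\big]$ W/m²,
  with skin emissivity $\varepsilon = 0.98$ and
  $\sigma = 5.673\times10^{-8}\,\mathrm{W\,m^{-2}\,K^{-4}}$;
- pediatric body surface area $A = \dfrac{4W+7}{W+90}$ m²;
- total energy expenditure, assuming radiation carries 75 % of resting heat
  loss: $\mathrm{TEE} = \dfrac{P \cdot 86400}{4184 \cdot 0.75}$ kcal/m²/day.

Skin under a textile of thermal resistance $R_t$ (K·m²/W) reads low by the
flux it transmits; the inversion $T_{\mathrm{skin}} = T_{\mathrm{cloth}} +
\varphi R_t$ recovers it, with $\varphi$ estimated as the radiative flux of
the bare-skin mean. Bare vs covered skin is decided by exact 1-D $k$-means
($k=2$) on the patient-pixel temperatures — the warmest cluster is bare skin.
$R_t$ for a material is measured on a heating plate as
$R_t = \Delta T \cdot A_{\mathrm{sample}} / Q$.

Segmentation itself is a compact UNet-style encoder–decoder (NumPy
implementation: im2col convolutions, skip connections, Adam, weighted
cross-entropy) that consumes the raw temperature matrix.

## Worked example

```sh
python examples/03_energy_report.py
```

```
mean skin temperature: 35.50 C
radiative power:       76.9 W/m^2 (40.2 W total)
body surface area:     0.522 m^2
TEE:                   2118 kcal/m^2/day (1106 kcal/day)
vs reference 1500:     +41.2% -> zone 'hyper'
true phantom TEE:      2118 kcal/m^2/day (recovery error 0.01%)
```

A phantom with a blanket-covered lower body is generated with 0.1 °C sensor
noise, partitioned into bare/covered skin, occlusion-corrected, and converted
to energy: the pipeline recovers the phantom's true TEE to 0.01 % here. The
`zone` compares the estimate with the 1500 kcal/m²/day clinical reference
(within ±10 % → normal, ±25 % → monitor, beyond → hyper-/hypometabolism).

The other examples cover phantom generation (`01`), the bare-skin partition
and textile inversion (`02`), segmentation training (`04`) and the 116-patient
cohort statistics (`05`). A thin CLI wraps the same stages:
`thermotee phantom | train | segment | tee | batch | monitor | stats`.

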