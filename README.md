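# vascage

In silico assessment of noninvasive pulse-wave indices of vascular aging.

Arterial walls stiffen with age, and aortic stiffness — summarised by the
aortic Young's modulus E_Ao — predicts cardiovascular events. E_Ao cannot
be measured directly in people, so clinicians and wearable devices rely on
surrogate indices computed from pulse waves: transit-time pulse wave
velocities (PWV), pressure-morphology measures, the cardio-ankle vascular
index (CAVI), carotid distensibility (DC), and photoplethysmogram (PPG)
features. How faithfully each surrogate tracks E_Ao, how badly it is
confounded by heart rate, stroke volume or vessel diameter, and how it
survives measurement noise are empirical questions that are hard to answer
in vivo — but straightforward on virtual subjects whose true wall
stiffness is known exactly.

`vascage` is a pipeline for exactly that study, aimed at researchers in
hemodynamic signal analysis:

* **19 indices** from multi-site single-beat pressure, flow-velocity,
  luminal-area and PPG waveforms: aoPWV, cfPWV, baPWV, cbPWV, crPWV,
  ftPWV, cPP, bPP, AP, AIx, P_b amplitude, RM, CAVI, DC, RI, SI, AGI,
  AIx_ppg and d/a.
* **Exact stiffness reference** via the exponential wall law
  Eh/r = k1·e^(k2·r) + k3, the length-weighted aortic modulus
  E_Ao = Σ (L_j/L_Ao)·E_j, and the theoretical root speed
  aoPWV_t = sqrt(2Eh/(3ρr)).
* **Statistical harness**: Spearman/Pearson correlations vs E_Ao with
  young/elderly subgroups, Bland–Altman agreement of the PWVs with
  aoPWV_t, a relative sensitivity index for six cardiac/vascular model
  parameters, and an SNR-controlled noise-robustness experiment
  (white noise at 30/20/15 dB + zero-phase 0.0665–35 Hz band-pass).
* **Virtual-subject generator** with closed-form beats and exact ground
  truth (E_Ao, transit delays, reflection ratio, distensibility), so the
  entire pipeline is testable offline.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
from vascage import SyntheticSpec, make_subject, compute_panel

subject, truth = make_subject(SyntheticSpec(), age=45.0)
panel = compute_panel(subject)

print(f"reference:  E_Ao = {truth.e_ao/1e6:.3f} MPa,  aoPWV_t = {truth.ao_pwv_t:.2f} m/s")
print(f"transit:    cfPWV = {panel.get('cfPWV'):.2f} m/s,  baPWV = {panel.get('baPWV'):.2f} m/s")
print(f"morphology: cPP = {panel.get('cPP')/133.322:.1f} mmHg,  AIx = {panel.get('AIx'):.3f}")
print(f"reflection: RM = {panel.get('RM'):.3f}  (generator gain {truth.reflection_gain:.3f})")
print(f"stiffness:  CAVI = {panel.get('CAVI'):.2f},  DC = {panel.get('DC')*1e3:.4f} 1/kPa")
print(f"PPG:        SI = {panel.get('SI_ppg'):.2f} m/s,  RI = {panel.get('RI_ppg'):.3f}")
```

prints

```
reference:  E_Ao = 0.761 MPa,  aoPWV_t = 8.47 m/s
transit:    cfPWV = 8.47 m/s,  baPWV = 8.59 m/s
morphology: cPP = 52.6 mmHg,  AIx = 0.098
reflection: RM = 0.305  (generator gain 0.306)
stiffness:  CAVI = 12.19,  DC = 0.0127 1/kPa
PPG:        SI = 6.48 m/s,  RI = 1.439
```

The 45-year-old virtual subject has a mid-range aortic modulus
(0.76 MPa). The measured carotid–femoral PWV (8.47 m/s) matches the
theoretical root wave speed, the wave-separation reflection magnitude
recovers the generator's reflection gain to three decimals, and the
distensibility and CAVI values sit where a moderately stiffened aorta
should put them. Ages 25 and 75 give E_Ao ≈ 0.40 and 1.30 MPa with the
index panel shifting accordingly (larger pulse pressure, positive
augmentation, vanishing PPG diastolic peak).

Population-level work goes through the assessment layer or the CLI:

```bash
vascage assess --n 100 --seed 7 --snr inf,30,20,15 --out results/
vascage generate --n 20 --seed 1 --out population/
vascage indices --population population/ --out panels.csv
```

`assess` writes `panels.csv`, `correlations.csv` (all/young/elderly
cohorts, sorted by descending Spearman correlation), `bland_altman.csv`
(six PWVs vs aoPWV_t), `sensitivity.csv` and `noise_robustness.csv`.

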