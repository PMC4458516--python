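# rodmap

Cell-cycle-resolved fluorescence localization analysis and
envelope-defect quantification for rod-shaped bacteria, with a synthetic
microscopy-scene generator that provides full ground truth.

`rodmap` is aimed at microbiologists who quantify where a protein sits in
the cell as division proceeds. Given a phase-contrast-like channel and
one or more fluorescence channels, it:

1. **segments** individual rods (or accepts label masks), extracting a
   closed contour, a pole-to-pole medial axis, the cell length, and a
   diameter/phase-brightness profile per cell;
2. **profiles** each cell: integrated fluorescence per axial bin, and
   fluorescence sampled along the contour at 1-pixel (0.064 µm) spacing;
3. **maps** the population: in a steady-state exponential culture the
   age density is p(a) = 2 ln2 · 2⁻ᵃ with CDF F(a) = 2(1 − 2⁻ᵃ), so with
   exponential single-cell growth L(a) = L₀·2ᵃ each cell's cycle age is
   assigned from its length rank, a = −log₂(1 − F/2), F = (rank−½)/n.
   Length-sorted stacks of axial profiles form the profile map
   (demograph); 10% age classes give average profiles, and two mid-cell
   statistics are computed over an absolute 0.8 µm window — the **ring
   fraction** (window fluorescence / total) and **FCplus** (window
   fluorescence above the mean of two flanking windows). Population
   trends of FCplus define the **initiation** (first age class with
   significant mid-cell enrichment) and the **moment** (class of peak
   enrichment);
4. **classifies envelope defects**: a cell exhibits *periplasmic
   leakage* when its median contour fluorescence falls below the 98th
   percentile of a leaky reference population's medians; *outer-membrane
   blebs* are isolated bright puncta (brightness above the 99.7th
   percentile of reference cell brightness, area < 4 µm²) within 0.3 µm
   of a segmented cell.

Because no public dataset accompanies this kind of analysis, the
`synthgen` module renders steady-state populations (growth law,
constriction, localization classes, injected leaky cells and blebs) as
multi-channel TIFF scenes with per-cell ground truth, so every stage is
testable against known answers.

## Worked example

```python
import rodmap

septal = rodmap.ChannelModel(name="sep", kind="septal",
                             septal_onset_age=0.4, septal_peak_age=0.65)
pop, truth = rodmap.sample_population(3000, seed=1)
profiles = rodmap.analytic_profiles(truth, septal, seed=2)
table = rodmap.assign_ages(pop["length_um"], pop["cell_id"])

summary = rodmap.age_class_averages(profiles, table)
print("initiation age:", round(rodmap.detect_initiation(summary), 2))

import numpy as np
fc = np.array([rodmap.fc_plus(p) for p in profiles])
print("moment age:", rodmap.detect_moment(fc, table["age"].to_numpy()))
print("mean assigned age:", round(table["age"].mean(), 4))
```

prints

```
initiation age: 0.3
moment age: 0.75
mean assigned age: 0.4427
```

The generator switched the septal band on at age 0.40 with peak
amplitude at 0.65; the detected initiation (0.3) and moment (0.75) land
one 10% age class away from those ground-truth values, which is the
resolution limit of rank-based age assignment under 5% length noise
(averaged over seeds the recovery is unbiased; see
`scripts/acceptance.py`). The population mean assigned age equals the
steady-state expectation 1/ln2 − 1 ≈ 0.4427.

The same analysis runs on rendered images end to end from the shell:

```bash
rodmap all --seed 1 --out runs/demo
```

which writes the scene (TIFF + ground-truth tables), per-cell tables,
profile maps (TSV + PNG), localization statistics, and leakage/bleb
calls, each stage with a JSON manifest.

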