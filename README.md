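# photoblue

Quantifying photoconversion ("photoblueing") artifacts in confocal and STED
fluorescence microscopy, on fully synthetic, seeded data.

## The problem

Intense illumination does more than photobleach fluorophores: it also
converts a fraction of red-emitting dyes into species with blue-shifted
emission. These photoblued species leak into detection channels reserved for
other dyes, bias ratiometric spectral readouts such as generalized
polarization (GP) imaging of membrane lipid packing, and — through a
separate mechanism, partial bleaching of mutually quenching dyes on
multi-labelled antibodies — produce spurious fluorescence-lifetime changes.
`photoblue` implements the complete measurement pipeline used to quantify
these artifacts, driven by a photophysics simulator so every stage is
verifiable against known ground truth:

- **`photoblue.synth`** — seeded generators: first-order
  red → blue → dark photoconversion kinetics per illumination frame,
  16-channel log-normal emission spectra, intensity traces of 2D Brownian
  diffusers with triplet blinking, two-channel membrane image stacks, and
  TCSPC decay histograms (including the multi-dye antibody quenching
  mechanism).
- **`photoblue.spectral`** — one/two-component asymmetric log-normal
  spectral unmixing (asymmetry fixed at a = 0.24) extracting the photoblued
  species' peak shift and emission fraction.
- **`photoblue.fcs`** — multi-tau autocorrelation and model fitting with
  the 2D anomalous-diffusion model G(τ) = (1/N)(1 + (τ/τ_D)^α)⁻¹,
  optionally multiplied by the triplet factor (1 − T + T·e^(−τ/τ_triplet));
  molecular brightness Q = rate/N, molecule percentages N(t)/N(0), and the
  STED spot-size calibration ω₀,STED = ω₀,conf·√(τ_D,STED/τ_D,conf).
- **`photoblue.gp`** — ratiometric GP = (I_b − I_r)/(I_b + I_r) imaging:
  membrane masking, saturated-pixel exclusion, mean-GP time series.
- **`photoblue.flim`** — lifetime estimation on TCSPC histograms
  (period-truncation-corrected mean arrival time, mono-exponential tail fit)
  and frame-series lifetime tracking.
- **`photoblue.config` / `photoblue.pipeline` / `photoblue.cli`** — scenario
  presets (standard vs. exchangeable probes, oxygen depletion, confocal vs.
  STED dose), end-to-end deterministic runs, CSV/TIFF interfaces and a CLI.

## Worked example

```python
import numpy as np
from photoblue.synth import (PhotoKineticsParams, simulate_photoconversion,
                             spectral_series_from_trajectory)
from photoblue.spectral import (SpectralBinning, LogNormalComponent,
                                blue_fraction_series)

kin = PhotoKineticsParams(k_blue=0.03, k_bleach_red=0.05, k_bleach_blue=0.01)
traj = simulate_photoconversion(kin, 10)
print(f"after 10 frames: {100*traj.f_blue[10]:.1f}% photoblued, "
      f"{100*traj.f_red[10]:.1f}% intact")

bins = SpectralBinning.default16()          # 16 channels x 12.5 nm
red  = LogNormalComponent(1000.0, 655.0, 45.0)
blue = LogNormalComponent(1000.0, 633.0, 42.0)   # 22 nm blue-shifted
initial, series = spectral_series_from_trajectory(
    traj, red, blue, bins, total_counts_initial=2e5, noise_seed=1)
fr = blue_fraction_series(series, initial)
print(f"unmixed blue emission fraction, frame 10: {fr[10]:.3f}")
```

prints

```
after 10 frames: 19.5% photoblued, 44.9% intact
unmixed blue emission fraction, frame 10: 0.287
```

i.e. under this illumination dose roughly a fifth of the molecules have
photoblued after ten frames, and spectral unmixing attributes ~30 % of the
561 nm-excited emission to the blue-shifted species (the intact red
population has also bleached, which raises the blue *emission* fraction
above the blue *molecule* fraction).

The same scenarios are runnable from the shell:

```bash
photoblue report --preset nr12a_cells --seed 1 --out out/nr12a
photoblue unmix --initial init.csv --series manifest.csv --a 0.24 --out fractions.csv
photoblue fcs correlate --trace t.csv --m 16 --out c.csv
photoblue fcs fit --curve c.csv --triplet fixed:5e-6 --out fit.json
```

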