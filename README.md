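# apostim

Tools for studying how warning-signal **luminance contrast** deters naive
avian predators. Many aposematic (warning-coloured) prey advertise their
defences with high-contrast spots and stripes; testing whether contrast
itself — independent of mean brightness — drives predator wariness requires
stimuli whose internal Michelson contrast is controlled exactly while mean
luminance stays constant, and an analysis pipeline for the resulting binary
approach/eat trial data. `apostim` provides both halves:

- **Pattern synthesis** — Gray-Scott reaction-diffusion fields with named
  spot and stripe regimes, plus a morphology classifier that verifies each
  field's class.
- **Stimulus factory** — mirror-symmetric triangular "moth" targets
  (44 x 37 mm at 600 dpi) whose patterned region hits a Michelson contrast
  target `C = (Rmax - Rmin)/(Rmax + Rmin)` to within 8-bit quantization
  (levels 0.15 and 1.0) with the masked mean grey identical across
  conditions — the confound control at the heart of the design.
- **Avian luminance** — grey-to-arena-luminance calibration anchored at the
  measured 13 and 216 cd/m^2 endpoints, and double-cone (achromatic channel)
  luminance as the spectral integral reflectance x illuminant x sensitivity.
- **Synthetic behavior** — cohorts with the experiment's exact design
  (80 chicks in groups of 19/21/20/20, five trials, two batches) from a
  two-stage random-intercept logistic model in which eating is conditional
  on approaching.
- **GLMM analysis** — binomial logit mixed models with a per-chick random
  intercept, fitted by Gauss-Hermite maximum likelihood (cross-checked
  against `lme4`), Wald chi-square per-term tests, and the study's
  model-reduction rules (pool non-significant batch; drop the three-way
  interaction only if AIC improves).

## Worked example

```python
from apostim import generate_category

images, manifest = generate_category("spots", 0.15, n_variants=2, base_seed=7)
print(manifest[["variant_id", "achieved_contrast", "achieved_mean"]])
```

```
 variant_id  achieved_contrast  achieved_mean
          0           0.149606       0.498039
          1           0.149606       0.498039
```

Each variant is a seeded reaction-diffusion field, upsampled, mirrored into
the triangle, tone-normalized, and mapped onto 8-bit greys (108, 146) —
the integer pair whose Michelson contrast, 0.1496, is closest to the 0.15
target. High-contrast categories measure exactly 1.0 (greys 0 and 255), and
the masked mean stays at ~0.5 in every condition, so contrast varies while
mean luminance does not. See `examples/` for the luminance calibration
(`(216-13)/(216+13) = 0.886` effective arena contrast), cohort simulation,
and the full GLMM report; `docs/methods.md` documents models, defaults and
limitations.

A thin CLI mirrors the workflow:

```sh
apostim generate --class spots --contrast 0.15 --n 30 --seed 1 --out stimuli/
apostim simulate --seed 1 --out trials.csv
apostim analyze --trials trials.csv --out report/
```

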