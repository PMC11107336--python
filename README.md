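# fiberscope

A desk-scale digital twin of a **scanning darkfield fiber-bundle
microendoscope** for imaging stained epithelial cell nuclei.

High-resolution microendoscopes relay an image of the epithelial surface
through a thin coherent fiber bundle placed in contact with the tissue. With
an absorbing nuclear stain (methylene blue), nuclei appear as dark dots in
reflectance — but ordinary widefield reflectance through a fiber bundle is
flooded by the mirror-like (specular) reflection generated at the bundle's
own surfaces. Scanning darkfield imaging solves this without moving parts:
a programmable projector illuminates a sequence of *line pairs* while the
sensor's rolling shutter acts as a moving line-shaped detection aperture,
and the sequence is designed so the illuminated rows and the detection band
never overlap. Specular reflection stays on the illuminated rows and is
rejected exactly; only light that scattered laterally inside the tissue is
collected.

`fiberscope` implements the whole chain as testable, physics-based
simulation:

- **phantom** — synthetic stained epithelium: a hard-core point process of
  elliptical nuclei with co-registered absorption (methylene-blue-like,
  nuclei dark in reflectance) and fluorescence (proflavine-like, nuclei
  bright) channels, with exact ground truth.
- **fiberbundle** — hexagonal core lattice clipped to a 790 µm circular
  field of view, disk-aperture signal integration per core, and rendering of
  the characteristic honeycomb pattern.
- **acquisition** — frame formation in three modes (widefield reflectance,
  scanning darkfield, fluorescence): double-pass Beer–Lambert absorption
  contrast `ρ·e^(−2τ)`, per-core specular reflection, polarizer leakage,
  Gaussian subsurface-scattering spread, line-pair scan sequences
  synchronized with a rolling-shutter detection band, shot/read noise and
  12-bit quantization.
- **restore** — the restoration chain applied identically to all modes:
  Gaussian honeycomb removal (normalized convolution inside the FOV), linear
  brightness adjustment, contrast-limited adaptive histogram equalization.
- **analyze** — multiscale Laplacian-of-Gaussian nuclei detection (dark or
  bright polarity), counting in 25 identical regions of interest
  (mean ± sd), Weber contrast `|µ_bg − µ_fg|/µ_bg` and background-referred
  SNR, and precision/recall against phantom ground truth.

## Worked example

```python
import fiberscope as fs

phantom = fs.default_phantom(seed=1)          # ~540 nuclei, 820 um field
bundle = fs.build_bundle()                    # 790 um FOV, 4.5 um pitch
report = fs.compare_modes(phantom, bundle, seed=7)

for mode, r in report.per_mode.items():
    print(f"{mode:24s} count {r.count_mean:5.2f} ± {r.count_sd:4.2f}  "
          f"Weber C {r.weber_contrast:6.3f}  SNR {r.snr:6.2f}  "
          f"recall {r.recall:.3f}")
print(f"darkfield vs fluorescence count difference: "
      f"{100 * report.count_agreement_rel_diff:.2f}%")
```

prints

```
widefield_reflectance    count 24.40 ± 4.09  Weber C  0.088  SNR   0.76  recall 0.414
darkfield                count  8.48 ± 1.71  Weber C  0.413  SNR   8.72  recall 0.995
fluorescence             count  8.48 ± 1.64  Weber C 17.277  SNR  59.13  recall 1.000
darkfield vs fluorescence count difference: 0.00%
```

Reading this: the three modes image the *same* phantom. Widefield
reflectance is dominated by the granular specular background — its Weber
contrast collapses, most detections are spurious (the inflated count of
24.4 per ROI), and fewer than half the true nuclei are recovered. Scanning
darkfield rejects the specular term, restoring contrast and near-perfect
recall, and its per-ROI counts agree with the fluorescence reference to
well under 5% — the simulated analogue of the finding that darkfield
reflectance with an absorbing stain counts nuclei as reliably as
fluorescence with a fluorescent stain.

The same pipeline is scriptable from the shell:

```bash
fiberscope simulate --seed 3 --out out/          # raw frames + ground truth
fiberscope process out/raw_darkfield.tif --out out/
fiberscope compare --seed 3 --out out/cmp        # full three-mode report
```

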