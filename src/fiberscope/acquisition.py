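"""Frame formation in three microendoscope imaging modes.

Modes
-----
* ``widefield_reflectance`` — the whole FOV is illuminated while the whole
  sensor integrates. The detection aperture therefore also collects the
  mirror-like (specular) reflection generated at the fiber bundle's proximal
  and distal surfaces, which floods the image with structured background.
* ``darkfield`` — scanning darkfield: a sequence of illumination line pairs
  is projected so that, at every instant, the illuminated rows and the
  rolling-shutter detection band never overlap. Specular reflection is
  non-spreading (it stays on the illuminated rows), so disjoint apertures
  reject it exactly; only light that scattered laterally inside the tissue
  reaches the detection band.
* ``fluorescence`` — widefield excitation with spectrally separated emission;
  no specular term survives the emission filter.

Physics conventions: epi-illumination reflectance traverses the absorbing
stain twice, so the tissue return is ``rho · exp(-2·tau)`` (Beer–Lambert
double pass) with ``tau`` the single-pass optical depth and ``rho`` the
diffuse reflectance. Lateral subsurface scattering that carries light from
an illuminated line into the detection band is modelled by an isotropic 2-D
Gaussian kernel of configurable width. The polarizer is a single scalar
leakage ``epsilon`` multiplying the specular and stray-background terms.
Time is abstracted to the scan-step index; the real system's video rate
(seven frames per second) is metadata only.

Row coordinates are 0-based with half-open bands ``[start, end)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter1d

from .fiberbundle import CoreSignals, FiberBundle, render_bundle_image, \
    sample_through_bundle
from .phantom import Phantom

MODES = ("widefield_reflectance", "darkfield", "fluorescence")


@dataclass(frozen=True)
class IlluminationPattern:
    """Illuminated sensor-row bands (half-open) at a relative intensity."""

    bands: tuple[tuple[int, int], ...]
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")
        for s, e in self.bands:
            if e <= s:
                raise ValueError(f"empty or inverted band [{s}, {e})")


@dataclass(frozen=True)
class ScanStep:
    pattern: IlluminationPattern
    detection_band: tuple[int, int]


@dataclass
class ScanSequence:
    """Ordered (illumination pattern, detection band) pairs tiling the sensor."""

    steps: list[ScanStep]
    n_rows: int
    offset_rows: int

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def validate(self) -> None:
        """Audit the darkfield geometry invariants; raise on violation.

        Every sensor row must be covered by exactly one detection band over
        the sequence, and within each step every illuminated band must be
        disjoint from the detection band with a gap of at least
        ``offset_rows``.
        """
        coverage = np.zeros(self.n_rows, dtype=int)
        for step in self.steps:
            ds, de = step.detection_band
            if not (0 <= ds < de <= self.n_rows):
                raise ValueError(f"detection band [{ds},{de}) outside sensor")
            coverage[ds:de] += 1
            for (is_, ie) in step.pattern.bands:
                if not (0 <= is_ < ie <= self.n_rows):
                    raise ValueError(f"illumination band [{is_},{ie}) outside sensor")
                gap = max(ds - ie, is_ - de)
                if gap < self.offset_rows:
                    raise ValueError(
                        f"illumination [{is_},{ie}) within {self.offset_rows} rows "
                        f"of detection [{ds},{de})"
                    )
        if not np.all(coverage == 1):
            bad = np.flatnonzero(coverage != 1)
            raise ValueError(f"rows covered != 1 time: {bad[:10]}...")

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for k, step in enumerate(self.steps):
            b = list(step.pattern.bands) + [(-1, -1)] * (2 - len(step.pattern.bands))
            rows.append(dict(
                step=k, det_start=step.detection_band[0],
                det_end=step.detection_band[1],
                ill1_start=b[0][0], ill1_end=b[0][1],
                ill2_start=b[1][0], ill2_end=b[1][1],
            ))
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class AcquisitionConfig:
    """Everything that parameterises frame formation for one mode.

    ``specular_reflectance`` is the combined proximal+distal fiber-surface
    reflection, expressed on the same relative scale as the tissue return;
    ``specular_cv`` is the per-core variability of that reflection (each
    core's surfaces reflect slightly differently, producing the granular
    background characteristic of widefield reflectance through a bundle).
    ``polarization_leakage`` multiplies the specular and stray terms;
    ``residual_background`` is the post-polarizer stray level.
    """

    mode: str = "darkfield"
    specular_reflectance: float = 20.0
    specular_cv: float = 0.3
    polarization_leakage: float = 0.1
    residual_background: float = 0.05
    illumination_level: float = 1000.0
    double_pass: bool = True
    scatter_sigma_um: float = 30.0
    shot_noise: bool = True
    read_noise_sd: float = 3.0
    bit_depth: int = 12
    pixel_pitch_um: float = 1.0
    rng_seed: int | None = None
    frame_rate_hz: float = 7.0  # metadata only; time is the scan-step index

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.specular_reflectance < 0:
            raise ValueError("specular_reflectance must be >= 0")
        if not (0.0 <= self.polarization_leakage <= 1.0):
            raise ValueError("polarization_leakage must be in [0, 1]")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")

    def replace(self, **kw) -> "AcquisitionConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class RawFrame:
    """Acquired sensor frame (quantized counts) with provenance."""

    pixels: np.ndarray  # uint16, values in [0, 2^bit_depth - 1]
    mode: str
    config: AcquisitionConfig
    pixel_pitch_um: float
    fov_diameter_um: float
    background: np.ndarray | None = None  # optional paired background frame
    provenance: list = field(default_factory=list)

    @property
    def max_count(self) -> int:
        return 2**self.config.bit_depth - 1

    def as_float(self) -> np.ndarray:
        """Linear counts rescaled to [0, 1]."""
        return self.pixels.astype(np.float64) / self.max_count

    def save(self, path: str | Path) -> None:
        path = Path(path)
        tifffile.imwrite(path, self.pixels.astype(np.uint16))
        sidecar = dict(
            mode=self.mode,
            pixel_pitch_um=self.pixel_pitch_um,
            fov_diameter_um=self.fov_diameter_um,
            provenance=self.provenance,
            config={k: v for k, v in dataclasses.asdict(self.config).items()},
        )
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


# ---------------------------------------------------------------------------
# scan-sequence construction

def make_scan_sequence(
    n_rows: int,
    band_height_rows: int = 16,
    offset_rows: int = 4,
    line_width_rows: int = 8,
) -> ScanSequence:
    """Build the line-pair illumination / rolling-shutter detection sequence.

    Detection bands of ``band_height_rows`` tile the sensor top to bottom
    (the last band may be shorter). Each step illuminates two lines of
    ``line_width_rows`` flanking the detection band symmetrically at a gap of
    ``offset_rows``; a flank that would fall off the sensor is clipped, and
    dropped entirely at the sensor edges (single-line steps).
    """
    if offset_rows < 1 or line_width_rows < 1 or band_height_rows < 1:
        raise ValueError("band_height_rows, offset_rows, line_width_rows must be >= 1")
    if band_height_rows + 2 * (offset_rows + line_width_rows) > n_rows:
        raise ValueError(
            f"geometry infeasible: band {band_height_rows} + 2*offset {offset_rows} "
            f"+ 2*line {line_width_rows} exceeds {n_rows} sensor rows"
        )
    steps = []
    for ds in range(0, n_rows, band_height_rows):
        de = min(ds + band_height_rows, n_rows)
        bands = []
        up_e = ds - offset_rows
        up_s = up_e - line_width_rows
        if up_e > 0:
            bands.append((max(up_s, 0), up_e))
        lo_s = de + offset_rows
        lo_e = lo_s + line_width_rows
        if lo_s < n_rows:
            bands.append((lo_s, min(lo_e, n_rows)))
        steps.append(ScanStep(IlluminationPattern(tuple(bands)), (ds, de)))
    seq = ScanSequence(steps=steps, n_rows=n_rows, offset_rows=offset_rows)
    seq.validate()
    return seq


# ---------------------------------------------------------------------------
# tissue interaction

def tissue_return_field(phantom: Phantom, mode: str,
                        double_pass: bool = True) -> np.ndarray:
    """Tissue-side return field on the phantom grid, before core sampling.

    Reflectance modes: ``rho · exp(-k·tau)`` with k = 2 for epi double pass
    (k = 1 single pass), bounded in [0, 1]. Fluorescence: the emission-yield
    map itself.
    """
    if mode == "fluorescence":
        return np.maximum(phantom.fluorescence_map, 0.0)
    if mode in ("widefield_reflectance", "darkfield"):
        k = 2.0 if double_pass else 1.0
        return phantom.diffuse_reflectance_map * np.exp(-k * phantom.absorption_map)
    raise ValueError(f"unknown mode {mode!r}")


def tissue_return(phantom: Phantom, bundle: FiberBundle, mode: str,
                  double_pass: bool = True) -> CoreSignals:
    """Per-core tissue return for a uniformly illuminated phantom."""
    f = tissue_return_field(phantom, mode, double_pass)
    return sample_through_bundle(f, phantom.pixel_pitch_um, bundle, mode=mode)


# ---------------------------------------------------------------------------
# noise and quantization

def add_sensor_noise(frame: np.ndarray, config: AcquisitionConfig,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Apply shot noise (Poisson, pixel values in photoelectron units at unit
    gain) and additive Gaussian read noise. Returns an un-quantized float
    frame; quantization (with clipping) is a separate step."""
    frame = np.asarray(frame, dtype=np.float64)
    if np.any(frame < 0):
        raise ValueError("noise model requires non-negative pixel values")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    out = frame
    if config.shot_noise:
        out = rng.poisson(out).astype(np.float64)
    if config.read_noise_sd > 0:
        out = out + rng.normal(0.0, config.read_noise_sd, size=out.shape)
    return out


def quantize(frame: np.ndarray, bit_depth: int) -> np.ndarray:
    """Linear ADC: round half-up, clip to [0, 2^bit_depth - 1], uint16."""
    top = 2**bit_depth - 1
    return np.clip(np.floor(frame + 0.5), 0, top).astype(np.uint16)


# ---------------------------------------------------------------------------
# frame formation

def _specular_core_values(bundle: FiberBundle, config: AcquisitionConfig,
                          rng: np.random.Generator) -> np.ndarray:
    """Per-core specular reflectance: lognormal about the configured mean."""
    r = config.specular_reflectance
    if r == 0 or config.specular_cv == 0:
        return np.full(bundle.n_cores, r)
    s2 = np.log1p(config.specular_cv**2)
    return r * rng.lognormal(-s2 / 2.0, np.sqrt(s2), size=bundle.n_cores)


def _frame_rngs(config: AcquisitionConfig) -> tuple[np.random.Generator, np.random.Generator]:
    # independent substreams for the static specular pattern and the per-frame noise
    base = 0 if config.rng_seed is None else int(config.rng_seed)
    return (np.random.default_rng(np.random.SeedSequence([base, 1])),
            np.random.default_rng(np.random.SeedSequence([base, 2])))


def _finalize(lin: np.ndarray, mode: str, config: AcquisitionConfig,
              bundle: FiberBundle, rng_noise: np.random.Generator,
              provenance: list) -> RawFrame:
    noisy = add_sensor_noise(lin, config, rng_noise) if (
        config.shot_noise or config.read_noise_sd > 0) else lin
    return RawFrame(
        pixels=quantize(noisy, config.bit_depth),
        mode=mode, config=config,
        pixel_pitch_um=config.pixel_pitch_um,
        fov_diameter_um=bundle.fov_diameter_um,
        provenance=provenance,
    )


def acquire_widefield(phantom: Phantom, bundle: FiberBundle,
                      config: AcquisitionConfig) -> RawFrame:
    """Non-scanning frame: full-FOV illumination, full-frame integration.

    Linear pixel signal, rendered through the bundle honeycomb:
    ``L·[eps·R_spec (reflectance only) + tissue_return + eps·b0]``. The
    fluorescence emission filter removes the specular term spectrally.
    """
    if config.mode not in ("widefield_reflectance", "fluorescence"):
        raise ValueError("acquire_widefield handles widefield_reflectance or "
                         f"fluorescence, not {config.mode!r}")
    rng_spec, rng_noise = _frame_rngs(config)
    cores = tissue_return(phantom, bundle, config.mode, config.double_pass)
    eps = config.polarization_leakage
    core_signal = cores.values + eps * config.residual_background
    img = render_bundle_image(core_signal, bundle, config.pixel_pitch_um)
    if config.mode == "widefield_reflectance" and config.specular_reflectance > 0:
        spec_img = render_bundle_image(
            _specular_core_values(bundle, config, rng_spec), bundle,
            config.pixel_pitch_um)
        img = img + eps * spec_img
    lin = config.illumination_level * img
    return _finalize(lin, config.mode, config, bundle, rng_noise,
                     [("acquire_widefield", dict(mode=config.mode))])


def _illumination_profile(pattern: IlluminationPattern, n_rows: int,
                          sigma_rows: float) -> np.ndarray:
    """Row profile of illumination reaching the tissue after lateral
    subsurface scattering (1-D because line patterns are constant along x).
    ``sigma_rows = inf`` gives the uniform-spread limit."""
    p = np.zeros(n_rows)
    for s, e in pattern.bands:
        p[s:e] = pattern.intensity
    if not np.isfinite(sigma_rows):
        return np.full(n_rows, p.mean())
    if sigma_rows <= 0:
        return p
    return gaussian_filter1d(p, sigma_rows, mode="constant", cval=0.0)


def acquire_darkfield(phantom: Phantom, bundle: FiberBundle,
                      config: AcquisitionConfig, scan_sequence: ScanSequence,
                      validate: bool = True) -> RawFrame:
    """Scanning darkfield frame assembled band by band.

    For each step the illuminated line pair is spread by the scattering
    kernel into a row profile, normalized to unit mean over the detection
    band (exposure equalization), and multiplied into the tissue return; the
    detection-band rows of the bundle-rendered image are copied into the
    output. The specular term is strictly local to the illuminated rows, so
    it reaches the output only on illumination∩detection overlap — which a
    valid sequence precludes, making the rejection exact for any
    ``R_spec``.
    """
    if config.mode != "darkfield":
        raise ValueError(f"acquire_darkfield requires mode='darkfield', got {config.mode!r}")
    n_px = int(round(bundle.fov_diameter_um / config.pixel_pitch_um))
    if scan_sequence.n_rows != n_px:
        raise ValueError(
            f"scan sequence has {scan_sequence.n_rows} rows but the frame has {n_px}")
    if validate:
        scan_sequence.validate()

    rng_spec, rng_noise = _frame_rngs(config)
    eps = config.polarization_leakage
    f = tissue_return_field(phantom, config.mode, config.double_pass)
    n_ph = f.shape[0]
    sigma_rows = config.scatter_sigma_um / config.pixel_pitch_um

    # map sensor-row profile onto phantom-grid rows (shared um frame)
    sensor_extent = n_px * config.pixel_pitch_um
    y_ph = (np.arange(n_ph) + 0.5) * phantom.pixel_pitch_um - phantom.field_extent_um / 2
    r_sensor = (y_ph + sensor_extent / 2) / config.pixel_pitch_um - 0.5

    frame = np.zeros((n_px, n_px))
    spec_img = None
    if config.specular_reflectance > 0 and eps > 0:
        spec_img = render_bundle_image(
            _specular_core_values(bundle, config, rng_spec), bundle,
            config.pixel_pitch_um)
    for step in scan_sequence.steps:
        ds, de = step.detection_band
        e_sensor = _illumination_profile(step.pattern, n_px, sigma_rows)
        band_mean = e_sensor[ds:de].mean()
        if band_mean > 1e-12:
            e_sensor = e_sensor / band_mean
        e_ph = np.interp(r_sensor, np.arange(n_px), e_sensor)
        cores = sample_through_bundle(f, phantom.pixel_pitch_um, bundle,
                                      mode="darkfield", row_weights=e_ph)
        core_signal = cores.values + eps * config.residual_background
        img = render_bundle_image(core_signal, bundle, config.pixel_pitch_um)
        frame[ds:de, :] = img[ds:de, :]
        if spec_img is not None:
            # specular lands only on illuminated rows; collected only where
            # those rows fall inside this step's detection band
            for (is_, ie) in step.pattern.bands:
                lo, hi = max(is_, ds), min(ie, de)
                if lo < hi:
                    frame[lo:hi, :] += eps * step.pattern.intensity * spec_img[lo:hi, :]
    lin = config.illumination_level * frame
    return _finalize(lin, "darkfield", config, bundle, rng_noise,
                     [("acquire_darkfield", dict(n_steps=scan_sequence.n_steps))])


def acquire_background(bundle: FiberBundle, config: AcquisitionConfig,
                       scan_sequence: ScanSequence | None = None,
                       field_extent_um: float | None = None,
                       pixel_pitch_um: float = 1.0) -> RawFrame:
    """Acquire a no-tissue background frame (absorbing void: zero diffuse
    reflectance, no stain) for background subtraction."""
    from .phantom import render_phantom
    extent = field_extent_um or bundle.fov_diameter_um + 30 * pixel_pitch_um
    void = render_phantom([], extent, pixel_pitch_um,
                          nuclear_optical_depth=0.0, background_optical_depth=0.0,
                          nuclear_fluor_yield=0.0, background_fluor_yield=0.0,
                          diffuse_reflectance=0.0)
    if config.mode == "darkfield":
        if scan_sequence is None:
            raise ValueError("darkfield background needs the scan sequence")
        return acquire_darkfield(void, bundle, config, scan_sequence)
    return acquire_widefield(void, bundle, config)


def subtract_background(frame: RawFrame, background_frame: RawFrame) -> RawFrame:
    """Pixelwise subtraction of a paired background frame, clipped at 0."""
    if frame.pixels.shape != background_frame.pixels.shape:
        raise ValueError("frame and background shapes differ")
    if frame.mode != background_frame.mode:
        raise ValueError("frame and background modes differ")
    diff = np.clip(frame.pixels.astype(np.int64)
                   - background_frame.pixels.astype(np.int64), 0, None)
    return RawFrame(
        pixels=diff.astype(np.uint16), mode=frame.mode, config=frame.config,
        pixel_pitch_um=frame.pixel_pitch_um,
        fov_diameter_um=frame.fov_diameter_um,
        provenance=frame.provenance + [("subtract_background", {})],
    )


def acquire(phantom: Phantom, bundle: FiberBundle, config: AcquisitionConfig,
            scan_sequence: ScanSequence | None = None) -> RawFrame:
    """Dispatch to the mode-appropriate acquisition."""
    if config.mode == "darkfield":
        if scan_sequence is None:
            n_px = int(round(bundle.fov_diameter_um / config.pixel_pitch_um))
            scan_sequence = make_scan_sequence(n_px)
        return acquire_darkfield(phantom, bundle, config, scan_sequence)
    return acquire_widefield(phantom, bundle, config)
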