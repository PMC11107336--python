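"""Synthetic stained-epithelium phantoms with exact ground truth.

A phantom is a flat field of elliptical epithelial nuclei carrying two
co-registered contrast channels on a common micrometre grid:

* an **absorption** channel (single-pass optical depth) emulating a cationic
  absorbing nuclear stain such as methylene blue — nuclei appear *dark* in
  epi-reflectance;
* a **fluorescence** channel (relative emission yield) emulating a topical
  fluorescent nuclear stain such as proflavine — nuclei appear *bright*.

Healthy epithelium shows well-isolated, regularly spaced nuclei of roughly
uniform size and shape; this regularity is emulated with a hard-core
(minimum pairwise distance) point process realised by dart throwing.

Coordinate convention: continuous micrometre coordinates with the origin at
the field centre. Raster grids are 0-based row-major with the pixel centre of
element ``(i, j)`` at ``(-E/2 + (j + 0.5)·pitch, -E/2 + (i + 0.5)·pitch)``
for field extent ``E``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


@dataclass(frozen=True)
class NucleusRecord:
    """One elliptical nucleus of the generative ground truth.

    Attributes
    ----------
    center_x, center_y : float
        Centre in micrometres (origin at field centre).
    semi_major, semi_minor : float
        Ellipse semi-axes in micrometres, ``semi_major >= semi_minor > 0``.
    orientation : float
        Major-axis angle in radians, counter-clockwise from +x.
    stain_uptake : float
        Relative stain uptake in [0, 1]; 1 means nominal stain strength.
    """

    center_x: float
    center_y: float
    semi_major: float
    semi_minor: float
    orientation: float
    stain_uptake: float

    def __post_init__(self) -> None:
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError(
                f"require semi_major >= semi_minor > 0, got "
                f"({self.semi_major}, {self.semi_minor})"
            )
        if not (0.0 <= self.stain_uptake <= 1.0):
            raise ValueError(f"stain_uptake must be in [0, 1], got {self.stain_uptake}")


@dataclass
class Phantom:
    """Ground-truth nuclei plus co-registered scalar contrast maps.

    ``absorption_map`` holds single-pass optical depth (dimensionless,
    >= 0); the epi-illumination double pass is applied downstream by the
    acquisition model. ``fluorescence_map`` holds relative emission yield and
    ``diffuse_reflectance_map`` the unstained diffuse reflectance in [0, 1].
    All maps share one grid.
    """

    nuclei: list[NucleusRecord]
    absorption_map: np.ndarray
    fluorescence_map: np.ndarray
    diffuse_reflectance_map: np.ndarray
    pixel_pitch_um: float
    field_extent_um: float
    rng_seed: int | None = None
    params: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.absorption_map.shape

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) micrometre coordinates of pixel centres as 1-D arrays
        (x along columns, y along rows)."""
        n = self.shape[0]
        c = (np.arange(n) + 0.5) * self.pixel_pitch_um - self.field_extent_um / 2.0
        return c, c

    def save(self, outdir: str | Path, stem: str = "phantom") -> None:
        """Write ground truth CSV, 32-bit float TIFF maps, and a JSON sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = [
            dict(
                x_um=n.center_x, y_um=n.center_y, a_um=n.semi_major,
                b_um=n.semi_minor, theta_rad=n.orientation, uptake=n.stain_uptake,
            )
            for n in self.nuclei
        ]
        pd.DataFrame(
            rows, columns=["x_um", "y_um", "a_um", "b_um", "theta_rad", "uptake"]
        ).to_csv(outdir / f"{stem}_truth.csv", index=False)
        for name, arr in (
            ("absorption", self.absorption_map),
            ("fluorescence", self.fluorescence_map),
            ("reflectance", self.diffuse_reflectance_map),
        ):
            tifffile.imwrite(outdir / f"{stem}_{name}.tif", arr.astype(np.float32))
        sidecar = dict(
            pixel_pitch_um=self.pixel_pitch_um,
            field_extent_um=self.field_extent_um,
            rng_seed=self.rng_seed,
            n_nuclei=len(self.nuclei),
            params=self.params,
        )
        (outdir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))


def generate_nuclei_field(
    field_extent_um: float,
    density_per_mm2: float = 800.0,
    mean_radius_um: float = 4.0,
    radius_cv: float = 0.1,
    eccentricity_max: float = 0.3,
    min_spacing_um: float = 18.0,
    seed: int | None = None,
    stain_uptake_range: tuple[float, float] = (0.8, 1.0),
    max_attempts_per_nucleus: int = 200,
) -> list[NucleusRecord]:
    """Draw a hard-core point field of elliptical nuclei.

    The target count is Poisson with mean ``density_per_mm2 × field area``;
    centres are then placed by dart throwing, rejecting any candidate closer
    than ``min_spacing_um`` to an accepted centre (Matérn-style hard-core
    thinning). With ``min_spacing_um = 0`` the result is an exact homogeneous
    Poisson process.

    Semi-minor axes are drawn from a normal distribution with mean
    ``mean_radius_um`` and coefficient of variation ``radius_cv`` (truncated
    at > 0.1·mean); aspect ratio is uniform in ``[1, 1/(1 - eccentricity_max)]``
    so that eccentricity-like elongation stays bounded. Orientation is uniform.

    Raises
    ------
    RuntimeError
        If dart throwing cannot place the requested count (density infeasible
        under the hard core); the message names achieved vs requested counts.
    """
    if density_per_mm2 < 0:
        raise ValueError("density_per_mm2 must be >= 0")
    if min_spacing_um < 0:
        raise ValueError("min_spacing_um must be >= 0")
    if mean_radius_um <= 0:
        raise ValueError("mean_radius_um must be > 0")

    rng = np.random.default_rng(seed)
    area_mm2 = (field_extent_um / 1000.0) ** 2
    n_target = int(rng.poisson(density_per_mm2 * area_mm2))
    if n_target == 0:
        return []

    half = field_extent_um / 2.0
    centers: list[tuple[float, float]] = []
    accepted = np.empty((0, 2))
    attempts_budget = n_target * max_attempts_per_nucleus
    attempts = 0
    while len(centers) < n_target and attempts < attempts_budget:
        attempts += 1
        cand = rng.uniform(-half, half, size=2)
        if min_spacing_um > 0 and len(centers):
            d2 = np.sum((accepted - cand) ** 2, axis=1)
            if d2.min() < min_spacing_um**2:
                continue
        centers.append((float(cand[0]), float(cand[1])))
        accepted = np.asarray(centers)
    if len(centers) < n_target:
        raise RuntimeError(
            f"hard-core placement saturated: placed {len(centers)} of "
            f"{n_target} requested nuclei (density {density_per_mm2}/mm^2, "
            f"min_spacing {min_spacing_um} um)"
        )

    sd = radius_cv * mean_radius_um
    lo = 0.1 * mean_radius_um
    nuclei = []
    for cx, cy in centers:
        b = float(rng.normal(mean_radius_um, sd))
        while b <= lo:  # truncate the radius distribution away from zero
            b = float(rng.normal(mean_radius_um, sd))
        aspect_max = 1.0 / (1.0 - eccentricity_max) if eccentricity_max < 1 else 3.0
        a = b * float(rng.uniform(1.0, aspect_max))
        theta = float(rng.uniform(0.0, np.pi))
        uptake = float(rng.uniform(*stain_uptake_range))
        nuclei.append(NucleusRecord(cx, cy, a, b, theta, uptake))
    return nuclei


def _ellipse_indicator(
    nuclei: list[NucleusRecord],
    n_px: int,
    pitch: float,
    extent: float,
    supersample: int = 4,
) -> np.ndarray:
    """Anti-aliased coverage map in [0,1] weighted by per-nucleus stain uptake.

    Each nucleus is rasterised on a ``supersample×`` finer grid inside its
    bounding box and box-averaged down, so edge pixels carry fractional
    coverage.
    """
    out = np.zeros((n_px, n_px), dtype=np.float64)
    s = supersample
    sub_pitch = pitch / s
    for nuc in nuclei:
        r = nuc.semi_major
        # bounding box in pixel indices (clipped)
        x0 = nuc.center_x + extent / 2.0
        y0 = nuc.center_y + extent / 2.0
        j_lo = max(int(np.floor((x0 - r) / pitch)) - 1, 0)
        j_hi = min(int(np.ceil((x0 + r) / pitch)) + 1, n_px)
        i_lo = max(int(np.floor((y0 - r) / pitch)) - 1, 0)
        i_hi = min(int(np.ceil((y0 + r) / pitch)) + 1, n_px)
        if j_lo >= j_hi or i_lo >= i_hi:
            continue
        xs = (np.arange(j_lo * s, j_hi * s) + 0.5) * sub_pitch - extent / 2.0
        ys = (np.arange(i_lo * s, i_hi * s) + 0.5) * sub_pitch - extent / 2.0
        dx = xs[None, :] - nuc.center_x
        dy = ys[:, None] - nuc.center_y
        ct, st = np.cos(nuc.orientation), np.sin(nuc.orientation)
        u = (dx * ct + dy * st) / nuc.semi_major
        v = (-dx * st + dy * ct) / nuc.semi_minor
        inside = (u * u + v * v) <= 1.0
        cov = inside.reshape(i_hi - i_lo, s, j_hi - j_lo, s).mean(axis=(1, 3))
        out[i_lo:i_hi, j_lo:j_hi] += nuc.stain_uptake * cov
    return np.clip(out, 0.0, 1.0)


def render_phantom(
    nuclei: list[NucleusRecord],
    field_extent_um: float,
    pixel_pitch_um: float = 1.0,
    nuclear_optical_depth: float = 0.8,
    background_optical_depth: float = 0.05,
    nuclear_fluor_yield: float = 1.0,
    background_fluor_yield: float = 0.02,
    diffuse_reflectance: float = 0.6,
    rng_seed: int | None = None,
    supersample: int = 4,
) -> Phantom:
    """Rasterise nuclei into co-registered absorption / fluorescence /
    reflectance maps.

    Inside each ellipse the absorption map is
    ``background + uptake · (nuclear − background)`` (anti-aliased at edges by
    4× supersampling); the fluorescence map is analogous with the fluorescence
    yields, on the identical ellipse support. The diffuse reflectance map is
    uniform by default (the unstained tissue matrix).
    """
    if pixel_pitch_um <= 0:
        raise ValueError("pixel_pitch_um must be > 0")
    if not (nuclear_optical_depth >= background_optical_depth >= 0):
        raise ValueError("require nuclear_optical_depth >= background_optical_depth >= 0")
    n_px = int(round(field_extent_um / pixel_pitch_um))
    if n_px <= 0:
        raise ValueError("field extent / pixel pitch gives a non-positive grid")

    cov = _ellipse_indicator(nuclei, n_px, pixel_pitch_um, field_extent_um,
                             supersample=supersample)
    absorption = background_optical_depth + cov * (
        nuclear_optical_depth - background_optical_depth
    )
    fluorescence = background_fluor_yield + cov * (
        nuclear_fluor_yield - background_fluor_yield
    )
    reflectance = np.full((n_px, n_px), float(diffuse_reflectance))
    return Phantom(
        nuclei=list(nuclei),
        absorption_map=absorption,
        fluorescence_map=fluorescence,
        diffuse_reflectance_map=reflectance,
        pixel_pitch_um=pixel_pitch_um,
        field_extent_um=field_extent_um,
        rng_seed=rng_seed,
        params=dict(
            nuclear_optical_depth=nuclear_optical_depth,
            background_optical_depth=background_optical_depth,
            nuclear_fluor_yield=nuclear_fluor_yield,
            background_fluor_yield=background_fluor_yield,
            diffuse_reflectance=diffuse_reflectance,
            # stain concentrations the phantom channels emulate, as metadata
            stain_metadata={
                "absorption_stain": "methylene blue 0.3% w/v in deionized water",
                "fluorescence_stain": "proflavine 0.01% w/v in PBS",
                "band_nm": 605,
            },
        ),
    )


def default_phantom(
    seed: int | None = 0,
    field_extent_um: float = 820.0,
    pixel_pitch_um: float = 1.0,
    **overrides,
) -> Phantom:
    """The package's standard epithelium phantom: ~800 nuclei/mm^2 of mean
    radius 4 um with an 18 um hard core, sized to cover a 790 um circular
    field of view with margin."""
    gen_keys = {
        "density_per_mm2", "mean_radius_um", "radius_cv", "eccentricity_max",
        "min_spacing_um", "stain_uptake_range",
    }
    gen_kw = {k: v for k, v in overrides.items() if k in gen_keys}
    ren_kw = {k: v for k, v in overrides.items() if k not in gen_keys}
    nuclei = generate_nuclei_field(field_extent_um, seed=seed, **gen_kw)
    return render_phantom(
        nuclei, field_extent_um, pixel_pitch_um, rng_seed=seed, **ren_kw
    )
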