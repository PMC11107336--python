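"""Nuclei detection, ROI counting, and cross-mode image-quality metrics.

Nuclei are detected with multiscale scale-normalized Laplacian-of-Gaussian
(LoG) blob detection. One detector serves both polarities: reflectance
nuclei are dark dots (the image is inverted first), fluorescence nuclei are
bright. Detections are scored by the LoG response and pruned by greedy
non-maximum suppression at one radius.

Counting statistics follow the mean ± sample standard deviation over a grid
of congruent, disjoint regions of interest (default 25, in a 5×5 grid)
placed inside the circular field of view. Image quality is summarised by
Weber contrast ``|mean_bg − mean_fg| / mean_bg`` and a background-noise
referred SNR ``|mean_bg − mean_fg| / sd_bg``; both are computed on
honeycomb-removed linear images so that the offset sensitivity of Weber
contrast (the reason specular background degrades visibility) is preserved.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .acquisition import AcquisitionConfig, RawFrame, ScanSequence, acquire, \
    make_scan_sequence
from .fiberbundle import FiberBundle
from .phantom import Phantom, _ellipse_indicator
from .restore import ProcessParams, ProcessedImage, fov_mask, process_pipeline, \
    remove_honeycomb, normalize_brightness


@dataclass(frozen=True)
class Detection:
    """One detected nucleus candidate in micrometre coordinates."""

    x_um: float
    y_um: float
    equivalent_radius_um: float
    score: float
    polarity: str  # "dark" | "bright"


@dataclass
class DetectParams:
    polarity: str = "dark"
    min_radius_um: float = 3.0
    max_radius_um: float = 8.0
    response_threshold: float = 0.22
    scale_step: float = 1.25


@dataclass
class RoiGrid:
    """Congruent, pairwise-disjoint ROI rectangles inside the FOV.

    Rectangles are half-open ``[x0, x1) × [y0, y1)`` in micrometres.
    """

    rois: list[tuple[float, float, float, float]]
    roi_size_um: float

    @property
    def n_rois(self) -> int:
        return len(self.rois)

    @property
    def roi_area_um2(self) -> float:
        return self.roi_size_um**2


# ---------------------------------------------------------------------------
# detection

def detect_nuclei(
    image: ProcessedImage | np.ndarray,
    polarity: str = "dark",
    min_radius_um: float = 3.0,
    max_radius_um: float = 8.0,
    response_threshold: float = 0.22,
    pixel_pitch_um: float | None = None,
    fov_diameter_um: float | None = None,
    scale_step: float = 1.25,
) -> list[Detection]:
    """Multiscale LoG blob detection on a processed, FOV-masked image.

    The image is inverted for dark polarity so a single bright-blob detector
    serves both stains. Scales are geometric with ratio ``scale_step`` over
    ``sigma = radius/sqrt(2)``; candidates are 26-connected local maxima of
    the scale-normalized response above ``response_threshold``, then pruned
    by greedy one-radius non-maximum suppression in score order.
    """
    if isinstance(image, ProcessedImage):
        pitch = image.pixel_pitch_um
        fov = image.fov_diameter_um
        data = image.data
    else:
        pitch = pixel_pitch_um if pixel_pitch_um is not None else 1.0
        fov = fov_diameter_um
        data = np.asarray(image, dtype=np.float64)
    if polarity not in ("dark", "bright"):
        raise ValueError("polarity must be 'dark' or 'bright'")
    if not (0 < min_radius_um < max_radius_um):
        raise ValueError("need 0 < min_radius_um < max_radius_um")

    sig_lo = min_radius_um / np.sqrt(2.0) / pitch
    sig_hi = max_radius_um / np.sqrt(2.0) / pitch
    n_scales = int(np.floor(np.log(sig_hi / sig_lo) / np.log(scale_step))) + 1
    if n_scales < 2:
        raise ValueError("radius band narrower than one scale step")
    sigmas = sig_lo * scale_step ** np.arange(n_scales)

    mask = fov_mask(data.shape, pitch, fov)
    work = data.astype(np.float64)
    if polarity == "dark":
        work = -work
    # zero-mean inside the FOV (offset invariance) and keep the surround
    # neutral so the rim does not fire
    fill = work[mask].mean() if mask.any() else 0.0
    work = np.where(mask, work - fill, 0.0)

    stack = np.empty((n_scales,) + data.shape)
    for i, s in enumerate(sigmas):
        stack[i] = -(s**2) * ndimage.gaussian_laplace(work, s)
    # local maxima over scale-space (3x3x3 neighbourhood)
    maxed = ndimage.maximum_filter(stack, size=3, mode="nearest")
    peaks = (stack == maxed) & (stack > response_threshold)
    peaks &= mask[None, :, :]
    si, ii, jj = np.nonzero(peaks)
    if len(si) == 0:
        return []
    scores = stack[si, ii, jj]
    order = np.argsort(scores)[::-1]
    si, ii, jj, scores = si[order], ii[order], jj[order], scores[order]

    n = data.shape[0]
    extent = n * pitch
    xs = (jj + 0.5) * pitch - extent / 2.0
    ys = (ii + 0.5) * pitch - extent / 2.0
    radii = sigmas[si] * np.sqrt(2.0) * pitch

    kept: list[int] = []
    kept_xy = np.empty((0, 2))
    for idx in range(len(scores)):
        p = np.array([xs[idx], ys[idx]])
        if len(kept):
            d = np.hypot(kept_xy[:, 0] - p[0], kept_xy[:, 1] - p[1])
            if np.any(d < np.maximum(radii[kept], radii[idx])):
                continue
        kept.append(idx)
        kept_xy = np.vstack([kept_xy, p])
    return [
        Detection(float(xs[i]), float(ys[i]), float(radii[i]), float(scores[i]),
                  polarity)
        for i in kept
    ]


def match_detections(
    detections: list[Detection],
    nuclei,
    tolerance_um: float,
) -> dict:
    """Greedy one-to-one nearest-neighbour matching against ground truth.

    Detections are visited in score order (ties already broken by score);
    each claims its nearest unclaimed truth nucleus within ``tolerance_um``.
    Returns precision, recall, and the index pairs.
    """
    truth = np.array([[n.center_x, n.center_y] for n in nuclei]) \
        if len(nuclei) else np.empty((0, 2))
    dets = sorted(detections, key=lambda d: -d.score)
    matched_truth: set[int] = set()
    pairs = []
    if len(truth):
        tree = cKDTree(truth)
        k = min(len(truth), 8)
        for di, d in enumerate(dets):
            dist, idx = tree.query([d.x_um, d.y_um], k=k)
            dist, idx = np.atleast_1d(dist), np.atleast_1d(idx)
            for dd, ti in zip(dist, idx):
                if dd > tolerance_um:
                    break
                if ti not in matched_truth:
                    matched_truth.add(int(ti))
                    pairs.append((di, int(ti)))
                    break
    tp = len(pairs)
    precision = tp / len(dets) if dets else (1.0 if not len(truth) else 0.0)
    recall = tp / len(truth) if len(truth) else 1.0
    det_matched = np.zeros(len(dets), bool)
    truth_matched = np.zeros(len(truth), bool)
    for di, ti in pairs:
        det_matched[di] = True
        truth_matched[ti] = True
    return dict(precision=precision, recall=recall, n_matched=tp,
                n_detections=len(dets), n_truth=int(len(truth)), pairs=pairs,
                det_order=dets, det_matched=det_matched,
                truth_matched=truth_matched)


def region_precision_recall(detections: list[Detection], nuclei,
                            tolerance_um: float, r_eval_um: float) -> dict:
    """Precision/recall scored inside an evaluation region.

    Matching runs against *all* nuclei so a rim detection of a real nucleus
    is never a false positive, but both precision (over detections) and
    recall (over truth) are evaluated only for centres within ``r_eval_um``
    of the FOV axis — the region the instrument fully sees.
    """
    m = match_detections(detections, nuclei, tolerance_um)
    dr = np.array([np.hypot(d.x_um, d.y_um) for d in m["det_order"]]) \
        if detections else np.empty(0)
    tr = np.array([np.hypot(n.center_x, n.center_y) for n in nuclei]) \
        if len(nuclei) else np.empty(0)
    d_in = dr < r_eval_um
    t_in = tr < r_eval_um
    precision = (m["det_matched"] & d_in).sum() / d_in.sum() if d_in.any() else 1.0
    recall = (m["truth_matched"] & t_in).sum() / t_in.sum() if t_in.any() else 1.0
    return dict(precision=float(precision), recall=float(recall),
                n_detections=int(d_in.sum()), n_truth=int(t_in.sum()))


# ---------------------------------------------------------------------------
# ROI counting

def make_roi_grid(fov_diameter_um: float = 790.0, n_rois: int = 25,
                  roi_size_um: float = 100.0) -> RoiGrid:
    """Deterministic centred tiling of ``n_rois`` congruent square ROIs.

    The grid is the most-square factorisation of ``n_rois`` (5×5 for 25) and
    must fit inside the inscribed square of the circular FOV.
    """
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    best = None
    for r in range(1, int(np.sqrt(n_rois)) + 1):
        if n_rois % r == 0:
            best = (r, n_rois // r)
    rows, cols = best
    inscribed = fov_diameter_um / np.sqrt(2.0)
    if cols * roi_size_um > inscribed + 1e-9 or rows * roi_size_um > inscribed + 1e-9:
        raise ValueError(
            f"{rows}x{cols} grid of {roi_size_um} um ROIs does not fit the "
            f"{inscribed:.1f} um inscribed square of a {fov_diameter_um} um FOV"
        )
    w, h = cols * roi_size_um, rows * roi_size_um
    rois = []
    for i in range(rows):
        for j in range(cols):
            x0 = -w / 2 + j * roi_size_um
            y0 = -h / 2 + i * roi_size_um
            rois.append((x0, y0, x0 + roi_size_um, y0 + roi_size_um))
    return RoiGrid(rois=rois, roi_size_um=roi_size_um)


def count_in_rois(detections: list[Detection], roi_grid: RoiGrid) -> dict:
    """Per-ROI counts with mean ± sample (n−1) standard deviation.

    A detection belongs to an ROI iff its centre lies inside the half-open
    rectangle (left/top edges in, right/bottom out), so shared boundaries
    count a detection exactly once.
    """
    if roi_grid.n_rois == 0:
        raise ValueError("empty ROI grid")
    counts = np.zeros(roi_grid.n_rois, dtype=int)
    for d in detections:
        for k, (x0, y0, x1, y1) in enumerate(roi_grid.rois):
            if x0 <= d.x_um < x1 and y0 <= d.y_um < y1:
                counts[k] += 1
                break
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1)) if roi_grid.n_rois > 1 else 0.0
    return dict(counts=counts, mean=mean, sd=sd)


# ---------------------------------------------------------------------------
# contrast metrics

def contrast_metrics(image: np.ndarray, fg_mask: np.ndarray,
                     bg_mask: np.ndarray) -> dict:
    """Weber contrast and background-referred SNR between truth masks.

    ``C = |mean_bg − mean_fg| / mean_bg``; ``SNR = |mean_bg − mean_fg| / sd_bg``.
    Weber contrast is offset-sensitive: adding a constant background (e.g.
    specular reflection) strictly decreases it.
    """
    fg_mask = np.asarray(fg_mask, bool)
    bg_mask = np.asarray(bg_mask, bool)
    if not fg_mask.any() or not bg_mask.any():
        raise ValueError("foreground and background masks must be nonempty")
    if (fg_mask & bg_mask).any():
        raise ValueError("foreground and background masks must be disjoint")
    mean_fg = float(image[fg_mask].mean())
    mean_bg = float(image[bg_mask].mean())
    if mean_bg == 0:
        raise ValueError("background mean is zero; Weber contrast undefined")
    sd_bg = float(image[bg_mask].std())
    diff = abs(mean_bg - mean_fg)
    return dict(weber_contrast=diff / mean_bg,
                snr=diff / sd_bg if sd_bg > 0 else np.inf,
                mean_fg=mean_fg, mean_bg=mean_bg, sd_bg=sd_bg)


def truth_masks(phantom: Phantom, frame_shape: tuple[int, int],
                pixel_pitch_um: float, fov_diameter_um: float,
                margin_um: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
    """Foreground (nucleus interior) and background masks on the frame grid.

    The phantom grid is centre-cropped to the frame grid (both share the
    origin and pixel pitch). Foreground = ellipse coverage > 0.5; background
    = in-FOV pixels farther than ``margin_um`` from any nucleus support.
    """
    if abs(phantom.pixel_pitch_um - pixel_pitch_um) > 1e-9:
        raise ValueError("phantom and frame pixel pitch must match")
    n_ph = phantom.shape[0]
    cov = _ellipse_indicator(phantom.nuclei, n_ph, phantom.pixel_pitch_um,
                             phantom.field_extent_um)
    n_fr = frame_shape[0]
    off = (n_ph - n_fr) // 2
    if off < 0:
        raise ValueError("frame grid larger than phantom grid")
    cov = cov[off:off + n_fr, off:off + n_fr]
    fg = cov > 0.5
    it = max(int(round(margin_um / pixel_pitch_um)), 1)
    near = ndimage.binary_dilation(cov > 0.01, iterations=it)
    mask = fov_mask(frame_shape, pixel_pitch_um, fov_diameter_um)
    bg = mask & ~near
    fg &= mask
    return fg, bg


# ---------------------------------------------------------------------------
# cross-mode comparison

@dataclass
class ModeResult:
    mode: str
    detections: list[Detection]
    roi_counts: np.ndarray
    count_mean: float
    count_sd: float
    weber_contrast: float
    snr: float
    precision: float | None = None
    recall: float | None = None


@dataclass
class AnalysisReport:
    """Per-mode detections, ROI count statistics, image-quality metrics, and
    the darkfield-vs-fluorescence count agreement."""

    per_mode: dict
    count_agreement_rel_diff: float | None
    n_rois: int
    roi_size_um: float

    def to_dict(self) -> dict:
        out = dict(n_rois=self.n_rois, roi_size_um=self.roi_size_um,
                   count_agreement_rel_diff=self.count_agreement_rel_diff,
                   modes={})
        for mode, r in self.per_mode.items():
            out["modes"][mode] = dict(
                n_detections=len(r.detections),
                roi_counts=[int(c) for c in r.roi_counts],
                count_mean=r.count_mean, count_sd=r.count_sd,
                weber_contrast=r.weber_contrast, snr=r.snr,
                precision=r.precision, recall=r.recall,
            )
        return out

    def save(self, outdir: str | Path, stem: str = "report") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / f"{stem}.json").write_text(json.dumps(self.to_dict(), indent=2))
        rows = []
        for mode, r in self.per_mode.items():
            for d in r.detections:
                rows.append(dict(mode=mode, x_um=d.x_um, y_um=d.y_um,
                                 radius_um=d.equivalent_radius_um,
                                 score=d.score, polarity=d.polarity))
        pd.DataFrame(rows).to_csv(outdir / f"{stem}_detections.csv", index=False)


def analyze_mode(
    frame: RawFrame,
    phantom: Phantom,
    process_params: ProcessParams,
    detect_params: DetectParams | None = None,
    roi_grid: RoiGrid | None = None,
    core_pitch_um: float | None = None,
    match_tolerance_um: float = 4.0,
) -> ModeResult:
    """Process one frame, detect nuclei, count in ROIs, compute metrics."""
    if detect_params is None:
        detect_params = DetectParams()
    polarity = "bright" if frame.mode == "fluorescence" else "dark"
    processed = process_pipeline(frame, process_params)
    dets = detect_nuclei(
        processed, polarity=polarity,
        min_radius_um=detect_params.min_radius_um,
        max_radius_um=detect_params.max_radius_um,
        response_threshold=detect_params.response_threshold,
        scale_step=detect_params.scale_step,
    )
    if roi_grid is None:
        roi_grid = make_roi_grid(frame.fov_diameter_um)
    cc = count_in_rois(dets, roi_grid)
    # contrast on the honeycomb-removed linear image (Weber contrast is
    # offset- but not scale-sensitive; CLAHE would erase the offset effect)
    mask = fov_mask(frame.pixels.shape, frame.pixel_pitch_um, frame.fov_diameter_um)
    lin = remove_honeycomb(frame.as_float(), process_params.sigma_um,
                           frame.pixel_pitch_um, mask)
    fg, bg = truth_masks(phantom, frame.pixels.shape, frame.pixel_pitch_um,
                         frame.fov_diameter_um)
    cm = contrast_metrics(lin, fg, bg)
    # evaluation region: the FOV interior clear of the rim by 2 tolerances,
    # where visibility is unambiguous
    r_eval = frame.fov_diameter_um / 2.0 - 2 * match_tolerance_um
    m = region_precision_recall(dets, phantom.nuclei, match_tolerance_um, r_eval)
    return ModeResult(
        mode=frame.mode, detections=dets, roi_counts=cc["counts"],
        count_mean=cc["mean"], count_sd=cc["sd"],
        weber_contrast=cm["weber_contrast"], snr=cm["snr"],
        precision=m["precision"], recall=m["recall"],
    )


def compare_modes(
    phantom: Phantom,
    bundle: FiberBundle,
    acq_configs: dict[str, AcquisitionConfig] | None = None,
    process_params: ProcessParams | None = None,
    detect_params: DetectParams | None = None,
    scan_sequence: ScanSequence | None = None,
    n_rois: int = 25,
    roi_size_um: float = 100.0,
    seed: int | None = None,
) -> AnalysisReport:
    """Image one phantom in all three modes and compare them.

    All modes share the phantom, bundle, restoration parameters and detector;
    only the acquisition physics differs. The report includes the relative
    difference of ROI-count means between darkfield and fluorescence — the
    cross-stain count-agreement statistic.
    """
    if acq_configs is None:
        acq_configs = default_mode_configs(seed=seed)
    if process_params is None:
        process_params = ProcessParams(sigma_um=bundle.core_pitch_um / 2.0)
    pitch = next(iter(acq_configs.values())).pixel_pitch_um
    n_px = int(round(bundle.fov_diameter_um / pitch))
    if scan_sequence is None:
        scan_sequence = make_scan_sequence(n_px)
    roi_grid = make_roi_grid(bundle.fov_diameter_um, n_rois, roi_size_um)
    per_mode = {}
    for mode, cfg in acq_configs.items():
        frame = acquire(phantom, bundle, cfg, scan_sequence)
        per_mode[mode] = analyze_mode(frame, phantom, process_params,
                                      detect_params, roi_grid)
    agreement = None
    if "darkfield" in per_mode and "fluorescence" in per_mode:
        mf = per_mode["fluorescence"].count_mean
        md = per_mode["darkfield"].count_mean
        agreement = abs(md - mf) / mf if mf > 0 else None
    return AnalysisReport(per_mode=per_mode,
                          count_agreement_rel_diff=agreement,
                          n_rois=n_rois, roi_size_um=roi_size_um)


def default_mode_configs(seed: int | None = None, **overrides) -> dict:
    """One AcquisitionConfig per mode at the package defaults, sharing a seed."""
    cfgs = {}
    for mode in ("widefield_reflectance", "darkfield", "fluorescence"):
        cfgs[mode] = AcquisitionConfig(mode=mode, rng_seed=seed, **overrides)
    return cfgs
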