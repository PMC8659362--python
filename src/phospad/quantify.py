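"""Photograph to per-zone intensities and the ARI statistic.

The quantifier registers the known device layout against the circular wax
edges detected in the image (rigid fit, so blank/detection roles are
inherited from the layout and never guessed from colour), samples the inner
70% of each zone, and computes the normalised statistic

    ARI = (AI_reaction - AI_blank) / AI_ref,

where AI is the inverted Rec.601 grayscale mean over a zone's mask
(255 - gray, so deeper blue development gives a larger value) and AI_ref is
the reference-square intensity measured relative to the plain laminate
beside it.  Background-referencing the internal standard makes every ARI
value exactly invariant under multiplicative illumination gain and additive
offset, which is the whole point of printing a reference patch on the card;
an additive water tint that darkens reaction and blank zones alike cancels
exactly in the numerator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import canny
from skimage.transform import estimate_transform, hough_circle, hough_circle_peaks

from .errors import AlignmentError, DetectionError
from .layout import DEFAULT_SAMPLING_FRACTION, DeviceLayout, disk_pixels

_GRAY_W = np.array([0.299, 0.587, 0.114])


def grayscale(image: np.ndarray) -> np.ndarray:
    """Rec.601 luma of an RGB image (float64); pass-through for 2-D input."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] == 3:
        return img @ _GRAY_W
    raise ValueError(f"expected (H, W) or (H, W, 3) image, got shape {img.shape}")


def mean_intensity(image: np.ndarray, mask: np.ndarray) -> float:
    """AI of a region: mean over the mask of (255 - grayscale).

    ``mask`` is an (N, 2) integer array of (ix, iy) pixel indices.  The value
    is kept as a real number (no rounding).
    """
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("mask is empty")
    if mask.ndim != 2 or mask.shape[1] != 2:
        raise ValueError("mask must be an (N, 2) array of (x, y) pixel indices")
    h, w = np.asarray(image).shape[:2]
    if (
        mask[:, 0].min() < 0
        or mask[:, 0].max() >= w
        or mask[:, 1].min() < 0
        or mask[:, 1].max() >= h
    ):
        raise ValueError("mask extends outside the image bounds")
    gray = grayscale(image)
    return float(np.mean(255.0 - gray[mask[:, 1], mask[:, 0]]))


def compute_ari(ai_reaction: float, ai_blank: float, ai_ref: float) -> float:
    """Average relative intensity of one reaction zone.

    May be negative: on noisy input a blank can read darker than a reaction
    zone.  ``ai_ref`` must be positive (reference square found and not
    saturated white).
    """
    if ai_ref <= 0:
        raise ValueError(
            f"reference intensity must be positive, got {ai_ref} "
            "(reference square not found or saturated)"
        )
    return (ai_reaction - ai_blank) / ai_ref


@dataclass(frozen=True)
class ZoneReading:
    zone_id: int
    role: str
    centre_px: tuple[float, float]
    ai: float
    n_pixels: int
    saturated: bool = False


@dataclass(frozen=True)
class ZoneFit:
    """Result of registering the layout to an image."""

    centres_px: dict[int, tuple[float, float]]
    ref_centre_px: tuple[float, float]
    bg_centre_px: tuple[float, float]
    scale_px_per_mm: float
    rotation_deg: float
    residual_px: float


@dataclass(frozen=True)
class DeviceReading:
    """Quantified device: per-zone AIs, the six ARI values and their summary."""

    device_code: str
    zone_readings: tuple[ZoneReading, ...]
    ai_ref: float
    ai_background: float
    ari_per_zone: dict[int, float]
    ari_mean: float
    ari_sd: float
    capture_source: str = "synthetic"
    flags: tuple[str, ...] = ()
    fit: ZoneFit | None = None

    def to_dict(self) -> dict:
        return {
            "device_code": self.device_code,
            "capture_source": self.capture_source,
            "ai_ref": self.ai_ref,
            "ai_background": self.ai_background,
            "ari_per_zone": {str(k): v for k, v in self.ari_per_zone.items()},
            "ari_mean": self.ari_mean,
            "ari_sd": self.ari_sd,
            "flags": list(self.flags),
            "zones": [
                {
                    "zone_id": z.zone_id,
                    "role": z.role,
                    "centre_px": list(z.centre_px),
                    "ai": z.ai,
                    "n_pixels": z.n_pixels,
                    "saturated": z.saturated,
                }
                for z in self.zone_readings
            ],
        }


def save_reading(reading: DeviceReading, path) -> None:
    with open(path, "w") as fh:
        json.dump(reading.to_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# zone location


def _refine_ring_centre(
    gray: np.ndarray, cx: float, cy: float, r_px: float, iterations: int = 5
) -> tuple[float, float]:
    """Sub-pixel circle centre via the darkness centroid of the wax ring.

    Iterates a weighted centroid over an annulus window just outside the
    zone radius; the printed ring is dark against the bright laminate, so
    the centroid converges to the true centre.  Illumination-robust: the
    weight threshold is taken from the annulus itself.
    """
    shape = gray.shape
    for _ in range(iterations):
        outer = disk_pixels(cx, cy, 1.45 * r_px, shape=shape)
        d2 = (outer[:, 0] + 0.5 - cx) ** 2 + (outer[:, 1] + 0.5 - cy) ** 2
        ring = outer[d2 >= (0.95 * r_px) ** 2]
        if len(ring) == 0:
            break
        vals = gray[ring[:, 1], ring[:, 0]]
        thr = 0.5 * (vals.min() + vals.max())
        w = np.clip(thr - vals, 0.0, None)
        total = w.sum()
        if total <= 0:
            break
        cx = float(np.sum(w * (ring[:, 0] + 0.5)) / total)
        cy = float(np.sum(w * (ring[:, 1] + 0.5)) / total)
    return (cx, cy)


def locate_zones(
    image: np.ndarray,
    layout: DeviceLayout,
    pixels_per_mm: float | None = None,
    max_residual_px: float | None = None,
) -> ZoneFit:
    """Rigid-fit the layout's circular zones to wax edges in the image.

    A Hough circle transform over canny edges proposes circle centres; the
    layout's zone pattern is then matched to the detections (nearest
    neighbour after centroid/scale alignment, refined twice) and a
    similarity transform estimated.  The returned centres are the
    transform's prediction for every zone, so one weak detection cannot
    displace its zone.  ``pixels_per_mm``, when known (e.g. scanner
    captures), narrows the searched radius range; otherwise the scale is
    seeded from the assumption that the device roughly fills the frame.
    """
    img = np.asarray(image)
    gray = grayscale(img)
    edges = canny(gray / 255.0, sigma=2.0)

    zone_r_mm = layout.zones[0].radius
    ppm0 = pixels_per_mm or img.shape[1] / layout.laminate_size[0]
    r0 = zone_r_mm * ppm0
    radii = np.arange(max(4, int(0.82 * r0)), int(1.12 * r0) + 1)
    hough = hough_circle(edges, radii)
    min_sep = max(1, int(1.5 * r0))
    accums, cxs, cys, rads = hough_circle_peaks(
        hough,
        radii,
        min_xdistance=min_sep,
        min_ydistance=min_sep,
        total_num_peaks=16,
        threshold=0.3 * (hough.max() if hough.size else 1.0),
    )
    n_required = len(layout.zones)
    if len(cxs) < n_required:
        raise DetectionError(found=len(cxs), required=n_required)

    detected = np.stack([cxs, cys], axis=1).astype(float)
    scale0 = float(np.median(rads)) / zone_r_mm
    src = np.array([z.centre for z in layout.zones], dtype=float)

    # initial guess: centroid alignment of the 8 strongest detections
    strongest = detected[: n_required]
    translation = strongest.mean(axis=0) - scale0 * src.mean(axis=0)
    predicted = scale0 * src + translation

    matched = None
    tform = None
    for _ in range(3):
        idx = []
        for p in predicted:
            d = np.linalg.norm(detected - p, axis=1)
            j = int(np.argmin(d))
            if d[j] > 0.9 * r0 or j in idx:
                raise DetectionError(
                    found=len(set(idx)),
                    required=n_required,
                    message=(
                        f"could not match all {n_required} layout zones to "
                        f"{len(detected)} detected circles"
                    ),
                )
            idx.append(j)
        matched = detected[idx]
        tform = estimate_transform("similarity", src, matched)
        predicted = tform(src)

    # sub-pixel refinement of each matched centre on the dark wax ring,
    # then a final similarity fit
    r_fit = zone_r_mm * float(tform.scale)
    refined = np.array(
        [_refine_ring_centre(gray, cx, cy, r_fit) for cx, cy in matched]
    )
    tform = estimate_transform("similarity", src, refined)
    predicted = tform(src)
    matched = refined

    residual = float(np.mean(np.linalg.norm(predicted - matched, axis=1)))
    threshold = max_residual_px if max_residual_px is not None else max(3.0, 0.08 * r0)
    if residual > threshold:
        raise AlignmentError(
            f"registration residual {residual:.2f} px exceeds {threshold:.2f} px"
        )
    centres = {z.zone_id: tuple(map(float, p)) for z, p in zip(layout.zones, predicted)}
    ref_c = tform(np.array([layout.ref_square.centre]))[0]
    bg_c = tform(np.array([layout.bg_patch.centre]))[0]
    return ZoneFit(
        centres_px=centres,
        ref_centre_px=tuple(map(float, ref_c)),
        bg_centre_px=tuple(map(float, bg_c)),
        scale_px_per_mm=float(tform.scale),
        rotation_deg=float(np.rad2deg(tform.rotation)),
        residual_px=residual,
    )


# ---------------------------------------------------------------------------
# quantification


def _saturation_fraction(gray: np.ndarray, mask: np.ndarray) -> float:
    vals = gray[mask[:, 1], mask[:, 0]]
    return float(np.mean((vals <= 0.5) | (vals >= 254.5)))


def _read_geometry(
    image: np.ndarray,
    layout: DeviceLayout,
    centres: dict[int, tuple[float, float]],
    ref_centre: tuple[float, float],
    bg_centre: tuple[float, float],
    scale: float,
    sampling_fraction: float,
    capture_source: str,
    dispersion_threshold: float,
    fit: ZoneFit | None,
) -> DeviceReading:
    img = np.asarray(image)
    gray = grayscale(img)
    shape = gray.shape

    readings = []
    flags: list[str] = []
    for z in layout.zones:
        cx, cy = centres[z.zone_id]
        mask = disk_pixels(cx, cy, sampling_fraction * z.radius * scale, shape=shape)
        ai = mean_intensity(img, mask)
        sat = _saturation_fraction(gray, mask) > 0.01
        if sat:
            flags.append(f"saturated_zone_{z.zone_id}")
        readings.append(
            ZoneReading(
                zone_id=z.zone_id,
                role=z.role,
                centre_px=(cx, cy),
                ai=ai,
                n_pixels=len(mask),
                saturated=sat,
            )
        )

    # internal standard, background-referenced against the plain laminate
    ref_r = 0.7 * min(layout.ref_square.w, layout.ref_square.h) / 2.0 * scale
    bg_r = 0.7 * min(layout.bg_patch.w, layout.bg_patch.h) / 2.0 * scale
    ai_ref_sq = mean_intensity(img, disk_pixels(*ref_centre, ref_r, shape=shape))
    ai_bg = mean_intensity(img, disk_pixels(*bg_centre, bg_r, shape=shape))
    ai_ref = ai_ref_sq - ai_bg

    blanks = [r.ai for r in readings if r.role == "blank"]
    ai_blank = float(np.mean(blanks))
    ari_per_zone = {
        r.zone_id: compute_ari(r.ai, ai_blank, ai_ref)
        for r in readings
        if r.role == "detection"
    }
    aris = np.array(list(ari_per_zone.values()))
    ari_mean = float(np.mean(aris))
    ari_sd = float(np.std(aris, ddof=1)) if len(aris) > 1 else 0.0
    # dispersion flag: relative criterion with an absolute floor so that
    # near-zero blanks do not trip it
    if ari_sd > dispersion_threshold * abs(ari_mean) and ari_sd > 0.02:
        flags.append("high_dispersion")

    return DeviceReading(
        device_code=layout.device_code,
        zone_readings=tuple(readings),
        ai_ref=ai_ref,
        ai_background=ai_bg,
        ari_per_zone=ari_per_zone,
        ari_mean=ari_mean,
        ari_sd=ari_sd,
        capture_source=capture_source,
        flags=tuple(flags),
        fit=fit,
    )


def quantify_device(
    image: np.ndarray,
    layout: DeviceLayout,
    pixels_per_mm: float | None = None,
    sampling_fraction: float = DEFAULT_SAMPLING_FRACTION,
    capture_source: str = "synthetic",
    dispersion_threshold: float = 0.5,
) -> DeviceReading:
    """Full readout of one photograph: locate zones, then quantify.

    Propagates :class:`DetectionError`/:class:`AlignmentError` from zone
    location; high within-device ARI dispersion is flagged, never fatal.
    """
    fit = locate_zones(image, layout, pixels_per_mm=pixels_per_mm)
    return _read_geometry(
        image,
        layout,
        fit.centres_px,
        fit.ref_centre_px,
        fit.bg_centre_px,
        fit.scale_px_per_mm,
        sampling_fraction,
        capture_source,
        dispersion_threshold,
        fit,
    )


def quantify_scene(
    image: np.ndarray,
    layout: DeviceLayout,
    truth,
    sampling_fraction: float = DEFAULT_SAMPLING_FRACTION,
    capture_source: str = "synthetic",
    dispersion_threshold: float = 0.5,
) -> DeviceReading:
    """Quantify using known geometry (a generator truth sidecar or a prior
    registration), skipping circle detection.

    ``truth`` needs attributes zone_centres_px, ref_centre_px, bg_centre_px
    and scale_px_per_mm (a :class:`phospad.synthgen.GroundTruth` fits).
    """
    return _read_geometry(
        image,
        layout,
        truth.zone_centres_px,
        truth.ref_centre_px,
        truth.bg_centre_px,
        truth.scale_px_per_mm,
        sampling_fraction,
        capture_source,
        dispersion_threshold,
        None,
    )
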