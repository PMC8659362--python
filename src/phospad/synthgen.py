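"""Ground-truthed synthetic device photographs and campaign records.

The phosphomolybdenum-blue (PMB) reaction turns reagent-loaded zones blue in
proportion to orthophosphate concentration, developing over the first two
minutes of incubation and then plateauing.  This module emulates that
behaviour with a saturating dose response crossed with first-order
development kinetics,

    S(c, t) = blank_level + a_max * c / (c + K_half) * (1 - exp(-k_rate * t)),

renders whole-device photographs with realistic capture effects
(illumination gain and gradient, water-colour tint, per-zone reagent/paper
heterogeneity, per-pixel camera noise, small rotations), and synthesises
geolocated citizen sampling records with a seasonal concentration signal.
Every stochastic output is fully determined by an integer seed, and each
rendered image carries a ground-truth annotation (true zone centres, true
per-zone signals) so the downstream quantifier can be tested without any
external data.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image
from skimage.transform import SimilarityTransform, warp

from .campaign import SampleRecord, records_to_csv
from .errors import GeometryError
from .layout import DeviceLayout, Rect, build_field_layout, disk_pixels

#: Reflectance grey of plain laminated filter paper, 8-bit counts at gain 1.
#: Chosen with headroom so the modelled +/-20% illumination swing between
#: scanner and smartphone captures never clips white pixels.
PAPER_GREY = 210.0
#: Grey of printed wax edges (rings around zones, box outline).
WAX_GREY = 100.0
#: Blue-channel attenuation relative to red/green for the blue PMB complex.
BLUE_ATTENUATION_FACTOR = 0.15

_GRAY_W = np.array([0.299, 0.587, 0.114])  # Rec.601 luma


@dataclass(frozen=True)
class KineticsParams:
    """Colour-development model parameters.

    a_max : maximum attainable colour signal (reflectance deficit, unitless)
    K_half : phosphate concentration at half-maximal signal, mg/L
    k_rate : first-order development rate, 1/min (plateau by ~2-3 min)
    blank_level : residual signal of a reagent-loaded zone at zero phosphate
        (molybdate auto-reduction background); becomes the calibration
        intercept downstream
    """

    a_max: float = 0.55
    K_half: float = 40.0
    k_rate: float = 1.5
    blank_level: float = 0.02

    def __post_init__(self):
        if not 0.0 < self.a_max <= 1.0:
            raise ValueError(f"a_max must be in (0, 1], got {self.a_max}")
        if self.K_half <= 0:
            raise ValueError(f"K_half must be positive, got {self.K_half}")
        if self.k_rate <= 0:
            raise ValueError(f"k_rate must be positive, got {self.k_rate}")
        if not 0.0 <= self.blank_level < self.a_max:
            raise ValueError(
                f"blank_level must be in [0, a_max), got {self.blank_level}"
            )


@dataclass(frozen=True)
class SceneParams:
    """Capture conditions for one rendered photograph.

    gain and gain_gradient model illumination (smartphone vs scanner),
    water_tint is a per-channel absorption of the water sample applied inside
    every porous zone (positive values darken), zone_noise_sd is per-zone
    signal jitter from reagent deposition and paper heterogeneity (the
    dominant replicate-dispersion term), and noise_sd is per-pixel Gaussian
    camera noise.  All randomness derives from ``seed``.
    """

    gain: float = 1.0
    gain_gradient: float = 0.0
    offset: float = 0.0
    water_tint: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd: float = 2.0
    zone_noise_sd: float = 0.0068
    pixels_per_mm: float = 10.0
    rotation: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.gain <= 0:
            raise ValueError(f"gain must be positive, got {self.gain}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be non-negative, got {self.noise_sd}")
        if self.zone_noise_sd < 0:
            raise ValueError(
                f"zone_noise_sd must be non-negative, got {self.zone_noise_sd}"
            )
        if self.pixels_per_mm <= 0:
            raise ValueError(
                f"pixels_per_mm must be positive, got {self.pixels_per_mm}"
            )
        if abs(self.rotation) > 10.0:
            raise ValueError(
                f"|rotation| must be <= 10 degrees, got {self.rotation}"
            )


def noiseless(scene: SceneParams | None = None, **overrides) -> SceneParams:
    """A copy of ``scene`` (or the defaults) with every noise source zeroed."""
    base = scene or SceneParams()
    return replace(base, noise_sd=0.0, zone_noise_sd=0.0, **overrides)


@dataclass(frozen=True)
class SyntheticScene:
    """One ground-truthed scene: what is on the device and how it is lit."""

    layout: DeviceLayout
    concentration: float
    incubation: float = 3.0
    kinetics: KineticsParams = field(default_factory=KineticsParams)
    scene: SceneParams = field(default_factory=SceneParams)
    #: optional (species, concentration mg/L, rate multiplier)
    interferent: tuple[str, float, float] | None = None

    def __post_init__(self):
        if self.concentration < 0:
            raise ValueError(
                f"concentration must be non-negative, got {self.concentration}"
            )
        if self.incubation < 0:
            raise ValueError(f"incubation must be non-negative, got {self.incubation}")


@dataclass
class GroundTruth:
    """Sidecar annotation for a rendered image (all positions in pixels)."""

    zone_centres_px: dict[int, tuple[float, float]]
    zone_signals: dict[int, float]
    expected_ai: dict[int, float]
    ref_centre_px: tuple[float, float]
    bg_centre_px: tuple[float, float]
    scale_px_per_mm: float
    rotation_deg: float
    concentration: float
    incubation_min: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "zone_centres_px": {str(k): list(v) for k, v in self.zone_centres_px.items()},
            "zone_signals": {str(k): v for k, v in self.zone_signals.items()},
            "expected_ai": {str(k): v for k, v in self.expected_ai.items()},
            "ref_centre_px": list(self.ref_centre_px),
            "bg_centre_px": list(self.bg_centre_px),
            "scale_px_per_mm": self.scale_px_per_mm,
            "rotation_deg": self.rotation_deg,
            "concentration": self.concentration,
            "incubation_min": self.incubation_min,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            zone_centres_px={int(k): tuple(v) for k, v in d["zone_centres_px"].items()},
            zone_signals={int(k): v for k, v in d["zone_signals"].items()},
            expected_ai={int(k): v for k, v in d["expected_ai"].items()},
            ref_centre_px=tuple(d["ref_centre_px"]),
            bg_centre_px=tuple(d["bg_centre_px"]),
            scale_px_per_mm=d["scale_px_per_mm"],
            rotation_deg=d["rotation_deg"],
            concentration=d["concentration"],
            incubation_min=d["incubation_min"],
            seed=d["seed"],
        )


@dataclass
class RenderResult:
    image: np.ndarray  # uint8, (H, W, 3)
    truth: GroundTruth


# ---------------------------------------------------------------------------
# kinetics


def pmb_signal(c, t, kp: KineticsParams | None = None):
    """Colour signal of the PMB complex at concentration ``c`` (mg/L) and
    incubation time ``t`` (minutes).

    Monotone non-decreasing in both arguments, bounded by
    ``blank_level + a_max``.  Accepts scalars or arrays.
    """
    kp = kp or KineticsParams()
    c = np.asarray(c, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = kp.blank_level + kp.a_max * (c / (c + kp.K_half)) * (
        1.0 - np.exp(-kp.k_rate * t)
    )
    return float(out) if out.ndim == 0 else out


def interferent_signal(
    c_int, t, rate_multiplier: float = 0.005, kp: KineticsParams | None = None
):
    """Signal contributed by a slow-reacting interferent (e.g. silicate).

    Same dose-response form as :func:`pmb_signal` but with the development
    rate scaled by ``rate_multiplier`` (in (0, 1)): silicate forms the
    heteropoly complex over much longer timescales, so within a 3-minute
    incubation even 1000 mg/L silicate stays equivalent to a blank.
    """
    if not 0.0 < rate_multiplier < 1.0:
        raise ValueError(
            f"rate_multiplier must be in (0, 1), got {rate_multiplier}"
        )
    kp = kp or KineticsParams()
    slow = KineticsParams(
        a_max=kp.a_max,
        K_half=kp.K_half,
        k_rate=rate_multiplier * kp.k_rate,
        blank_level=kp.blank_level,
    )
    return pmb_signal(c_int, t, slow)


# ---------------------------------------------------------------------------
# rendering


def _zone_rgb(g0: float, s: float, tint: np.ndarray) -> np.ndarray:
    """Surface colour of a porous zone carrying signal ``s`` under water tint.

    The blue complex absorbs mostly red and green: R and G are attenuated by
    (1 - s), B by (1 - 0.15 s).  Tint counts are subtracted per channel
    (pigmented water darkens the paper).
    """
    rgb = np.array(
        [
            g0 * (1.0 - s),
            g0 * (1.0 - s),
            g0 * (1.0 - BLUE_ATTENUATION_FACTOR * s),
        ]
    )
    return rgb - tint


def _fill_rect(canvas: np.ndarray, rect: Rect, ppm: float, rgb) -> None:
    y0 = int(round(rect.y * ppm))
    y1 = int(round(rect.y1 * ppm))
    x0 = int(round(rect.x * ppm))
    x1 = int(round(rect.x1 * ppm))
    canvas[y0:y1, x0:x1] = rgb


def _fill_disk(canvas: np.ndarray, cx, cy, r, rgb) -> None:
    px = disk_pixels(cx, cy, r, shape=canvas.shape[:2])
    canvas[px[:, 1], px[:, 0]] = rgb


def _rotation_matrix(theta_deg: float, cx: float, cy: float) -> np.ndarray:
    """3x3 homogeneous rotation about (cx, cy) in pixel (x, y) coordinates."""
    th = math.radians(theta_deg)
    c, s = math.cos(th), math.sin(th)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    t_in = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1.0]])
    t_out = np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1.0]])
    return t_out @ rot @ t_in


def zone_signals(scene: SyntheticScene, rng: np.random.Generator | None = None) -> dict[int, float]:
    """True per-zone signals, including per-zone heterogeneity when ``rng`` given.

    Detection zones carry the PMB signal (plus any interferent contribution);
    blank zones carry zero chemical signal.  Zone jitter is additive in signal
    units on all eight zones.
    """
    base = {}
    s_det = pmb_signal(scene.concentration, scene.incubation, scene.kinetics)
    s_interf = 0.0
    if scene.interferent is not None:
        _, c_int, mult = scene.interferent
        s_interf = (
            interferent_signal(c_int, scene.incubation, mult, scene.kinetics)
            - scene.kinetics.blank_level
        )
    for z in scene.layout.zones:
        base[z.zone_id] = s_det + s_interf if z.role == "detection" else 0.0
    if rng is not None and scene.scene.zone_noise_sd > 0:
        for zid in base:
            base[zid] = float(
                np.clip(base[zid] + rng.normal(0.0, scene.scene.zone_noise_sd), -0.2, 1.0)
            )
    return base


def render_device_image(scene: SyntheticScene) -> RenderResult:
    """Render an 8-bit RGB photograph of the device plus its ground truth.

    Painting order: laminate background, wax box outline, wax rings and zone
    interiors, reference square; then the multiplicative gain field, additive
    offset, rotation about the image centre, per-pixel noise, and clipping to
    uint8.
    """
    lay = scene.layout
    sp = scene.scene
    ppm = sp.pixels_per_mm
    w_px = int(round(lay.laminate_size[0] * ppm))
    h_px = int(round(lay.laminate_size[1] * ppm))
    # every printed element must fit on the laminate at this scale
    for rect in (lay.wax_box, lay.ref_square, lay.bg_patch):
        if rect.x < 0 or rect.y < 0 or rect.x1 > lay.laminate_size[0] or rect.y1 > lay.laminate_size[1]:
            raise GeometryError("layout element falls outside the laminate")
    if w_px < 8 or h_px < 8:
        raise GeometryError(
            f"image {w_px}x{h_px} px too small to contain the layout"
        )

    rng = np.random.default_rng(sp.seed)
    signals = zone_signals(scene, rng)
    tint = np.asarray(sp.water_tint, dtype=float)

    canvas = np.full((h_px, w_px, 3), PAPER_GREY, dtype=float)

    # wax box outline, 1 mm thick
    box = lay.wax_box
    _fill_rect(canvas, box, ppm, WAX_GREY)
    inner = Rect(box.x + 1.0, box.y + 1.0, box.w - 2.0, box.h - 2.0)
    _fill_rect(canvas, inner, ppm, PAPER_GREY)

    # zones: wax ring (1 mm) then porous interior
    for z in lay.zones:
        cx, cy = z.centre[0] * ppm, z.centre[1] * ppm
        _fill_disk(canvas, cx, cy, (z.radius + 1.0) * ppm, WAX_GREY)
        _fill_disk(canvas, cx, cy, z.radius * ppm, _zone_rgb(PAPER_GREY, signals[z.zone_id], tint))

    _fill_rect(canvas, lay.ref_square, ppm, np.asarray(lay.ref_colour, dtype=float))

    # illumination: gain with a horizontal gradient, then offset
    xs = np.arange(w_px) + 0.5
    gain_field = sp.gain * (1.0 + sp.gain_gradient * (xs - w_px / 2.0) / w_px)
    canvas *= gain_field[None, :, None]
    canvas += sp.offset

    # geometric pose
    mat = _rotation_matrix(sp.rotation, w_px / 2.0, h_px / 2.0)
    if sp.rotation != 0.0:
        inv = SimilarityTransform(matrix=np.linalg.inv(mat))
        rotated = np.empty_like(canvas)
        for ch in range(3):
            rotated[:, :, ch] = warp(
                canvas[:, :, ch],
                inv,
                order=1,
                mode="constant",
                cval=255.0,
                preserve_range=True,
            )
        canvas = rotated

    if sp.noise_sd > 0:
        canvas += rng.normal(0.0, sp.noise_sd, canvas.shape)

    image = np.clip(canvas, 0.0, 255.0).astype(np.uint8)

    # ground truth: analytic expected AI per zone (noiseless, local gain)
    def _transform(px, py):
        v = mat @ np.array([px, py, 1.0])
        return (float(v[0]), float(v[1]))

    centres, expected_ai = {}, {}
    for z in lay.zones:
        cx, cy = z.centre[0] * ppm, z.centre[1] * ppm
        centres[z.zone_id] = _transform(cx, cy)
        local_gain = sp.gain * (1.0 + sp.gain_gradient * (cx - w_px / 2.0) / w_px)
        gray = float(_GRAY_W @ _zone_rgb(PAPER_GREY, signals[z.zone_id], tint))
        expected_ai[z.zone_id] = 255.0 - (local_gain * gray + sp.offset)

    truth = GroundTruth(
        zone_centres_px=centres,
        zone_signals=signals,
        expected_ai=expected_ai,
        ref_centre_px=_transform(lay.ref_square.centre[0] * ppm, lay.ref_square.centre[1] * ppm),
        bg_centre_px=_transform(lay.bg_patch.centre[0] * ppm, lay.bg_patch.centre[1] * ppm),
        scale_px_per_mm=ppm,
        rotation_deg=sp.rotation,
        concentration=scene.concentration,
        incubation_min=scene.incubation,
        seed=sp.seed,
    )
    return RenderResult(image=image, truth=truth)


def save_render(result: RenderResult, image_path) -> None:
    """Write the image as PNG with a ``<image>.truth.json`` sidecar."""
    Image.fromarray(result.image).save(image_path)
    with open(f"{image_path}.truth.json", "w") as fh:
        json.dump(result.truth.to_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# dataset generators


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def generate_calibration_set(
    concs,
    replicates: int,
    layout: DeviceLayout | None = None,
    kinetics: KineticsParams | None = None,
    scene_template: SceneParams | None = None,
    incubation: float = 3.0,
    seed: int = 0,
) -> list[tuple[SyntheticScene, RenderResult]]:
    """Render ``len(concs) x replicates`` calibration standards.

    Each image gets an independent noise stream derived from ``seed``; the
    scene metadata records the true concentration.
    """
    concs = list(concs)
    if not concs:
        raise ValueError("concs must be non-empty")
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    layout = layout or build_field_layout("0000")
    kinetics = kinetics or KineticsParams()
    template = scene_template or SceneParams()
    seeds = _child_seeds(seed, len(concs) * replicates)
    out = []
    i = 0
    for c in concs:
        for _ in range(replicates):
            scene = SyntheticScene(
                layout=layout,
                concentration=float(c),
                incubation=incubation,
                kinetics=kinetics,
                scene=replace(template, seed=seeds[i]),
            )
            out.append((scene, render_device_image(scene)))
            i += 1
    return out


_WATERBODIES = (
    "Pocklington Canal",
    "River Aire",
    "River Derwent",
    "Leven Canal",
    "Market Weighton Canal",
    "River Hull",
)


@dataclass
class CampaignResult:
    records: list[SampleRecord]
    scenes: list[SyntheticScene]
    renders: list[RenderResult]
    true_concentrations: list[float]


def generate_campaign(
    n: int,
    bbox: tuple[float, float, float, float],
    date_range: tuple[_dt.date, _dt.date],
    seasonal_amplitude: float = 0.4,
    median_mg_per_l: float = 3.0,
    log_sd: float = 0.7,
    layout_code_prefix: str = "",
    kinetics: KineticsParams | None = None,
    scene_template: SceneParams | None = None,
    seed: int = 0,
) -> CampaignResult:
    """Synthesise ``n`` geolocated citizen sampling records with images.

    bbox is (west, south, east, north) in WGS84 decimal degrees.  True
    concentrations follow a lognormal baseline (median ``median_mg_per_l``,
    log-sd ``log_sd``) modulated by a sinusoidal seasonal term of the given
    log-amplitude peaking in mid-July.  GPS points are uniform in the bbox,
    timestamps uniform in the date range (UTC).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    west, south, east, north = bbox
    if not (west < east and south < north):
        raise ValueError(f"invalid bbox {bbox!r}: need west < east and south < north")
    d0, d1 = date_range
    if d1 < d0:
        raise ValueError(f"empty date range {date_range!r}")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    scene_seeds = _child_seeds(seed + 1, n)
    kinetics = kinetics or KineticsParams()
    template = scene_template or SceneParams()
    span_days = (d1 - d0).days + 1

    records, scenes, renders, truths = [], [], [], []
    for i in range(n):
        day_offset = int(rng.integers(0, span_days))
        seconds = int(rng.integers(0, 86400))
        ts = _dt.datetime.combine(
            d0 + _dt.timedelta(days=day_offset), _dt.time(0, 0), tzinfo=_dt.timezone.utc
        ) + _dt.timedelta(seconds=seconds)
        doy = ts.timetuple().tm_yday
        seasonal = seasonal_amplitude * math.cos(2.0 * math.pi * (doy - 196) / 365.25)
        c_true = float(
            math.exp(math.log(median_mg_per_l) + seasonal + rng.normal(0.0, log_sd))
        )
        lon = float(rng.uniform(west, east))
        lat = float(rng.uniform(south, north))
        device_code = f"{int(rng.integers(0, 10000)):04d}"
        scene = SyntheticScene(
            layout=build_field_layout(device_code),
            concentration=c_true,
            incubation=3.0,
            kinetics=kinetics,
            scene=replace(template, seed=scene_seeds[i]),
        )
        render = render_device_image(scene)
        user_level = int(np.clip(round(c_true + rng.normal(0.0, 1.0)), 0, 10))
        records.append(
            SampleRecord(
                record_id=f"R{i:04d}",
                device_code=device_code,
                timestamp=ts,
                lat=lat,
                lon=lon,
                waterbody=_WATERBODIES[int(rng.integers(0, len(_WATERBODIES)))],
                incubation_s=180.0,
                image_path=f"images/R{i:04d}.png",
                user_level=user_level,
                notes="",
            )
        )
        scenes.append(scene)
        renders.append(render)
        truths.append(c_true)
    return CampaignResult(
        records=records, scenes=scenes, renders=renders, true_concentrations=truths
    )


def write_campaign(result: CampaignResult, out_dir) -> None:
    """Write campaign records CSV plus PNG images and truth sidecars."""
    import os

    os.makedirs(os.path.join(out_dir, "images"), exist_ok=True)
    records_to_csv(result.records, os.path.join(out_dir, "records.csv"))
    for rec, render in zip(result.records, result.renders):
        save_render(render, os.path.join(out_dir, rec.image_path))
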