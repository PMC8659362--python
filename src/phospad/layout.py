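"""Geometry of the wax-printed paper test card (PAD).

The field device is a laminated strip of wax-patterned filter paper carrying
eight 10 mm circular zones inside a rectangular wax box: six reagent-loaded
detection zones and two reagent-free blank (negative-control) zones that pick
up only the colour of the water itself.  Next to the wax box sit a printed
blue reference square (the internal standard used to normalise illumination)
and a four-digit device code.  Both the synthetic-image generator and the
quantifier consume the same :class:`DeviceLayout`, so zone roles are always
known by position and never inferred from colour.

Coordinates are millimetres in the device frame: origin at the top-left
corner of the laminate, x rightward, y downward.  Pixel frames use the same
convention; a pixel with index ``(ix, iy)`` has its centre at
``(ix + 0.5, iy + 0.5)``.
"""

from __future__ import annotations

import re
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .errors import LayoutValidationError

LAYOUT_VERSION = 1

#: Zone diameter of the field design, millimetres.
ZONE_DIAMETER_MM = 10.0

#: Default fraction of the zone radius sampled for intensity, excluding the
#: wax edge (standard edge exclusion for spot assays).
DEFAULT_SAMPLING_FRACTION = 0.7

ROLE_DETECTION = "detection"
ROLE_BLANK = "blank"

#: Nominal printed colour of the internal-standard square (saturated blue),
#: 8-bit RGB at unit illumination gain.
REF_SQUARE_RGB = (0, 20, 160)

_CODE_RE = re.compile(r"^[0-9]{4}$")

# Field-design dimensions (mm).  The zone diameter is the only dimension the
# device definition fixes; the arrangement below (4 x 2 grid, 14 mm pitch,
# 62 x 34 mm wax box on an 80 x 50 mm laminate) is the package's canonical
# layout and is shared by generator and quantifier, which is all the ARI
# analysis requires.
LAMINATE_MM = (80.0, 50.0)
WAX_BOX_MM = (4.0, 8.0, 62.0, 34.0)  # x, y, w, h
ZONE_PITCH_MM = 14.0
ZONE_GRID_ORIGIN_MM = (13.0, 18.0)  # centre of zone 1 (top-left)
REF_SQUARE_MM = (69.0, 10.0, 8.0, 8.0)
BG_PATCH_MM = (69.0, 24.0, 8.0, 8.0)  # plain laminate, used as white reference


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in device millimetres."""

    x: float
    y: float
    w: float
    h: float

    @property
    def x1(self) -> float:
        return self.x + self.w

    @property
    def y1(self) -> float:
        return self.y + self.h

    @property
    def centre(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    def contains_circle(self, cx: float, cy: float, r: float) -> bool:
        return (
            cx - r >= self.x
            and cx + r <= self.x1
            and cy - r >= self.y
            and cy + r <= self.y1
        )

    def overlaps_circle(self, cx: float, cy: float, r: float) -> bool:
        # distance from circle centre to the rectangle
        dx = max(self.x - cx, 0.0, cx - self.x1)
        dy = max(self.y - cy, 0.0, cy - self.y1)
        return dx * dx + dy * dy < r * r


@dataclass(frozen=True)
class ZoneSpec:
    """One circular zone: position, size and role."""

    zone_id: int
    centre: tuple[float, float]
    diameter: float = ZONE_DIAMETER_MM
    role: str = ROLE_DETECTION

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class DeviceLayout:
    """Full machine-readable geometry of one test card."""

    device_code: str
    zones: tuple[ZoneSpec, ...]
    wax_box: Rect
    ref_square: Rect
    bg_patch: Rect
    laminate_size: tuple[float, float]
    ref_colour: tuple[int, int, int] = REF_SQUARE_RGB

    def zone(self, zone_id: int) -> ZoneSpec:
        for z in self.zones:
            if z.zone_id == zone_id:
                return z
        raise KeyError(f"no zone with id {zone_id!r} in layout")

    @property
    def detection_zones(self) -> tuple[ZoneSpec, ...]:
        return tuple(z for z in self.zones if z.role == ROLE_DETECTION)

    @property
    def blank_zones(self) -> tuple[ZoneSpec, ...]:
        return tuple(z for z in self.zones if z.role == ROLE_BLANK)


def _check_device_code(device_code: str) -> None:
    if not isinstance(device_code, str) or not _CODE_RE.match(device_code):
        raise LayoutValidationError(
            f"device code must be exactly four digits, got {device_code!r}"
        )


def build_field_layout(device_code: str, pitch_mm: float = ZONE_PITCH_MM) -> DeviceLayout:
    """Construct the canonical eight-zone field layout.

    Zones are numbered in reading order (top row left to right, then bottom
    row); zones 1-6 are detection zones, zones 7-8 (the two rightmost of the
    bottom row) are the reagent-free blanks.  Construction is deterministic.
    """
    _check_device_code(device_code)
    x0, y0 = ZONE_GRID_ORIGIN_MM
    zones = []
    zone_id = 1
    for row in range(2):
        for col in range(4):
            role = ROLE_DETECTION if zone_id <= 6 else ROLE_BLANK
            zones.append(
                ZoneSpec(
                    zone_id=zone_id,
                    centre=(x0 + col * pitch_mm, y0 + row * pitch_mm),
                    diameter=ZONE_DIAMETER_MM,
                    role=role,
                )
            )
            zone_id += 1
    return DeviceLayout(
        device_code=device_code,
        zones=tuple(zones),
        wax_box=Rect(*WAX_BOX_MM),
        ref_square=Rect(*REF_SQUARE_MM),
        bg_patch=Rect(*BG_PATCH_MM),
        laminate_size=LAMINATE_MM,
    )


def validate_layout(layout: DeviceLayout) -> list[str]:
    """Check every structural invariant; return human-readable violations.

    Returns an empty list iff the layout is valid.  Never raises.
    """
    violations: list[str] = []
    zones = layout.zones
    if len(zones) != 8:
        violations.append(f"zones: expected 8 zones, found {len(zones)}")
    n_det = sum(1 for z in zones if z.role == ROLE_DETECTION)
    n_blank = sum(1 for z in zones if z.role == ROLE_BLANK)
    bad_roles = [z.zone_id for z in zones if z.role not in (ROLE_DETECTION, ROLE_BLANK)]
    if bad_roles:
        violations.append(f"zones.role: unknown role on zones {bad_roles}")
    if n_det != 6:
        violations.append(f"zones.role: expected 6 detection zones, found {n_det}")
    if n_blank != 2:
        violations.append(f"zones.role: expected 2 blank zones, found {n_blank}")
    for z in zones:
        if z.diameter <= 0:
            violations.append(f"zones[{z.zone_id}].diameter: must be positive")
    # pairwise non-overlap
    for i, a in enumerate(zones):
        for b in zones[i + 1 :]:
            d = float(np.hypot(a.centre[0] - b.centre[0], a.centre[1] - b.centre[1]))
            if d < a.radius + b.radius:
                violations.append(
                    f"zones: zones {a.zone_id} and {b.zone_id} overlap "
                    f"(centre distance {d:.2f} mm < {a.radius + b.radius:.2f} mm)"
                )
    for z in zones:
        if not layout.wax_box.contains_circle(*z.centre, z.radius):
            violations.append(f"wax_box: zone {z.zone_id} not fully inside wax box")
    for z in zones:
        if layout.ref_square.overlaps_circle(*z.centre, z.radius):
            violations.append(f"ref_square: overlaps zone {z.zone_id}")
    if not isinstance(layout.device_code, str) or not _CODE_RE.match(layout.device_code):
        violations.append(
            f"device_code: {layout.device_code!r} does not match the four-digit pattern"
        )
    return violations


def zone_mask(
    layout: DeviceLayout,
    zone_id: int,
    pixels_per_mm: float,
    sampling_fraction: float = DEFAULT_SAMPLING_FRACTION,
) -> np.ndarray:
    """Pixel indices sampled for one zone at a given scale.

    Returns an ``(N, 2)`` integer array of ``(ix, iy)`` pixel indices whose
    centres lie within ``sampling_fraction x radius`` of the zone centre after
    the mm-to-pixel conversion.
    """
    if not 0.0 < sampling_fraction <= 1.0:
        raise ValueError(
            f"sampling_fraction must be in (0, 1], got {sampling_fraction}"
        )
    if pixels_per_mm <= 0:
        raise ValueError(f"pixels_per_mm must be positive, got {pixels_per_mm}")
    zone = layout.zone(zone_id)  # KeyError for unknown ids
    cx = zone.centre[0] * pixels_per_mm
    cy = zone.centre[1] * pixels_per_mm
    r = sampling_fraction * zone.radius * pixels_per_mm
    return disk_pixels(cx, cy, r)


def disk_pixels(
    cx: float, cy: float, r: float, shape: tuple[int, int] | None = None
) -> np.ndarray:
    """All pixel indices whose centres fall inside a circle.

    ``shape`` (rows, cols), when given, clips the result to image bounds.
    """
    x_lo = int(np.floor(cx - r - 1))
    x_hi = int(np.ceil(cx + r + 1))
    y_lo = int(np.floor(cy - r - 1))
    y_hi = int(np.ceil(cy + r + 1))
    if shape is not None:
        x_lo, x_hi = max(x_lo, 0), min(x_hi, shape[1])
        y_lo, y_hi = max(y_lo, 0), min(y_hi, shape[0])
    xs, ys = np.meshgrid(np.arange(x_lo, x_hi), np.arange(y_lo, y_hi))
    inside = (xs + 0.5 - cx) ** 2 + (ys + 0.5 - cy) ** 2 <= r * r
    return np.stack([xs[inside], ys[inside]], axis=1)


# ---------------------------------------------------------------------------
# serialization


def layout_to_dict(layout: DeviceLayout) -> dict:
    return {
        "layout_version": LAYOUT_VERSION,
        "device_code": layout.device_code,
        "laminate_size": list(layout.laminate_size),
        "wax_box": asdict(layout.wax_box),
        "ref_square": asdict(layout.ref_square),
        "bg_patch": asdict(layout.bg_patch),
        "ref_colour": list(layout.ref_colour),
        "zones": [
            {
                "zone_id": z.zone_id,
                "centre": list(z.centre),
                "diameter": z.diameter,
                "role": z.role,
            }
            for z in layout.zones
        ],
    }


def layout_from_dict(doc: dict) -> DeviceLayout:
    version = doc.get("layout_version")
    if version != LAYOUT_VERSION:
        raise LayoutValidationError(
            f"unsupported layout_version {version!r} (expected {LAYOUT_VERSION})"
        )
    return DeviceLayout(
        device_code=doc["device_code"],
        zones=tuple(
            ZoneSpec(
                zone_id=z["zone_id"],
                centre=tuple(z["centre"]),
                diameter=z["diameter"],
                role=z["role"],
            )
            for z in doc["zones"]
        ),
        wax_box=Rect(**doc["wax_box"]),
        ref_square=Rect(**doc["ref_square"]),
        bg_patch=Rect(**doc["bg_patch"]),
        laminate_size=tuple(doc["laminate_size"]),
        ref_colour=tuple(doc["ref_colour"]),
    )


def save_layout(layout: DeviceLayout, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(layout_to_dict(layout), fh, sort_keys=False)


def load_layout(path) -> DeviceLayout:
    with open(path) as fh:
        return layout_from_dict(yaml.safe_load(fh))
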