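"""Morphometric feature extraction from colour-annotated macular-hole OCT masks.

The input is not a raw B-scan but its *annotation layer*: a 256x256 indexed
label image in which the retinal bands between the manually drawn demarcation
lines are flood-filled with a fixed palette -- green for ILM->OPL, yellow for
the outer nuclear layer (OPL->ELM), sky-blue for ELM->EZ, blue for EZ->RPE,
and red for intraretinal fluid.  A full-thickness macular hole appears as a
central background cavity interrupting every band.

From one mask this module measures three families of handcrafted features:

1. *defect lengths* (DL) across the hole at the OPL, ELM and EZ boundaries
   (band-interface endpoint to endpoint),
2. *shortest defect lengths* (sDL) per colour band (minimum pixel-centre
   distance between the two flanking band components), and
3. the *hole diameters*: the minimum linear diameter (narrowest horizontal
   cavity run) and the base diameter (cavity width at the RPE level),

plus per-band pixel areas.  Together with eleven clinical background items and
sixteen arithmetic combinations they form the canonical 41-feature record used
throughout the pipeline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# Palette and acquisition geometry
# --------------------------------------------------------------------------

BACKGROUND, GREEN, YELLOW, SKY_BLUE, BLUE, RED = range(6)
BAND_CLASSES = (GREEN, YELLOW, SKY_BLUE, BLUE)
CLASS_NAMES = {
    BACKGROUND: "background",
    GREEN: "green",
    YELLOW: "yellow",
    SKY_BLUE: "sky_blue",
    BLUE: "blue",
    RED: "red",
}
#: RGB palette used when masks are written to / read from indexed PNG.
PALETTE_RGB = (
    (0, 0, 0),
    (0, 176, 80),
    (255, 255, 0),
    (0, 176, 240),
    (0, 32, 96),
    (255, 0, 0),
)

#: band boundaries as (upper class, lower class) interfaces
BOUNDARIES = {"OPL": (GREEN, YELLOW), "ELM": (YELLOW, SKY_BLUE), "EZ": (SKY_BLUE, BLUE)}

# Spectralis B-scan raster: 768 x 496 px covering 9 x 1.9 mm over a 30 deg field.
SOURCE_SHAPE_PX = (496, 768)  # (rows, cols)
SOURCE_WIDTH_MM = 9.0
SOURCE_DEPTH_MM = 1.9
SOURCE_FIELD_DEG = 30.0

TRIM_SIZE_PX = 256
#: axial pixel pitch, um/px; the 256-px trim is taken in a space resampled to
#: this pitch on both axes (256 px * 3.8306 um = 0.98 mm).
AXIAL_PITCH_UM = SOURCE_DEPTH_MM * 1000.0 / SOURCE_SHAPE_PX[0]
#: native lateral pitch of the uncropped raster, provided for reference.
LATERAL_PITCH_UM = SOURCE_WIDTH_MM * 1000.0 / SOURCE_SHAPE_PX[1]
#: rounded isotropic default used by the synthetic renderer.
DEFAULT_PITCH_UM = 3.83


def trim_extent_mm(pitch_um: float = AXIAL_PITCH_UM, size_px: int = TRIM_SIZE_PX) -> float:
    """Physical extent of the trimmed image along one axis, in mm."""
    return size_px * pitch_um / 1000.0


def trim_field_degrees(pitch_um: float = AXIAL_PITCH_UM, size_px: int = TRIM_SIZE_PX) -> float:
    """Angular subtense of the trim width on the 30 deg / 9 mm scan geometry."""
    return trim_extent_mm(pitch_um, size_px) / SOURCE_WIDTH_MM * SOURCE_FIELD_DEG


# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------


class MaskError(ValueError):
    """Base class for malformed-mask conditions."""


class MissingLayerError(MaskError):
    """A band class required for the measurement is absent."""


class AmbiguousBandError(MaskError):
    """A band splits into more than two flanking components."""


class NoHoleError(MaskError):
    """No bounded background cavity touches the central column."""


class OutOfBoundsError(ValueError):
    """Requested crop window does not fit inside the source image."""


class MissingDataError(ValueError):
    """A record cannot be composed (non-finite input or zero ratio denominator)."""


# --------------------------------------------------------------------------
# Canonical 41-feature schema (Table of patient background + OCT features)
# --------------------------------------------------------------------------

#: categorical feature -> allowed levels (first level is the reference)
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "Sex": ("Man", "Woman"),
    "Method": ("PPV", "Phaco+PPV"),
    "Affected eye": ("Right", "Left"),
    "Stage": ("2", "3", "4"),
    "ILM": ("Peel", "Invert", "Not peel"),
    "VMT": ("Present", "Absent"),
    "PVD": ("Complete", "Not complete"),
}

CLINICAL_CONTINUOUS = ("Age", "Preoperative BCVA", "Axial length", "Disease duration")

#: the 11 patient-background items, in canonical order
CLINICAL_FEATURES = (
    "Sex",
    "Age",
    "Preoperative BCVA",
    "Method",
    "Affected eye",
    "Axial length",
    "Stage",
    "Disease duration",
    "ILM",
    "VMT",
    "PVD",
)

ONL_SDL = "Yellow-sDL (ONL-DL)"

MORPHOMETRIC_LENGTHS = (
    "BDM",
    "Hole-min",
    "OPL-DL",
    "ELM-DL",
    "EZ-DL",
    "Green-sDL",
    ONL_SDL,
    "Sky blue-sDL",
    "Blue-sDL",
)

AREA_FEATURES = ("Area IRF", "Area-green", "Area-yellow", "Area-sky_blue", "Area-blue")

#: combination name -> (minuend, subtrahend)
DIFFERENCE_FEATURES: dict[str, tuple[str, str]] = {
    "(OPL-DL) - (ONL-DL)": ("OPL-DL", ONL_SDL),
    "(ELM-DL) - (ONL-DL)": ("ELM-DL", ONL_SDL),
    "(OPL-DL) - (Green-sDL)": ("OPL-DL", "Green-sDL"),
    "(ELM-DL) - (Sky blue-sDL)": ("ELM-DL", "Sky blue-sDL"),
    "(EZ-DL) - (Sky blue-sDL)": ("EZ-DL", "Sky blue-sDL"),
    "(EZ-DL) - (Blue-sDL)": ("EZ-DL", "Blue-sDL"),
    "BDM - (Blue-sDL)": ("BDM", "Blue-sDL"),
    "BDM - (Hole-min)": ("BDM", "Hole-min"),
}

#: combination name -> (numerator, denominator)
RATIO_FEATURES: dict[str, tuple[str, str]] = {
    "(Green-sDL)/(OPL-DL)": ("Green-sDL", "OPL-DL"),
    "(OPL-DL)/(ONL-DL)": ("OPL-DL", ONL_SDL),
    "(ELM-DL)/(ONL-DL)": ("ELM-DL", ONL_SDL),
    "(ELM-DL)/(Sky blue-sDL)": ("ELM-DL", "Sky blue-sDL"),
    "(EZ-DL)/(Sky blue-sDL)": ("EZ-DL", "Sky blue-sDL"),
    "(EZ-DL)/(Blue-sDL)": ("EZ-DL", "Blue-sDL"),
    "BDM/(Blue-sDL)": ("BDM", "Blue-sDL"),
    "BDM/(Hole-min)": ("BDM", "Hole-min"),
}

COMBINATION_FEATURES = tuple(DIFFERENCE_FEATURES) + tuple(RATIO_FEATURES)

MORPHOMETRIC_BASE = MORPHOMETRIC_LENGTHS + AREA_FEATURES

#: all 41 features in canonical order
FEATURE_NAMES: tuple[str, ...] = CLINICAL_FEATURES + MORPHOMETRIC_BASE + COMBINATION_FEATURES

CATEGORICAL_FEATURES = tuple(CATEGORICAL_LEVELS)
CONTINUOUS_FEATURES = tuple(f for f in FEATURE_NAMES if f not in CATEGORICAL_LEVELS)

LABEL_COLUMN = "Group"
GROUP_GOOD = "A"
GROUP_POOR = "B"

assert len(FEATURE_NAMES) == 41


def canonical_order(names) -> list[str]:
    """Sort feature names into canonical schema order."""
    rank = {n: i for i, n in enumerate(FEATURE_NAMES)}
    return sorted(names, key=lambda n: rank[n])


# --------------------------------------------------------------------------
# LayerMask container
# --------------------------------------------------------------------------


@dataclass
class LayerMask:
    """An annotated OCT crop: integer label image plus pixel-pitch metadata."""

    labels: np.ndarray
    pixel_pitch_x: float = DEFAULT_PITCH_UM
    pixel_pitch_y: float = DEFAULT_PITCH_UM
    provenance: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or self.labels.size == 0:
            raise MaskError("mask must be a non-empty 2-D label image")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise MaskError("mask labels must be integers")
        present = np.unique(self.labels)
        if present.min() < 0 or present.max() > RED:
            raise MaskError(f"mask contains classes outside 0..5: {present}")
        if self.pixel_pitch_x <= 0 or self.pixel_pitch_y <= 0:
            raise MaskError("pixel pitches must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def classes(self) -> set[int]:
        return set(np.unique(self.labels).tolist())


def crop_to_trim(image: np.ndarray, center: tuple[int, int], size: int = TRIM_SIZE_PX,
                 pitch_um: float = AXIAL_PITCH_UM, provenance: str = "") -> LayerMask:
    """Crop a ``size x size`` window centred on ``center`` = (row, col).

    The window spans ``[c - size//2, c + size - size//2)`` on each axis and the
    pitch metadata is set to the axial pitch on both axes (the trim is defined
    in the resampled isotropic space: 256 px = 0.98 mm).
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise MaskError("source image must be 2-D")
    r, c = int(center[0]), int(center[1])
    half = size // 2
    r0, c0 = r - half, c - half
    r1, c1 = r0 + size, c0 + size
    if r0 < 0 or c0 < 0 or r1 > image.shape[0] or c1 > image.shape[1]:
        raise OutOfBoundsError(
            f"{size}x{size} window at centre ({r},{c}) exceeds image {image.shape}"
        )
    return LayerMask(image[r0:r1, c0:c1].copy(), pitch_um, pitch_um, provenance=provenance)


# --------------------------------------------------------------------------
# Band geometry
# --------------------------------------------------------------------------

_EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass
class BandComponents:
    """The two connected components of a band flanking the central hole."""

    left: np.ndarray  # (n, 2) array of (row, col) pixel coordinates
    right: np.ndarray | None
    defect: bool  # False when the band is unbroken


def split_band(mask: LayerMask, band_class: int) -> BandComponents:
    """Split a colour band into the two components flanking the central column.

    An unbroken band yields a single component with ``defect=False``; more than
    two components signal a malformed annotation.
    """
    binary = mask.labels == band_class
    if not binary.any():
        raise MissingLayerError(f"class {band_class} ({CLASS_NAMES.get(band_class)}) absent")
    labeled, n = ndimage.label(binary, structure=_EIGHT_CONN)
    if n == 1:
        return BandComponents(np.argwhere(binary), None, defect=False)
    if n > 2:
        raise AmbiguousBandError(
            f"band {CLASS_NAMES.get(band_class)} has {n} components (expected 2)"
        )
    comp1 = np.argwhere(labeled == 1)
    comp2 = np.argwhere(labeled == 2)
    if comp1[:, 1].mean() <= comp2[:, 1].mean():
        return BandComponents(comp1, comp2, defect=True)
    return BandComponents(comp2, comp1, defect=True)


def _interface_columns(mask: LayerMask, upper: int, lower: int) -> dict[int, int]:
    """Map column -> uppermost row of the (upper above lower) interface pixels."""
    lab = mask.labels
    contact = (lab[:-1, :] == upper) & (lab[1:, :] == lower)
    cols: dict[int, int] = {}
    rows_idx, cols_idx = np.nonzero(contact)
    for r, c in zip(rows_idx.tolist(), cols_idx.tolist()):
        if c not in cols or r < cols[c]:
            cols[c] = r
    return cols


def defect_length(mask: LayerMask, boundary: str) -> float:
    """Inter-edge distance across the hole at a layer boundary, in um.

    The boundary is the interface between two adjacent colour bands (OPL =
    green/yellow, ELM = yellow/sky-blue, EZ = sky-blue/blue).  The defect
    length is the Euclidean distance between the two interface endpoints
    flanking the central gap, measured as the missing-gap extent (an unbroken
    interface has length 0).
    """
    if boundary not in BOUNDARIES:
        raise ValueError(f"unknown boundary {boundary!r}; expected one of {list(BOUNDARIES)}")
    upper, lower = BOUNDARIES[boundary]
    present = mask.classes()
    for cls in (upper, lower):
        if cls not in present:
            raise MissingLayerError(
                f"boundary {boundary} needs class {CLASS_NAMES[cls]} which is absent"
            )
    iface = _interface_columns(mask, upper, lower)
    if not iface:
        raise MissingLayerError(f"bands never adjacent: no {boundary} interface found")
    cols = np.array(sorted(iface))
    breaks = np.nonzero(np.diff(cols) > 1)[0]
    if breaks.size == 0:
        return 0.0
    # choose the gap containing the central column, else the widest gap
    center = mask.shape[1] // 2
    best = None
    for i in breaks:
        c_l, c_r = int(cols[i]), int(cols[i + 1])
        width = c_r - c_l
        contains = c_l < center < c_r
        key = (contains, width)
        if best is None or key > best[0]:
            best = (key, c_l, c_r)
    _, c_l, c_r = best
    dx = (c_r - c_l - 1) * mask.pixel_pitch_x
    dy = (iface[c_r] - iface[c_l]) * mask.pixel_pitch_y
    return math.hypot(dx, dy)


def shortest_defect_length(mask: LayerMask, band_class: int) -> float:
    """Minimum pixel-centre distance between the two band components, in um."""
    comps = split_band(mask, band_class)
    if not comps.defect:
        logger.debug("band %s unbroken: no defect", CLASS_NAMES.get(band_class))
        return 0.0
    scale = np.array([mask.pixel_pitch_y, mask.pixel_pitch_x])
    left = comps.left * scale
    right = comps.right * scale
    # query the smaller set against a KD-tree over the larger one
    if len(left) > len(right):
        left, right = right, left
    tree = cKDTree(right)
    dists, _ = tree.query(left, k=1)
    return float(dists.min())


def hole_diameters(mask: LayerMask) -> tuple[float, float]:
    """(Hole-min, BDM) in um.

    The hole cavity is the set of background runs that contain the central
    column and are bounded by retinal classes on both sides, over the rows
    above the RPE level (bottom of the blue band).  Hole-min is the narrowest
    horizontal run; BDM is the run width at the deepest cavity row, i.e. the
    base of the hole at the RPE.
    """
    lab = mask.labels
    blue_rows = np.nonzero((lab == BLUE).any(axis=1))[0]
    if blue_rows.size == 0:
        raise MissingLayerError("blue band absent: RPE level undefined")
    rpe_row = int(blue_rows.max())
    center = lab.shape[1] // 2
    widths: list[tuple[int, int]] = []  # (row, width)
    for r in range(rpe_row + 1):
        row = lab[r]
        if row[center] != BACKGROUND:
            continue
        c0 = center
        while c0 > 0 and row[c0 - 1] == BACKGROUND:
            c0 -= 1
        c1 = center
        while c1 < lab.shape[1] - 1 and row[c1 + 1] == BACKGROUND:
            c1 += 1
        if c0 == 0 or c1 == lab.shape[1] - 1:
            continue  # unbounded run (vitreous), not a cavity row
        widths.append((r, c1 - c0 + 1))
    if not widths:
        raise NoHoleError("no bounded background cavity at the central column")
    hole_min = min(w for _, w in widths) * mask.pixel_pitch_x
    deepest = max(widths, key=lambda rw: rw[0])
    bdm = deepest[1] * mask.pixel_pitch_x
    return hole_min, bdm


def band_areas(mask: LayerMask, in_um2: bool = False) -> dict[str, float]:
    """Pixel counts (or um^2 with ``in_um2``) per annotated class."""
    counts = np.bincount(mask.labels.ravel(), minlength=6)
    scale = mask.pixel_pitch_x * mask.pixel_pitch_y if in_um2 else 1.0
    return {
        "Area IRF": counts[RED] * scale,
        "Area-green": counts[GREEN] * scale,
        "Area-yellow": counts[YELLOW] * scale,
        "Area-sky_blue": counts[SKY_BLUE] * scale,
        "Area-blue": counts[BLUE] * scale,
    }


# --------------------------------------------------------------------------
# Full extraction and record composition
# --------------------------------------------------------------------------

_SDL_BANDS = {
    "Green-sDL": GREEN,
    ONL_SDL: YELLOW,
    "Sky blue-sDL": SKY_BLUE,
    "Blue-sDL": BLUE,
}


def extract_morphometrics(mask: LayerMask) -> dict[str, float]:
    """All 14 base morphometric features (9 lengths + 5 areas) from one mask."""
    out: dict[str, float] = {}
    for name in ("OPL", "ELM", "EZ"):
        out[f"{name}-DL"] = defect_length(mask, name)
    for name, cls in _SDL_BANDS.items():
        out[name] = shortest_defect_length(mask, cls)
    try:
        out["Hole-min"], out["BDM"] = hole_diameters(mask)
    except NoHoleError:
        logger.info("no hole cavity found; Hole-min and BDM set to 0")
        out["Hole-min"] = out["BDM"] = 0.0
    out.update(band_areas(mask))
    return out


def compose_features(morphometrics: dict[str, float], clinical: dict) -> dict:
    """Assemble the full 41-feature record from base measurements.

    Every combination feature is computed exactly from its base features.  A
    zero ratio denominator or a non-finite base value raises
    :class:`MissingDataError`; such records mirror the study's "no missing
    data" inclusion criterion and are dropped downstream.
    """
    record: dict[str, object] = {}
    for name in CLINICAL_FEATURES:
        if name not in clinical:
            raise MissingDataError(f"clinical feature {name!r} missing")
        value = clinical[name]
        if name in CATEGORICAL_LEVELS:
            value = str(value)
            if value not in CATEGORICAL_LEVELS[name]:
                raise MissingDataError(
                    f"unknown level {value!r} for {name!r}; expected {CATEGORICAL_LEVELS[name]}"
                )
        else:
            value = float(value)
            if not math.isfinite(value):
                raise MissingDataError(f"non-finite clinical value for {name!r}")
        record[name] = value
    for name in MORPHOMETRIC_BASE:
        if name not in morphometrics:
            raise MissingDataError(f"morphometric feature {name!r} missing")
        value = float(morphometrics[name])
        if not math.isfinite(value) or value < 0:
            raise MissingDataError(f"invalid value {value} for {name!r}")
        record[name] = value
    for name, (a, b) in DIFFERENCE_FEATURES.items():
        record[name] = record[a] - record[b]
    for name, (num, den) in RATIO_FEATURES.items():
        if record[den] == 0:
            raise MissingDataError(f"zero denominator {den!r} in ratio {name!r}")
        record[name] = record[num] / record[den]
    assert len(record) == 41
    return record
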