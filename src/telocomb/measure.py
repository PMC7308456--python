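"""Calibrated telomere-length measurement.

A fiber's length in pixels is the geodesic path length along its skeleton
(unit steps for 4-neighbors, sqrt(2) for diagonals) plus a 1 px endpoint
correction; calibration converts it to microns and, through the combing
stretch factor, to kilobases. The DNA counterstain channel, when present,
classifies each telomere as terminal (at a counterstain fiber end),
interstitial (inside a fiber) or orphan (no underlying fiber).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .calibration import CalibrationConfig, to_kb
from .detect import CandidateObject
from .errors import FormatError, MeasurementError
from .io import ImagePair
from .skeleton import geodesic_length_px

TERMINAL = "terminal"
INTERSTITIAL = "interstitial"
ORPHAN = "orphan"
UNKNOWN = "unknown"

MEASUREMENT_COLUMNS = [
    "fiber_id",
    "length_px",
    "length_um",
    "length_kb",
    "terminal_status",
    "centroid_row",
    "centroid_col",
    "qc_branched",
    "qc_touches_border",
    "qc_merged_from_gaps",
]


@dataclass
class TelomereMeasurement:
    """One fiber's calibrated length and QC status."""

    fiber_id: int
    length_px: float
    length_um: float
    length_kb: float
    terminal_status: str = UNKNOWN
    centroid: tuple[float, float] = (np.nan, np.nan)
    qc_branched: bool = False
    qc_touches_border: bool = False
    qc_merged_from_gaps: bool = False

    @property
    def passes_qc(self) -> bool:
        return not (self.qc_branched or self.qc_touches_border)


@dataclass
class LengthDistribution:
    """A sample's collection of telomere lengths (kb) with provenance."""

    sample_id: str
    lengths: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.lengths.size and not (self.lengths > 0).all():
            raise MeasurementError("all lengths in a distribution must be > 0")

    @property
    def n(self) -> int:
        return int(self.lengths.size)


def measure_length_px(obj: CandidateObject, endpoint_correction: float = 1.0) -> float:
    """Skeleton geodesic length of an unbranched fiber object, in pixels.

    Raises
    ------
    MeasurementError
        If the skeleton is branched (more than two endpoints).
    """
    if obj.is_branched:
        raise MeasurementError(
            f"object {obj.label_id} has a branched skeleton "
            f"({obj.n_skeleton_endpoints} endpoints)"
        )
    return geodesic_length_px(obj.skeleton_mask(), endpoint_correction)


def counterstain_mask(channel: np.ndarray) -> np.ndarray:
    """Binarize a DNA counterstain channel (Otsu + closing)."""
    img = np.asarray(channel, dtype=float)
    if np.ptp(img) == 0:
        return np.zeros_like(img, dtype=bool)
    mask = img > threshold_otsu(img)
    return ndimage.binary_closing(mask, structure=np.ones((3, 3), dtype=bool))


def classify_terminal(
    obj: CandidateObject,
    counterstain: np.ndarray,
    tol_um: float,
    pixel_size_um: float,
) -> str:
    """Position of a telomere object relative to the counterstained fiber.

    ``terminal`` if the object overlaps a counterstain component and at
    least one of its endpoints lies within ``tol_um`` of that component's
    end; ``interstitial`` if it overlaps but both endpoints are interior;
    ``orphan`` if there is no overlap.
    """
    cs = np.asarray(counterstain, dtype=bool)
    if cs.shape != obj.image_shape:
        raise FormatError(
            f"counterstain shape {cs.shape} does not match image {obj.image_shape}"
        )
    if tol_um < 0:
        raise MeasurementError("tol_um must be >= 0")
    labels = cc_label(cs, connectivity=2)
    overlap = labels[obj.coords[:, 0], obj.coords[:, 1]]
    overlap = overlap[overlap > 0]
    if overlap.size == 0:
        return ORPHAN
    lab = int(np.bincount(overlap).argmax())
    fiber_coords = np.argwhere(labels == lab).astype(float)
    fiber_ends = _extreme_points(fiber_coords)
    tel_ends = obj.skeleton_end_coords().astype(float)
    if len(tel_ends) < 2:
        tel_ends = _extreme_points(obj.coords.astype(float))
    tol_px = tol_um / pixel_size_um
    for te in tel_ends:
        for fe in fiber_ends:
            if np.hypot(*(te - fe)) <= tol_px:
                return TERMINAL
    return INTERSTITIAL


def _extreme_points(coords: np.ndarray) -> np.ndarray:
    """Two points of a coordinate cloud with extreme projections on its
    principal axis."""
    centered = coords - coords.mean(axis=0)
    if len(coords) == 1:
        return np.array([coords[0], coords[0]])
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    t = centered @ vt[0]
    return np.array([coords[np.argmin(t)], coords[np.argmax(t)]])


def measure_scene(
    accepted: list[CandidateObject],
    image_pair: ImagePair,
    cal: CalibrationConfig,
    sample_id: str = "sample",
    terminal_only: bool = False,
    exclude_border: bool = True,
    terminal_tol_um: float = 1.0,
    provenance: dict | None = None,
) -> tuple[LengthDistribution, pd.DataFrame]:
    """Measure every accepted object; collect QC-passing lengths.

    The distribution keeps fibers that are unbranched and away from the
    image border (censored lengths are flagged, not measured into the
    distribution); ``terminal_only`` additionally restricts to telomeres at
    a counterstain fiber end. Returns the distribution and the complete
    per-fiber table, one row per accepted object.
    """
    cs_mask = None
    if image_pair.has_counterstain:
        cs_mask = counterstain_mask(image_pair.counterstain_channel)

    measurements: list[TelomereMeasurement] = []
    for obj in accepted:
        branched = obj.is_branched
        if branched:
            length_px = float(obj.skeleton_length_px)
        else:
            length_px = measure_length_px(obj)
        length_um = cal.px_to_um(length_px)
        length_kb = to_kb(length_px, cal)
        status = UNKNOWN
        if cs_mask is not None:
            status = classify_terminal(obj, cs_mask, terminal_tol_um, cal.pixel_size_um)
        measurements.append(
            TelomereMeasurement(
                fiber_id=obj.label_id,
                length_px=length_px,
                length_um=length_um,
                length_kb=length_kb,
                terminal_status=status,
                centroid=obj.centroid,
                qc_branched=branched,
                qc_touches_border=obj.touches_border,
                qc_merged_from_gaps=len(obj.merged_from) > 1,
            )
        )

    table = measurements_frame(measurements)
    kept = [
        m.length_kb
        for m in measurements
        if not m.qc_branched
        and not (exclude_border and m.qc_touches_border)
        and (not terminal_only or m.terminal_status == TERMINAL)
        and m.length_kb > 0
    ]
    dist = LengthDistribution(
        sample_id=sample_id,
        lengths=np.array(kept, dtype=float),
        provenance=dict(provenance or {}),
    )
    return dist, table


def measurements_frame(measurements: list[TelomereMeasurement]) -> pd.DataFrame:
    rows = []
    for m in measurements:
        d = dataclasses.asdict(m)
        cy, cx = d.pop("centroid")
        d["centroid_row"], d["centroid_col"] = cy, cx
        rows.append(d)
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def write_measurements(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path
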