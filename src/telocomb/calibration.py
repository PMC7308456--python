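"""Physical calibration of combed-fiber images.

Molecular combing stretches DNA at a constant, sequence-independent factor,
conventionally 2 kb of DNA per micron of combed fiber. Together with the
camera pixel size this gives an exact linear map from pixel distances to
DNA lengths in kilobases::

    length_kb = length_px * pixel_size_um * stretch_factor_kb_per_um

The combing axis is the direction fibers are stretched along; by convention
0 degrees means the image vertical (increasing row index).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError

#: Stretch factor of the vinylsilane combing surface, kb per micron.
DEFAULT_STRETCH_KB_PER_UM = 2.0

#: Default pixel size of a 40x acquisition, microns per pixel.
DEFAULT_PIXEL_SIZE_UM = 0.1625


@dataclass(frozen=True)
class CalibrationConfig:
    """Physical conversion constants for one acquisition setup.

    Parameters
    ----------
    pixel_size_um
        Microns per pixel, > 0.
    stretch_factor_kb_per_um
        Kilobases of DNA per micron of combed fiber, > 0.
    combing_axis_deg
        Direction fibers run along, degrees from the image vertical.
    """

    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    stretch_factor_kb_per_um: float = DEFAULT_STRETCH_KB_PER_UM
    combing_axis_deg: float = 0.0

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise ConfigurationError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if not self.stretch_factor_kb_per_um > 0:
            raise ConfigurationError(
                f"stretch_factor_kb_per_um must be > 0, got {self.stretch_factor_kb_per_um}"
            )

    @property
    def kb_per_px(self) -> float:
        return self.pixel_size_um * self.stretch_factor_kb_per_um

    def px_to_um(self, length_px: float) -> float:
        return length_px * self.pixel_size_um

    def um_to_kb(self, length_um: float) -> float:
        return length_um * self.stretch_factor_kb_per_um

    def kb_to_px(self, length_kb: float) -> float:
        return length_kb / self.kb_per_px


def to_kb(length_px: float, cal: CalibrationConfig) -> float:
    """Convert a pixel length to kilobases of DNA.

    Exact linear conversion ``length_px * pixel_size_um * stretch_factor``.

    Raises
    ------
    ConfigurationError
        If ``length_px`` is negative.
    """
    if length_px < 0:
        raise ConfigurationError(f"length_px must be >= 0, got {length_px}")
    return length_px * cal.kb_per_px
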