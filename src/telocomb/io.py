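"""Image and table I/O.

Images are TIFF, one or two channels; channel order is (telomere probe,
DNA counterstain). Calibration always comes from configuration, never from
TIFF metadata — resolution tags are too dialect-dependent to trust; when a
resolution tag is present and disagrees with the configured pixel size a
warning is emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import FormatError


@dataclass
class ImagePair:
    """A telomere-probe channel with an optional DNA-counterstain channel.

    Both channels are 2-D non-negative intensity arrays of identical shape;
    ``pixel_size_um`` carries the shared geometry.
    """

    telomere_channel: np.ndarray
    counterstain_channel: np.ndarray | None = None
    pixel_size_um: float = 0.1625
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        tel = np.asarray(self.telomere_channel)
        if tel.ndim != 2:
            raise FormatError(f"telomere channel must be 2-D, got shape {tel.shape}")
        self.telomere_channel = tel
        if self.counterstain_channel is not None:
            cs = np.asarray(self.counterstain_channel)
            if cs.shape != tel.shape:
                raise FormatError(
                    f"channel shapes differ: telomere {tel.shape} vs counterstain {cs.shape}"
                )
            self.counterstain_channel = cs
        if not self.pixel_size_um > 0:
            raise FormatError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.telomere_channel.shape

    @property
    def has_counterstain(self) -> bool:
        return self.counterstain_channel is not None


def write_image_pair(path: str | Path, pair: ImagePair) -> Path:
    """Write an :class:`ImagePair` as a (C, H, W) 16-bit TIFF."""
    path = Path(path)
    channels = [pair.telomere_channel]
    if pair.counterstain_channel is not None:
        channels.append(pair.counterstain_channel)
    stack = np.stack([np.clip(np.rint(c), 0, 65535).astype(np.uint16) for c in channels])
    if stack.shape[0] == 1:
        stack = stack[0]
    tifffile.imwrite(path, stack, resolution=(1e4 / pair.pixel_size_um, 1e4 / pair.pixel_size_um))
    return path


def read_image_pair(
    path: str | Path,
    pixel_size_um: float,
    counterstain_path: str | Path | None = None,
) -> ImagePair:
    """Read a 1- or 2-channel TIFF (or two single-channel TIFFs).

    Channel order in a 2-channel file is (telomere, counterstain). Intensities
    are preserved as stored. A single-channel input yields a pair without a
    counterstain channel (terminal classification is then unavailable).

    Raises
    ------
    FormatError
        More than two channels, or mismatched channel shapes.
    """
    arr = tifffile.imread(Path(path))
    _warn_on_resolution_mismatch(Path(path), pixel_size_um)
    if counterstain_path is not None:
        if arr.ndim != 2:
            raise FormatError("telomere file must be single-channel when counterstain file given")
        cs = tifffile.imread(Path(counterstain_path))
        if cs.ndim != 2:
            raise FormatError("counterstain file must be single-channel")
        return ImagePair(arr, cs, pixel_size_um)
    if arr.ndim == 2:
        return ImagePair(arr, None, pixel_size_um)
    if arr.ndim == 3:
        # accept (C, H, W) or (H, W, C) with C in {1, 2}
        if arr.shape[0] in (1, 2):
            chans = [arr[i] for i in range(arr.shape[0])]
        elif arr.shape[-1] in (1, 2):
            chans = [arr[..., i] for i in range(arr.shape[-1])]
        else:
            raise FormatError(f"expected 1 or 2 channels, got shape {arr.shape}")
        cs = chans[1] if len(chans) == 2 else None
        return ImagePair(chans[0], cs, pixel_size_um)
    raise FormatError(f"cannot interpret TIFF with shape {arr.shape}")


def _warn_on_resolution_mismatch(path: Path, pixel_size_um: float) -> None:
    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if xres is None or unit is None:
                return
            num, den = xres.value
            if num == 0 or den == 0:
                return
            # unit 3 = centimeter
            if getattr(unit.value, "value", unit.value) == 3:
                tag_px_um = 1e4 / (num / den)
                if abs(tag_px_um - pixel_size_um) / pixel_size_um > 0.01:
                    warnings.warn(
                        f"TIFF resolution tag implies {tag_px_um:.4f} um/px but configuration "
                        f"says {pixel_size_um:.4f} um/px; using the configured value",
                        stacklevel=3,
                    )
    except Exception:
        return
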