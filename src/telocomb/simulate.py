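"""Synthetic combed-DNA scene generator.

Renders ground-truthed two-channel fluorescence images that emulate
molecularly combed DNA hybridized with a telomere PNA probe:

* near-parallel straight fibers along a combing axis (small orientation
  jitter), with the telomere signal either terminal (at one end of the
  counterstained DNA fiber), interstitial (mid-fiber), or orphan (telomeric
  signal with no underlying counterstain fiber, emulating extra-chromosomal
  telomeric repeats);
* an anti-aliased line profile of configurable full-width-at-half-maximum,
  convolved with a Gaussian PSF;
* photobreaking gaps: a Poisson number of breaks along each telomere signal
  with exponentially distributed gap lengths;
* background speckle, Poisson shot noise and additive Gaussian read noise.

The geometric contract that downstream measurement relies on: before gaps
and PSF are applied, the extent of a telomere segment along its axis is
exactly ``true_length_kb / (stretch_factor * pixel_size)`` pixels, with the
extent defined between the half-maximum points of the anti-aliased profile.

Identical (spec, seed) reproduces identical pixel arrays bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .calibration import DEFAULT_PIXEL_SIZE_UM, DEFAULT_STRETCH_KB_PER_UM
from .errors import ConfigurationError, PlacementError
from .io import ImagePair

TERMINAL = "terminal"
INTERSTITIAL = "interstitial"
ORPHAN = "orphan"

GROUND_TRUTH_COLUMNS = [
    "fiber_id",
    "true_length_kb",
    "true_length_um",
    "row0",
    "col0",
    "row1",
    "col1",
    "orientation_deg",
    "terminal_status",
    "n_gaps_introduced",
    "n_crossings",
]


@dataclass(frozen=True)
class DistributionSpec:
    """Length-distribution descriptor, parameterized by its mean (and sd).

    family ``fixed`` ignores ``sd``; ``normal`` redraws non-positive values
    (truncation at zero); ``lognormal`` is parameterized so that its
    arithmetic mean equals ``mean`` and its standard deviation ``sd``
    (``sigma^2 = ln(1 + (sd/mean)^2)``, ``mu = ln(mean) - sigma^2/2``).
    """

    family: str = "lognormal"
    mean: float = 7.0
    sd: float = 3.0

    def __post_init__(self) -> None:
        if self.family not in ("fixed", "normal", "lognormal"):
            raise ConfigurationError(f"unknown distribution family {self.family!r}")
        if not self.mean > 0:
            raise ConfigurationError(f"distribution mean must be > 0, got {self.mean}")
        if self.family != "fixed" and self.sd < 0:
            raise ConfigurationError(f"distribution sd must be >= 0, got {self.sd}")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if n < 0:
            raise ConfigurationError(f"n must be >= 0, got {n}")
        if n == 0:
            return np.empty(0)
        if self.family == "fixed" or self.sd == 0:
            return np.full(n, float(self.mean))
        if self.family == "normal":
            out = rng.normal(self.mean, self.sd, size=n)
            # strictly positive lengths: redraw the non-positive tail
            for _ in range(1000):
                bad = out <= 0
                if not bad.any():
                    return out
                out[bad] = rng.normal(self.mean, self.sd, size=int(bad.sum()))
            raise ConfigurationError(
                f"normal({self.mean}, {self.sd}) produces almost no positive draws"
            )
        sigma2 = np.log1p((self.sd / self.mean) ** 2)
        mu = np.log(self.mean) - sigma2 / 2.0
        return rng.lognormal(mu, np.sqrt(sigma2), size=n)


@dataclass(frozen=True)
class NoiseSpec:
    """Camera/background noise model: constant background offset, Poisson
    shot noise on (signal + background) at ``poisson_gain`` counts per photon
    (0 disables shot noise), plus additive Gaussian read noise."""

    background: float = 100.0
    gaussian_sd: float = 8.0
    poisson_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.background < 0 or self.gaussian_sd < 0 or self.poisson_gain < 0:
            raise ConfigurationError("noise parameters must be >= 0")


@dataclass(frozen=True)
class SceneSpec:
    """Full parameterization of one synthetic scene.

    Pixel coordinates are 0-based (row, col) with rows increasing downward;
    ``combing_axis_deg = 0`` means fibers run along the image vertical.
    """

    image_height_px: int = 1024
    image_width_px: int = 1024
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    stretch_factor_kb_per_um: float = DEFAULT_STRETCH_KB_PER_UM
    combing_axis_deg: float = 0.0
    n_fibers: int = 25
    length_dist: DistributionSpec = field(default_factory=DistributionSpec)
    counterstain_length_dist: DistributionSpec = field(
        default_factory=lambda: DistributionSpec("lognormal", 150.0, 60.0)
    )
    orientation_jitter_sd_deg: float = 3.0
    fiber_width_px: float = 2.0
    psf_sigma_px: float = 0.8
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    signal_amplitude: float = 600.0
    counterstain_amplitude: float = 400.0
    photobreak_rate_per_um: float = 0.02
    gap_length_um: float = 0.4
    gap_length_max_um: float | None = None
    interstitial_fraction: float = 0.05
    orphan_fraction: float = 0.05
    speckle_density_per_px2: float = 1e-6
    speckle_amplitude: float = 300.0
    # two collinear fibers closer than the gap-closing radius plus mask
    # broadening are indistinguishable from one photobroken fiber, so
    # "well-separated" placement must clear that radius with margin
    min_separation_px: float = 25.0
    margin_px: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px < 1 or self.image_width_px < 1:
            raise ConfigurationError("image dimensions must be positive")
        if not self.pixel_size_um > 0:
            raise ConfigurationError("pixel_size_um must be > 0")
        if not self.stretch_factor_kb_per_um > 0:
            raise ConfigurationError("stretch_factor_kb_per_um must be > 0")
        if self.n_fibers < 0:
            raise ConfigurationError("n_fibers must be >= 0")
        if not self.fiber_width_px > 0:
            raise ConfigurationError("fiber_width_px must be > 0")
        if self.psf_sigma_px < 0 or self.orientation_jitter_sd_deg < 0:
            raise ConfigurationError("psf_sigma_px and orientation jitter must be >= 0")
        if self.photobreak_rate_per_um < 0 or self.gap_length_um < 0:
            raise ConfigurationError("photobreak parameters must be >= 0")
        for frac in (self.interstitial_fraction, self.orphan_fraction):
            if not 0 <= frac <= 1:
                raise ConfigurationError("fractions must be in [0, 1]")
        if self.interstitial_fraction + self.orphan_fraction > 1:
            raise ConfigurationError("interstitial_fraction + orphan_fraction must be <= 1")

    @property
    def kb_per_px(self) -> float:
        return self.pixel_size_um * self.stretch_factor_kb_per_um

    def replace(self, **kw) -> "SceneSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruthRecord:
    """Per-fiber ground truth: the quantity the pipeline tries to recover."""

    fiber_id: int
    true_length_kb: float
    true_length_um: float
    row0: float
    col0: float
    row1: float
    col1: float
    orientation_deg: float
    terminal_status: str
    n_gaps_introduced: int
    n_crossings: int = 0

    @property
    def endpoints(self) -> np.ndarray:
        return np.array([[self.row0, self.col0], [self.row1, self.col1]])

    @property
    def midpoint(self) -> np.ndarray:
        return np.array([(self.row0 + self.row1) / 2.0, (self.col0 + self.col1) / 2.0])


def sample_lengths(spec: DistributionSpec, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` strictly positive lengths (kb) from a distribution spec."""
    return spec.sample(np.random.default_rng(seed), n)


# ---------------------------------------------------------------------------
# geometry helpers


def _segment_distance(a0, a1, b0, b1) -> float:
    """Minimum distance between two 2-D segments."""

    def pt_seg(p, s0, s1):
        d = s1 - s0
        L2 = float(d @ d)
        if L2 == 0:
            return float(np.hypot(*(p - s0)))
        t = np.clip(float((p - s0) @ d) / L2, 0.0, 1.0)
        return float(np.hypot(*(p - (s0 + t * d))))

    def intersects(p, p2, q, q2):
        def orient(a, b, c):
            return np.sign((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))

        return (
            orient(p, p2, q) != orient(p, p2, q2)
            and orient(q, q2, p) != orient(q, q2, p2)
        )

    if intersects(a0, a1, b0, b1):
        return 0.0
    return min(
        pt_seg(a0, b0, b1), pt_seg(a1, b0, b1), pt_seg(b0, a0, a1), pt_seg(b1, a0, a1)
    )


def _render_segment(
    canvas: np.ndarray,
    p0: np.ndarray,
    direction: np.ndarray,
    length_px: float,
    width_px: float,
    amplitude: float,
    gaps_px: list[tuple[float, float]] | None = None,
) -> None:
    """Add an anti-aliased segment to ``canvas`` in place.

    The along-axis extent between half-maximum points is exactly
    ``length_px``; the across-axis full width at half maximum is
    ``width_px``. ``gaps_px`` are (start, stop) intervals of the along-axis
    coordinate where the signal is suppressed (anti-aliased as well).
    """
    h, w = canvas.shape
    p1 = p0 + direction * length_px
    pad = width_px / 2.0 + 2.0
    r_lo = max(int(np.floor(min(p0[0], p1[0]) - pad)), 0)
    r_hi = min(int(np.ceil(max(p0[0], p1[0]) + pad)) + 1, h)
    c_lo = max(int(np.floor(min(p0[1], p1[1]) - pad)), 0)
    c_hi = min(int(np.ceil(max(p0[1], p1[1]) + pad)) + 1, w)
    if r_lo >= r_hi or c_lo >= c_hi:
        return
    rr, cc = np.meshgrid(
        np.arange(r_lo, r_hi, dtype=float), np.arange(c_lo, c_hi, dtype=float), indexing="ij"
    )
    dr = rr - p0[0]
    dc = cc - p0[1]
    t = dr * direction[0] + dc * direction[1]
    dperp = np.abs(dr * -direction[1] + dc * direction[0])
    along = np.clip(np.minimum(t, length_px - t) + 0.5, 0.0, 1.0)
    across = np.clip(width_px / 2.0 + 0.5 - dperp, 0.0, 1.0)
    profile = along * across
    if gaps_px:
        for a, b in gaps_px:
            gap = np.clip(np.minimum(t - a, b - t) + 0.5, 0.0, 1.0)
            profile = profile * (1.0 - gap)
    canvas[r_lo:r_hi, c_lo:c_hi] += amplitude * profile


def _place_segment(
    rng: np.random.Generator,
    spec: SceneSpec,
    direction: np.ndarray,
    length_px: float,
    tel_offset_px: float,
    tel_length_px: float,
    existing_signals: list[tuple[np.ndarray, np.ndarray]],
    label: str,
    max_tries: int = 300,
) -> tuple[np.ndarray, int]:
    """Pick a start point so the whole fiber is in bounds, preferring
    positions whose *telomere signal* (the sub-segment starting at
    ``tel_offset_px``) keeps at least ``min_separation_px`` from previously
    placed signals — counterstain molecules may share a lane, but the
    probe signals the detector sees should be resolvable. Returns
    (start point, number of signals the new one still comes close to)."""
    h, w = spec.image_height_px, spec.image_width_px
    m = spec.margin_px
    lo = np.array([m, m])
    hi = np.array([h - 1 - m, w - 1 - m])
    disp = direction * length_px
    s_lo = np.maximum(lo, lo - disp)
    s_hi = np.minimum(hi, hi - disp)
    if np.any(s_hi < s_lo):
        raise PlacementError(
            f"{label}: fiber of {length_px:.1f} px cannot fit inside a "
            f"{h}x{w} image with margin {m}"
        )
    best = None
    for _ in range(max_tries):
        p0 = s_lo + rng.random(2) * (s_hi - s_lo)
        t0 = p0 + direction * tel_offset_px
        t1 = t0 + direction * tel_length_px
        n_close = sum(
            1
            for (q0, q1) in existing_signals
            if _segment_distance(t0, t1, q0, q1) < spec.min_separation_px
        )
        if n_close == 0:
            return p0, 0
        if best is None or n_close < best[1]:
            best = (p0, n_close)
    return best  # crossing/near signals permitted; caller records the count


# ---------------------------------------------------------------------------
# scene rendering


def render_scene(spec: SceneSpec) -> tuple[ImagePair, list[GroundTruthRecord]]:
    """Render a synthetic two-channel scene with per-fiber ground truth.

    The telomere channel holds one bright segment per non-orphan fiber (plus
    orphan telomere signals); the counterstain channel holds the full DNA
    fiber for every non-orphan record. PSF blur, photobreak gaps, speckle
    and noise are applied after the geometry is laid down.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height_px, spec.image_width_px
    tel = np.zeros((h, w), dtype=float)
    cs = np.zeros((h, w), dtype=float)

    px_per_um = 1.0 / spec.pixel_size_um
    kb_per_px = spec.kb_per_px

    tel_kb = spec.length_dist.sample(rng, spec.n_fibers)
    cs_kb = spec.counterstain_length_dist.sample(rng, spec.n_fibers)
    status_u = rng.random(spec.n_fibers)

    records: list[GroundTruthRecord] = []
    placed: list[tuple[np.ndarray, np.ndarray]] = []
    for i in range(spec.n_fibers):
        if status_u[i] < spec.orphan_fraction:
            status = ORPHAN
        elif status_u[i] < spec.orphan_fraction + spec.interstitial_fraction:
            status = INTERSTITIAL
        else:
            status = TERMINAL

        theta = np.deg2rad(
            spec.combing_axis_deg + rng.normal(0.0, spec.orientation_jitter_sd_deg)
        )
        direction = np.array([np.cos(theta), np.sin(theta)])  # (drow, dcol)

        L_tel_px = tel_kb[i] / kb_per_px
        if status == ORPHAN:
            L_total_px = L_tel_px
        else:
            total_kb = max(cs_kb[i], 1.5 * tel_kb[i])
            # counterstain context fibers are clipped to what fits on screen
            # (but never below the telomere itself)
            extent_r = (
                (h - 1 - 2 * spec.margin_px) / abs(direction[0]) if direction[0] else np.inf
            )
            extent_c = (
                (w - 1 - 2 * spec.margin_px) / abs(direction[1]) if direction[1] else np.inf
            )
            # small back-off keeps the clipped extent strictly feasible
            # under floating-point rounding in the placement bounds
            feasible_px = min(extent_r, extent_c) * (1.0 - 1e-6)
            L_total_px = min(total_kb / kb_per_px, max(feasible_px, L_tel_px))
        if L_tel_px > np.hypot(h, w):
            raise PlacementError(
                f"fiber {i}: telomere draw of {tel_kb[i]:.2f} kb "
                f"({L_tel_px:.0f} px) exceeds the image diagonal"
            )

        # telomere sub-segment within the DNA fiber
        if status == ORPHAN:
            t_start = 0.0
        elif status == TERMINAL:
            t_start = 0.0 if rng.random() < 0.5 else L_total_px - L_tel_px
        else:  # interstitial: strictly interior with a one-telomere margin min
            slack = L_total_px - L_tel_px
            t_start = slack * (0.2 + 0.6 * rng.random())

        p0, n_cross = _place_segment(
            rng, spec, direction, L_total_px, t_start, L_tel_px, placed, f"fiber {i}"
        )
        tel_p0 = p0 + direction * t_start
        tel_p1 = tel_p0 + direction * L_tel_px
        placed.append((tel_p0, tel_p1))

        # photobreak gaps along the telomere signal
        L_tel_um = L_tel_px * spec.pixel_size_um
        n_breaks = int(rng.poisson(spec.photobreak_rate_per_um * L_tel_um))
        gaps: list[tuple[float, float]] = []
        for _ in range(n_breaks):
            center = rng.random() * L_tel_px
            g_um = rng.exponential(spec.gap_length_um) if spec.gap_length_um > 0 else 0.0
            if spec.gap_length_max_um is not None:
                g_um = min(g_um, spec.gap_length_max_um)
            g_px = g_um * px_per_um
            a, b = center - g_px / 2.0, center + g_px / 2.0
            if b > 0.5 and a < L_tel_px - 0.5 and b > a:
                gaps.append((max(a, 0.0), min(b, L_tel_px)))

        _render_segment(
            tel, tel_p0, direction, L_tel_px, spec.fiber_width_px, spec.signal_amplitude, gaps
        )
        if status != ORPHAN:
            _render_segment(
                cs, p0, direction, L_total_px, spec.fiber_width_px, spec.counterstain_amplitude
            )

        orientation_deg = float(np.rad2deg(theta))
        if orientation_deg > 90:
            orientation_deg -= 180
        elif orientation_deg <= -90:
            orientation_deg += 180
        records.append(
            GroundTruthRecord(
                fiber_id=i,
                true_length_kb=float(tel_kb[i]),
                true_length_um=float(tel_kb[i] / spec.stretch_factor_kb_per_um),
                row0=float(tel_p0[0]),
                col0=float(tel_p0[1]),
                row1=float(tel_p1[0]),
                col1=float(tel_p1[1]),
                orientation_deg=orientation_deg,
                terminal_status=status,
                n_gaps_introduced=len(gaps),
                n_crossings=n_cross,
            )
        )

    # background speckle: small roundish debris in the telomere channel
    n_speckle = int(rng.poisson(spec.speckle_density_per_px2 * h * w))
    for _ in range(n_speckle):
        pos = rng.random(2) * [h - 1, w - 1]
        amp = spec.speckle_amplitude * (0.3 + 0.7 * rng.random())
        sig = 1.0 + rng.random()
        r_lo, r_hi = max(int(pos[0] - 4 * sig), 0), min(int(pos[0] + 4 * sig) + 1, h)
        c_lo, c_hi = max(int(pos[1] - 4 * sig), 0), min(int(pos[1] + 4 * sig) + 1, w)
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        rr, cc = np.meshgrid(np.arange(r_lo, r_hi), np.arange(c_lo, c_hi), indexing="ij")
        tel[r_lo:r_hi, c_lo:c_hi] += amp * np.exp(
            -((rr - pos[0]) ** 2 + (cc - pos[1]) ** 2) / (2 * sig**2)
        )

    if spec.psf_sigma_px > 0:
        tel = gaussian_filter(tel, spec.psf_sigma_px)
        cs = gaussian_filter(cs, spec.psf_sigma_px)

    tel = _apply_noise(tel, spec.noise, rng)
    cs = _apply_noise(cs, spec.noise, rng)

    pair = ImagePair(tel, cs, spec.pixel_size_um, meta={"seed": spec.seed})
    return pair, records


def _apply_noise(img: np.ndarray, noise: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    signal = img + noise.background
    if noise.poisson_gain > 0:
        signal = rng.poisson(signal * noise.poisson_gain) / noise.poisson_gain
    if noise.gaussian_sd > 0:
        signal = signal + rng.normal(0.0, noise.gaussian_sd, size=signal.shape)
    return np.clip(np.rint(signal), 0, 65535).astype(np.uint16)


# ---------------------------------------------------------------------------
# ground-truth tables


def ground_truth_frame(records: list[GroundTruthRecord]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    return pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)


def write_ground_truth(records: list[GroundTruthRecord], path: str | Path) -> Path:
    """Write per-fiber truth as CSV (header-only when empty); lossless
    round-trip via :func:`read_ground_truth`."""
    path = Path(path)
    ground_truth_frame(records).to_csv(path, index=False, float_format=lambda x: repr(float(x)))
    return path


def read_ground_truth(path: str | Path) -> list[GroundTruthRecord]:
    df = pd.read_csv(Path(path), float_precision="round_trip")
    records = []
    for _, row in df.iterrows():
        records.append(
            GroundTruthRecord(
                fiber_id=int(row["fiber_id"]),
                true_length_kb=float(row["true_length_kb"]),
                true_length_um=float(row["true_length_um"]),
                row0=float(row["row0"]),
                col0=float(row["col0"]),
                row1=float(row["row1"]),
                col1=float(row["col1"]),
                orientation_deg=float(row["orientation_deg"]),
                terminal_status=str(row["terminal_status"]),
                n_gaps_introduced=int(row["n_gaps_introduced"]),
                n_crossings=int(row["n_crossings"]),
            )
        )
    return records
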