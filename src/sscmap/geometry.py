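"""Radiometric calibration and shape-aware correction of hyperspectral cubes.

Supports four correction modes on raw intensity cubes: plain reflectance
calibration, inverse-square height correction (closed-form or via a white
reference measured at several heights), Lambertian cosine angle correction,
and the combined height+angle chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

CORRECTION_MODES = ("none", "height", "angle", "height_angle")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class HyperCube:
    """A hyperspectral image cube: scan rows x detector columns x bands.

    ``kind`` tracks whether values are raw detector counts or calibrated
    relative reflectance; ``dark_subtracted`` marks intensity cubes that have
    already had the dark reference removed by a correction stage.
    """

    values: np.ndarray          # (rows, cols, bands)
    wavelengths: np.ndarray     # (bands,) nm, strictly increasing
    kind: str = "intensity"     # intensity | reflectance
    scan_mode: str = "line"     # line | rotation
    dark_subtracted: bool = False
    correction: str = "none"    # which geometric correction has been applied
    pixel_pitch_mm: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("cube values must be 3D (rows, cols, bands)")
        if self.values.shape[2] != self.wavelengths.size:
            raise ValueError("band axis length does not match wavelength axis")
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind not in ("intensity", "reflectance"):
            raise ValueError(f"unknown cube kind {self.kind!r}")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the band nearest ``wavelength_nm``.

        Raises if the requested wavelength falls outside the axis by more
        than one band spacing.
        """
        wl = self.wavelengths
        idx = int(np.argmin(np.abs(wl - wavelength_nm)))
        spacing = np.median(np.diff(wl)) if wl.size > 1 else np.inf
        if abs(wl[idx] - wavelength_nm) > spacing:
            raise ValueError(
                f"wavelength {wavelength_nm} nm outside axis "
                f"[{wl[0]}, {wl[-1]}] by more than one band spacing"
            )
        return idx

    def subset_bands(self, indices: np.ndarray) -> "HyperCube":
        return replace(
            self,
            values=self.values[:, :, indices],
            wavelengths=self.wavelengths[indices],
        )


@dataclass
class DarkReference:
    """Dark-current reference, one spectrum per detector column."""

    values: np.ndarray  # (cols, bands)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("dark reference must be 2D (cols, bands)")


@dataclass
class WhiteReference:
    """White-panel reference: single height or a stack of heights.

    2D values are (cols, bands); 3D values are (heights, cols, bands) with
    ``heights_mm`` giving the strictly increasing measurement heights.
    """

    values: np.ndarray
    heights_mm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (2, 3):
            raise ValueError("white reference must be 2D or 3D")
        if self.values.ndim == 3:
            if self.heights_mm is None:
                raise ValueError("white stack requires heights_mm")
            self.heights_mm = np.asarray(self.heights_mm, dtype=float)
            if self.heights_mm.size != self.values.shape[0]:
                raise ValueError("heights_mm length must match stack depth")
            if self.heights_mm.size > 1 and not np.all(np.diff(self.heights_mm) > 0):
                raise ValueError("stack heights must be strictly increasing")

    @property
    def is_stack(self) -> bool:
        return self.values.ndim == 3


@dataclass
class HeightMap:
    """Per-pixel surface height in mm; the white-panel plane is 0."""

    values: np.ndarray  # (rows, cols)
    pixel_pitch_mm: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("height map must be 2D")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel_pitch_mm must be positive")


@dataclass
class GeometryParams:
    """Source/detector geometry and correction options.

    ``height_sign`` may be set to -1 for instruments whose height axis points
    the opposite way from the printed convention.
    """

    H1_mm: float = 100.0
    H2_mm: float = 200.0
    k_correction_mode: str = "none"
    cos_floor: float = 0.2
    height_sign: float = 1.0
    angle_mode: str = "width"  # width | full

    def __post_init__(self) -> None:
        if self.H1_mm <= 0 or self.H2_mm <= 0:
            raise ValueError("H1_mm and H2_mm must be positive")
        if not (0.0 < self.cos_floor < 1.0):
            raise ValueError("cos_floor must lie in (0, 1)")
        if self.k_correction_mode not in CORRECTION_MODES:
            raise ValueError(f"unknown correction mode {self.k_correction_mode!r}")


@dataclass
class AngleMap:
    """Angle between the surface normal and vertical, radians in [0, pi/2]."""

    theta: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)

    @property
    def cos(self) -> np.ndarray:
        return np.cos(self.theta)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def align_height_to_cube(height: HeightMap, cube: HyperCube) -> HeightMap:
    """Resample a height map onto the cube's spatial grid.

    Linear interpolation at output cell centres, assuming both grids span
    the same physical extent.
    """
    src = height.values
    rows, cols = cube.n_rows, cube.n_cols
    if src.shape == (rows, cols):
        return height
    # Map output cell centres into source index coordinates over a shared extent.
    ri = (np.arange(rows) + 0.5) * src.shape[0] / rows - 0.5
    ci = (np.arange(cols) + 0.5) * src.shape[1] / cols - 0.5
    rr, cc = np.meshgrid(ri, ci, indexing="ij")
    out = ndimage.map_coordinates(src, [rr, cc], order=1, mode="nearest")
    pitch = height.pixel_pitch_mm * src.shape[1] / cols
    return HeightMap(values=out, pixel_pitch_mm=pitch)


def compute_reflectance(
    cube: HyperCube, white: WhiteReference, dark: DarkReference
) -> HyperCube:
    """Relative reflectance R = (I - D) / (W - D) per column and band.

    If the cube has already been dark-subtracted by a correction stage the
    numerator is used as-is (R' = I' / (W - D)).
    """
    if cube.kind != "intensity":
        raise ValueError("compute_reflectance expects an intensity cube")
    if white.is_stack:
        raise ValueError("single-height white reference required; interpolate first")
    w_minus_d = white.values - dark.values  # (cols, bands)
    bad = w_minus_d <= 0
    if np.any(bad):
        col, band = np.argwhere(bad)[0]
        raise ValueError(
            f"white minus dark is non-positive at column {col}, band {band}"
        )
    if cube.dark_subtracted:
        numer = cube.values
    else:
        numer = cube.values - dark.values[np.newaxis, :, :]
    refl = numer / w_minus_d[np.newaxis, :, :]
    return replace(cube, values=refl, kind="reflectance", dark_subtracted=False)


def height_factor(Hs_mm, params: GeometryParams):
    """Inverse-square correction factor ((H1+Hs)/H1)^2 * ((H2+Hs)/H2)^2."""
    Hs = np.asarray(Hs_mm, dtype=float) * params.height_sign
    h1 = params.H1_mm + Hs
    h2 = params.H2_mm + Hs
    if np.any(h1 <= 0) or np.any(h2 <= 0):
        raise ValueError("degenerate source/detector distance (H + Hs <= 0)")
    factor = (h1 / params.H1_mm) ** 2 * (h2 / params.H2_mm) ** 2
    if np.isscalar(Hs_mm):
        return float(factor)
    return factor


def height_correct_intensity(
    cube: HyperCube,
    dark: DarkReference,
    height: HeightMap,
    params: GeometryParams,
) -> HyperCube:
    """I'_h = (I - D) * height_factor(Hs), per pixel."""
    if cube.kind != "intensity":
        raise ValueError("height correction applies to intensity cubes")
    if height.values.shape != (cube.n_rows, cube.n_cols):
        raise ValueError("height map not aligned to cube grid")
    factor = height_factor(height.values, params)
    numer = cube.values if cube.dark_subtracted else cube.values - dark.values[np.newaxis]
    out = numer * factor[:, :, np.newaxis]
    return replace(cube, values=out, dark_subtracted=True, correction="height")


def interpolated_white(white_stack: WhiteReference, Hs_mm) -> np.ndarray:
    """White-reference spectra at height(s) Hs by linear interpolation.

    Clamped at the ends of the measured height range. For scalar Hs returns
    a (cols, bands) array; for a 2D height map returns (rows, cols, bands).
    """
    if not white_stack.is_stack:
        raise ValueError("a white-reference stack is required")
    heights = white_stack.heights_mm
    stack = white_stack.values  # (nh, cols, bands)
    Hs = np.asarray(Hs_mm, dtype=float)
    hs_clamped = np.clip(Hs, heights[0], heights[-1])
    # fractional position along the height knots
    pos = np.interp(hs_clamped, heights, np.arange(heights.size))
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, heights.size - 1)
    frac = pos - lo
    if Hs.ndim == 0:
        return (1 - frac) * stack[int(lo)] + frac * stack[int(hi)]
    if Hs.ndim == 2:
        # per-pixel height map: column c of the output interpolates the
        # stack's column c only
        col = np.arange(stack.shape[1])[np.newaxis, :]
        lo_w = stack[lo, col, :]
        hi_w = stack[hi, col, :]
        return (1 - frac)[..., np.newaxis] * lo_w + frac[..., np.newaxis] * hi_w
    out = (1 - frac)[..., np.newaxis] * stack[lo] + frac[..., np.newaxis] * stack[hi]
    return out


def height_correct_reflectance_interpolated(
    cube: HyperCube,
    dark: DarkReference,
    white_stack: WhiteReference,
    height: HeightMap,
) -> HyperCube:
    """Height-corrected reflectance using a per-pixel interpolated white.

    Each pixel is calibrated against the white-panel spectrum interpolated at
    that pixel's height, rather than the closed-form inverse-square factor.
    """
    if cube.kind != "intensity":
        raise ValueError("expects an intensity cube")
    w = interpolated_white(white_stack, height.values)  # (rows, cols, bands)
    w_minus_d = w - dark.values[np.newaxis]
    if np.any(w_minus_d <= 0):
        raise ValueError("interpolated white minus dark non-positive")
    numer = cube.values if cube.dark_subtracted else cube.values - dark.values[np.newaxis]
    refl = numer / w_minus_d
    return replace(cube, values=refl, kind="reflectance", dark_subtracted=False,
                   correction="height")


def surface_angle(
    height: HeightMap, mode: str = "width"
) -> AngleMap:
    """Surface tilt from the height map.

    ``width`` mode (default) uses the gradient along the detector-width axis
    only: theta = arctan(|dHs/dx_width|). ``full`` mode uses the magnitude of
    the full 2D gradient. Central differences with edge replication, scaled
    by the physical pixel pitch.
    """
    h = height.values
    pitch = height.pixel_pitch_mm
    if mode == "width":
        if h.shape[1] < 3:
            raise ValueError("width-only angle mode needs grid width >= 3")
        grad = np.gradient(h, pitch, axis=1)
        theta = np.arctan(np.abs(grad))
    elif mode == "full":
        gr = np.gradient(h, pitch, axis=0)
        gc = np.gradient(h, pitch, axis=1)
        theta = np.arctan(np.hypot(gr, gc))
    else:
        raise ValueError(f"unknown angle mode {mode!r}")
    return AngleMap(theta=theta)


def angle_correct_intensity(
    cube: HyperCube,
    dark: DarkReference,
    theta: AngleMap,
    params: GeometryParams,
) -> HyperCube:
    """Lambertian correction I'_a = (I - D) / cos(theta).

    Pixels with cos(theta) below ``params.cos_floor`` are masked (NaN) rather
    than divided; the masked fraction is reported via a warning.
    """
    if cube.kind != "intensity":
        raise ValueError("angle correction applies to intensity cubes")
    cos_t = theta.cos
    if cos_t.shape != (cube.n_rows, cube.n_cols):
        raise ValueError("angle map not aligned to cube grid")
    numer = cube.values if cube.dark_subtracted else cube.values - dark.values[np.newaxis]
    usable = cos_t >= params.cos_floor
    divisor = np.where(usable, cos_t, np.nan)
    out = numer / divisor[:, :, np.newaxis]
    n_masked = int((~usable).sum())
    if n_masked:
        warnings.warn(
            f"angle correction masked {n_masked} pixels below "
            f"cos_floor={params.cos_floor}",
            stacklevel=2,
        )
    return replace(cube, values=out, dark_subtracted=True, correction="angle")


def combined_correct(
    cube: HyperCube,
    dark: DarkReference,
    height: HeightMap,
    theta: AngleMap,
    params: GeometryParams,
) -> HyperCube:
    """Height then angle correction on the intensity stage."""
    h_corr = height_correct_intensity(cube, dark, height, params)
    out = angle_correct_intensity(h_corr, dark, theta, params)
    return replace(out, correction="height_angle")


def correct_cube(
    cube: HyperCube,
    dark: DarkReference,
    white: WhiteReference,
    height: HeightMap | None,
    params: GeometryParams,
    mode: str,
) -> HyperCube:
    """Full correction chain for one mode, ending in a reflectance cube."""
    if mode not in CORRECTION_MODES:
        raise ValueError(f"unknown correction mode {mode!r}")
    if mode == "none":
        corrected = cube
    elif mode == "height":
        if white.is_stack:
            if height is None:
                raise ValueError("height mode requires a height map")
            return height_correct_reflectance_interpolated(cube, dark, white, height)
        corrected = height_correct_intensity(cube, dark, height, params)
    elif mode == "angle":
        theta = surface_angle(height, mode=params.angle_mode)
        corrected = angle_correct_intensity(cube, dark, theta, params)
    else:  # height_angle
        theta = surface_angle(height, mode=params.angle_mode)
        corrected = combined_correct(cube, dark, height, theta, params)
    white_single = white
    if white.is_stack:
        white_single = WhiteReference(values=interpolated_white(white, 0.0))
    refl = compute_reflectance(corrected, white_single, dark)
    return replace(refl, correction=mode)
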