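"""Synthetic fruit-like hyperspectral scenes with known ground truth.

The forward model applies exactly the distortions the correction chain is
built to invert: Lambertian cosine fall-off from surface tilt, inverse-square
attenuation from surface height, dark offset, white-reference scaling, and
additive detector noise. Gaussian absorption features are imprinted on a
smooth reflectance baseline; the depths of the sugar-related features scale
linearly with the local soluble-solids content so a regression model can
recover the SSC field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    DarkReference,
    GeometryParams,
    HeightMap,
    HyperCube,
    WhiteReference,
    height_factor,
    surface_angle,
)

DEFAULT_ABSORPTION_CENTERS_NM = (970.0, 1165.0, 1420.0, 1780.0, 1900.0)
# widths keep each feature's reflectance minimum at its own center despite
# the overlapping tails of the broad water bands
DEFAULT_ABSORPTION_WIDTHS_NM = (30.0, 40.0, 50.0, 25.0, 40.0)
DEFAULT_ABSORPTION_STRENGTHS = (0.30, 0.15, 0.35, 0.18, 0.45)
# indices of the sugar-related (C-H) features whose depth follows SSC
SUGAR_FEATURE_INDICES = (1, 3)
SSC_REFERENCE_BRIX = 10.0


@dataclass
class PhantomConfig:
    """Parameters of a synthetic scene."""

    shape_mode: str = "ellipsoid"  # flat_disc | ellipsoid
    semi_axes_mm: tuple[float, float, float] = (18.0, 14.0, 12.0)
    pixel_pitch_mm: float = 1.0
    grid_shape: tuple[int, int] = (48, 48)
    wavelength_axis: np.ndarray = field(
        default_factory=lambda: np.linspace(913.0, 2166.0, 200)
    )
    ssc_apex_brix: float = 11.0
    ssc_base_brix: float = 8.0
    absorption_centers_nm: tuple[float, ...] = DEFAULT_ABSORPTION_CENTERS_NM
    absorption_widths_nm: tuple[float, ...] = DEFAULT_ABSORPTION_WIDTHS_NM
    absorption_strengths: tuple[float, ...] = DEFAULT_ABSORPTION_STRENGTHS
    ssc_coupling: float = 0.012
    achene_density: float = 0.03
    noise_sd: float = 0.0
    baseline_tilt_sd: float = 0.0
    dark_level: float = 1000.0
    white_level: float = 9000.0
    H1_mm: float = 100.0
    H2_mm: float = 200.0
    angle_mode: str = "width"
    seed: int = 0

    def __post_init__(self) -> None:
        self.wavelength_axis = np.asarray(self.wavelength_axis, dtype=float)
        if not np.all(np.isfinite(self.wavelength_axis)):
            raise ValueError("non-finite wavelength axis")
        if self.wavelength_axis.size > 1 and not np.all(
            np.diff(self.wavelength_axis) > 0
        ):
            raise ValueError("wavelength_axis must be strictly increasing")
        for name in ("ssc_apex_brix", "ssc_base_brix"):
            v = getattr(self, name)
            if not (0.0 <= v <= 30.0):
                raise ValueError(f"{name}={v} outside [0, 30] Brix")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.achene_density <= 1.0):
            raise ValueError("achene_density must lie in [0, 1]")
        if self.shape_mode not in ("flat_disc", "ellipsoid"):
            raise ValueError(f"unknown shape_mode {self.shape_mode!r}")
        if len(self.absorption_centers_nm) != len(self.absorption_widths_nm) or len(
            self.absorption_centers_nm
        ) != len(self.absorption_strengths):
            raise ValueError("absorption parameter tuples must share one length")
        half_r = self.grid_shape[0] * self.pixel_pitch_mm / 2
        half_c = self.grid_shape[1] * self.pixel_pitch_mm / 2
        if self.semi_axes_mm[0] >= half_r or self.semi_axes_mm[1] >= half_c:
            raise ValueError("grid too small to contain the fruit silhouette")


@dataclass
class PhantomScene:
    """A generated scene plus its ground truth."""

    cube: HyperCube
    height: HeightMap
    white: WhiteReference
    dark: DarkReference
    true_reflectance: np.ndarray  # (rows, cols, bands)
    true_ssc_map: np.ndarray      # (rows, cols), NaN outside silhouette
    achene_mask: np.ndarray       # bool (rows, cols)
    flesh_mask: np.ndarray        # bool (rows, cols)
    config: PhantomConfig = None
    sample_id: str = "phantom-0"

    @property
    def silhouette(self) -> np.ndarray:
        return self.flesh_mask | self.achene_mask

    @property
    def geometry_params(self) -> GeometryParams:
        return GeometryParams(
            H1_mm=self.config.H1_mm,
            H2_mm=self.config.H2_mm,
            angle_mode=self.config.angle_mode,
        )


@dataclass
class SSCRecord:
    """One reference Brix measurement for a fruit section."""

    sample_id: str
    section: str  # top | bottom
    brix: float


def _absorbance(
    wavelengths: np.ndarray,
    ssc: np.ndarray,
    config: PhantomConfig,
) -> np.ndarray:
    """Summed Gaussian absorbance per pixel; sugar feature depths follow SSC.

    ``ssc`` is (n_pixels,); result is (n_pixels, n_bands).
    """
    total = np.zeros((ssc.size, wavelengths.size))
    for i, (c, w, s) in enumerate(
        zip(
            config.absorption_centers_nm,
            config.absorption_widths_nm,
            config.absorption_strengths,
        )
    ):
        profile = np.exp(-((wavelengths - c) ** 2) / (2 * w**2))
        if i in SUGAR_FEATURE_INDICES:
            depth = s + config.ssc_coupling * (ssc - SSC_REFERENCE_BRIX)
            depth = np.clip(depth, 0.0, None)
        else:
            depth = np.full(ssc.size, s)
        total += depth[:, np.newaxis] * profile[np.newaxis, :]
    return total


def make_phantom(config: PhantomConfig) -> PhantomScene:
    """Generate one deterministic scene from a config.

    Measured counts per pixel and band:
        I = D + (W - D) * R_true * cos(theta) / g(Hs) + noise
    where theta comes from the generated height map exactly as the correction
    chain will recompute it, and g is the inverse-square height factor.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.grid_shape
    wl = config.wavelength_axis
    pitch = config.pixel_pitch_mm

    # surface geometry
    rr = (np.arange(rows) - (rows - 1) / 2) * pitch
    cc = (np.arange(cols) - (cols - 1) / 2) * pitch
    ry, cx = np.meshgrid(rr, cc, indexing="ij")
    a, b, c_ax = config.semi_axes_mm
    inside = (ry / a) ** 2 + (cx / b) ** 2 < 1.0
    if not inside.any():
        raise ValueError("fruit silhouette does not intersect the grid")
    if config.shape_mode == "flat_disc":
        height_vals = np.zeros((rows, cols))
    else:
        arg = np.clip(1.0 - (ry / a) ** 2 - (cx / b) ** 2, 0.0, None)
        height_vals = c_ax * np.sqrt(arg)
    height = HeightMap(values=height_vals, pixel_pitch_mm=pitch)
    theta = surface_angle(height, mode=config.angle_mode)
    cos_t = theta.cos

    # SSC field: apex at row 0, linear gradient toward the base row
    frac = np.linspace(0.0, 1.0, rows)[:, np.newaxis] * np.ones((1, cols))
    ssc_field = config.ssc_apex_brix + frac * (
        config.ssc_base_brix - config.ssc_apex_brix
    )
    true_ssc_map = np.where(inside, ssc_field, np.nan)

    # achene speckles inside the silhouette
    achene_mask = inside & (rng.random((rows, cols)) < config.achene_density)
    flesh_mask = inside & ~achene_mask

    # true reflectance
    baseline = 0.78 - 1.0e-4 * (wl - wl[0])
    if config.baseline_tilt_sd > 0:
        tilt = rng.normal(0.0, config.baseline_tilt_sd)
        span = (wl - wl.mean()) / (wl[-1] - wl[0])
        baseline = baseline * (1.0 + tilt * span)
    true_reflectance = np.full((rows, cols, wl.size), 0.05)
    flesh_idx = np.where(flesh_mask)
    absorb = _absorbance(wl, ssc_field[flesh_idx], config)
    true_reflectance[flesh_idx] = baseline[np.newaxis, :] * np.exp(-absorb)
    true_reflectance[achene_mask] = 0.92  # flat, bright achene signature

    # references
    dark = DarkReference(values=np.full((cols, wl.size), config.dark_level))
    white = WhiteReference(values=np.full((cols, wl.size), config.white_level))

    # forward model
    params = GeometryParams(
        H1_mm=config.H1_mm, H2_mm=config.H2_mm, angle_mode=config.angle_mode
    )
    g = height_factor(height.values, params)
    w_minus_d = config.white_level - config.dark_level
    signal = (
        w_minus_d
        * true_reflectance
        * cos_t[:, :, np.newaxis]
        / g[:, :, np.newaxis]
    )
    intensity = config.dark_level + signal
    if config.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, config.noise_sd, intensity.shape)
    cube = HyperCube(
        values=intensity,
        wavelengths=wl,
        kind="intensity",
        pixel_pitch_mm=pitch,
    )
    return PhantomScene(
        cube=cube,
        height=height,
        white=white,
        dark=dark,
        true_reflectance=true_reflectance,
        true_ssc_map=true_ssc_map,
        achene_mask=achene_mask,
        flesh_mask=flesh_mask,
        config=config,
        sample_id=f"phantom-{config.seed}",
    )


def make_reference_table(scene: PhantomScene) -> list[SSCRecord]:
    """Top/bottom mean true SSC over the flesh mask, one record per half.

    The split row is the flesh-mask row centroid; the apex half is rows
    above it.
    """
    mask = scene.flesh_mask
    if not mask.any():
        raise ValueError("empty flesh mask")
    rows_idx = np.where(mask.any(axis=1))[0]
    centroid = np.average(np.arange(mask.shape[0]), weights=mask.sum(axis=1))
    top = mask & (np.arange(mask.shape[0])[:, np.newaxis] <= centroid)
    bottom = mask & ~top
    records = []
    for section, sec_mask in (("top", top), ("bottom", bottom)):
        if not sec_mask.any():
            raise ValueError(f"empty {section} half")
        brix = float(np.nanmean(scene.true_ssc_map[sec_mask]))
        records.append(
            SSCRecord(sample_id=scene.sample_id, section=section, brix=brix)
        )
    return records


def save_scene(scene: PhantomScene, out_dir) -> None:
    """Write a scene to a directory: ENVI cube plus CSV side files."""
    import os

    import numpy as np

    from . import envi

    os.makedirs(out_dir, exist_ok=True)
    envi.write_envi(scene.cube, os.path.join(out_dir, "cube"))
    np.savetxt(os.path.join(out_dir, "dark.csv"), scene.dark.values,
               delimiter=",")
    np.savetxt(os.path.join(out_dir, "white.csv"), scene.white.values,
               delimiter=",")
    np.savetxt(os.path.join(out_dir, "height.csv"), scene.height.values,
               delimiter=",")
    np.savetxt(os.path.join(out_dir, "flesh_mask.csv"),
               scene.flesh_mask.astype(int), fmt="%d", delimiter=",")
    np.savetxt(os.path.join(out_dir, "achene_mask.csv"),
               scene.achene_mask.astype(int), fmt="%d", delimiter=",")
    np.savetxt(os.path.join(out_dir, "true_ssc.csv"), scene.true_ssc_map,
               delimiter=",")
    with open(os.path.join(out_dir, "meta.txt"), "w") as fh:
        fh.write(f"sample_id={scene.sample_id}\n")
        fh.write(f"pixel_pitch_mm={scene.height.pixel_pitch_mm}\n")
        fh.write(f"H1_mm={scene.config.H1_mm}\n")
        fh.write(f"H2_mm={scene.config.H2_mm}\n")
        fh.write(f"angle_mode={scene.config.angle_mode}\n")


def load_scene(scene_dir) -> PhantomScene:
    """Read back a scene written by :func:`save_scene`."""
    import os

    import numpy as np

    from . import envi
    from .geometry import DarkReference, HeightMap, WhiteReference

    meta = {}
    with open(os.path.join(scene_dir, "meta.txt")) as fh:
        for line in fh:
            key, _, val = line.strip().partition("=")
            meta[key] = val
    cube = envi.read_envi(os.path.join(scene_dir, "cube"))
    cube.pixel_pitch_mm = float(meta.get("pixel_pitch_mm", 1.0))
    pitch = cube.pixel_pitch_mm
    dark = DarkReference(np.loadtxt(os.path.join(scene_dir, "dark.csv"),
                                    delimiter=",", ndmin=2))
    white = WhiteReference(np.loadtxt(os.path.join(scene_dir, "white.csv"),
                                      delimiter=",", ndmin=2))
    height = HeightMap(np.loadtxt(os.path.join(scene_dir, "height.csv"),
                                  delimiter=",", ndmin=2),
                       pixel_pitch_mm=pitch)
    flesh = np.loadtxt(os.path.join(scene_dir, "flesh_mask.csv"),
                       delimiter=",", ndmin=2).astype(bool)
    achene = np.loadtxt(os.path.join(scene_dir, "achene_mask.csv"),
                        delimiter=",", ndmin=2).astype(bool)
    true_ssc = np.loadtxt(os.path.join(scene_dir, "true_ssc.csv"),
                          delimiter=",", ndmin=2)
    cfg = PhantomConfig(
        grid_shape=height.values.shape,
        wavelength_axis=cube.wavelengths,
        pixel_pitch_mm=pitch,
        H1_mm=float(meta.get("H1_mm", 100.0)),
        H2_mm=float(meta.get("H2_mm", 200.0)),
        angle_mode=meta.get("angle_mode", "width"),
    )
    return PhantomScene(
        cube=cube, height=height, white=white, dark=dark,
        true_reflectance=np.full(cube.values.shape, np.nan),
        true_ssc_map=true_ssc, achene_mask=achene, flesh_mask=flesh,
        config=cfg, sample_id=meta.get("sample_id", "sample"),
    )


def make_phantom_batch(
    n_fruits: int,
    base_config: PhantomConfig | None = None,
    seed: int = 0,
    ssc_spread: float = 1.5,
    **overrides,
) -> list[PhantomScene]:
    """A batch of fruits with per-fruit SSC levels drawn around the defaults."""
    rng = np.random.default_rng(seed)
    base = base_config or PhantomConfig(**overrides)
    scenes = []
    for i in range(n_fruits):
        shift = rng.normal(0.0, ssc_spread)
        cfg_kwargs = {
            f.name: getattr(base, f.name)
            for f in base.__dataclass_fields__.values()
        }
        cfg_kwargs["ssc_apex_brix"] = float(
            np.clip(base.ssc_apex_brix + shift, 1.0, 29.0)
        )
        cfg_kwargs["ssc_base_brix"] = float(
            np.clip(base.ssc_base_brix + shift, 0.5, 28.0)
        )
        cfg_kwargs["seed"] = int(rng.integers(0, 2**31 - 1))
        scene = make_phantom(PhantomConfig(**cfg_kwargs))
        scene.sample_id = f"fruit-{i:03d}"
        scenes.append(scene)
    return scenes
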