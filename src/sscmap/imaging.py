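"""Pixel-wise SSC maps and 3D fusion with height data."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr

from .geometry import HeightMap, HyperCube
from .preprocess import PreprocessSpec, apply_pattern
from .roi import ROIMask, split_sections


@dataclass
class SSCMap:
    """Per-pixel Brix predictions; NaN outside the defined flesh pixels.

    No spatial smoothing is ever applied to the map.
    """

    values: np.ndarray
    model_id: str = ""
    pattern: str = "none"
    geometry_mode: str = "none"
    n_failed: int = 0

    @property
    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class FruitPointCloud:
    points: np.ndarray  # (n, 3) mm
    ssc: np.ndarray     # (n,)
    source: str = "line"


def predict_map(
    cube: HyperCube,
    flesh: ROIMask,
    model,
    spec: PreprocessSpec,
) -> SSCMap:
    """Apply a calibration model to each flesh pixel's preprocessed spectrum.

    Pixels whose preprocessing fails (constant spectrum under SNV) or whose
    corrected spectrum is non-finite are left undefined and counted.
    """
    if cube.kind != "reflectance":
        raise ValueError("predict_map expects a corrected reflectance cube")
    if getattr(model, "x_mean").size != cube.n_bands:
        raise ValueError("band axis mismatch between model and cube")
    out = np.full(flesh.mask.shape, np.nan)
    pix = np.where(flesh.mask)
    spectra = cube.values[pix]
    finite = np.isfinite(spectra).all(axis=1)
    processed = np.full_like(spectra, np.nan)
    if finite.any():
        processed[finite] = apply_pattern(spectra[finite], spec, on_error="nan")
    ok = np.isfinite(processed).all(axis=1)
    preds = np.full(spectra.shape[0], np.nan)
    if ok.any():
        preds[ok] = model.predict(processed[ok])
    out[pix] = preds
    return SSCMap(
        values=out,
        pattern=spec.pattern,
        geometry_mode=cube.correction,
        n_failed=int((~ok).sum()),
    )


def region_imaging_values(ssc_map: SSCMap, flesh_mask: np.ndarray,
                          apex_axis: str = "row") -> dict:
    """Mean of defined map pixels over the top and bottom flesh sections."""
    top, bottom = split_sections(np.asarray(flesh_mask, dtype=bool), apex_axis)
    out = {}
    for name, sec in (("top", top), ("bottom", bottom)):
        vals = ssc_map.values[sec]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"no defined pixels in {name} section")
        out[name] = float(vals.mean())
    return out


def r_star(imaging_values, references) -> float:
    """Pearson correlation between imaging-based and reference section SSC."""
    x = np.asarray(imaging_values, dtype=float)
    y = np.asarray(references, dtype=float)
    if x.size < 3:
        raise ValueError("need at least three paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in paired values")
    return float(pearsonr(x, y).statistic)


def fuse_line_scan(ssc_map: SSCMap, height: HeightMap) -> FruitPointCloud:
    """Lift defined map pixels to 3D using the co-registered height map."""
    if height.values.shape != ssc_map.values.shape:
        raise ValueError("height map grid does not match SSC map")
    mask = ssc_map.defined_mask
    rr, cc = np.where(mask)
    pitch = height.pixel_pitch_mm
    points = np.column_stack([
        cc * pitch,
        rr * pitch,
        height.values[rr, cc],
    ])
    return FruitPointCloud(points=points, ssc=ssc_map.values[rr, cc],
                           source="line")


def fuse_rotation_scan(
    ssc_map: SSCMap,
    radius_profiles: np.ndarray,
    frame_rate_hz: float,
    turn_rate_deg_s: float,
) -> FruitPointCloud:
    """Cylindrical reconstruction of a rotation-scan map.

    Map rows are scan frames; the azimuth of frame f is
    turn_rate / frame_rate * f degrees about the turntable axis. Map columns
    index height along the axis (one radius value per frame/column pair).
    Frames beyond a full rotation are dropped, keeping the first pass.
    """
    if frame_rate_hz <= 0 or turn_rate_deg_s <= 0:
        raise ValueError("rates must be positive")
    radius_profiles = np.asarray(radius_profiles, dtype=float)
    if radius_profiles.shape != ssc_map.values.shape:
        raise ValueError("radius profiles must match the map grid")
    n_frames = ssc_map.values.shape[0]
    step_deg = turn_rate_deg_s / frame_rate_hz
    total_deg = step_deg * n_frames
    if total_deg < 360.0 - step_deg:
        import warnings
        warnings.warn(
            f"frames cover only {total_deg:.1f} deg of rotation", stacklevel=2
        )
    full_turn = int(np.ceil(360.0 / step_deg))
    mask = ssc_map.defined_mask
    rr, cc = np.where(mask)
    keep = rr < full_turn
    rr, cc = rr[keep], cc[keep]
    az = np.deg2rad(step_deg * rr)
    r = radius_profiles[rr, cc]
    points = np.column_stack([
        r * np.cos(az),
        r * np.sin(az),
        cc.astype(float),
    ])
    return FruitPointCloud(points=points, ssc=ssc_map.values[rr, cc],
                           source="rotation")


def write_ply(cloud: FruitPointCloud, path) -> None:
    """ASCII PLY with a per-vertex scalar 'ssc'."""
    n = cloud.points.shape[0]
    header = "\n".join([
        "ply",
        "format ascii 1.0",
        f"element vertex {n}",
        "property float x",
        "property float y",
        "property float z",
        "property float ssc",
        "end_header",
    ])
    body = "\n".join(
        f"{p[0]:.4f} {p[1]:.4f} {p[2]:.4f} {s:.4f}"
        for p, s in zip(cloud.points, cloud.ssc)
    )
    with open(path, "w") as fh:
        fh.write(header + "\n" + body + "\n")
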