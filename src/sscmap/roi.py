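"""Flesh region-of-interest extraction.

Background is removed by thresholding a single-band image; achenes are then
separated from flesh by projecting each remaining pixel onto the first
principal component of a wavelength window and binarizing the score image
with Otsu's method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import HyperCube

# Named parameter presets for the two acquisition systems. Which preset
# belongs to which instrument is a configuration choice, not an assertion.
PRESETS = {
    "preset_linescan": dict(
        band_nm=1204.0, threshold=0.2, compare="reflectance",
        window_nm=(1160.0, 2168.0),
    ),
    "preset_rotation": dict(
        band_nm=1123.0, threshold=12000.0, compare="intensity",
        window_nm=(1476.0, 1917.0),
    ),
}


@dataclass
class ROIMask:
    mask: np.ndarray                  # bool (rows, cols)
    stage: str                        # background_removed | flesh
    params_used: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class SectionSpectra:
    sample_id: str
    section: str          # top | bottom
    spectrum: np.ndarray  # (bands,)
    n_pixels: int


def background_mask(
    cube: HyperCube,
    band_nm: float,
    threshold: float,
    compare: str = "reflectance",
) -> ROIMask:
    """Pixels whose value at the band nearest ``band_nm`` exceeds threshold."""
    if compare not in ("reflectance", "intensity"):
        raise ValueError(f"unknown compare mode {compare!r}")
    idx = cube.band_index(band_nm)
    image = cube.values[:, :, idx]
    with np.errstate(invalid="ignore"):
        mask = image > threshold
    return ROIMask(
        mask=mask,
        stage="background_removed",
        params_used=dict(band_nm=band_nm, threshold=threshold, compare=compare),
    )


def pc1_scores(
    cube: HyperCube, mask: ROIMask, window_nm: tuple[float, float]
) -> np.ndarray:
    """First-principal-component score per masked pixel.

    PCA on mean-centred masked spectra restricted to the wavelength window;
    no variance scaling. The loading sign is fixed so its largest-magnitude
    element is positive. Returns a 2D image, NaN outside the mask.
    """
    lo, hi = window_nm
    band_sel = (cube.wavelengths >= lo) & (cube.wavelengths <= hi)
    if not band_sel.any():
        raise ValueError(f"window {window_nm} outside wavelength axis")
    pix = np.where(mask.mask)
    if pix[0].size < 2:
        raise ValueError("need at least two masked pixels for PCA")
    X = cube.values[pix[0], pix[1]][:, band_sel]
    finite = np.isfinite(X).all(axis=1)
    Xc = X[finite] - X[finite].mean(axis=0)
    if np.allclose(Xc, 0):
        raise ValueError("masked spectra are constant; PC1 undefined")
    # SVD of the centred data; PC1 loading = leading right singular vector
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    loading = vt[0]
    if loading[np.argmax(np.abs(loading))] < 0:
        loading = -loading
    scores = np.full(mask.mask.shape, np.nan)
    vals = np.full(X.shape[0], np.nan)
    vals[finite] = Xc @ loading
    scores[pix] = vals
    return scores


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold maximizing between-class variance on an n-bin histogram.

    Returns the threshold on the original value scale (bin upper edge).
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0 or np.ptp(v) == 0:
        raise ValueError("Otsu threshold undefined for constant input")
    hist, edges = np.histogram(v, bins=n_bins, range=(v.min(), v.max()))
    p = hist.astype(float) / hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2
    omega = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    k = int(np.argmax(sigma_b))
    return float(edges[k + 1])


def otsu_flesh_mask(scores: np.ndarray, mask: ROIMask) -> ROIMask:
    """Binarize PC1 scores with Otsu; flesh is the class holding the median.

    Scores are min-max scaled before histogramming; the polarity rule keeps
    the majority (flesh) class regardless of the loading's sign convention.
    """
    vals = scores[mask.mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0 or np.ptp(vals) == 0:
        raise ValueError("constant scores; Otsu binarization undefined")
    scaled = (scores - vals.min()) / np.ptp(vals)
    thr = otsu_threshold((vals - vals.min()) / np.ptp(vals))
    with np.errstate(invalid="ignore"):
        upper = mask.mask & (scaled > thr)
    lower = mask.mask & np.isfinite(scores) & ~upper
    median = np.median(vals)
    med_scaled = (median - vals.min()) / np.ptp(vals)
    flesh = upper if med_scaled > thr else lower
    params = dict(mask.params_used)
    params["otsu_threshold"] = thr
    return ROIMask(mask=flesh, stage="flesh", params_used=params)


def flesh_roi(
    cube: HyperCube,
    preset: str | None = None,
    band_nm: float | None = None,
    threshold: float | None = None,
    compare: str = "reflectance",
    window_nm: tuple[float, float] | None = None,
) -> ROIMask:
    """Background removal + PC1/Otsu achene exclusion in one call."""
    if preset is not None:
        cfg = PRESETS[preset]
        band_nm = cfg["band_nm"] if band_nm is None else band_nm
        threshold = cfg["threshold"] if threshold is None else threshold
        compare = cfg["compare"]
        window_nm = cfg["window_nm"] if window_nm is None else window_nm
    bg = background_mask(cube, band_nm, threshold, compare)
    scores = pc1_scores(cube, bg, window_nm)
    return otsu_flesh_mask(scores, bg)


def split_sections(mask: np.ndarray, apex_axis: str = "row"):
    """Split a flesh mask into (top, bottom) halves at its centroid."""
    axis = 0 if apex_axis == "row" else 1
    idx = np.arange(mask.shape[axis])
    counts = mask.sum(axis=1 - axis)
    if counts.sum() == 0:
        raise ValueError("empty flesh mask")
    centroid = np.average(idx, weights=counts)
    coord = idx[:, np.newaxis] if axis == 0 else idx[np.newaxis, :]
    top = mask & (coord <= centroid)
    bottom = mask & ~top
    return top, bottom


def section_mean_spectra(
    cube: HyperCube,
    flesh: ROIMask,
    apex_axis: str = "row",
    sample_id: str = "sample",
) -> list[SectionSpectra]:
    """Mean spectrum of the top and bottom halves of the flesh mask."""
    top, bottom = split_sections(flesh.mask, apex_axis)
    out = []
    for section, sec_mask in (("top", top), ("bottom", bottom)):
        if not sec_mask.any():
            raise ValueError(f"empty {section} section")
        spectra = cube.values[sec_mask]
        finite = np.isfinite(spectra).all(axis=1)
        if not finite.any():
            raise ValueError(f"no finite spectra in {section} section")
        out.append(
            SectionSpectra(
                sample_id=sample_id,
                section=section,
                spectrum=spectra[finite].mean(axis=0),
                n_pixels=int(finite.sum()),
            )
        )
    return out
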