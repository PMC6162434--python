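"""Histology quantification: H&E cellularity and MCT4 (DAB) staining fraction.

Cellularity follows a CellProfiler-style pipeline: un-mix the hematoxylin
stain by color deconvolution (Ruifrok–Johnston H&E basis, as implemented in
``skimage.color.rgb2hed``), Otsu-threshold the smoothed hematoxylin
optical-density channel, de-clump touching nuclei by distance-transform
watershed constrained by the expected nucleus diameter, and report the
percentage of the image area covered by nuclei.

MCT4 membrane staining (brown DAB chromogen) is quantified in HSV space:
a pixel counts as stained when hue ∈ [0, 0.169], saturation ∈ [0.189, 1.0]
and value lies within the per-image 16th percentile (lower tail, DAB being
dark; the percentile adapts to per-slide illumination).  The stained pixel
count is expressed as a percent of the tissue area, averaged over sampled
regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2hed, rgb2hsv
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed
from sklearn.base import BaseEstimator


@dataclass(frozen=True)
class NucleiSegParams:
    """Settings of the nuclei segmentation stage."""

    expected_diameter_range: tuple[float, float] = (8.0, 30.0)
    smoothing_scale: float = 1.0
    declump: str = "shape"  # distance-transform watershed
    threshold: str = "otsu"

    def __post_init__(self) -> None:
        lo, hi = self.expected_diameter_range
        if not (0 < lo < hi):
            raise ValueError("expected_diameter_range must satisfy 0 < min < max")


@dataclass(frozen=True)
class CellularityResult:
    """Cellularity as the percentage of the image area covered by nuclei."""

    pct_nuclei_area: float
    n_nuclei: int
    mean_nucleus_area: float
    mean_equiv_diameter: float


@dataclass(frozen=True)
class Mct4Thresholds:
    """HSV window defining DAB-positive (MCT4) pixels.

    ``value_mode='percentile'`` reads "within the 16th percentile" as the
    lower tail V ≤ P₁₆(V over tissue pixels), computed per image to adapt to
    illumination; ``'absolute'`` instead uses the fixed band ``value_band``.
    """

    hue: tuple[float, float] = (0.0, 0.169)
    saturation: tuple[float, float] = (0.189, 1.0)
    value_mode: str = "percentile"
    value_percentile: float = 16.0
    value_band: tuple[float, float] = (0.0, 0.16)
    hue_wrap: bool = False

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("hue", self.hue), ("saturation", self.saturation),
                               ("value_band", self.value_band)):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} interval must lie within [0, 1]")
        if self.value_mode not in ("percentile", "absolute"):
            raise ValueError("value_mode must be 'percentile' or 'absolute'")


@dataclass(frozen=True)
class Mct4Result:
    """Stained-pixel percentage of tissue area, per region and mean."""

    pct_stained: float
    region_pcts: tuple[float, ...]


def _check_rgb(rgb: np.ndarray) -> np.ndarray:
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if rgb.dtype == np.uint8:
        return rgb.astype(float) / 255.0
    if np.issubdtype(rgb.dtype, np.floating):
        return np.clip(rgb, 0.0, 1.0)
    raise ValueError(f"unsupported image dtype {rgb.dtype}")


def unmix_hematoxylin(rgb: np.ndarray) -> np.ndarray:
    """Isolate the hematoxylin optical-density channel of an H&E image.

    Applies the Beer–Lambert OD transform and projects onto the
    hematoxylin vector of the standard H&E color-deconvolution basis.
    Pure white (no absorbance) maps to 0; small negative deconvolution
    residues are clipped to 0.
    """
    rgb = _check_rgb(rgb)
    hema = rgb2hed(rgb)[..., 0]
    return np.clip(hema, 0.0, None)


class NucleiSegmenter(BaseEstimator):
    """Otsu + watershed nuclei segmentation of a hematoxylin OD channel.

    ``predict`` returns a labeled mask (0 = background).  De-clumping seeds
    are distance-transform maxima at least half the minimum expected
    diameter apart; objects whose equivalent diameter falls outside
    ``expected_diameter_range`` are discarded.
    """

    def __init__(
        self,
        expected_diameter_range: tuple[float, float] = (8.0, 30.0),
        smoothing_scale: float = 1.0,
        declump: str = "shape",
        threshold: str = "otsu",
    ):
        self.expected_diameter_range = expected_diameter_range
        self.smoothing_scale = smoothing_scale
        self.declump = declump
        self.threshold = threshold

    def fit(self, X=None, y=None) -> "NucleiSegmenter":
        NucleiSegParams(
            expected_diameter_range=tuple(self.expected_diameter_range),
            smoothing_scale=self.smoothing_scale,
            declump=self.declump,
            threshold=self.threshold,
        )
        if self.threshold != "otsu":
            raise ValueError("only Otsu thresholding is supported")
        return self

    def predict(self, hema: np.ndarray) -> np.ndarray:
        self.fit()
        hema = np.asarray(hema, dtype=float)
        if hema.ndim != 2:
            raise ValueError("expected a single-channel image")
        d_min, d_max = self.expected_diameter_range
        smoothed = gaussian(hema, sigma=self.smoothing_scale) if self.smoothing_scale > 0 else hema
        if np.ptp(smoothed) < 1e-12:
            warnings.warn("blank channel: no foreground after thresholding")
            return np.zeros(hema.shape, dtype=int)
        binary = smoothed > threshold_otsu(smoothed)
        if not binary.any():
            warnings.warn("blank channel: no foreground after thresholding")
            return np.zeros(hema.shape, dtype=int)
        if self.declump == "shape":
            distance = ndi.distance_transform_edt(binary)
            coords = peak_local_max(
                distance,
                min_distance=max(1, int(round(d_min / 2))),
                labels=binary,
            )
            markers = np.zeros(hema.shape, dtype=int)
            markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
            labels = watershed(-distance, markers, mask=binary)
        elif self.declump == "intensity":
            coords = peak_local_max(
                smoothed, min_distance=max(1, int(round(d_min / 2))), labels=binary
            )
            markers = np.zeros(hema.shape, dtype=int)
            markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
            labels = watershed(-smoothed, markers, mask=binary)
        else:
            raise ValueError(f"unknown declump mode {self.declump!r}")
        return self._filter_by_diameter(labels, d_min, d_max)

    @staticmethod
    def _filter_by_diameter(labels: np.ndarray, d_min: float, d_max: float) -> np.ndarray:
        # renumber kept labels directly: relabelling by connectivity would
        # re-merge de-clumped objects that touch
        lut = np.zeros(labels.max() + 1, dtype=np.int32)
        nxt = 0
        for prop in regionprops(labels):
            if d_min <= prop.equivalent_diameter_area <= d_max:
                nxt += 1
                lut[prop.label] = nxt
        return lut[labels]


def segment_nuclei(hema: np.ndarray, params: NucleiSegParams | None = None) -> np.ndarray:
    """Functional wrapper around :class:`NucleiSegmenter`."""
    params = params or NucleiSegParams()
    return NucleiSegmenter(
        expected_diameter_range=params.expected_diameter_range,
        smoothing_scale=params.smoothing_scale,
        declump=params.declump,
        threshold=params.threshold,
    ).predict(hema)


def cellularity(labels: np.ndarray, image_shape: tuple[int, int] | None = None) -> CellularityResult:
    """Percentage of the image area covered by nuclei, with object stats.

    The denominator is the total image pixel count (not tissue area).
    """
    labels = np.asarray(labels)
    shape = image_shape or labels.shape
    total = int(np.prod(shape))
    fg = int(np.count_nonzero(labels))
    n = int(labels.max())
    areas = np.bincount(labels.ravel())[1:] if n else np.array([])
    areas = areas[areas > 0]
    mean_area = float(areas.mean()) if areas.size else 0.0
    return CellularityResult(
        pct_nuclei_area=100.0 * fg / total,
        n_nuclei=int(areas.size),
        mean_nucleus_area=mean_area,
        mean_equiv_diameter=float(2.0 * np.sqrt(mean_area / np.pi)) if areas.size else 0.0,
    )


def tissue_mask(hsv: np.ndarray, sat_min: float = 0.05, val_max: float = 0.95) -> np.ndarray:
    """Non-background pixels: saturated or non-white (excludes bare slide)."""
    return (hsv[..., 1] > sat_min) | (hsv[..., 2] < val_max)


class Mct4Quantifier(BaseEstimator):
    """HSV-threshold quantifier of DAB (MCT4) staining fraction."""

    def __init__(self, thresholds: Mct4Thresholds | None = None):
        self.thresholds = thresholds

    def _thr(self) -> Mct4Thresholds:
        return self.thresholds if self.thresholds is not None else Mct4Thresholds()

    def fit(self, X=None, y=None) -> "Mct4Quantifier":
        self._thr()
        return self

    def stain_mask(self, rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Boolean stained-pixel mask and tissue mask for one image."""
        thr = self._thr()
        hsv = rgb2hsv(_check_rgb(rgb))
        h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
        tissue = tissue_mask(hsv)
        if not tissue.any():
            raise ValueError("image contains no tissue pixels")
        h_lo, h_hi = thr.hue
        in_hue = (h >= h_lo) & (h <= h_hi)
        if thr.hue_wrap:
            # treat the window as wrapping through red at hue = 1
            in_hue |= h >= 1.0 - (h_hi - h_lo)
        s_lo, s_hi = thr.saturation
        in_sat = (s >= s_lo) & (s <= s_hi)
        if thr.value_mode == "percentile":
            v_cut = float(np.percentile(v[tissue], thr.value_percentile))
            in_val = v <= v_cut
        else:
            v_lo, v_hi = thr.value_band
            in_val = (v >= v_lo) & (v <= v_hi)
        return tissue & in_hue & in_sat & in_val, tissue

    def quantify(
        self, rgb: np.ndarray, regions: list[np.ndarray] | None = None
    ) -> Mct4Result:
        """Stained percentage of tissue area; multi-region values averaged.

        ``regions`` are boolean masks (e.g. three sampled fields per tumor);
        the per-image HSV thresholds are computed once on the full image.
        """
        stained, tissue = self.stain_mask(rgb)
        if regions is None:
            pct = 100.0 * stained.sum() / tissue.sum()
            return Mct4Result(pct_stained=float(pct), region_pcts=(float(pct),))
        pcts = []
        for reg in regions:
            reg = np.asarray(reg, dtype=bool)
            t = (tissue & reg).sum()
            if t == 0:
                raise ValueError("a sampled region contains no tissue pixels")
            pcts.append(100.0 * (stained & reg).sum() / t)
        return Mct4Result(pct_stained=float(np.mean(pcts)), region_pcts=tuple(map(float, pcts)))


def mct4_fraction(
    rgb: np.ndarray,
    thresholds: Mct4Thresholds | None = None,
    regions: list[np.ndarray] | None = None,
) -> Mct4Result:
    """Functional wrapper around :class:`Mct4Quantifier`."""
    return Mct4Quantifier(thresholds=thresholds).quantify(rgb, regions=regions)
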