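"""Image-quality metrics for PT-OCT reconstructions.

Three criteria compare a reconstruction against the long-trace ground truth:

* Michelson contrast between two regions,
  ``C = (L_max - L_min) / (L_max + L_min)``, with the two luminances taken
  as the region-mean amplitudes (a literal per-pixel-extrema variant is
  provided for single-window use);
* mean squared error over the jointly masked pixels;
* a single global SSIM,
  ``SSIM = (2 mu_A mu_B + C1)(2 sigma_AB + C2) /
  ((mu_A^2 + mu_B^2 + C1)(sigma_A^2 + sigma_B^2 + C2))``,
  with ``C1 = (K1 L)^2``, ``C2 = (K2 L)^2``, ``K1 = 0.01``, ``K2 = 0.03``,
  computed from population moments over the jointly masked pixels (no
  sliding window).

Contrast and SSIM are reported x100 in :class:`MetricsReport` to match the
conventional percentage presentation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .lockin import PTImage

__all__ = [
    "RegionSpec",
    "MetricsReport",
    "michelson_contrast",
    "michelson_contrast_window",
    "mse_images",
    "ssim_global",
    "metrics_report",
    "regions_from_labels",
]


@dataclass
class RegionSpec:
    """Named pixel set (boolean matrix) used to window the metrics."""

    name: str
    pixel_set: np.ndarray

    def __post_init__(self) -> None:
        self.pixel_set = np.asarray(self.pixel_set, dtype=bool)


@dataclass
class MetricsReport:
    """Region-wise contrast / MSE / SSIM in the conventional table layout.

    ``contrast_pct`` maps image kind -> region pair (``"P0-P1"``) -> percent;
    ``mse`` and ``ssim_pct`` map comparison (``"GT-ST"``, ``"GT-NET"``) ->
    region name or ``"overall"``.
    """

    contrast_pct: dict[str, dict[str, float]]
    mse: dict[str, dict[str, float]]
    ssim_pct: dict[str, dict[str, float]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "contrast_pct": self.contrast_pct,
                "mse": self.mse,
                "ssim_pct": self.ssim_pct,
            },
            indent=2,
            sort_keys=True,
        )


def _region_values(image: PTImage, region: RegionSpec) -> np.ndarray:
    if region.pixel_set.shape != image.shape:
        raise ValueError("region and image shapes differ")
    sel = region.pixel_set & image.mask
    if not np.any(sel):
        raise ValueError(f"region {region.name!r} has no masked pixels")
    return image.amplitude_rad[sel]


def michelson_contrast(
    image: PTImage, region_a: RegionSpec, region_b: RegionSpec
) -> float:
    """Michelson contrast (percent) between two regions' mean amplitudes.

    ``100 (L_max - L_min) / (L_max + L_min)`` with ``L`` the region-mean
    amplitude over masked pixels; 0 when both means vanish.  Symmetric in
    its two regions and in [0, 100] for non-negative images.
    """
    la = float(_region_values(image, region_a).mean())
    lb = float(_region_values(image, region_b).mean())
    hi, lo = max(la, lb), min(la, lb)
    if hi + lo == 0:
        return 0.0
    return 100.0 * (hi - lo) / (hi + lo)


def michelson_contrast_window(image: PTImage, region: RegionSpec) -> float:
    """Literal single-window variant: per-pixel extrema within one region."""
    v = _region_values(image, region)
    hi, lo = float(v.max()), float(v.min())
    if hi + lo == 0:
        return 0.0
    return 100.0 * (hi - lo) / (hi + lo)


def _joint_values(
    a: PTImage, b: PTImage, region: RegionSpec | None
) -> tuple[np.ndarray, np.ndarray]:
    if a.shape != b.shape:
        raise ValueError("image shapes differ")
    sel = a.mask & b.mask
    if region is not None:
        if region.pixel_set.shape != a.shape:
            raise ValueError("region shape differs from images")
        sel = sel & region.pixel_set
    if not np.any(sel):
        raise ValueError("empty joint masked region")
    return a.amplitude_rad[sel], b.amplitude_rad[sel]


def mse_images(a: PTImage, b: PTImage, region: RegionSpec | None = None) -> float:
    """Mean squared pixel difference over the jointly masked region."""
    va, vb = _joint_values(a, b, region)
    return float(np.mean((va - vb) ** 2))


def ssim_global(
    a: PTImage,
    b: PTImage,
    dynamic_range: float,
    k1: float = 0.01,
    k2: float = 0.03,
    region: RegionSpec | None = None,
) -> float:
    """Single global SSIM over the jointly masked pixels (unit scale).

    Uses population (1/n) moments; ``dynamic_range`` is the luminance range
    ``L`` entering the stabilisation constants.  Equals 1 iff the two images
    agree on the evaluated pixels.
    """
    if dynamic_range <= 0:
        raise ValueError("dynamic_range must be positive")
    va, vb = _joint_values(a, b, region)
    mu_a, mu_b = va.mean(), vb.mean()
    var_a, var_b = va.var(), vb.var()
    cov = ((va - mu_a) * (vb - mu_b)).mean()
    c1 = (k1 * dynamic_range) ** 2
    c2 = (k2 * dynamic_range) ** 2
    return float(
        (2 * mu_a * mu_b + c1)
        * (2 * cov + c2)
        / ((mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2))
    )


def regions_from_labels(
    labels: np.ndarray, names: list[str] | None = None, within: np.ndarray | None = None
) -> list[RegionSpec]:
    """One :class:`RegionSpec` per label value (P0, P1, ... by default)."""
    labels = np.asarray(labels, dtype=int)
    ids = np.unique(labels)
    if names is None:
        names = [f"P{i}" for i in ids]
    regions = []
    for i, name in zip(ids, names):
        sel = labels == i
        if within is not None:
            sel = sel & within
        regions.append(RegionSpec(name=name, pixel_set=sel))
    return regions


def _contrast_pairs(regions: list[RegionSpec]) -> list[tuple[RegionSpec, RegionSpec]]:
    """Conventional pairing: P0 against every other region, plus adjacent
    absorber regions — 5 pairs for 4 regions (P0-P1 ... P2-P3)."""
    pairs = [(regions[0], r) for r in regions[1:]]
    pairs += [(regions[i], regions[i + 1]) for i in range(1, len(regions) - 1)]
    return pairs


def metrics_report(
    gt: PTImage,
    st: PTImage,
    net: PTImage,
    regions: list[RegionSpec],
    dynamic_range: float | None = None,
) -> MetricsReport:
    """Assemble the conventional comparison table.

    Michelson contrast for every region pair within each image; MSE and
    SSIM per region and overall for (GT, ST) and (GT, NET).  The SSIM
    dynamic range defaults to the GT image's masked maximum.
    """
    if dynamic_range is None:
        dynamic_range = float(np.nanmax(gt.amplitude_rad[gt.mask]))
        if dynamic_range <= 0:
            dynamic_range = 1.0
    images = {"GT": gt, "ST": st, "NET": net}
    contrast = {
        kind: {
            f"{ra.name}-{rb.name}": michelson_contrast(img, ra, rb)
            for ra, rb in _contrast_pairs(regions)
        }
        for kind, img in images.items()
    }
    mse: dict[str, dict[str, float]] = {}
    ssim: dict[str, dict[str, float]] = {}
    for label, other in (("GT-ST", st), ("GT-NET", net)):
        mse[label] = {r.name: mse_images(gt, other, r) for r in regions}
        mse[label]["overall"] = mse_images(gt, other)
        ssim[label] = {
            r.name: 100.0 * ssim_global(gt, other, dynamic_range, region=r)
            for r in regions
        }
        ssim[label]["overall"] = 100.0 * ssim_global(gt, other, dynamic_range)
    return MetricsReport(contrast_pct=contrast, mse=mse, ssim_pct=ssim)
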