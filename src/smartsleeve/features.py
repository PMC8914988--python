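"""The 100-feature static descriptor of a single pressure image.

Three families:

* statistical (Feat1-8) — order and dispersion statistics of all pixel
  values, plus the Shannon entropy of the pressure-mass distribution;
* geometric (Feat9-52) — centroid / center-of-mass geometry, bounding
  rectangle, contact area, Hu's seven invariant moments, coverage
  fractions, contour (connected-region) statistics, and the same
  location features recomputed on the masked image that keeps only the
  highest-pressure contour;
* symmetry (Feat53-100) — per-side area and pressure, and their ratios,
  for left/right and upper/lower splits through the center of mass and
  the centroid, on the image and on its masked version.

Coordinate convention: origin at the upper-left pixel center, x along the
short side (columns), y along the long side (rows).  "Area" always means
the number of pixels at or above the activity threshold of 2 ADC counts;
"coverage" means the fraction of strictly positive pixels.  Degenerate
images (all-zero, empty support) follow fixed conventions — centroid and
center of mass fall back to the image center, ratios of two empty sides
are 1 and a division by an empty side is capped — so every feature is
finite on every input.
"""

from __future__ import annotations

import numpy as np
from skimage import measure

from .types import Sample

#: pixels >= this many ADC counts belong to the active (contact) region
ACTIVITY_THRESHOLD = 2.0

#: cap for a ratio whose denominator side carries no mass
RATIO_CAP = 1e6

N_FEATURES = 100
FEATURE_NAMES = [f"Feat{i}" for i in range(1, N_FEATURES + 1)]


# ---------------------------------------------------------------------------
# statistical features


def statistical_features(image: np.ndarray) -> np.ndarray:
    """Feat1-8: max, median, sum, range (max - median), mean, population
    variance, mean absolute deviation, and Shannon entropy (natural log)
    of the pressure-mass distribution; an all-zero image has entropy 0."""
    v = np.asarray(image, dtype=float).ravel()
    vmax = v.max()
    vmed = float(np.median(v))
    total = v.sum()
    mean = v.mean()
    if total > 0:
        p = v[v > 0] / total
        entropy = float(-(p * np.log(p)).sum())
    else:
        entropy = 0.0
    return np.array(
        [
            vmax,
            vmed,
            total,
            vmax - vmed,
            mean,
            v.var(),
            np.abs(v - mean).mean(),
            entropy,
        ]
    )


def contact_area(image: np.ndarray, rel_threshold: float = 0.1) -> int:
    """Pixels belonging to the contact print: at or above ``rel_threshold``
    of the image's own peak value.

    A peak-relative support is used rather than a near-zero absolute
    threshold because bilinear upsampling and Gaussian smoothing surround
    every patch with a shallow skirt of fixed width in pixels; at a
    threshold of a few ADC counts that skirt — whose size depends on the
    processing resolution, not on the subject — dominates the count.
    """
    peak = image.max()
    if peak <= 0:
        return 0
    return int((image >= rel_threshold * peak).sum())


# ---------------------------------------------------------------------------
# geometry helpers


def _image_center_xy(image: np.ndarray) -> tuple[float, float]:
    h, w = image.shape
    return ((w - 1) / 2.0, (h - 1) / 2.0)


def centroid_xy(image: np.ndarray) -> tuple[float, float]:
    """Unweighted mean (x, y) of pixels at/above the activity threshold;
    image center when no pixel qualifies."""
    rr, cc = np.nonzero(image >= ACTIVITY_THRESHOLD)
    if rr.size == 0:
        return _image_center_xy(image)
    return (float(cc.mean()), float(rr.mean()))


def com_xy(image: np.ndarray) -> tuple[float, float]:
    """Pressure-weighted mean (x, y); image center for an all-zero image."""
    total = image.sum()
    if total <= 0:
        return _image_center_xy(image)
    rows = np.arange(image.shape[0], dtype=float)
    cols = np.arange(image.shape[1], dtype=float)
    y = float((image.sum(axis=1) @ rows) / total)
    x = float((image.sum(axis=0) @ cols) / total)
    return (x, y)


def _bounding_rect(image: np.ndarray) -> tuple[float, float, float, float]:
    """(width, height, aspect ratio, area) of the active region's bounding
    rectangle; zeros when the region is empty."""
    rr, cc = np.nonzero(image >= ACTIVITY_THRESHOLD)
    if rr.size == 0:
        return (0.0, 0.0, 0.0, 0.0)
    width = float(cc.max() - cc.min() + 1)
    height = float(rr.max() - rr.min() + 1)
    return (width, height, width / height, width * height)


def hu_moments(image: np.ndarray) -> np.ndarray:
    """Hu's seven invariant moments of the pressure image (intensity-
    weighted); zeros for an all-zero image."""
    image = np.asarray(image, dtype=float)
    if image.sum() <= 0:
        return np.zeros(7)
    m = measure.moments(image, order=3)
    mc = measure.moments_central(image, order=3)
    mn = measure.moments_normalized(mc, order=3)
    return measure.moments_hu(mn)


def coverage_quantile(image: np.ndarray, q: float) -> float:
    """Smallest fraction of pixels whose (descending) cumulative pressure
    reaches ``q`` of the total; 0 for an all-zero image."""
    if not 0 < q < 1:
        raise ValueError("q must lie strictly between 0 and 1")
    v = np.sort(np.asarray(image, dtype=float).ravel())[::-1]
    total = v.sum()
    if total <= 0:
        return 0.0
    count = int(np.searchsorted(np.cumsum(v), q * total) + 1)
    return count / v.size


def region_coverage(image: np.ndarray) -> np.ndarray:
    """Coverage over four fixed rectangles: the grid is cut at the upper
    third of the long side (rows) and the midpoint of the short side
    (columns); order is top-left, top-right, bottom-left, bottom-right."""
    h, w = image.shape
    rs, cs = h // 3, w // 2
    blocks = [
        image[:rs, :cs],
        image[:rs, cs:],
        image[rs:, :cs],
        image[rs:, cs:],
    ]
    return np.array(
        [float((b > 0).mean()) if b.size else 0.0 for b in blocks]
    )


def contour_regions(image: np.ndarray) -> list[dict]:
    """Connected regions (8-connectivity) of the image binarized at its
    mean pixel value (strictly above).  Each region reports its area
    (pixel count), pressure (pixel sum) and intensity (pressure/area)."""
    image = np.asarray(image, dtype=float)
    mask = image > image.mean()
    labels = measure.label(mask, connectivity=2)
    regions = []
    for lab in range(1, labels.max() + 1):
        sel = labels == lab
        area = int(sel.sum())
        pressure = float(image[sel].sum())
        regions.append(
            {
                "label": lab,
                "mask": sel,
                "area": area,
                "pressure": pressure,
                "intensity": pressure / area,
            }
        )
    return regions


def masked_image(image: np.ndarray, regions: list[dict] | None = None) -> np.ndarray:
    """Zero out everything outside the contour with maximum pressure.

    Ties on pressure break toward the region found first in row-major
    scan order; an image with no contours masks to all zeros.
    """
    image = np.asarray(image, dtype=float)
    if regions is None:
        regions = contour_regions(image)
    if not regions:
        return np.zeros_like(image)
    best = max(regions, key=lambda r: (r["pressure"], -r["label"]))
    out = np.zeros_like(image)
    out[best["mask"]] = image[best["mask"]]
    return out


def _location_features(image: np.ndarray) -> np.ndarray:
    """The 12 location features (Feat9-20 layout): centroid x/y, com x/y,
    their distances to the origin, their angles to the +x axis (radians),
    and the bounding rectangle width/height/aspect/area."""
    cx, cy = centroid_xy(image)
    mx, my = com_xy(image)
    return np.array(
        [
            cx,
            cy,
            mx,
            my,
            float(np.hypot(cx, cy)),
            float(np.hypot(mx, my)),
            float(np.arctan2(cy, cx)),
            float(np.arctan2(my, mx)),
            *_bounding_rect(image),
        ]
    )


def geometric_features(image: np.ndarray) -> np.ndarray:
    """Feat9-52 (44 values) of one pressure image."""
    image = np.asarray(image, dtype=float)
    regions = contour_regions(image)
    masked = masked_image(image, regions)

    if regions:
        max_area = float(max(r["area"] for r in regions))
        max_pressure = float(max(r["pressure"] for r in regions))
        max_intensity = float(max(r["intensity"] for r in regions))
    else:
        max_area = max_pressure = max_intensity = 0.0

    return np.concatenate(
        [
            _location_features(image),  # Feat9-20
            [float((image >= ACTIVITY_THRESHOLD).sum())],  # Feat21
            hu_moments(image),  # Feat22-28
            [float((image > 0).mean())],  # Feat29
            [coverage_quantile(image, q) for q in (0.25, 0.5, 0.75)],  # Feat30-32
            region_coverage(image),  # Feat33-36
            [float(len(regions)), max_area, max_pressure, max_intensity],  # Feat37-40
            _location_features(masked),  # Feat41-52
        ]
    )


# ---------------------------------------------------------------------------
# symmetry features


def _guarded_ratio(a: float, b: float) -> float:
    if b == 0:
        return 1.0 if a == 0 else RATIO_CAP
    return a / b


def _split_features(image: np.ndarray, coord: float, axis: str) -> np.ndarray:
    """Area/pressure of the two sides of a vertical (``axis='x'``) or
    horizontal (``axis='y'``) split, plus their ratios.

    A pixel belongs to the first (left/upper) side iff its coordinate is
    strictly below the split, so the two sides partition the image.
    """
    h, w = image.shape
    if axis == "x":
        idx = np.arange(w) < coord
        side_a = image[:, idx]
        side_b = image[:, ~idx]
    else:
        idx = np.arange(h) < coord
        side_a = image[idx, :]
        side_b = image[~idx, :]
    area_a = float((side_a >= ACTIVITY_THRESHOLD).sum())
    area_b = float((side_b >= ACTIVITY_THRESHOLD).sum())
    press_a = float(side_a.sum())
    press_b = float(side_b.sum())
    return np.array(
        [
            area_a,
            area_b,
            press_a,
            press_b,
            _guarded_ratio(area_a, area_b),
            _guarded_ratio(press_a, press_b),
        ]
    )


def symmetry_features(image: np.ndarray) -> np.ndarray:
    """Feat53-100 (48 values): the 6 split statistics for the four splits
    (com-x, com-y, centroid-x, centroid-y) on the image, then the same 24
    values on its masked image."""
    image = np.asarray(image, dtype=float)

    def block(img: np.ndarray) -> np.ndarray:
        mx, my = com_xy(img)
        cx, cy = centroid_xy(img)
        return np.concatenate(
            [
                _split_features(img, mx, "x"),
                _split_features(img, my, "y"),
                _split_features(img, cx, "x"),
                _split_features(img, cy, "y"),
            ]
        )

    return np.concatenate([block(image), block(masked_image(image))])


# ---------------------------------------------------------------------------
# full vectors


def extract_image(image: np.ndarray) -> np.ndarray:
    """All 100 features of one pressure image, in Feat1..Feat100 order."""
    feats = np.concatenate(
        [
            statistical_features(image),
            geometric_features(image),
            symmetry_features(image),
        ]
    )
    assert feats.shape == (N_FEATURES,)
    if not np.all(np.isfinite(feats)):
        bad = [FEATURE_NAMES[i] for i in np.nonzero(~np.isfinite(feats))[0]]
        raise FloatingPointError(f"non-finite features: {bad}")
    return feats


SAMPLE_FEATURE_NAMES = [f"smoothed/{n}" for n in FEATURE_NAMES] + [
    f"normalized/{n}" for n in FEATURE_NAMES
]


def extract_sample(sample: Sample) -> np.ndarray:
    """The 200-feature vector of one sample: 100 features of the smoothed
    image followed by 100 features of the normalized image."""
    if sample.smoothed_image is None or sample.normalized_image is None:
        raise ValueError("sample must carry both images")
    return np.concatenate(
        [extract_image(sample.smoothed_image), extract_image(sample.normalized_image)]
    )
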