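"""Pressure-image preprocessing: upsampling, smoothing, body-size
normalization and per-round positional alignment.

The processing chain per frame is::

    20x10 raw --(bilinear x3)--> 60x30 --(5x5 Gaussian)--> smoothed
    smoothed --(anthropometric rescale)--> scaled
    scaled --(center on 84x42 canvas, rigid per-round shift)--> normalized

Both the smoothed 60x30 image and the normalized 84x42 image are kept on
each :class:`~smartsleeve.types.Sample`, doubling the images per instance:
rescaling and shifting can destroy information, so the original smoothed
image stays available to downstream feature extraction.

Body-size normalization: rows are rescaled by ``alpha = mean(L_FA)/L_FA(i)``
and columns by ``beta = mean(L_BC)/L_BC(i)`` (forearm length along the arm,
biceps circumference around it), shrinking large subjects' images toward
the cohort-average geometry.  Re-wearing offsets are estimated per round
from the center of mass of the round's "exposure image" (the elementwise
sum of all its frames) and every frame of the round is shifted so all
rounds share the cohort-mean center of mass.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import (
    NORMALIZED_SHAPE,
    ExposureImage,
    RawFrame,
    Sample,
    ScaleRatios,
    SubjectAnthropometrics,
)

logger = logging.getLogger(__name__)


def bilinear_resize(image: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Resize with bilinear interpolation, corner-aligned.

    Output sample positions are ``linspace(0, H-1, out_h)`` per axis, so
    the first/last output rows coincide with the first/last input rows and
    constant images are reproduced exactly.  A singleton output axis
    samples the axis midpoint.
    """
    image = np.asarray(image, dtype=float)
    out_h, out_w = out_shape
    if out_h < 1 or out_w < 1:
        raise ValueError("output dimensions must be >= 1")
    h, w = image.shape
    rows = np.linspace(0.0, h - 1.0, out_h) if out_h > 1 else np.array([(h - 1) / 2.0])
    cols = np.linspace(0.0, w - 1.0, out_w) if out_w > 1 else np.array([(w - 1) / 2.0])
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(image, [rr, cc], order=1, mode="nearest")


def upsample_bilinear(image: np.ndarray, factor: int) -> np.ndarray:
    """Upsample each axis by an integer factor with bilinear interpolation."""
    if factor < 1:
        raise ValueError("upsampling factor must be >= 1")
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    return bilinear_resize(image, (h * factor, w * factor))


def gaussian_kernel(size: int = 5, sigma: float = 1.0) -> np.ndarray:
    """Normalized separable Gaussian kernel of odd side length."""
    half = size // 2
    x = np.arange(-half, half + 1, dtype=float)
    g = np.exp(-(x**2) / (2 * sigma**2))
    g /= g.sum()
    return np.outer(g, g)


def gaussian_smooth(image: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Smooth with a normalized 5x5 Gaussian, reflective borders.

    Shape and non-negativity are preserved; a constant image is returned
    unchanged.
    """
    image = np.asarray(image, dtype=float)
    if image.shape[0] < 5 or image.shape[1] < 5:
        raise ValueError("image must be at least 5x5 to smooth")
    return ndimage.correlate(image, gaussian_kernel(5, sigma), mode="reflect")


def compute_scale_ratios(
    subject: SubjectAnthropometrics, cohort: pd.DataFrame
) -> ScaleRatios:
    """Row/column scale ratios for one subject against the cohort.

    ``alpha`` = cohort-mean forearm length / subject forearm length;
    ``beta`` = cohort-mean biceps circumference / subject circumference.
    """
    if len(cohort) == 0:
        raise ValueError("cohort table is empty")
    fa = cohort["forearm_length_cm"].to_numpy(dtype=float)
    bc = cohort["biceps_circumference_cm"].to_numpy(dtype=float)
    if np.any(fa <= 0) or np.any(bc <= 0):
        raise ValueError("all cohort lengths must be strictly positive")
    return ScaleRatios(
        alpha=fa.mean() / subject.forearm_length_cm,
        beta=bc.mean() / subject.biceps_circumference_cm,
    )


def scale_image(image: np.ndarray, ratios: ScaleRatios) -> np.ndarray:
    """Rescale rows by ``alpha`` and columns by ``beta`` (bilinear).

    Ratios of exactly 1 return the input unchanged.
    """
    image = np.asarray(image, dtype=float)
    if ratios.alpha == 1.0 and ratios.beta == 1.0:
        return image.copy()
    h, w = image.shape
    out_h = int(round(h * ratios.alpha))
    out_w = int(round(w * ratios.beta))
    if out_h < 1 or out_w < 1:
        raise ValueError("scaling would collapse the image below 1 pixel")
    return bilinear_resize(image, (out_h, out_w))


def center_of_mass(image: np.ndarray) -> tuple[float, float] | None:
    """Pressure-weighted mean (row, col); ``None`` for an all-zero image."""
    total = image.sum()
    if total <= 0:
        return None
    rows = np.arange(image.shape[0], dtype=float)
    cols = np.arange(image.shape[1], dtype=float)
    return (
        float((image.sum(axis=1) @ rows) / total),
        float((image.sum(axis=0) @ cols) / total),
    )


def exposure_image(images: list[np.ndarray], round_key: tuple = ()) -> ExposureImage:
    """Sum all images of one round and locate the round's center of mass."""
    if not images:
        raise ValueError("a round must contain at least one frame")
    shapes = {im.shape for im in images}
    if len(shapes) != 1:
        raise ValueError(f"frames of one round must share a shape, got {shapes}")
    total = np.sum(np.stack([np.asarray(im, dtype=float) for im in images]), axis=0)
    com = center_of_mass(total)
    if com is None:
        logger.warning("exposure image of round %s is all zero; com undefined", round_key)
    return ExposureImage(round_key=round_key, image=total, com=com)


def compute_round_offsets(
    exposures: list[ExposureImage],
) -> dict[tuple, tuple[float, float]]:
    """Rigid (d_row, d_col) shift per round toward the mean center of mass.

    The target is the mean of all defined round centers of mass; each
    round's offset is target minus its own center, so offsets average to
    zero across rounds.
    """
    coms = [e.com for e in exposures if e.com is not None]
    if not coms:
        raise ValueError("no round has a defined center of mass")
    target = np.mean(np.asarray(coms), axis=0)
    offsets: dict[tuple, tuple[float, float]] = {}
    for e in exposures:
        if e.com is None:
            offsets[e.round_key] = (0.0, 0.0)
        else:
            offsets[e.round_key] = (
                float(target[0] - e.com[0]),
                float(target[1] - e.com[1]),
            )
    return offsets


def embed_centered(
    image: np.ndarray, out_shape: tuple[int, int] = NORMALIZED_SHAPE
) -> np.ndarray:
    """Zero-pad an image into the center of a larger canvas.

    Inputs larger than the canvas are center-cropped with a warning.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    out_h, out_w = out_shape
    if h > out_h or w > out_w:
        logger.warning(
            "image %s larger than canvas %s; cropping", image.shape, out_shape
        )
        r0 = max(0, (h - out_h) // 2)
        c0 = max(0, (w - out_w) // 2)
        image = image[r0 : r0 + out_h, c0 : c0 + out_w]
        h, w = image.shape
    canvas = np.zeros(out_shape, dtype=float)
    r0 = (out_h - h) // 2
    c0 = (out_w - w) // 2
    canvas[r0 : r0 + h, c0 : c0 + w] = image
    return canvas


def shift_and_pad(
    image: np.ndarray,
    offset: tuple[float, float],
    out_shape: tuple[int, int] = NORMALIZED_SHAPE,
) -> np.ndarray:
    """Embed an image centered on the zero canvas and translate it rigidly.

    Fractional offsets are applied by bilinear resampling; content shifted
    beyond the canvas is discarded and the result is clipped at zero to
    guard against interpolation round-off.
    """
    canvas = embed_centered(image, out_shape)
    if offset != (0.0, 0.0):
        canvas = ndimage.shift(canvas, offset, order=1, mode="constant", cval=0.0)
    return np.maximum(canvas, 0.0)


def preprocess_dataset(
    frames: list[RawFrame],
    anthropometrics: pd.DataFrame,
    sigma: float = 1.0,
    upsample_factor: int = 3,
) -> list[Sample]:
    """Run the full preprocessing chain over a labeled frame list.

    Every frame yields one :class:`Sample` carrying the smoothed 60x30
    image and the normalized 84x42 image.  Subjects without a row in
    ``anthropometrics`` raise a ``KeyError``.
    """
    anthro_by_id = {
        int(row["subject_id"]): SubjectAnthropometrics(
            subject_id=int(row["subject_id"]),
            forearm_length_cm=float(row["forearm_length_cm"]),
            biceps_circumference_cm=float(row["biceps_circumference_cm"]),
        )
        for _, row in anthropometrics.iterrows()
    }

    smoothed: list[np.ndarray] = []
    embedded: list[np.ndarray] = []
    by_round: dict[tuple, list[int]] = defaultdict(list)
    for i, frame in enumerate(frames):
        if frame.subject_id not in anthro_by_id:
            raise KeyError(f"no anthropometrics for subject {frame.subject_id}")
        sm = gaussian_smooth(upsample_bilinear(frame.values, upsample_factor), sigma)
        ratios = compute_scale_ratios(anthro_by_id[frame.subject_id], anthropometrics)
        scaled = scale_image(sm, ratios)
        smoothed.append(sm)
        embedded.append(embed_centered(scaled))
        by_round[(frame.subject_id, frame.round_id)].append(i)

    if not frames:
        return []

    exposures = [
        exposure_image([embedded[i] for i in idx], round_key=key)
        for key, idx in by_round.items()
    ]
    if any(e.com is not None for e in exposures):
        offsets = compute_round_offsets(exposures)
    else:  # fully empty dataset (e.g. all-zero frames): nothing to align
        offsets = {e.round_key: (0.0, 0.0) for e in exposures}
    for key, (dr, dc) in sorted(offsets.items()):
        logger.info("round %s offset: (%.3f, %.3f) px", key, dr, dc)

    samples: list[Sample] = []
    for i, frame in enumerate(frames):
        key = (frame.subject_id, frame.round_id)
        normalized = _apply_offset(embedded[i], offsets[key])
        samples.append(
            Sample(
                subject_id=frame.subject_id,
                round_id=frame.round_id,
                activity=frame.activity,
                smoothed_image=smoothed[i],
                normalized_image=normalized,
            )
        )
    return samples


def _apply_offset(canvas: np.ndarray, offset: tuple[float, float]) -> np.ndarray:
    if offset == (0.0, 0.0):
        return np.maximum(canvas, 0.0)
    return np.maximum(
        ndimage.shift(canvas, offset, order=1, mode="constant", cval=0.0), 0.0
    )
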