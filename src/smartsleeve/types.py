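"""Core domain containers for the pressure-sleeve pipeline.

A *frame* (or *pressure image*) is one simultaneous readout of the 20x10
textile sensor matrix, 12-bit values in [0, 4095].  A *sample* is one
activity instance carrying two processed images: the smoothed 60x30 image
and the body-size-normalized 84x42 image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GRID_ROWS = 20
GRID_COLS = 10
ADC_MAX = 4095

SMOOTHED_SHAPE = (60, 30)
NORMALIZED_SHAPE = (84, 42)


@dataclass
class RawFrame:
    """One 20x10 pressure image with its labels."""

    values: np.ndarray  # (20, 10) float array, >= 0
    subject_id: int
    round_id: int
    activity: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (GRID_ROWS, GRID_COLS):
            raise ValueError(
                f"frame must be {GRID_ROWS}x{GRID_COLS}, got {self.values.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("pressure values must be non-negative")


@dataclass
class SubjectAnthropometrics:
    """Forearm length and biceps circumference of one subject (cm)."""

    subject_id: int
    forearm_length_cm: float
    biceps_circumference_cm: float

    def __post_init__(self) -> None:
        if self.forearm_length_cm <= 0 or self.biceps_circumference_cm <= 0:
            raise ValueError("anthropometric lengths must be strictly positive")


@dataclass
class ScaleRatios:
    """Row/column rescaling ratios for one subject.

    alpha rescales rows (along the arm, driven by forearm length) and beta
    rescales columns (around the arm, driven by biceps circumference); both
    are cohort-mean length divided by the subject's length, so larger
    subjects get ratios < 1 and their images shrink.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("scale ratios must be strictly positive")


@dataclass
class ExposureImage:
    """Elementwise sum of all frames of one wearing round, plus its
    pressure-weighted center of mass in fractional (row, col) pixels.

    ``com`` is ``None`` when the summed image is identically zero.
    """

    round_key: tuple
    image: np.ndarray
    com: tuple[float, float] | None


@dataclass
class Sample:
    """One activity instance after preprocessing: both image variants."""

    subject_id: int
    round_id: int
    activity: str
    smoothed_image: np.ndarray  # (60, 30)
    normalized_image: np.ndarray  # (84, 42)

    def __post_init__(self) -> None:
        if self.smoothed_image.shape != SMOOTHED_SHAPE:
            raise ValueError(f"smoothed image must be {SMOOTHED_SHAPE}")
        if self.normalized_image.shape != NORMALIZED_SHAPE:
            raise ValueError(f"normalized image must be {NORMALIZED_SHAPE}")


@dataclass
class EvalResult:
    """Cross-validated classification result.

    Metrics are fractions in [0, 1], averaged over folds; the confusion
    matrix pools all test predictions (rows = true class, cols = predicted).
    """

    scheme: str  # "kfold" | "loso"
    classifier: str
    accuracy: float
    macro_p: float
    macro_r: float
    macro_f1: float
    per_fold: list[dict] = field(default_factory=list)
    confusion: np.ndarray | None = None
    labels: list[str] = field(default_factory=list)
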