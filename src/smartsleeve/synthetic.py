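"""Synthetic pressure-sleeve datasets.

Generates labeled 20x10 frames with the statistical structure the real
recordings exhibit: each activity has a characteristic contact pattern
(a sum of anisotropic Gaussian bumps), bigger-armed subjects press a
larger area (contact extent scales with forearm length along rows and
biceps circumference across columns), every wearing round carries one
rigid positional offset (the sleeve is re-worn between rounds), and
readings are integer 12-bit ADC counts with additive sensor noise.

Because a subject's blob geometry is stretched by exactly
``L_FA(i) / mean(L_FA)`` in rows and ``L_BC(i) / mean(L_BC)`` in columns,
the anthropometric rescaling in :mod:`smartsleeve.preprocessing` can be
shown to undo the size effect — the key recovery property the pipeline
is tested against.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .types import ADC_MAX, GRID_COLS, GRID_ROWS, RawFrame

# Table-derived plausible cohort ranges (cm)
FOREARM_RANGE_CM = (23.0, 28.0)
BICEPS_RANGE_CM = (21.0, 38.0)


def default_activity_blobs() -> dict[str, list[tuple[float, float, float, float, float]]]:
    """Load the 18 shipped activity archetypes.

    Returns a mapping from activity name to a list of blobs
    ``(center_row, center_col, row_sd, col_sd, peak_amplitude)``.
    """
    ref = importlib.resources.files("smartsleeve").joinpath("activities.yaml")
    spec = yaml.safe_load(ref.read_text())
    return {
        name: [tuple(float(v) for v in blob) for blob in blobs]
        for name, blobs in spec["activities"].items()
    }


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic-data generator.

    Parameters
    ----------
    n_subjects, n_rounds
        Cohort size and number of re-wearing rounds per subject.
    activities
        Activity names; defaults to the 18 shipped archetypes.
    blob_specs
        Mapping activity -> list of (row, col, row_sd, col_sd, amplitude)
        blobs on the grid.  Defaults to the shipped archetypes.
    size_effect
        Strength of the body-size effect in [0, 1].  1 means contact
        extent scales fully with the subject's anthropometrics; 0 disables
        between-subject size differences.
    round_offset_sd
        Standard deviation (grid pixels) of the per-round rigid shift;
        draws are rounded to integer pixels.
    blob_floor
        Contact patches on a resistive fabric have compact support — the
        sensor reads zero where nothing presses — so blob values below
        this many ADC counts are truncated to zero, keeping the Gaussian
        bump from trailing off across the whole grid.
    noise_sd
        Additive Gaussian noise, in ADC counts, applied per pixel before
        integer quantization.  Frames emulate per-activity *averaged*
        images (many raw 50 Hz frames averaged), so the residual noise is
        far smaller than single-readout ADC noise; the default of 1
        count corresponds to tens of counts of raw readout noise averaged
        over a recording.
    """

    n_subjects: int = 14
    n_rounds: int = 10
    activities: list[str] | None = None
    grid_rows: int = GRID_ROWS
    grid_cols: int = GRID_COLS
    adc_max: int = ADC_MAX
    blob_specs: dict[str, list[tuple]] | None = None
    size_effect: float = 1.0
    round_offset_sd: float = 1.0
    blob_floor: float = 150.0
    noise_sd: float = 1.0
    seed: int = 0
    _blobs: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_rounds < 1:
            raise ValueError("n_subjects and n_rounds must be >= 1")
        if self.adc_max <= 0:
            raise ValueError("adc_max must be positive")
        if self.noise_sd < 0 or self.round_offset_sd < 0:
            raise ValueError("noise_sd and round_offset_sd must be >= 0")
        blobs = self.blob_specs if self.blob_specs is not None else default_activity_blobs()
        if self.activities is None:
            self.activities = list(blobs)
        missing = [a for a in self.activities if a not in blobs]
        if missing:
            raise ValueError(f"no blob spec for activities: {missing}")
        for name in self.activities:
            for r, c, *_ in blobs[name]:
                if not (0 <= r < self.grid_rows and 0 <= c < self.grid_cols):
                    raise ValueError(
                        f"blob center ({r}, {c}) of activity {name!r} outside "
                        f"{self.grid_rows}x{self.grid_cols} grid"
                    )
        self._blobs = {name: blobs[name] for name in self.activities}


def generate_anthropometrics(n_subjects: int, seed: int = 0) -> pd.DataFrame:
    """Sample a subject table with forearm length and biceps circumference.

    Lengths are uniform over the plausible adult ranges 23-28 cm (forearm)
    and 21-38 cm (biceps circumference); deterministic under ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "subject_id": np.arange(n_subjects),
            "forearm_length_cm": rng.uniform(*FOREARM_RANGE_CM, size=n_subjects),
            "biceps_circumference_cm": rng.uniform(*BICEPS_RANGE_CM, size=n_subjects),
        }
    )


def _render_frame(
    blobs: list[tuple],
    row_factor: float,
    col_factor: float,
    offset: tuple[int, int],
    shape: tuple[int, int],
    floor: float = 0.0,
) -> np.ndarray:
    """Evaluate the blob sum on the grid.

    The noiseless image is ``I(r, c) = I_0(r / row_factor - dr,
    c / col_factor - dc)`` where ``I_0`` is the unit-size archetype, so a
    bilinear resize by ``1/row_factor, 1/col_factor`` followed by a rigid
    shift recovers the archetype.
    """
    rows = np.arange(shape[0], dtype=float)[:, None] / row_factor - offset[0]
    cols = np.arange(shape[1], dtype=float)[None, :] / col_factor - offset[1]
    image = np.zeros(shape, dtype=float)
    for cr, cc, sr, sc, amp in blobs:
        image += amp * np.exp(
            -((rows - cr) ** 2 / (2 * sr**2) + (cols - cc) ** 2 / (2 * sc**2))
        )
    image[image < floor] = 0.0
    return image


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[list[RawFrame], pd.DataFrame]:
    """Generate a fully labeled synthetic dataset.

    Returns exactly ``n_subjects * n_rounds * len(activities)`` frames —
    one averaged pressure image per (subject, round, activity) — together
    with the cohort anthropometrics table.  All values are integer ADC
    counts clipped to ``[0, adc_max]``; everything is reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    anthro = generate_anthropometrics(
        config.n_subjects, seed=int(rng.integers(2**31))
    )
    mean_fa = anthro["forearm_length_cm"].mean()
    mean_bc = anthro["biceps_circumference_cm"].mean()

    shape = (config.grid_rows, config.grid_cols)
    frames: list[RawFrame] = []
    for _, subj in anthro.iterrows():
        sid = int(subj["subject_id"])
        row_factor = 1.0 + config.size_effect * (subj["forearm_length_cm"] / mean_fa - 1.0)
        col_factor = 1.0 + config.size_effect * (subj["biceps_circumference_cm"] / mean_bc - 1.0)
        for round_id in range(config.n_rounds):
            offset = tuple(
                int(np.rint(d))
                for d in rng.normal(0.0, config.round_offset_sd, size=2)
            )
            for activity in config.activities:
                clean = _render_frame(
                    config._blobs[activity],
                    row_factor,
                    col_factor,
                    offset,
                    shape,
                    floor=config.blob_floor,
                )
                noisy = clean + rng.normal(0.0, config.noise_sd, size=shape)
                values = np.clip(np.rint(noisy), 0, config.adc_max)
                frames.append(
                    RawFrame(
                        values=values,
                        subject_id=sid,
                        round_id=round_id,
                        activity=activity,
                    )
                )
    return frames, anthro
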