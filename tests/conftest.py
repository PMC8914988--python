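import numpy as np
import pytest
from hypothesis import settings

from smartsleeve import preprocessing as pp
from smartsleeve import synthetic

settings.register_profile("default", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_dataset():
    """6 subjects x 3 rounds x 18 activities with all effects enabled."""
    cfg = synthetic.SyntheticConfig(n_subjects=6, n_rounds=3, seed=7)
    frames, anthro = synthetic.generate_dataset(cfg)
    return cfg, frames, anthro


@pytest.fixture(scope="session")
def small_samples(small_dataset):
    _, frames, anthro = small_dataset
    return pp.preprocess_dataset(frames, anthro)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def flood_fill_regions(mask):
    """Brute-force 8-connected component labeling by BFS; the independent
    oracle for the contour statistics."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    regions = []
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            stack, pixels = [(r0, c0)], []
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                pixels.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (
                            0 <= rr < mask.shape[0]
                            and 0 <= cc < mask.shape[1]
                            and mask[rr, cc]
                            and not seen[rr, cc]
                        ):
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            regions.append(pixels)
    return regions
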