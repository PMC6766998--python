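import numpy as np
import pytest

import seedspectra as ss


@pytest.fixture(scope="session")
def strong_profiles():
    """Seven variety profiles with a strong planted signal: 10 discriminative
    bands per class offset by 0.05 reflectance."""
    return ss.make_variety_profiles(
        n_classes=7, band_count=200, n_discriminative=10, deviation=0.05,
        rng_seed=11)


@pytest.fixture(scope="session")
def strong_table(strong_profiles):
    """Seed-level spectra in the strong-signal regime (deviation/noise = 5)."""
    return ss.make_labeled_spectra(strong_profiles, n_per_class=60,
                                   noise_sd=0.01, rng_seed=21)


@pytest.fixture(scope="session")
def noiseless_scene(strong_profiles):
    spec = ss.SceneSpec(image_shape=(96, 96), seeds_per_image=5,
                        noise_sd_additive=0.0, noise_sd_multiplicative=0.0,
                        rng_seed=3)
    return ss.render_scene(spec, strong_profiles, [0, 1, 2, 3, 4])


def flood_fill_components(binary: np.ndarray, connectivity: int = 8) -> int:
    """Brute-force connected-component count by breadth-first flood fill."""
    binary = np.asarray(binary, dtype=bool)
    seen = np.zeros_like(binary)
    if connectivity == 8:
        steps = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                 if (dy, dx) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    count = 0
    rows, cols = binary.shape
    for y0 in range(rows):
        for x0 in range(cols):
            if not binary[y0, x0] or seen[y0, x0]:
                continue
            count += 1
            stack = [(y0, x0)]
            seen[y0, x0] = True
            while stack:
                y, x = stack.pop()
                for dy, dx in steps:
                    ny, nx = y + dy, x + dx
                    if (0 <= ny < rows and 0 <= nx < cols
                            and binary[ny, nx] and not seen[ny, nx]):
                        seen[ny, nx] = True
                        stack.append((ny, nx))
    return count
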