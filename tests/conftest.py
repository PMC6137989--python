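import numpy as np
import pytest

from zdep.islands import call_islands
from zdep.pipeline import pool_tracks
from zdep.simulate import SimulationConfig, simulate_bundle


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def bundle(default_config):
    """Full synthetic bundle on default settings (shared, read-only)."""
    return simulate_bundle(default_config)


@pytest.fixture(scope="session")
def pooled_tracks(bundle):
    out = {}
    for cond in ("control", "stress"):
        for role in ("chip", "input"):
            reps = [bundle.tracks[f"{cond}_{role}_r{r}"] for r in (1, 2)]
            out[(cond, role)] = pool_tracks(reps, f"{cond}_{role}_pooled")
    return out


@pytest.fixture(scope="session")
def control_islands(pooled_tracks):
    return call_islands(pooled_tracks[("control", "chip")],
                        pooled_tracks[("control", "input")])


def random_track_pair(rng, n_windows=40, n_chroms=1, rate=4.0, window=200):
    """A small random chip/control track pair on a shared grid."""
    from zdep.io import CoverageTrack

    chip, ctrl = {}, {}
    for i in range(n_chroms):
        chrom = f"chr{i + 1}"
        chip[chrom] = rng.poisson(rng.uniform(0.5, 3) * rate, n_windows).astype(float)
        ctrl[chrom] = rng.poisson(rate, n_windows).astype(float)
        # sprinkle spiky enrichment so islands actually form
        for _ in range(rng.integers(0, 4)):
            w = rng.integers(0, n_windows)
            chip[chrom][w] += rng.poisson(8 * rate)
    a = CoverageTrack("chip", window, chip)
    b = CoverageTrack("ctrl", window, ctrl)
    return a, b
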