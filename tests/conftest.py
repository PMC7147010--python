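import numpy as np
import pytest

from ewsbench.cohort import build_cohort_frame
from ewsbench.scoring import AvpuLevel, VitalSet, load_bundled_systems
from ewsbench.simulate import SimulationConfig, generate_frame


@pytest.fixture(scope="session")
def systems():
    return load_bundled_systems()


@pytest.fixture(scope="session")
def default_cohort():
    """One shared n=20000 simulated cohort, built once per session."""
    frame, truth = generate_frame(SimulationConfig(n_encounters=20000, seed=42))
    cohort, flow = build_cohort_frame(frame)
    return frame, truth, cohort, flow


def random_vitalset(rng, on_oxygen=None) -> VitalSet:
    """Physiologically plausible random complete vital set."""
    return VitalSet(
        sbp=float(rng.uniform(40, 250)),
        hr=float(rng.uniform(25, 200)),
        temp=float(rng.uniform(26, 43)),
        rr=float(rng.uniform(2, 50)),
        spo2=float(rng.uniform(60, 100)),
        loc=AvpuLevel(int(rng.integers(0, 4))),
        agitated=bool(rng.integers(0, 2)),
        on_oxygen=bool(rng.integers(0, 2)) if on_oxygen is None else on_oxygen,
    )


def band_representatives(scale):
    """One value inside every band of a scale."""
    out = []
    for b in scale.bands:
        if b.lower == -np.inf:
            out.append(b.upper - 1.0)
        elif b.upper == np.inf:
            out.append(b.lower + 1.0)
        else:
            out.append((b.lower + b.upper) / 2.0)
    return out
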