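import numpy as np
import pandas as pd
import pytest

from elbar import SignalSet, SimConfig, simulate_manifest, simulate_sample


def make_sigset(rows, controls=None, sample_id="toy"):
    """rows: list of (probe_id, design, M, U, oob_M, oob_U)."""
    probes = pd.DataFrame(
        rows, columns=["probe_id", "design", "M", "U", "oob_M", "oob_U"]
    ).set_index("probe_id")
    if controls is None:
        ctl = pd.DataFrame(columns=["control_id", "channel", "intensity"])
    else:
        ctl = pd.DataFrame(controls, columns=["control_id", "channel", "intensity"])
    return SignalSet(sample_id=sample_id, probes=probes, neg_controls=ctl)


@pytest.fixture
def toy_sigset():
    """Four background-level type-II probes plus two strong foreground ones."""
    nan = float("nan")
    return make_sigset(
        [
            ("A", "II", 10, 10, nan, nan),
            ("B", "II", 12, 8, nan, nan),
            ("C", "II", 9, 11, nan, nan),
            ("D", "II", 11, 9, nan, nan),
            ("E", "II", 400, 0, nan, nan),
            ("F", "II", 0, 380, nan, nan),
        ]
    )


@pytest.fixture(scope="session")
def sim_low_input():
    """A 4000-probe low-input sample with ground truth (shared across tests)."""
    cfg = SimConfig(n_probes=4000, seed=11, input_scale=0.01)
    man = simulate_manifest(cfg)
    sigset, truth = simulate_sample(man, cfg)
    return man, cfg, sigset, truth
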