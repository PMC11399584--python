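"""Shared fixtures: all inputs are generated programmatically at test time."""

import numpy as np
import pandas as pd
import pytest

from plasmaome.pipeline import analyze_synthetic
from plasmaome.synthetic import SimConfig, generate_study, make_design


@pytest.fixture(scope="session")
def default_study():
    """The default 90-sample, 3-modality synthetic study (fixed seed)."""
    return generate_study(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_results(default_study):
    """Full pipeline results on the default study (default 10k permutations)."""
    return analyze_synthetic(default_study, seed=1)


@pytest.fixture(scope="session")
def design_no_plex():
    return make_design(10, with_plexes=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def toy_design(n_mice: int = 4, n_draws: int = 3) -> pd.DataFrame:
    """Tiny balanced design: half the mice adult, one adult mouse on HFD."""
    rows = []
    batches = ["Z10", "Z22", "Z15"][:n_draws]
    for m in range(n_mice):
        age = "adult" if m >= n_mice // 2 else "young"
        diet = "hfd" if m == n_mice - 1 else "chow"
        for k, batch in enumerate(batches):
            rows.append({"sample_id": f"s{m}_{k}", "mouse_id": f"m{m}",
                         "age_group": age, "diet": diet, "draw_batch": batch,
                         "plex": None, "channel": None, "is_bridge": False})
    return pd.DataFrame(rows)
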