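import numpy as np
import pandas as pd
import pytest

from forageval import synthetic


@pytest.fixture(scope="session")
def preset():
    return synthetic.stay_green_preset()


@pytest.fixture(scope="session")
def preset_data(preset):
    design, specs = preset
    return synthetic.generate_trial(design, specs, seed=7)


@pytest.fixture(scope="session")
def noiseless_data():
    design, specs = synthetic.stay_green_preset(residual_scale=0.0)
    return synthetic.generate_trial(design, specs, seed=1)


def random_balanced_trial(seed: int, trait: str = "y") -> pd.DataFrame:
    """Random 2x2x2x3 balanced dataset with arbitrary cell structure."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in ("CK", "SG"):
        for l in ("HZ", "YM"):
            for y in ("2023", "2024"):
                for r in range(1, 4):
                    rows.append(
                        {"genotype": g, "location": l, "year": y, "replicate": r,
                         trait: rng.normal()}
                    )
    return pd.DataFrame(rows)
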