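import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from bcivalidate.datatypes import GeneratorConfig, MorphometricRecord
from bcivalidate.synthetic_data import generate_dataset


def make_clean_config(**overrides) -> GeneratorConfig:
    """A generator config that produces data surviving cleaning intact."""
    defaults = dict(
        n=300,
        seed=0,
        zero_fat_prob=0.0,
        flag_probs={},
        days_held_range=(0, 4),
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


def records_from_arrays(svl, mass, fat=None, sex=None, days=None):
    """Build validated records directly from numeric arrays."""
    svl = np.asarray(svl, float)
    mass = np.asarray(mass, float)
    n = len(svl)
    fat = np.full(n, np.nan) if fat is None else np.asarray(fat, float)
    recs = []
    for i in range(n):
        f = fat[i] if np.isfinite(fat[i]) else 0.01 * mass[i]
        recs.append(
            MorphometricRecord(
                id=f"r{i:04d}",
                sex="female" if sex is None else sex[i],
                svl_cm=float(svl[i]),
                mass_g=float(mass[i]),
                fat_g=float(f),
                days_held=0 if days is None else int(days[i]),
            )
        )
    return recs


@pytest.fixture(scope="session")
def clean_records():
    """300 clean moment-model records (no flags, no zero fat)."""
    return generate_dataset(make_clean_config())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
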