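import os

# pin BLAS threading before numpy loads: keeps training runs bit-reproducible
# across machines with different core counts
for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest

from facedep import synthetic
from facedep.cohort import CohortSample
from facedep.openface_io import select_features


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_spec():
    """4-second clips: long enough for 30-frame windows, fast to train on."""
    return synthetic.SignatureSpec(duration_s=4.0)


@pytest.fixture
def tiny_table(tiny_spec):
    return synthetic.generate_participant("moderate", tiny_spec, seed=3)


def make_samples(counts, duration_s=2.0, seed=0, spec=None):
    """In-memory cohort: counts = (normal, mild, moderate, severe)."""
    spec = spec or synthetic.SignatureSpec(duration_s=duration_s)
    cohort = synthetic.generate_cohort(counts, spec, seed=seed)
    return [
        CohortSample.from_severity(pid, level, select_features(table, pid))
        for pid, (table, level) in zip(cohort.participant_ids, cohort.samples)
    ]


def label_only_samples(counts):
    """Metadata-only cohort (no series) for split/balance arithmetic."""
    levels = ["normal", "mild", "moderate", "severe"]
    out = []
    i = 0
    for level, n in zip(levels, counts):
        for _ in range(n):
            out.append(CohortSample.from_severity(f"P{i:04d}", level))
            i += 1
    return out


@pytest.fixture
def numgrad():
    def _numgrad(f, x, eps=1e-6):
        g = np.zeros_like(x)
        it = np.nditer(x, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            x[i] += eps
            fp = f(x)
            x[i] -= 2 * eps
            fm = f(x)
            x[i] += eps
            g[i] = (fp - fm) / (2 * eps)
        return g

    return _numgrad
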