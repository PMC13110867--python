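import numpy as np
import pytest
from hypothesis import settings

from argsweep import Metric, SimSpec, Sample, Sequence, TreeBuildConfig
from argsweep.simulate import simulate_sample

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


def make_sample(bits_rows, positions=None, l=None, mu_prime=1e-8, Ne=1e4):
    """Sample from explicit 0/1 rows (one row per haplotype)."""
    seqs = [Sequence.from_bits([int(b) for b in r]) for r in bits_rows]
    s = seqs[0].s
    if positions is None:
        positions = [10.0 * (k + 1) for k in range(s)]
    if l is None:
        l = positions[-1] + 10.0
    return Sample(seqs, positions, l, mu_prime, Ne)


@pytest.fixture
def four_gamete_sample():
    # all four gametes at two markers: no tree explains both
    return make_sample(["00", "01", "10", "11"])


def random_samples(n_cases, rng, n_max=20, s_max=40, l=4e4):
    """Stream of small synthetic samples from the builtin simulator."""
    out = []
    trial = 0
    while len(out) < n_cases:
        trial += 1
        n = int(rng.integers(4, n_max + 1))
        seed = int(rng.integers(1, 2**31 - 1))
        sample = simulate_sample(SimSpec(n=n, l=l, seed=seed), engine="builtin")
        if 2 <= sample.s <= s_max:
            out.append(sample)
    return out
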