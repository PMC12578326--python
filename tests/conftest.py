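import numpy as np
import pytest

from parallign import FixtureSpec, PlantedGroup, render_fixture, run_single


@pytest.fixture(scope="session")
def standard_fixture():
    """Noiseless planted fixture: groups {2, 3, 4} plus 5 distractors."""
    return render_fixture(FixtureSpec(seed=3))


@pytest.fixture(scope="session")
def standard_result(standard_fixture):
    img, _ = standard_fixture
    return run_single(img)


@pytest.fixture(scope="session")
def jittered_spec():
    """Factory for noisy fixtures with 5 deg within-group angle jitter."""

    def make(seed, noise_sigma=10.0):
        return FixtureSpec(
            seed=seed,
            noise_sigma=noise_sigma,
            planted_groups=(
                PlantedGroup(2, 10.0, jitter_deg=5.0),
                PlantedGroup(3, 60.0, jitter_deg=5.0),
                PlantedGroup(4, 120.0, jitter_deg=5.0),
            ),
        )

    return make


def exact_binom_pmf(n, k):
    """Independent oracle: Binomial(n, 1/n) pmf in exact rational arithmetic."""
    from fractions import Fraction
    from math import comb

    return Fraction(comb(n, k)) * Fraction(1, n) ** k * Fraction(n - 1, n) ** (n - k)
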