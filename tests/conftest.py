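import pytest

from neoprog import (CharacteristicDescriptor, ClassDistribution, CohortSpec,
                     generate_cohort)


@pytest.fixture(scope="session")
def motor_dist():
    return ClassDistribution.packaged_defaults("motor")


@pytest.fixture(scope="session")
def cognitive_dist():
    return ClassDistribution.packaged_defaults("cognitive")


@pytest.fixture(scope="session")
def study_cohort(motor_dist):
    """A motor-outcome-sized cohort: 103 subjects at 12.6% prevalence."""
    spec = CohortSpec(n_subjects=103, prevalence=0.126, seed=7)
    return generate_cohort(spec, motor_dist)


@pytest.fixture(scope="session")
def planted_cohort(motor_dist):
    """Cohort with one strongly localised characteristic planted for the
    delayed class (mI/Cr in right central white matter, octile 3)."""
    char = CharacteristicDescriptor("mI/Cr", "CWMR")
    spec = CohortSpec(n_subjects=103, prevalence=0.126,
                      planted_localised=((char, 3),), seed=21)
    return generate_cohort(spec, motor_dist), char


def shifted_distribution(base: ClassDistribution, chars, shift_sd: float):
    """Copy of ``base`` where on the given characteristics the delayed class
    sits ``shift_sd`` class SDs above the non-delayed class (equal SDs) — a
    planted separable signal of known effect size."""
    delayed = dict(base.delayed)
    for c in chars:
        m, s = base.normal[c]
        delayed[c] = (m + shift_sd * s, s)
    return ClassDistribution(delayed=delayed, normal=dict(base.normal),
                             rho=base.rho)


def brute_force_ld(all_values, delayed_values):
    """Independent LD oracle: test each delayed value against each of the 8
    explicit interval bounds (left-closed, last right-closed)."""
    lo, hi = min(all_values), max(all_values)
    bounds = [lo] + [lo + (hi - lo) * k / 8.0 for k in range(1, 8)] + [hi]
    occupied = set()
    for v in delayed_values:
        for k in range(8):
            if bounds[k] <= v < bounds[k + 1] or (k == 7 and v <= bounds[8]):
                occupied.add(k)
                break
    return len(occupied) / 8.0
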