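import itertools
import random

import pytest

from bgsc import (
    EGFR_DESIGN,
    KnockdownTreatment,
    NestedDesign,
    Priors,
    RegulatorChannel,
    derive_pattern_groups,
)


@pytest.fixture(scope="session")
def egfr_design():
    return EGFR_DESIGN


@pytest.fixture(scope="session")
def egfr_patterns(egfr_design):
    return derive_pattern_groups(egfr_design)


@pytest.fixture(scope="session")
def pattern_by_label(egfr_patterns):
    return {p.label: p for p in egfr_patterns}


@pytest.fixture(scope="session")
def egfr_priors():
    return Priors({"a": 0.7, "b": 0.1, "c": 0.1, "d": 0.1})


def brute_force_pattern_partition(design):
    """Independent oracle: tabulate every mode x treatment response directly.

    Returns a set of (indicator, frozenset-of-regulator-subsets) pairs — a
    labeling-free description of the pattern partition.
    """
    channels = [c.name for c in design.channels]
    partition = {}
    for r in range(len(channels) + 1):
        for subset in itertools.combinations(channels, r):
            regulators = frozenset(subset)
            indicator = []
            for t in design.treatments:
                indicator.append(0)
                alive = regulators - t.knocked_down
                indicator.append(1 if alive else 0)
            partition.setdefault(tuple(indicator), set()).add(regulators)
    return {(ind, frozenset(members)) for ind, members in partition.items()}


def random_design(rng: random.Random, max_channels: int = 5, max_treatments: int = 4):
    """A random valid nested-style design (control first, arbitrary knockdowns)."""
    k = rng.randint(1, max_channels)
    channels = tuple(RegulatorChannel(f"ch{i}") for i in range(k))
    names = [c.name for c in channels]
    n_t = rng.randint(1, max_treatments)
    treatments = [KnockdownTreatment("control")]
    for j in range(1, n_t):
        kd = frozenset(n for n in names if rng.random() < 0.5)
        treatments.append(KnockdownTreatment(f"trt{j}", kd))
    return NestedDesign(channels, tuple(treatments))
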