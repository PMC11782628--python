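import numpy as np
import pandas as pd
import pytest

from memtrace import linking, lss
from memtrace.simulate import (BehaviorParams, NoiseSpec, PatternSpec,
                               TaskDesign, generate_association_schedule,
                               generate_localizer_schedule, simulate_behavior,
                               simulate_bold, simulate_localizer_behavior)


@pytest.fixture(scope="session")
def design():
    return TaskDesign()


@pytest.fixture(scope="session")
def assoc_schedule(design):
    return generate_association_schedule(design, seed=11)


@pytest.fixture(scope="session")
def assoc_behavior(assoc_schedule):
    return simulate_behavior(assoc_schedule, BehaviorParams(seed=12))


@pytest.fixture(scope="session")
def assoc_factors(assoc_behavior):
    return linking.code_factors(assoc_behavior)


@pytest.fixture(scope="session")
def localizer_schedule(design):
    return simulate_localizer_behavior(
        generate_localizer_schedule(design, seed=21), seed=21)


@pytest.fixture(scope="session")
def pattern():
    return PatternSpec.default(seed=0)


def correct_rejection(row) -> bool:
    return (not row["is_repetition"]) and (not row["pressed"])


@pytest.fixture(scope="session")
def localizer_betaseries(design, localizer_schedule, pattern):
    """Correct-rejection stimulus betaseries over all five localizer runs,
    simulated at default (study-condition) noise."""
    spec = lss.LssSpec(epoch="stimulus", smoothing_fwhm=0,
                       trial_filter=correct_rejection)
    mats, metas = [], []
    for run in sorted(localizer_schedule["run"].unique()):
        sub = localizer_schedule[localizer_schedule["run"] == run]
        vol, truth = simulate_bold(sub, pattern, NoiseSpec(seed=300 + run), design)
        maps, meta = lss.lss_deconvolve(vol, sub, truth.confounds, spec)
        bs = lss.extract_roi(maps, meta, pattern.roi_mask, fwhm=0)
        mats.append(bs.matrix)
        metas.append(bs.trial_meta)
    return lss.BetaSeries(np.vstack(mats), pd.concat(metas, ignore_index=True),
                          pattern.roi_mask)
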