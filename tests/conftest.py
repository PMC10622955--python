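"""Shared fixtures.

The expensive fixture is ``multiseed_runs``: ten independent end-to-end
experiments (cohort simulation, CNN training at the default protocol,
BrainAGE scoring, attention mapping, and a matched null cohort), shared by
the acceptance tests that quantify offset recovery, model sanity, attention
localization and null calibration.
"""

from __future__ import annotations

import pytest

from brainage.phantom import CohortSpec, generate_cohort
from brainage.pipeline import signal_and_null_run

#: root seeds of the repeated-seed experiments (fixed a priori)
EXPERIMENT_SEEDS = tuple(range(1, 11))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for unit-level checks (not the study conditions)."""
    return generate_cohort(
        CohortSpec(n_training=48, n_controls=12, n_patients=24, seed=7)
    )


@pytest.fixture(scope="session")
def multiseed_runs():
    """Ten seeds of the full-protocol experiment at the study conditions:
    200 training phantoms at 32^3, 24 controls, 70 patients with an injected
    aging offset ~N(4, 2) truncated at zero, default training protocol."""
    return [signal_and_null_run(seed) for seed in EXPERIMENT_SEEDS]
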