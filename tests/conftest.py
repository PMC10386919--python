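from __future__ import annotations

import pytest

from microcost import (
    Arm,
    DELIVERY_ARMS,
    load_observed_fixture,
    observed_participant_flow,
    observed_templates,
    per_participant,
    summarize_arm,
)


@pytest.fixture(scope="session")
def flow():
    return observed_participant_flow()


@pytest.fixture(scope="session")
def observed_summaries(flow):
    """ArmSummary per arm from the packaged observed ledgers."""
    return {arm: summarize_arm(load_observed_fixture(arm), arm) for arm in DELIVERY_ARMS}


@pytest.fixture(scope="session")
def observed_per_participant(observed_summaries, flow):
    return {
        arm: per_participant(summary, flow.recipients(arm))
        for arm, summary in observed_summaries.items()
    }


@pytest.fixture(scope="session")
def templates():
    return observed_templates()
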