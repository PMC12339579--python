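"""Shared fixtures: synthetic banks and hand-built session results."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from vocabcat.cat import (
    AdministeredItem,
    AdministrationConfig,
    Respondent,
    SessionResult,
    is_complete,
    record_response,
    select_next_item,
    start_session,
)
from vocabcat.item_bank import Kind
from vocabcat.simulate import BankSpec, make_synthetic_bank

_counter = itertools.count()


@pytest.fixture(scope="session")
def admin_bank():
    """A 100-item synthetic bank (60/20/20) with known true difficulties."""
    bank, truth = make_synthetic_bank(BankSpec(n_items=100), seed=7)
    return bank, truth


def run_policy_session(bank, policy, seed=0, config=None):
    """Administer a full session answering via ``policy(item, state) -> raw``."""
    config = config or AdministrationConfig(seed=seed)
    state = start_session(bank, config)
    while not is_complete(state):
        item = select_next_item(state, bank)
        record_response(state, item, policy(item, state), bank)
    return state


def make_result(
    session_id=None,
    vocabulary_size=60_000,
    age=30.0,
    nativeness="native",
    attention_index=95.0,
    duration=120.0,
    honesty=True,
    ended_at=None,
    theta=0.0,
    theta_se=0.4,
    item_log=(),
):
    """A SessionResult built directly, for filter/stats tests."""
    if session_id is None:
        session_id = f"s{next(_counter):04d}"
    return SessionResult(
        session_id=session_id,
        theta=theta,
        theta_se=theta_se,
        vocabulary_size=vocabulary_size,
        attention_index=attention_index,
        trustworthy=attention_index >= 70,
        duration=duration,
        respondent=Respondent(age=age, nativeness=nativeness, honesty_confirmed=honesty),
        item_log=tuple(item_log),
        ended_at=ended_at,
    )


def scored_log(pairs, prefix="w"):
    """An item log of scored binary records from (item_id, score) pairs."""
    return tuple(
        AdministeredItem(
            item_id=iid,
            kind=Kind.BINARY,
            answer="know" if score else "dont_know",
            option=None,
            scored=score,
            presented_options=None,
        )
        for iid, score in pairs
    )
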