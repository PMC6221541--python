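"""Shared fixtures: the full preset runs are expensive (tens of seconds), so
they are computed once per session and reused by the unit and acceptance
tests."""

from __future__ import annotations

import pytest

from denticle_rd.pipeline import run_preset


@pytest.fixture(scope="session")
def catshark_run():
    return run_preset("catshark")


@pytest.fixture(scope="session")
def gap_run():
    return run_preset("catshark_gap")


@pytest.fixture(scope="session")
def thornback_run():
    return run_preset("thornback")


@pytest.fixture(scope="session")
def little_skate_run():
    return run_preset("little_skate")
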