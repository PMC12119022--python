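"""Shared fixtures: bundled tables, configs and cached scenario runs."""

from __future__ import annotations

import pytest
from hypothesis import settings

import pigch4
from pigch4 import fixtures
from pigch4.scenario import run_standard_scenario

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")

CATEGORIES = fixtures.CATEGORIES


@pytest.fixture(scope="session")
def feed_table():
    return fixtures.feed_table()


@pytest.fixture(scope="session")
def managements():
    configs, storage = fixtures.management()
    return configs, storage


@pytest.fixture(scope="session")
def average_diets():
    return {cat: fixtures.average_diet(cat) for cat in CATEGORIES}


@pytest.fixture(scope="session")
def average_scenarios():
    """Full-chain results for the average diet of every category (cached:
    the manure simulation dominates suite runtime)."""
    return {cat: run_standard_scenario(cat) for cat in CATEGORIES}


@pytest.fixture(scope="session")
def grower_diet_scenarios():
    """Full-chain results for all five grower-finisher diets."""
    return {name: run_standard_scenario("grower_finisher", name)
            for name in fixtures.standard_diets("grower_finisher")}
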