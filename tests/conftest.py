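"""Shared fixtures: small deterministic covariance models.

Everything is generated programmatically; no data files. Model collections
are session-scoped because toy construction is cheap but link computations
are not, and several tests share the same models.
"""

from __future__ import annotations

import numpy as np
import pytest

from cmlink.toymodels import ToyModelSpec, build_toy_cm, random_toy_spec


@pytest.fixture(scope="session")
def single_column_model():
    """One MATL column, consensus A."""
    return build_toy_cm(ToyModelSpec("A", ".", seed=1, name="one"))


@pytest.fixture(scope="session")
def hairpin_model():
    return build_toy_cm(ToyModelSpec("ACGU", "(..)", seed=2, name="hairpin"))


@pytest.fixture(scope="session")
def chain_model():
    return build_toy_cm(ToyModelSpec("ACGU", "....", seed=3, name="chain"))


@pytest.fixture(scope="session")
def bif_model():
    """Two-hairpin model with one bifurcation."""
    return build_toy_cm(
        ToyModelSpec("AAACCCUUUGGG", "((..))((..))", seed=4, name="twohp")
    )


@pytest.fixture(scope="session")
def clan_table():
    """All-vs-all table over the planted clan fixture (shared: 10 links)."""
    from cmlink.toymodels import clan_fixture
    from cmlink.workflows import compare_all_vs_all

    return compare_all_vs_all(clan_fixture())


@pytest.fixture(scope="session")
def small_models():
    """A mixed bag of small bifurcation-free models for oracle sweeps."""
    rng = np.random.default_rng(2024)
    return [
        build_toy_cm(
            random_toy_spec(rng, min_len=1, max_len=4, allow_bif=False, name=f"s{i}")
        )
        for i in range(8)
    ]
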