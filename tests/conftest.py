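"""Shared fixtures: synthetic cohorts, rendered fixtures, and one session-scoped
leave-one-out run that several statistical tests inspect."""

from __future__ import annotations

import numpy as np
import pytest

from fundusage.crossval import loocv
from fundusage.synthetic import CohortSpec, generate_cohort, make_fixture_suite


@pytest.fixture(scope="session")
def cohort1000():
    """Default-condition cohort at n=1000: (table, generating truth)."""
    return generate_cohort(CohortSpec(n=1000, seed=123))


@pytest.fixture(scope="session")
def cohort500():
    """The end-to-end evaluation cohort: n=500, age = linear(features) + N(0, 3)."""
    return generate_cohort(CohortSpec(n=500, seed=11))


@pytest.fixture(scope="session")
def loocv500(cohort500):
    """Nested-CV leave-one-out result on the n=500 cohort (one run, shared)."""
    table, _ = cohort500
    return loocv(table, lambda_strategy="inner_cv", seed=3)


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    """A rendered fixture tree: 12 PNGs + landmark JSONs + one cohort CSV."""
    out = tmp_path_factory.mktemp("suite")
    manifest = make_fixture_suite(out, seed=5)
    return out, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
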