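"""Shared fixtures: the default synthetic dataset and its derived products.

Generating the default dataset and screening its proteome takes a few
seconds, so both are session-scoped and shared by unit and acceptance
tests.
"""

from __future__ import annotations

import pytest

from bactgrn.expression import ExpressionMatrix, deg_table
from bactgrn.grn import assign_targets, build_grn
from bactgrn.homology import screen_tfs
from bactgrn.motif import scan_all, transfer_pwm
from bactgrn.synth import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def dataset0():
    """Default-configuration synthetic dataset, seed 0."""
    return generate_dataset(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def screen0(dataset0):
    return screen_tfs(dataset0.proteome, dataset0.ref_proteins)


@pytest.fixture(scope="session")
def sites0(dataset0, screen0):
    pwms = transfer_pwm(screen0, dataset0.ref_pwms)
    return scan_all(pwms, dataset0.genome)


@pytest.fixture(scope="session")
def grn0(dataset0, screen0, sites0):
    raw = assign_targets(sites0, dataset0.annotation)
    return build_grn(raw, screen0.keys())


@pytest.fixture(scope="session")
def matrix0(dataset0):
    return ExpressionMatrix(
        dataset0.counts, dataset0.config.timepoints, dataset0.config.control
    )


@pytest.fixture(scope="session")
def degs0(matrix0):
    return deg_table(matrix0)
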