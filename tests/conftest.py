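"""Shared fixtures: small synthetic datasets and canonical example reactions."""

from dataclasses import replace

import pytest

from reaction_ad import builtin_suites, generate
from reaction_ad.benchmark import BenchmarkConfig, CVPlan

SN2 = "[CH3:1][Br:2].[OH-:3]>>[CH3:1][OH:3].[Br-:2]"
SN2_ETHYL = "[CH3:4][CH2:1][Br:2].[OH-:3]>>[CH3:4][CH2:1][OH:3].[Br-:2]"
SN2_CHLORIDE = "[CH3:1][Cl:2].[OH-:3]>>[CH3:1][OH:3].[Cl-:2]"
IDENTITY = "[CH4:1]>>[CH4:1]"
ZWITTERION = "[NH3+:1][CH2:2][C:3](=[O:4])[O-:5]>>[NH2:1][CH2:2][C:3](=[O:4])[OH:5]"
# two independent substitutions in one reaction -> two reaction centers
DOUBLE_SUBSTITUTION = (
    "[CH3:1][Br:2].[OH-:3].[CH3:4][I:5].[SH-:6]"
    ">>[CH3:1][OH:3].[Br-:2].[CH3:4][SH:6].[I-:5]"
)


@pytest.fixture(scope="session")
def suites():
    return builtin_suites()


@pytest.fixture(scope="session")
def substitution_dataset(suites):
    """80 substitution reactions with 5% gross Y-outliers."""
    spec = replace(suites["substitution-like"], outlier_fraction=0.05)
    return generate(spec, n=80, seed=11)


@pytest.fixture(scope="session")
def elimination_dataset(suites):
    return generate(suites["elimination-like"], n=80, seed=12)


@pytest.fixture(scope="session")
def zwitterion_dataset(suites):
    return generate(suites["zwitterion-tautomer-like"], n=40, seed=13)


@pytest.fixture(scope="session")
def fast_config():
    """Small forests keep unit tests quick; contracts are size-independent."""
    return BenchmarkConfig(n_trees=40, qrpr_max_features_grid=(1.0,))


@pytest.fixture(scope="session")
def fast_plan():
    return CVPlan(n_outer=3, n_inner=3, seed=7)
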