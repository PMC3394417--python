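import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cmrf import FitConfig, GeneNetwork, GroupData, TwoGroupExpressionData

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def chain_network() -> GeneNetwork:
    """a -> b -> c."""
    return GeneNetwork(genes=["a", "b", "c"], edges={("a", "b"), ("b", "c")})


@pytest.fixture
def fast_config() -> FitConfig:
    """Small differential-evolution budget for quick end-to-end fits."""
    return FitConfig(de_maxiter=30, de_pop=20, max_cycles=6, seed=0)


def make_two_group(
    genes,
    shift_A=None,
    shift_B=None,
    n=30,
    mu=0.0,
    sigma=1.0,
    seed=0,
) -> TwoGroupExpressionData:
    """Gaussian two-group data with per-gene non-control mean shifts.

    ``shift_A`` / ``shift_B`` map gene -> additive non-control shift for
    that group (default: no shift anywhere).
    """
    rng = np.random.default_rng(seed)
    shift_A = shift_A or {}
    shift_B = shift_B or {}
    cols = [f"s{j}" for j in range(n)]
    groups = {}
    for grp, shifts in (("A", shift_A), ("B", shift_B)):
        ctrl = pd.DataFrame(
            rng.normal(mu, sigma, size=(len(genes), n)), index=genes, columns=cols
        )
        non = pd.DataFrame(
            rng.normal(mu, sigma, size=(len(genes), n)), index=genes, columns=cols
        )
        for g, s in shifts.items():
            non.loc[g] += s
        groups[grp] = GroupData(control=ctrl, noncontrol=non)
    return TwoGroupExpressionData(groupA=groups["A"], groupB=groups["B"])
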