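import numpy as np
import pytest

from mmtt_metab import population_kinetics
from mmtt_metab.beta_cell_model import BetaCellParams
from mmtt_metab.synthetic_cohort import mmtt_glucose_curve

MMTT_TIMES = np.array([0.0, 15, 30, 45, 60, 90, 120, 150, 180])


@pytest.fixture(scope="session")
def kinetics():
    """Population kinetics for the packaged reference case (60 y man, 170 cm,
    70 kg, type 2 diabetes)."""
    return population_kinetics(60, "M", 170, 70, diabetes=True)


@pytest.fixture(scope="session")
def meal_glucose():
    """Dense meal-test glucose curve: fasting 7.5 mmol/l, +3.0 peak at 45 min."""
    return mmtt_glucose_curve(7.5, 3.0)


@pytest.fixture(scope="session")
def sample_times():
    return MMTT_TIMES.copy()


def make_truth(grid, slope=0.75, gs=60.0, isr55=110.0, rs=500.0):
    """Ground-truth beta cell parameter set with log-linear mean-1 potentiation."""
    lp = slope * (grid - grid.mean()) / 180.0
    p = np.exp(lp)
    p = p / (np.trapezoid(p, grid) / (grid[-1] - grid[0]))
    return BetaCellParams(
        glucose_sensitivity=gs, isr_at_5_5=isr55, rate_sensitivity=rs,
        potentiation_time=grid, potentiation=p,
    )
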