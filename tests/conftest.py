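import numpy as np
import pytest

from tipcascade.hydro import MonthlyField


def month_axis(start_year: int, n_months: int, start_month: int = 1):
    lin = np.arange(n_months) + (start_year * 12 + start_month - 1)
    return lin // 12, lin % 12 + 1


def make_field(values, start_year=2000, start_month=1, name="precipitation"):
    """MonthlyField from an (n_cells, n_time) array with a contiguous axis."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    years, months = month_axis(start_year, values.shape[1], start_month)
    return MonthlyField(values, years, months, name=name)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def brute_mcwd(p12, e12):
    """Step-by-step deficit recursion oracle for one 12-month block."""
    cwd, low = 0.0, 0.0
    for p, e in zip(p12, e12):
        cwd = min(0.0, cwd + (p - e))
        low = min(low, cwd)
    return abs(low)
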