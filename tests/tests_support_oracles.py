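"""Independent closed-form oracles used by the test suite.

These deliberately avoid the package's own code paths (and scipy's
``ttest_ind``): the t statistic and its degrees of freedom are computed
from first principles, with only the t distribution's survival function
taken from scipy.
"""

import numpy as np
from scipy import stats


def closed_form_ttest_p(x, y, equal_var=True):
    """Two-sided two-sample t-test p-value from the textbook formulas."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    diff = x.mean() - y.mean()
    if equal_var:
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se = np.sqrt(sp2 * (1 / nx + 1 / ny))
        df = nx + ny - 2
    else:
        se = np.sqrt(vx / nx + vy / ny)
        df = (vx / nx + vy / ny) ** 2 / (
            (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
        )
    t = diff / se
    return 2 * stats.t.sf(abs(t), df)
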