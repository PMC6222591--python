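"""Segregation-ratio chi-squared test for complementation and F2 checks.

A complementation cross between two recessive mutants is scored by
comparing observed phenotype counts with the Mendelian ratio expected
under allelism (1:1 when one parent is heterozygous, 1:3 for a selfed
heterozygote).  No Yates continuity correction is applied: the plain
Pearson statistic is the convention for segregation tests (with the
correction, 12 mutants in 26 F1s against 1:1 would give p ~ 0.84 rather
than the conventional ~ 0.69).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats as sstats


def segregation_chi_square(
    observed: Sequence[float], expected_ratio: Sequence[float]
) -> tuple[float, int, float]:
    """Pearson chi-squared goodness of fit to a segregation ratio.

    Parameters
    ----------
    observed : class counts (e.g. [mutant, wild-type]).
    expected_ratio : positive weights defining the expected ratio
        (e.g. [1, 1] or [1, 3]).

    Returns
    -------
    (chi2, df, p) with df = number of classes - 1 and p the upper-tail
    probability of the chi-squared distribution.
    """
    obs = np.asarray(observed, dtype=float)
    w = np.asarray(expected_ratio, dtype=float)
    if obs.ndim != 1 or obs.shape != w.shape or len(obs) < 2:
        raise ValueError("observed and expected_ratio must be equal-length, >= 2")
    if obs.sum() <= 0:
        raise ValueError("total observed count must be positive")
    if np.any(w <= 0):
        raise ValueError("ratio weights must be positive")
    if np.any(obs < 0):
        raise ValueError("observed counts must be non-negative")
    expected = obs.sum() * w / w.sum()
    if np.any(expected == 0):
        raise ValueError("an expected class count is zero")
    chi2, p = sstats.chisquare(obs, expected)
    return float(chi2), len(obs) - 1, float(p)
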