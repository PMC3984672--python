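"""Cross-platform and cross-preservation agreement metrics.

Rank concordance (Spearman), binary-classifier sensitivity/specificity with
one side as the reference standard, and dilution-series linearity of the
digital counting readout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import fraction_rsquared, spearman_exact_p
from .probes import ProbeCountMatrix


def rank_concordance(x, y, exact_max_n: int = 10) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided test; ties get average
    ranks. The p-value uses exact permutation enumeration for n <= 10 and the
    t-approximation above that."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need aligned vectors of length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant vector")
    rho, p_t = stats.spearmanr(x, y)
    if len(x) <= exact_max_n:
        return float(rho), float(spearman_exact_p(x, y))
    return float(rho), float(p_t)


@dataclass
class ClassifierMetrics:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float | None:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else None

    @property
    def specificity(self) -> float | None:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else None


def binary_agreement(reference, test) -> ClassifierMetrics:
    """Confusion metrics treating ``reference`` (e.g. frozen-tissue calls) as
    truth and ``test`` (e.g. FFPE calls) as the classifier. Sides where a
    metric is undefined (single-class reference) report None."""
    ref = np.asarray(reference, dtype=bool)
    tst = np.asarray(test, dtype=bool)
    if ref.shape != tst.shape:
        raise ValueError("reference and test must align")
    return ClassifierMetrics(
        tp=int(np.sum(ref & tst)),
        fp=int(np.sum(~ref & tst)),
        tn=int(np.sum(~ref & ~tst)),
        fn=int(np.sum(ref & ~tst)),
    )


def dilution_linearity(
    series: ProbeCountMatrix, fractions, probe_id: str
) -> dict:
    """Least-squares line of a probe's counts against the mixing fraction of
    the variant-high sample; the coefficient of determination quantifies
    readout linearity."""
    fr = np.asarray(fractions, dtype=float)
    if len(fr) < 3:
        raise ValueError("need >=3 dilution fractions")
    y = series.counts[probe_id].to_numpy(dtype=float)
    if len(y) != len(fr):
        raise ValueError("one series sample per fraction expected")
    slope, intercept = np.polyfit(fr, y, 1)
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "r_squared": fraction_rsquared(fr, y),
    }
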