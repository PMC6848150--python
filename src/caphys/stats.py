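"""Group statistics: Welch's unequal-variance t test and proportion arithmetic."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (reporting convention for percentages)."""
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass
class GroupComparison:
    group_a_label: str
    group_b_label: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t_stat: float
    df_welch: float
    p_two_tailed: float
    measure: str = ""
    units: str = ""
    defined: bool = True


def welch_t_test(
    sample_a,
    sample_b,
    label_a: str = "A",
    label_b: str = "B",
    measure: str = "",
    units: str = "",
) -> GroupComparison:
    """Unpaired two-tailed t test with Welch's correction.

    t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b), degrees of freedom by
    Welch-Satterthwaite, two-tailed p from the t distribution.  When both
    samples have zero variance and equal means the statistic is undefined
    and reported as NaN with ``defined=False``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")

    na, nb = a.size, b.size
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sem_a = math.sqrt(va / na)
    sem_b = math.sqrt(vb / nb)
    se2 = va / na + vb / nb

    if se2 == 0.0:
        # zero variance in both samples: t undefined when means are equal
        return GroupComparison(
            group_a_label=label_a,
            group_b_label=label_b,
            n_a=na,
            n_b=nb,
            mean_a=ma,
            mean_b=mb,
            sem_a=sem_a,
            sem_b=sem_b,
            t_stat=math.nan,
            df_welch=math.nan,
            p_two_tailed=math.nan,
            measure=measure,
            units=units,
            defined=False,
        )

    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return GroupComparison(
        group_a_label=label_a,
        group_b_label=label_b,
        n_a=na,
        n_b=nb,
        mean_a=ma,
        mean_b=mb,
        sem_a=sem_a,
        sem_b=sem_b,
        t_stat=t,
        df_welch=df,
        p_two_tailed=p,
        measure=measure,
        units=units,
    )


def proportion_responding(n_responders: int, n_total: int, decimals: int = 1) -> float:
    """Responding percentage, 100 * n_responders / n_total, rounded half-up.

    ``decimals=1`` matches the slice-report convention; pass ``decimals=0``
    for whole-percent reporting.
    """
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_responders <= n_total:
        raise ValueError("n_responders must be in [0, n_total]")
    return round_half_up(100.0 * n_responders / n_total, decimals)


def sem(sample) -> float:
    """Standard error of the mean, s / sqrt(n)."""
    a = np.asarray(sample, dtype=float)
    if a.size < 2:
        return math.nan
    return float(a.std(ddof=1) / math.sqrt(a.size))
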