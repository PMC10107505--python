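"""Replicate statistics: Grubbs outlier rejection and box-size aggregation.

Each simulation condition yields one kappa (or G) value per replicate and
per solvent-box size.  Values are screened with the two-sided Grubbs
(Smirnov-Grubbs) test at alpha = 0.05, applied iteratively — the single
most extreme value is tested and, if significant, removed, until the
remaining set is clean.  Reported numbers are the mean +/- sample standard
deviation over the retained values pooled across the selected box sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import ConfigError, InputError

__all__ = ["ValueSet", "grubbs_critical", "grubbs_filter", "aggregate"]


@dataclass
class ValueSet:
    """Replicate values for one condition with their retention mask."""

    values: np.ndarray
    label: str = ""
    retained_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if self.retained_mask is not None:
            self.retained_mask = np.asarray(self.retained_mask, dtype=bool)

    @property
    def retained(self) -> np.ndarray:
        if self.retained_mask is None:
            return self.values
        return self.values[self.retained_mask]


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value for sample size n.

    ``G_crit = (n-1)/sqrt(n) * sqrt(t^2 / (n - 2 + t^2))`` with t the upper
    ``alpha/(2n)`` quantile of Student's t with n-2 degrees of freedom.
    """
    if n < 3:
        raise InputError("grubbs_critical: need n >= 3")
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))


def grubbs_filter(
    values, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative two-sided Grubbs screening.

    Repeatedly tests the value farthest from the mean and removes it while
    its statistic ``|x - mean| / sd`` exceeds the critical value; stops when
    nothing is significant or only two values would remain.  Order of the
    input does not affect which values are flagged.

    Returns
    -------
    (retained, outliers) : pair of ndarray
        Retained values keep their input order.
    """
    vals = np.atleast_1d(np.asarray(values, dtype=float))
    mask = grubbs_mask(vals, alpha)
    return vals[mask], vals[~mask]


def grubbs_mask(values, alpha: float = 0.05) -> np.ndarray:
    """Boolean retention mask aligned with the input order."""
    vals = np.atleast_1d(np.asarray(values, dtype=float))
    if vals.size < 3:
        raise InputError("grubbs_filter: need at least 3 values")
    mask = np.ones(vals.size, dtype=bool)
    while mask.sum() >= 3:
        sub = vals[mask]
        mean, sd = sub.mean(), sub.std(ddof=1)
        if sd == 0.0:
            break
        dev = np.abs(sub - mean) / sd
        k = int(np.argmax(dev))
        if dev[k] <= grubbs_critical(int(sub.size), alpha):
            break
        mask[np.nonzero(mask)[0][k]] = False
    return mask


@dataclass(frozen=True)
class AggregateResult:
    mean: float
    sd: float
    n_retained: int
    n_total: int
    outliers: np.ndarray


def aggregate(
    values_by_box: dict,
    boxes: tuple[float, ...] = (3.0, 4.0, 4.5),
    alpha: float = 0.05,
    apply_filter: bool = True,
) -> AggregateResult:
    """Pool replicate values across box sizes and report mean +/- SD.

    Outlier screening (when enabled) runs per box-size value set before
    pooling; the pooled convention weights every retained value equally
    regardless of how many survive in each box.  SD uses the n-1
    denominator.

    Raises
    ------
    ConfigError
        If a requested box size is absent, listing the available ones.
    """
    missing = [b for b in boxes if b not in values_by_box]
    if missing:
        raise ConfigError(
            f"aggregate: box sizes {missing} not available; "
            f"have {sorted(values_by_box)}"
        )
    pooled: list[np.ndarray] = []
    outliers: list[np.ndarray] = []
    n_total = 0
    for b in boxes:
        vs = values_by_box[b]
        vals = vs.values if isinstance(vs, ValueSet) else np.atleast_1d(
            np.asarray(vs, dtype=float)
        )
        n_total += vals.size
        if apply_filter and vals.size >= 3:
            kept, out = grubbs_filter(vals, alpha)
        else:
            kept, out = vals, np.empty(0)
        pooled.append(kept)
        outliers.append(out)
    allv = np.concatenate(pooled)
    sd = float(allv.std(ddof=1)) if allv.size >= 2 else 0.0
    return AggregateResult(
        mean=float(allv.mean()),
        sd=sd,
        n_retained=int(allv.size),
        n_total=n_total,
        outliers=np.concatenate(outliers),
    )
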