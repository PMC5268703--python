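"""Bootstrap standard errors and two-sample tests for ensemble observables.

Frames are treated as independent observations, mirroring common MD
practice; because consecutive frames are autocorrelated this tends to
understate standard errors and overstate significance, so a block
bootstrap (blocks = replicas) is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from .errors import ConfigurationError, DegenerateTestError, EmptyInputError

#: Reporting floor used for formatted p-values, below which the exact
#: value is shown as "< 2.2e-16" (machine outputs keep the raw value).
P_VALUE_FLOOR = 2.2e-16


def bootstrap_se(
    values,
    n_reps: int = 1000,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> float:
    """Bootstrap standard error of the mean of ``values``.

    Resamples the observations with replacement ``n_reps`` times and
    returns the standard deviation of the resampled means.  Fully
    reproducible for a given (seed, n_reps).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise EmptyInputError("cannot bootstrap an empty sample")
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    idx = rng.integers(0, values.size, size=(n_reps, values.size))
    means = values[idx].mean(axis=1)
    return float(np.std(means, ddof=0))


def block_bootstrap_se(
    blocks: list[np.ndarray],
    n_reps: int = 1000,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> float:
    """Bootstrap SE of the pooled mean resampling whole blocks (replicas).

    Resamples blocks with replacement and recomputes the pooled mean,
    which respects within-replica autocorrelation.
    """
    blocks = [np.asarray(b, dtype=float) for b in blocks if len(b)]
    if not blocks:
        raise EmptyInputError("cannot bootstrap empty blocks")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    means = np.empty(n_reps)
    k = len(blocks)
    for r in range(n_reps):
        pick = rng.integers(0, k, size=k)
        means[r] = np.mean(np.concatenate([blocks[i] for i in pick]))
    return float(np.std(means, ddof=0))


def students_t(sample_a, sample_b, welch: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test: (t statistic, p-value).

    Classic pooled-variance Student's test by default; ``welch=True``
    switches to the unequal-variance variant.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateTestError("both samples need at least 2 observations")
    if np.var(a) == 0 and np.var(b) == 0:
        raise DegenerateTestError("zero variance in both samples: test undefined")
    t, p = sp_stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def format_p(p: float) -> str:
    """Human-readable p-value with the conventional 2.2e-16 floor."""
    if p < P_VALUE_FLOOR:
        return f"< {P_VALUE_FLOOR:.1e}"
    return f"{p:.3g}"


@dataclass
class ComparisonReport:
    """Two-condition comparison of one observable."""

    observable: str
    condition_a: str
    condition_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    mean_difference: float
    t_statistic: float
    p_value: float
    se_a: float
    se_b: float
    bootstrap_reps: int
    seed: int

    @property
    def p_display(self) -> str:
        return format_p(self.p_value)


def compare_conditions(
    observable: str,
    values_a,
    values_b,
    *,
    labels: tuple[str, str] = ("A", "B"),
    n_reps: int = 1000,
    seed: int = 0,
    welch: bool = False,
) -> ComparisonReport:
    """Compare one observable between two conditions.

    Reports means, bootstrap SEs, the mean difference (B − A) and a
    Student's t-test of the difference.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ConfigurationError(
            f"observable {observable!r}: both conditions need data"
        )
    t, p = students_t(a, b, welch=welch)
    ss_a, ss_b = np.random.SeedSequence(seed).spawn(2)
    return ComparisonReport(
        observable=observable,
        condition_a=labels[0],
        condition_b=labels[1],
        n_a=a.size,
        n_b=b.size,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        mean_difference=float(b.mean() - a.mean()),
        t_statistic=t,
        p_value=p,
        se_a=bootstrap_se(a, n_reps, ss_a),
        se_b=bootstrap_se(b, n_reps, ss_b),
        bootstrap_reps=n_reps,
        seed=seed,
    )
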