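"""Group-level statistics: Mann–Whitney U, FDR screening, per-animal
aggregation and simulation-based power analysis.

All two-group comparisons are nonparametric (Mann–Whitney U, two-sided).
Per-frequency power spectra are screened with Benjamini–Hochberg FDR
control. Because recording sessions from one animal are not independent,
metrics can be re-aggregated to one value per animal before testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import PipelineError

__all__ = [
    "GroupComparison",
    "mann_whitney_u",
    "compare_groups",
    "per_frequency_comparison",
    "aggregate_per_animal",
    "power_sample_size",
]


@dataclass
class GroupComparison:
    """Summary of a two-group Mann–Whitney comparison of one metric."""

    metric: str
    u_statistic: float
    p_value: float
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    n_a: int
    n_b: int
    aggregation_level: str = "session"

    def as_dict(self) -> dict:
        return {
            "metric": self.metric,
            "U": self.u_statistic,
            "p": self.p_value,
            "mean_a": self.mean_a,
            "sem_a": self.sem_a,
            "mean_b": self.mean_b,
            "sem_b": self.sem_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "aggregation_level": self.aggregation_level,
        }


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Returns ``(U, p)`` with U the statistic for the first group (number of
    pairs (x, y) with x > y, midranks for ties). The p-value is exact for
    small tie-free samples (min(n) <= 8) and uses the tie-corrected normal
    approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise PipelineError("both groups must be nonempty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _sem(x: np.ndarray) -> float:
    if x.size < 2:
        return float("nan")
    return float(x.std(ddof=1) / np.sqrt(x.size))


def compare_groups(
    metric: str,
    a: Sequence[float],
    b: Sequence[float],
    aggregation_level: str = "session",
) -> GroupComparison:
    """Mann–Whitney comparison with mean +/- SEM summaries per group."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    u, p = mann_whitney_u(a, b)
    return GroupComparison(
        metric=metric,
        u_statistic=u,
        p_value=p,
        mean_a=float(a.mean()),
        sem_a=_sem(a),
        mean_b=float(b.mean()),
        sem_b=_sem(b),
        n_a=int(a.size),
        n_b=int(b.size),
        aggregation_level=aggregation_level,
    )


def per_frequency_comparison(
    spectra_a: np.ndarray,
    spectra_b: np.ndarray,
    freqs: Sequence[float],
    q: float = 0.05,
) -> pd.DataFrame:
    """Mann–Whitney test at every frequency step with BH-FDR control.

    ``spectra_a``/``spectra_b`` are (session x frequency) power matrices on
    the same grid. Returns a frame with columns ``freq``, ``p``,
    ``significant`` (the BH mask at level ``q``).
    """
    spectra_a = np.atleast_2d(np.asarray(spectra_a, dtype=float))
    spectra_b = np.atleast_2d(np.asarray(spectra_b, dtype=float))
    freqs = np.asarray(freqs, dtype=float)
    if spectra_a.shape[1] != freqs.size or spectra_b.shape[1] != freqs.size:
        raise PipelineError("spectra columns must match the frequency grid")
    if min(spectra_a.shape[0], spectra_b.shape[0]) < 3:
        raise PipelineError("need at least 3 sessions per group")
    pvals = np.empty(freqs.size)
    for k in range(freqs.size):
        _, pvals[k] = mann_whitney_u(spectra_a[:, k], spectra_b[:, k])
    reject, _, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return pd.DataFrame({"freq": freqs, "p": pvals, "significant": reject})


def aggregate_per_animal(values: pd.DataFrame, value_col: str = "value",
                         animal_col: str = "animal_id") -> pd.Series:
    """Collapse session-level values to one unweighted mean per animal.

    Used to test robustness against within-animal dependence (e.g. volume
    conduction making same-animal recordings non-independent).
    """
    if animal_col not in values or values[animal_col].isna().any():
        raise PipelineError("every value needs an animal id")
    return values.groupby(animal_col, sort=True)[value_col].mean()


def power_sample_size(
    sample_a: Callable[[np.random.Generator, int], np.ndarray],
    sample_b: Callable[[np.random.Generator, int], np.ndarray],
    power: float = 0.9,
    alpha: float = 0.05,
    reps: int = 1000,
    n_max: int = 200,
    seed: int | None = None,
) -> tuple[int, bool]:
    """Monte-Carlo minimal equal group size for a Mann–Whitney test.

    ``sample_a``/``sample_b`` draw ``n`` values from each group's effect
    distribution. Returns ``(n, attainable)``: the smallest n per group at
    which the empirical rejection rate reaches ``power``, searched
    monotonically (doubling then bisection); ``attainable`` is False if the
    target is not reached by ``n_max`` (e.g. a null effect, where power
    equals alpha).
    """
    if reps < 1:
        raise PipelineError("reps must be >= 1")
    rng = np.random.default_rng(seed)

    def achieved(n: int) -> float:
        hits = 0
        for _ in range(reps):
            _, p = mann_whitney_u(sample_a(rng, n), sample_b(rng, n))
            hits += p < alpha
        return hits / reps

    lo, hi = 2, 2
    while achieved(hi) < power:
        if hi >= n_max:
            return n_max, False
        lo, hi = hi, min(2 * hi, n_max)
    while lo + 1 < hi:
        mid = (lo + hi) // 2
        if achieved(mid) >= power:
            hi = mid
        else:
            lo = mid
    return hi, True
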