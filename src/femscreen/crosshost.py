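"""Cross-host comparison of developmental expression profiles.

A gene's per-stage mean log2 expression ratios in the native host are
compared with its profile in a heterologous host using the sample
cross-correlation function over small integer stage lags, after an
autocorrelation pre-check on each series.  The two isopod hosts differ in
the timing of sexual differentiation by one intermolt stage, so a genuine
shared expression program shows up as a significant cross-correlation at
lag 1 (or lag 0 when no shift is present).  Eta squared summarizes how much
of the replicate variance is explained by stage, as a guard that noisy
profiles are not driving an apparent correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class CrossHostError(ValueError):
    pass


@dataclass
class StageSeries:
    """Ordered per-stage mean log2 ratios for one gene in one host."""

    host: str
    gene: str
    stages: tuple[int, ...]
    values: tuple[float, ...]
    #: optional per-stage replicate values (list per stage), kept for eta^2
    replicates: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self) -> None:
        if len(self.stages) != len(self.values):
            raise CrossHostError("stage and value lengths differ")
        if len(self.stages) < 5:
            raise CrossHostError("need at least 5 stages")
        if any(b != a + 1 for a, b in zip(self.stages, self.stages[1:])):
            raise CrossHostError("stages must be consecutive (no interior gaps)")


@dataclass
class CrossCorrResult:
    gene: str
    lags: tuple[int, ...]
    ccf: tuple[float, ...]
    best_lag: int
    best_ccf: float
    significant: bool
    eta_sq_a: float | None = None
    eta_sq_b: float | None = None
    flags: list[str] = field(default_factory=list)


def _check_variance(x: np.ndarray, label: str) -> float:
    sd = float(x.std())
    if sd == 0.0:
        raise CrossHostError(f"constant series ({label}): zero variance")
    return sd


def autocorrelation(
    series: StageSeries, max_lag: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sample ACF with overall-mean centering and lag-0 normalization.

    Returns (acf values for lags 0..max_lag, significance flags); lag l >= 1
    is flagged when |acf(l)| exceeds the white-noise band 1.96/sqrt(n).
    """
    x = np.asarray(series.values, dtype=float)
    n = x.size
    if n < max_lag + 3:
        raise CrossHostError(f"series too short for max_lag={max_lag}")
    _check_variance(x, series.gene)
    centered = x - x.mean()
    denom = float(np.sum(centered ** 2))
    acf = np.array(
        [np.sum(centered[: n - l] * centered[l:]) / denom for l in range(max_lag + 1)]
    )
    band = 1.96 / np.sqrt(n)
    flags = np.abs(acf) > band
    flags[0] = False
    return acf, flags


def cross_correlation(
    a: StageSeries, b: StageSeries, max_lag: int = 2
) -> CrossCorrResult:
    """Lagged cross-correlation between two per-stage profiles.

    ccf(l) = sum_t (a_t - abar)(b_{t+l} - bbar) / (n * s_a * s_b), summed
    over the n - |l| overlapping stages but normalized with the full-series
    standard deviations and n, so values shrink at large lags (the R ccf
    convention).  best_lag maximizes |ccf|, with ties broken toward smaller
    |l| and then toward the positive lag; it is significant when its |ccf|
    exceeds 1.96/sqrt(n).
    """
    if a.stages != b.stages:
        raise CrossHostError("stage grids differ between the two series")
    x = np.asarray(a.values, dtype=float)
    y = np.asarray(b.values, dtype=float)
    n = x.size
    if n < 5:
        raise CrossHostError("need at least 5 stages")
    s_x = _check_variance(x, a.gene)
    s_y = _check_variance(y, b.gene)
    xc = x - x.mean()
    yc = y - y.mean()
    lags = tuple(range(-max_lag, max_lag + 1))
    ccf = []
    for lag in lags:
        if lag >= 0:
            num = float(np.sum(xc[: n - lag] * yc[lag:]))
        else:
            num = float(np.sum(xc[-lag:] * yc[: n + lag]))
        ccf.append(num / (n * s_x * s_y))
    # argmax of |ccf|; ties toward smaller |lag|, then positive lag
    order = sorted(range(len(lags)), key=lambda i: (-abs(ccf[i]), abs(lags[i]), -lags[i]))
    best = order[0]
    significant = abs(ccf[best]) > 1.96 / np.sqrt(n)
    flags = []
    try:
        for series in (a, b):
            _, acf_flags = autocorrelation(series, min(max_lag, n - 3))
            if acf_flags.any():
                flags.append(f"autocorrelated:{series.host}")
    except CrossHostError:  # pragma: no cover - guarded by variance checks above
        pass
    result = CrossCorrResult(
        gene=a.gene,
        lags=lags,
        ccf=tuple(ccf),
        best_lag=lags[best],
        best_ccf=ccf[best],
        significant=significant,
        flags=flags,
    )
    if a.replicates is not None:
        result.eta_sq_a = eta_squared(a.replicates)
    if b.replicates is not None:
        result.eta_sq_b = eta_squared(b.replicates)
    for label, value in (("A", result.eta_sq_a), ("B", result.eta_sq_b)):
        if value is not None and value < 0.5:
            result.flags.append(f"low_eta_sq_{label}")
    return result


def eta_squared(replicates) -> float:
    """Proportion of variance explained by stage: SS_between / SS_total.

    ``replicates`` is a sequence of per-stage replicate value sequences.
    """
    groups = [np.asarray(g, dtype=float) for g in replicates if len(g) > 0]
    if len(groups) < 2:
        raise CrossHostError("eta squared needs at least 2 stages")
    if not any(g.size >= 2 for g in groups):
        raise CrossHostError("eta squared needs replication in at least one stage")
    values = np.concatenate(groups)
    grand = values.mean()
    ss_total = float(np.sum((values - grand) ** 2))
    if ss_total == 0.0:
        raise CrossHostError("all replicate values identical: SS_total = 0")
    ss_between = float(sum(g.size * (g.mean() - grand) ** 2 for g in groups))
    return ss_between / ss_total
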