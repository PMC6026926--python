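"""Amplification-curve processing and endosymbiont DNA-enrichment arithmetic.

Raw real-time PCR fluorescence curves are reduced to a per-well
amplification efficiency E (amplification factor 1 + E, so perfect doubling
is E = 1) and a fractional cycle threshold Ct.  Copy numbers follow from a
standard curve, and marker copy numbers for the three genomes present in a
host sample (Wolbachia *wsp*, mitochondrial *COI*, nuclear *AH*) are turned
into base-pair ratios and proportions that quantify how strongly a DNA
preparation is enriched in endosymbiont sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: Default genome sizes in bp: Wolbachia ~1.7 Mb, isopod mitochondrion
#: ~14 kb, isopod nuclear genome ~2 Gb.
DEFAULT_G_WO = 1.7e6
DEFAULT_G_MT = 14e3
DEFAULT_G_NUC = 2e9

MIN_FIT_WINDOW = 4
BASELINE_CYCLES = 5


class QpcrError(ValueError):
    pass


class NoAmplification(QpcrError):
    """The curve never rises above the detection threshold."""


class QualityFailure(QpcrError):
    """The exponential-phase fit is unusable (non-positive efficiency)."""


@dataclass(frozen=True)
class AmplificationCurve:
    gene: str
    sample: str
    cycles: tuple[int, ...]
    fluorescence: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.cycles) != len(self.fluorescence):
            raise QpcrError("cycles and fluorescence differ in length")
        if len(self.cycles) < 10:
            raise QpcrError("amplification curve needs at least 10 cycles")
        if any(b <= a for a, b in zip(self.cycles, self.cycles[1:])):
            raise QpcrError("cycles must be strictly increasing")
        if any(f < 0 for f in self.fluorescence):
            raise QpcrError("fluorescence must be nonnegative")


@dataclass(frozen=True)
class MarkerCounts:
    """Copy numbers of the three single-copy markers (may be fractional,
    e.g. per-cell averages from a standard curve)."""

    n_wsp: float
    n_coi: float
    n_ah: float

    def __post_init__(self) -> None:
        if min(self.n_wsp, self.n_coi, self.n_ah) < 0:
            raise QpcrError("marker counts must be nonnegative")


@dataclass(frozen=True)
class GenomeSizes:
    g_wo: float = DEFAULT_G_WO
    g_mt: float = DEFAULT_G_MT
    g_nuc: float = DEFAULT_G_NUC

    def __post_init__(self) -> None:
        if min(self.g_wo, self.g_mt, self.g_nuc) <= 0:
            raise QpcrError("genome sizes must be positive")


def estimate_efficiency_and_ct(curve: AmplificationCurve) -> tuple[float, float]:
    """Estimate (E, Ct) from a raw fluorescence curve.

    The baseline is the mean of the first five cycles; the detection
    threshold is 10x the baseline standard deviation (with a floor of 1% of
    the curve's corrected maximum so that noiseless synthetic curves remain
    analysable).  The efficiency comes from the log-linear fit
    log F_n = log F_0 + n*log(1+E) over the contiguous window of >= 4 cycles
    that maximizes R^2, restricted to the exponential region (above
    threshold, below 90% of the plateau).  Ct is the fractional cycle at
    which the fitted exponential crosses the threshold.
    """
    cycles = np.asarray(curve.cycles, dtype=float)
    fluo = np.asarray(curve.fluorescence, dtype=float)
    baseline = fluo[:BASELINE_CYCLES].mean()
    baseline_sd = fluo[:BASELINE_CYCLES].std(ddof=1)
    corrected = fluo - baseline
    peak = corrected.max()
    if peak <= 0:
        raise NoAmplification(f"{curve.gene}/{curve.sample}: flat curve")
    threshold = max(10.0 * baseline_sd, 0.01 * peak)
    in_phase = (corrected > threshold) & (corrected < 0.9 * peak)
    idx = np.flatnonzero(in_phase)
    if idx.size < MIN_FIT_WINDOW:
        raise NoAmplification(
            f"{curve.gene}/{curve.sample}: no exponential rise above threshold"
        )
    # Longest run of consecutive in-phase cycles, then best window inside it.
    runs: list[np.ndarray] = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    best: tuple[float, float, float] | None = None  # (r2, slope, intercept)
    for run in runs:
        if run.size < MIN_FIT_WINDOW:
            continue
        x_run = cycles[run]
        y_run = np.log(corrected[run])
        for width in range(MIN_FIT_WINDOW, run.size + 1):
            for start in range(run.size - width + 1):
                x = x_run[start:start + width]
                y = y_run[start:start + width]
                slope, intercept = np.polyfit(x, y, 1)
                resid = y - (slope * x + intercept)
                ss_tot = float(np.sum((y - y.mean()) ** 2))
                if ss_tot <= 0:
                    continue
                r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
                if best is None or r2 > best[0]:
                    best = (r2, slope, intercept)
    if best is None:
        raise NoAmplification(
            f"{curve.gene}/{curve.sample}: no usable exponential window"
        )
    _, slope, intercept = best
    if slope <= 0:
        raise QualityFailure(
            f"{curve.gene}/{curve.sample}: non-positive amplification slope"
        )
    efficiency = math.exp(slope) - 1.0
    if efficiency <= 0:
        raise QualityFailure(f"{curve.gene}/{curve.sample}: fitted E <= 0")
    ct = (math.log(threshold) - intercept) / slope
    return efficiency, ct


def copies_from_standard_curve(
    ct: float, standards: Sequence[tuple[float, float]]
) -> float:
    """Invert a standard curve Ct = a*log10(copies) + b at an observed Ct.

    ``standards`` is a list of (log10 copies, Ct) calibration points; at
    least three points spanning >= 2 log10 units are required.
    """
    if len(standards) < 3:
        raise QpcrError("need at least 3 standards")
    log_copies = np.array([s[0] for s in standards], dtype=float)
    cts = np.array([s[1] for s in standards], dtype=float)
    if log_copies.max() - log_copies.min() < 2.0:
        raise QpcrError("standards must span at least 2 log10 units")
    slope, intercept = np.polyfit(log_copies, cts, 1)
    if abs(slope) < 1e-12:
        raise QpcrError("standards are collinear in Ct (zero slope)")
    return float(10.0 ** ((ct - intercept) / slope))


def genome_bp_ratio(
    counts: MarkerCounts, sizes: GenomeSizes, which: str
) -> float:
    """Base pairs of the mitochondrial/nuclear genome per Wolbachia bp.

    R_mt = (G_mt * N_COI) / (G_Wo * N_wsp); R_nuc uses G_nuc and N_AH.
    """
    if counts.n_wsp == 0:
        raise QpcrError("n_wsp is zero: Wolbachia marker wsp not detected")
    if which == "mt":
        return (sizes.g_mt * counts.n_coi) / (sizes.g_wo * counts.n_wsp)
    if which == "nuc":
        return (sizes.g_nuc * counts.n_ah) / (sizes.g_wo * counts.n_wsp)
    raise QpcrError(f"unknown ratio target {which!r} (expected 'mt' or 'nuc')")


def bp_proportions(
    counts: MarkerCounts, sizes: GenomeSizes
) -> tuple[float, float, float]:
    """Proportion of sample base pairs from each genome: p_x = G_x*N_x / sum."""
    weights = (
        sizes.g_wo * counts.n_wsp,
        sizes.g_mt * counts.n_coi,
        sizes.g_nuc * counts.n_ah,
    )
    total = sum(weights)
    if total == 0:
        raise QpcrError("all marker counts are zero")
    return tuple(w / total for w in weights)  # type: ignore[return-value]


def enrichment_fold(
    before: MarkerCounts, after: MarkerCounts, sizes: GenomeSizes
) -> float:
    """Enrichment in Wolbachia DNA as an odds ratio of its bp proportion.

    fold = odds(p_wo after) / odds(p_wo before), odds(p) = p / (1 - p).
    """
    p_before = bp_proportions(before, sizes)[0]
    p_after = bp_proportions(after, sizes)[0]
    if p_before >= 1.0 or p_after >= 1.0:
        raise QpcrError("pure Wolbachia sample: odds undefined")
    if p_before == 0.0:
        raise QpcrError("no Wolbachia signal before enrichment")
    return (p_after / (1.0 - p_after)) / (p_before / (1.0 - p_before))
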