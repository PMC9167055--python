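"""Validation statistics for comparing simulator outputs.

Waveform agreement uses the NeuroML-DB similarity index
``1 - mean(|x - xhat|) / (max(x) - min(x))``; spike timing uses the percent
difference in mean inter-spike interval at a -20 mV threshold. Network
activity is summarized per unit by firing rate, mean ISI and local
variation, and across units by binned spike-count correlations (CC at a
fine bin, RC at a coarse bin) and the eigenvalue spectrum of the waveform
correlation matrix. Distribution shifts are quantified as Cohen's d with
its 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateRange, InsufficientSpikes, ZeroPooledVariance

SPIKE_THRESHOLD_V = -0.020  # -20 mV, the single-neuron protocol threshold

DEFAULT_BIN_SMALL = 0.002  # s
DEFAULT_BIN_LARGE = 0.100  # s


@dataclass
class SpikeTrain:
    times: np.ndarray  # strictly increasing, seconds
    duration: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)

    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def isis(self) -> np.ndarray:
        return np.diff(self.times)


@dataclass
class EffectSizeReport:
    d: float
    n1: int
    n2: int
    ci_low: float
    ci_high: float

    @property
    def half_width(self) -> float:
        return (self.ci_high - self.ci_low) / 2.0


def detect_spikes(waveform: np.ndarray, dt: float,
                  threshold: float = SPIKE_THRESHOLD_V,
                  duration: float | None = None) -> SpikeTrain:
    """One spike per upward threshold crossing: x[i-1] < th <= x[i],
    stamped at i*dt."""
    x = np.asarray(waveform, dtype=float)
    idx = np.flatnonzero((x[:-1] < threshold) & (x[1:] >= threshold)) + 1
    if duration is None:
        duration = (len(x) - 1) * dt
    return SpikeTrain(idx * dt, duration)


def nmldb_similarity(x: np.ndarray, xhat: np.ndarray) -> float:
    """1 - mean(|x - xhat|) / (max(x) - min(x)); 1 iff the waveforms agree."""
    x = np.asarray(x, dtype=float)
    xhat = np.asarray(xhat, dtype=float)
    if x.shape != xhat.shape:
        raise ValueError("waveforms must have equal length")
    span = float(np.max(x) - np.min(x))
    if span == 0.0:
        raise DegenerateRange("reference waveform is constant")
    return 1.0 - float(np.mean(np.abs(x - xhat))) / span


def local_variation(isis: np.ndarray) -> float | None:
    """Shinomoto's local variation: 3/(n-1) * sum(((Ti - Ti+1)/(Ti + Ti+1))^2)
    over consecutive ISI pairs; 0 for a regular train, ~1 for Poisson."""
    isis = np.asarray(isis, dtype=float)
    n = len(isis)
    if n < 2:
        return None
    a, b = isis[:-1], isis[1:]
    return float(3.0 / (n - 1) * np.sum(((a - b) / (a + b)) ** 2))


def train_statistics(train: SpikeTrain) -> tuple[float, float | None, float | None]:
    """(firing rate, mean ISI, local variation); ISI needs >= 2 spikes and
    LV needs >= 3, otherwise None."""
    rate = train.n / train.duration if train.duration > 0 else 0.0
    isis = train.isis
    mean_isi = float(np.mean(isis)) if train.n >= 2 else None
    lv = local_variation(isis) if train.n >= 3 else None
    return rate, mean_isi, lv


def isi_pct_diff(ref: SpikeTrain, test: SpikeTrain) -> float:
    """100 * (meanISI_test - meanISI_ref) / meanISI_ref."""
    if ref.n < 2 or test.n < 2:
        raise InsufficientSpikes(
            f"need >= 2 spikes in both trains (have {ref.n}, {test.n})"
        )
    m_ref = float(np.mean(ref.isis))
    m_test = float(np.mean(test.isis))
    return 100.0 * (m_test - m_ref) / m_ref


def binned_counts(trains: list[SpikeTrain], bin_size: float,
                  duration: float) -> np.ndarray:
    n_bins = int(round(duration / bin_size))
    out = np.zeros((len(trains), n_bins))
    for i, tr in enumerate(trains):
        idx = np.minimum((tr.times / bin_size).astype(int), n_bins - 1)
        np.add.at(out[i], idx, 1.0)
    return out


def _pearson_matrix(rows: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations; rows with zero variance yield NaN."""
    n = rows.shape[0]
    sd = rows.std(axis=1)
    centered = rows - rows.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / rows.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.outer(sd, sd)
    corr[np.isinf(corr)] = np.nan
    for i in range(n):
        if sd[i] == 0:
            corr[i, :] = np.nan
            corr[:, i] = np.nan
    return corr


def correlation_metrics(trains: list[SpikeTrain],
                        waveforms: np.ndarray | None = None,
                        bin_small: float = DEFAULT_BIN_SMALL,
                        bin_large: float = DEFAULT_BIN_LARGE,
                        duration: float | None = None,
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """(CC matrix, RC matrix, eigenvalues).

    CC/RC are Pearson correlations of spike counts binned at ``bin_small`` /
    ``bin_large``; the eigenvalues are the descending spectrum of the
    Pearson correlation matrix of the raw waveforms (None when no waveforms
    are supplied). Zero-variance units produce NaN rows/columns.
    """
    if len(trains) < 2:
        raise ValueError("need at least two units")
    if duration is None:
        duration = max(tr.duration for tr in trains)
    cc = _pearson_matrix(binned_counts(trains, bin_small, duration))
    rc = _pearson_matrix(binned_counts(trains, bin_large, duration))
    eig = None
    if waveforms is not None:
        corr = _pearson_matrix(np.asarray(waveforms, dtype=float))
        corr = np.nan_to_num(corr, nan=0.0)
        eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
    return cc, rc, eig


def effect_size(sample1, sample2) -> EffectSizeReport:
    """Cohen's d with the 95% CI
    d +/- 1.96 * sqrt((N1+N2)/(N1*N2) + d^2 / (2*(N1+N2-2)))."""
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per sample")
    s_pooled_sq = (((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1))
                   / (n1 + n2 - 2))
    if s_pooled_sq == 0.0:
        raise ZeroPooledVariance("both samples are constant")
    d = float((a.mean() - b.mean()) / np.sqrt(s_pooled_sq))
    half = 1.96 * np.sqrt((n1 + n2) / (n1 * n2) + d * d / (2 * (n1 + n2 - 2)))
    return EffectSizeReport(d, n1, n2, d - half, d + half)


def ci_half_width(d: float, n1: int, n2: int) -> float:
    """The effect-size CI half-width alone (useful for the d=0 reduced form
    1.96*sqrt((N1+N2)/(N1*N2)))."""
    return float(1.96 * np.sqrt((n1 + n2) / (n1 * n2)
                                + d * d / (2 * (n1 + n2 - 2))))
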