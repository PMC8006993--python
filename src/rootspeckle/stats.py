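"""Group-level statistics for RER traces.

Reproduces the comparison applied to the wet (well-watered) and dry
(water-stressed) seedling groups: five-number summaries with Tukey
outliers, shared-bin histograms, pooled and per-trace moments, one-sided
amplitude spectra with dominant-period detection, a band-limit /
peak-amplitude comparison between groups, and the two-sample Welch t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.stats

from .errors import InputError
from .traces import RERTrace

__all__ = [
    "FiveNumberSummary",
    "HistogramSummary",
    "GroupMoments",
    "SpectrumSummary",
    "SpectralComparison",
    "TTestResult",
    "GroupReport",
    "five_number_summary",
    "histogram_compare",
    "group_moments",
    "power_spectrum",
    "spectral_group_compare",
    "welch_t_test",
    "compare_groups",
]

RATE_UNIT = "nm s^-1 mm^-1"


# ---------------------------------------------------------------------------
# result containers


@dataclass
class FiveNumberSummary:
    """Box-and-whisker statistics: quartiles plus Tukey outlier fences."""

    min: float
    q1: float
    median: float
    q3: float
    max: float
    fences: tuple[float, float]
    outliers: np.ndarray
    unit: str = RATE_UNIT

    def to_dict(self) -> dict:
        return {
            "min": self.min,
            "q1": self.q1,
            "median": self.median,
            "q3": self.q3,
            "max": self.max,
            "fences": list(self.fences),
            "outliers": np.asarray(self.outliers).tolist(),
            "unit": self.unit,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FiveNumberSummary":
        return cls(
            min=d["min"],
            q1=d["q1"],
            median=d["median"],
            q3=d["q3"],
            max=d["max"],
            fences=tuple(d["fences"]),
            outliers=np.asarray(d["outliers"], dtype=float),
            unit=d.get("unit", RATE_UNIT),
        )


@dataclass
class HistogramSummary:
    """Per-group counts over bin edges shared between the compared groups."""

    bin_edges: np.ndarray
    counts: dict[str, np.ndarray]
    unit: str = RATE_UNIT

    def to_dict(self) -> dict:
        return {
            "bin_edges": np.asarray(self.bin_edges).tolist(),
            "counts": {k: np.asarray(v).tolist() for k, v in self.counts.items()},
            "unit": self.unit,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HistogramSummary":
        return cls(
            bin_edges=np.asarray(d["bin_edges"], dtype=float),
            counts={k: np.asarray(v, dtype=int) for k, v in d["counts"].items()},
            unit=d.get("unit", RATE_UNIT),
        )


@dataclass
class GroupMoments:
    """Pooled and per-trace mean/standard deviation of a trace collection."""

    pooled_mean: float
    pooled_std: float
    n_samples: int
    trace_means: np.ndarray
    trace_stds: np.ndarray
    unit: str = RATE_UNIT

    def to_dict(self) -> dict:
        return {
            "pooled_mean": self.pooled_mean,
            "pooled_std": self.pooled_std,
            "n_samples": self.n_samples,
            "trace_means": np.asarray(self.trace_means).tolist(),
            "trace_stds": np.asarray(self.trace_stds).tolist(),
            "unit": self.unit,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroupMoments":
        return cls(
            pooled_mean=d["pooled_mean"],
            pooled_std=d["pooled_std"],
            n_samples=d["n_samples"],
            trace_means=np.asarray(d["trace_means"], dtype=float),
            trace_stds=np.asarray(d["trace_stds"], dtype=float),
            unit=d.get("unit", RATE_UNIT),
        )


@dataclass
class SpectrumSummary:
    """One-sided amplitude spectrum with the dominant non-DC component."""

    freqs_hz: np.ndarray
    amplitude: np.ndarray
    dominant_freq_hz: float
    dominant_period_s: float
    peak_amplitude: float

    def to_dict(self) -> dict:
        return {
            "freqs_hz": np.asarray(self.freqs_hz).tolist(),
            "amplitude": np.asarray(self.amplitude).tolist(),
            "dominant_freq_hz": self.dominant_freq_hz,
            "dominant_period_s": self.dominant_period_s,
            "peak_amplitude": self.peak_amplitude,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpectrumSummary":
        return cls(
            freqs_hz=np.asarray(d["freqs_hz"], dtype=float),
            amplitude=np.asarray(d["amplitude"], dtype=float),
            dominant_freq_hz=d["dominant_freq_hz"],
            dominant_period_s=d["dominant_period_s"],
            peak_amplitude=d["peak_amplitude"],
        )


@dataclass
class SpectralComparison:
    """Band-limit check and peak-amplitude ratio between two spectrum groups."""

    dominant_freqs_a: np.ndarray
    dominant_freqs_b: np.ndarray
    band_limit_hz: float
    all_below_band_limit: bool
    peak_amplitude_ratio: float  # mean peak of group a / mean peak of group b

    def to_dict(self) -> dict:
        return {
            "dominant_freqs_a": np.asarray(self.dominant_freqs_a).tolist(),
            "dominant_freqs_b": np.asarray(self.dominant_freqs_b).tolist(),
            "band_limit_hz": self.band_limit_hz,
            "all_below_band_limit": self.all_below_band_limit,
            "peak_amplitude_ratio": self.peak_amplitude_ratio,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpectralComparison":
        return cls(
            dominant_freqs_a=np.asarray(d["dominant_freqs_a"], dtype=float),
            dominant_freqs_b=np.asarray(d["dominant_freqs_b"], dtype=float),
            band_limit_hz=d["band_limit_hz"],
            all_below_band_limit=d["all_below_band_limit"],
            peak_amplitude_ratio=d["peak_amplitude_ratio"],
        )


@dataclass
class TTestResult:
    """Two-sample t-test outcome with the group moments that produced it."""

    t_stat: float
    df: float
    p_value: float
    group_means: tuple[float, float]
    group_stds: tuple[float, float]
    group_ns: tuple[int, int]
    equal_var: bool = False

    def to_dict(self) -> dict:
        return {
            "t_stat": self.t_stat,
            "df": self.df,
            "p_value": self.p_value,
            "group_means": list(self.group_means),
            "group_stds": list(self.group_stds),
            "group_ns": list(self.group_ns),
            "equal_var": self.equal_var,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TTestResult":
        return cls(
            t_stat=d["t_stat"],
            df=d["df"],
            p_value=d["p_value"],
            group_means=tuple(d["group_means"]),
            group_stds=tuple(d["group_stds"]),
            group_ns=tuple(d["group_ns"]),
            equal_var=d.get("equal_var", False),
        )


# ---------------------------------------------------------------------------
# operations


def _pool(samples) -> np.ndarray:
    a = np.asarray(samples, dtype=float).ravel()
    return a


def five_number_summary(samples) -> FiveNumberSummary:
    """Minimum, quartiles, maximum and Tukey outliers of a sample.

    Quartiles use linear interpolation of order statistics; the whisker
    fences sit at q1 - 1.5*IQR and q3 + 1.5*IQR, and every sample outside
    the fences is reported as an outlier.
    """
    x = _pool(samples)
    if x.size < 4:
        raise InputError(f"need at least 4 samples, got {x.size}")
    q1, med, q3 = np.percentile(x, [25.0, 50.0, 75.0], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = np.sort(x[(x < lo) | (x > hi)])
    return FiveNumberSummary(
        min=float(x.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        max=float(x.max()),
        fences=(float(lo), float(hi)),
        outliers=outliers,
    )


def histogram_compare(
    group_a,
    group_b,
    bin_rule="fd",
    labels: tuple[str, str] = ("a", "b"),
) -> HistogramSummary:
    """Histogram both groups over bin edges shared across the pooled range.

    ``bin_rule`` is anything ``numpy.histogram_bin_edges`` accepts: a rule
    name (default Freedman-Diaconis), a bin count, or explicit edges.
    """
    a, b = _pool(group_a), _pool(group_b)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    edges = np.histogram_bin_edges(pooled, bins=bin_rule)
    counts_a, _ = np.histogram(a, bins=edges)
    counts_b, _ = np.histogram(b, bins=edges)
    return HistogramSummary(
        bin_edges=edges, counts={labels[0]: counts_a, labels[1]: counts_b}
    )


def group_moments(traces: Sequence[RERTrace]) -> GroupMoments:
    """Pooled and per-trace mean/std (sample std, ddof=1) of a trace group."""
    if len(traces) == 0:
        raise InputError("need at least one trace")
    rates = [np.asarray(t.rate, dtype=float) for t in traces]
    pooled = np.concatenate(rates)
    return GroupMoments(
        pooled_mean=float(pooled.mean()),
        pooled_std=float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0,
        n_samples=int(pooled.size),
        trace_means=np.array([r.mean() for r in rates]),
        trace_stds=np.array([r.std(ddof=1) if r.size > 1 else 0.0 for r in rates]),
    )


def power_spectrum(trace: RERTrace) -> SpectrumSummary:
    """One-sided amplitude spectrum of a rate trace.

    The mean is removed and no taper is applied; interior bins are scaled
    2|X_k|/N so a pure sinusoid of amplitude A shows amplitude A at its
    frequency (DC and the Nyquist bin, when present, are scaled |X_k|/N).
    The dominant frequency is the argmax over non-DC bins.
    """
    x = np.asarray(trace.rate, dtype=float)
    if x.size < 8:
        raise InputError(f"need at least 8 samples for a spectrum, got {x.size}")
    dt = np.diff(trace.times_s)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise InputError("spectrum requires uniform sampling")
    n = x.size
    X = np.fft.rfft(x - x.mean())
    amp = np.abs(X) / n
    # interior bins carry both halves of the two-sided spectrum
    if n % 2 == 0:
        amp[1:-1] *= 2.0
    else:
        amp[1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=float(dt[0]))
    k = 1 + int(np.argmax(amp[1:]))
    return SpectrumSummary(
        freqs_hz=freqs,
        amplitude=amp,
        dominant_freq_hz=float(freqs[k]),
        dominant_period_s=float(1.0 / freqs[k]),
        peak_amplitude=float(amp[k]),
    )


def spectral_group_compare(
    spectra_a: Sequence[SpectrumSummary],
    spectra_b: Sequence[SpectrumSummary],
    band_limit_hz: float = 1.5,
) -> SpectralComparison:
    """Compare dominant frequencies and peak amplitudes of two spectrum groups.

    Reports every spectrum's dominant frequency, whether all of them sit
    below ``band_limit_hz``, and the ratio of the groups' mean peak
    amplitudes (a over b).
    """
    if len(spectra_a) == 0 or len(spectra_b) == 0:
        raise InputError("both spectrum groups must be non-empty")
    ref = spectra_a[0].freqs_hz
    for s in list(spectra_a) + list(spectra_b):
        if len(s.freqs_hz) != len(ref) or not np.allclose(s.freqs_hz, ref):
            raise InputError("spectra must share a frequency grid")
    fa = np.array([s.dominant_freq_hz for s in spectra_a])
    fb = np.array([s.dominant_freq_hz for s in spectra_b])
    pa = float(np.mean([s.peak_amplitude for s in spectra_a]))
    pb = float(np.mean([s.peak_amplitude for s in spectra_b]))
    return SpectralComparison(
        dominant_freqs_a=fa,
        dominant_freqs_b=fb,
        band_limit_hz=band_limit_hz,
        all_below_band_limit=bool(np.all(fa < band_limit_hz) and np.all(fb < band_limit_hz)),
        peak_amplitude_ratio=pa / pb,
    )


def welch_t_test(group_a, group_b, equal_var: bool = False) -> TTestResult:
    """Two-sample t-test on pooled samples (Welch by default).

    The Welch variant does not assume equal group variances and uses the
    Welch-Satterthwaite degrees of freedom; ``equal_var=True`` selects the
    classic pooled-variance Student test instead.
    """
    a, b = _pool(group_a), _pool(group_b)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs at least 2 samples")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise InputError("degenerate: both groups have zero variance")
    res = scipy.stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(
        t_stat=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        group_means=(float(a.mean()), float(b.mean())),
        group_stds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        group_ns=(int(a.size), int(b.size)),
        equal_var=equal_var,
    )


@dataclass
class GroupReport:
    """Complete two-group comparison: moments, boxes, histograms, spectra, test."""

    labels: tuple[str, str]
    moments: dict[str, GroupMoments]
    summaries: dict[str, FiveNumberSummary]
    histogram: HistogramSummary
    spectra: dict[str, list[SpectrumSummary]]
    spectral: SpectralComparison
    ttest: TTestResult
    rate_unit: str = RATE_UNIT

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "rate_unit": self.rate_unit,
            "moments": {k: v.to_dict() for k, v in self.moments.items()},
            "summaries": {k: v.to_dict() for k, v in self.summaries.items()},
            "histogram": self.histogram.to_dict(),
            "spectra": {
                k: [s.to_dict() for s in v] for k, v in self.spectra.items()
            },
            "spectral": self.spectral.to_dict(),
            "ttest": self.ttest.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroupReport":
        return cls(
            labels=tuple(d["labels"]),
            rate_unit=d.get("rate_unit", RATE_UNIT),
            moments={k: GroupMoments.from_dict(v) for k, v in d["moments"].items()},
            summaries={
                k: FiveNumberSummary.from_dict(v) for k, v in d["summaries"].items()
            },
            histogram=HistogramSummary.from_dict(d["histogram"]),
            spectra={
                k: [SpectrumSummary.from_dict(s) for s in v]
                for k, v in d["spectra"].items()
            },
            spectral=SpectralComparison.from_dict(d["spectral"]),
            ttest=TTestResult.from_dict(d["ttest"]),
        )


def compare_groups(
    group_a: Sequence[RERTrace],
    group_b: Sequence[RERTrace],
    labels: tuple[str, str] = ("a", "b"),
    bin_rule="fd",
    band_limit_hz: float = 1.5,
    equal_var: bool = False,
) -> GroupReport:
    """Assemble the full two-group RER comparison into one report."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise InputError("both groups must contain at least one trace")
    la, lb = labels
    pooled_a = np.concatenate([t.rate for t in group_a])
    pooled_b = np.concatenate([t.rate for t in group_b])
    spectra_a = [power_spectrum(t) for t in group_a]
    spectra_b = [power_spectrum(t) for t in group_b]
    return GroupReport(
        labels=(la, lb),
        moments={la: group_moments(group_a), lb: group_moments(group_b)},
        summaries={
            la: five_number_summary(pooled_a),
            lb: five_number_summary(pooled_b),
        },
        histogram=histogram_compare(pooled_a, pooled_b, bin_rule=bin_rule, labels=labels),
        spectra={la: spectra_a, lb: spectra_b},
        spectral=spectral_group_compare(spectra_a, spectra_b, band_limit_hz=band_limit_hz),
        ttest=welch_t_test(pooled_a, pooled_b, equal_var=equal_var),
    )
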