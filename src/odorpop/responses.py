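"""Per unit-odour response metrics: PSTHs, z-scored responses, response
classification, peak features, and the pairwise discriminability index d′.

The z-scored response of a unit to an odour is computed on the trial-averaged
firing-rate trace in 100 ms bins:

    z_t = (FR_t − FR_baseline) / σ_baseline

where FR_baseline and σ_baseline are the mean and standard deviation of the
binned rate over the baseline window (−2.5 to −0.5 s before odour onset).
A unit-odour pair is classified *excited* if the mean z over the odour window
(0 to +0.5 s) exceeds +1.96 (the two-sided 95% standard-normal critical
value), *inhibited* if it falls below −1.96, and *none* otherwise.

Discriminability between two odours for one unit is

    d′ = |μ_A − μ_B| / σ_RMS,   σ_RMS = sqrt((sd_A² + sd_B²) / 2)

with μ and sd the mean and SD of the odour-window spike count across trials.

All windows are half-open [a, b); bin timestamps are bin centers.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import stats as _stats

from .simulate import RecordingSession, Unit

Z_CRITICAL = 1.96  # two-sided 95% standard-normal critical value


@dataclass
class AnalysisWindows:
    psth_bin: float = 0.05
    z_bin: float = 0.1
    baseline_window: tuple[float, float] = (-2.5, -0.5)
    odour_window: tuple[float, float] = (0.0, 0.5)
    feature_window: tuple[float, float] = (0.0, 1.0)
    z_span: tuple[float, float] = (-2.5, 1.5)
    z_thr: float = Z_CRITICAL

    def validate(self) -> None:
        if self.z_thr <= 0:
            raise ValueError("z_thr must be > 0")
        if self.baseline_window[1] > 0:
            raise ValueError("baseline window must precede odour onset")
        if self.baseline_window[0] >= self.baseline_window[1]:
            raise ValueError("baseline window is empty")


@dataclass
class ZResponse:
    unit_id: str
    odour_carbon: int
    bin_centers: np.ndarray
    z_t: np.ndarray
    fr_t: np.ndarray
    fr_baseline: float
    sigma_baseline: float
    mean_window_z: float
    label: str  # excited | inhibited | none
    degenerate: bool = False  # sigma_baseline == 0


@dataclass
class ResponseFeatures:
    peak_z: float
    peak_width: float
    time_to_peak: float
    missing: bool = False


@dataclass
class DprimeResult:
    mu_a: float
    mu_b: float
    sigma_rms: float
    dprime: float
    infinite: bool = False


def _trial_counts(unit: Unit, onsets: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Spike count per trial in a window relative to each onset."""
    lo = np.searchsorted(unit.spike_times, onsets + window[0], side="left")
    hi = np.searchsorted(unit.spike_times, onsets + window[1], side="left")
    return (hi - lo).astype(float)


def _binned_rates(unit: Unit, onsets: np.ndarray, span: tuple[float, float], bin_s: float) -> np.ndarray:
    """(n_trials, n_bins) firing rates in half-open bins tiling ``span``."""
    n_bins = int(round((span[1] - span[0]) / bin_s))
    edges = span[0] + np.arange(n_bins + 1) * bin_s
    out = np.empty((onsets.size, n_bins))
    for i, onset in enumerate(onsets):
        idx = np.searchsorted(unit.spike_times, onset + edges, side="left")
        out[i] = np.diff(idx) / bin_s
    return out


def _odour_onsets(session: RecordingSession, odour_carbon: int) -> np.ndarray:
    m = session.trials["odour_carbon"] == odour_carbon
    onsets = session.trials.loc[m, "onset_s"].to_numpy()
    if onsets.size == 0:
        raise ValueError(f"no trials of odour carbon {odour_carbon}")
    return onsets


def compute_psth(
    session: RecordingSession,
    unit_id: str,
    odour_carbon: int,
    bin_s: float = 0.05,
    span: tuple[float, float] = (-2.5, 2.0),
):
    """Trial-averaged firing rate (Hz) per ``bin_s`` bin aligned to onset.

    Returns ``(bin_centers, rates)``.
    """
    unit = session.unit(unit_id)
    onsets = _odour_onsets(session, odour_carbon)
    rates = _binned_rates(unit, onsets, span, bin_s).mean(axis=0)
    n_bins = rates.size
    centers = span[0] + (np.arange(n_bins) + 0.5) * bin_s
    return centers, rates


def zscore_response(
    session: RecordingSession,
    unit_id: str,
    odour_carbon: int,
    windows: AnalysisWindows | None = None,
) -> ZResponse:
    """Z-scored trial-averaged response of one unit to one odour.

    σ_baseline = 0 flags the pair degenerate (excluded from feature
    statistics downstream) rather than patching with an epsilon.
    """
    windows = windows or AnalysisWindows()
    windows.validate()
    unit = session.unit(unit_id)
    onsets = _odour_onsets(session, odour_carbon)
    fr_t = _binned_rates(unit, onsets, windows.z_span, windows.z_bin).mean(axis=0)
    n_bins = fr_t.size
    centers = windows.z_span[0] + (np.arange(n_bins) + 0.5) * windows.z_bin

    base = (centers >= windows.baseline_window[0]) & (centers < windows.baseline_window[1])
    if base.sum() < 2:
        raise ValueError("fewer than 2 baseline bins")
    fr_baseline = float(fr_t[base].mean())
    sigma_baseline = float(fr_t[base].std(ddof=1))

    if sigma_baseline == 0.0:
        z_t = np.full(n_bins, np.nan)
        return ZResponse(unit_id, odour_carbon, centers, z_t, fr_t,
                         fr_baseline, sigma_baseline, float("nan"), "none",
                         degenerate=True)

    z_t = (fr_t - fr_baseline) / sigma_baseline
    odw = (centers >= windows.odour_window[0]) & (centers < windows.odour_window[1])
    mean_window_z = float(z_t[odw].mean())
    if mean_window_z > windows.z_thr:
        label = "excited"
    elif mean_window_z < -windows.z_thr:
        label = "inhibited"
    else:
        label = "none"
    return ZResponse(unit_id, odour_carbon, centers, z_t, fr_t,
                     fr_baseline, sigma_baseline, mean_window_z, label)


def session_zresponses(session: RecordingSession, windows: AnalysisWindows | None = None):
    """All unit-odour ZResponse objects of a session."""
    windows = windows or AnalysisWindows()
    return [
        zscore_response(session, u.unit_id, c, windows)
        for u in session.units
        for c in session.odour_carbons
    ]


def response_fractions(zresponses) -> dict:
    """Responsive-unit fraction and excited/inhibited pair fractions."""
    if not zresponses:
        raise ValueError("no z-responses given")
    by_unit: dict[str, list[str]] = {}
    for z in zresponses:
        by_unit.setdefault(z.unit_id, []).append(z.label)
    n_units = len(by_unit)
    n_responsive = sum(any(l != "none" for l in labels) for labels in by_unit.values())
    labels = [z.label for z in zresponses]
    n_pairs = len(labels)
    return {
        "n_units": n_units,
        "n_pairs": n_pairs,
        "fraction_responsive_units": n_responsive / n_units,
        "n_excited_pairs": labels.count("excited"),
        "n_inhibited_pairs": labels.count("inhibited"),
        "fraction_excited_pairs": labels.count("excited") / n_pairs,
        "fraction_inhibited_pairs": labels.count("inhibited") / n_pairs,
    }


def peak_features(
    zresp: ZResponse,
    polarity: str,
    search_window: tuple[float, float] = (0.0, 1.0),
) -> ResponseFeatures:
    """Amplitude, width and latency of the z-scored response peak.

    For inhibited responses the negated trace is analysed; peak_z keeps the
    original sign.  Peak = largest local maximum in the search window; width
    is measured at half prominence with linear interpolation between bins.
    A window without a local maximum yields ``missing=True``.
    """
    if polarity not in ("excited", "inhibited"):
        raise ValueError("polarity must be excited or inhibited")
    trace = zresp.z_t if polarity == "excited" else -zresp.z_t
    m = (zresp.bin_centers >= search_window[0]) & (zresp.bin_centers <= search_window[1])
    y = trace[m]
    t = zresp.bin_centers[m]
    if y.size < 3 or not np.isfinite(y).all():
        return ResponseFeatures(math.nan, math.nan, math.nan, missing=True)
    peaks, props = _signal.find_peaks(y, prominence=0)
    if peaks.size == 0:
        return ResponseFeatures(math.nan, math.nan, math.nan, missing=True)
    best = peaks[np.argmax(y[peaks])]
    order = np.flatnonzero(peaks == best)
    widths, _, _, _ = _signal.peak_widths(y, peaks[order], rel_height=0.5)
    bin_s = t[1] - t[0]
    sign = 1.0 if polarity == "excited" else -1.0
    return ResponseFeatures(
        peak_z=sign * float(y[best]),
        peak_width=float(widths[0]) * bin_s,
        time_to_peak=float(t[best]),
    )


def pairwise_dprime(counts_a: np.ndarray, counts_b: np.ndarray) -> DprimeResult:
    """Discriminability index between two per-trial spike-count vectors."""
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    if counts_a.size < 2 or counts_b.size < 2:
        raise ValueError("need >= 2 trials per odour")
    mu_a, mu_b = counts_a.mean(), counts_b.mean()
    sd_a, sd_b = counts_a.std(ddof=1), counts_b.std(ddof=1)
    sigma_rms = math.sqrt((sd_a**2 + sd_b**2) / 2.0)
    if sigma_rms == 0.0:
        if mu_a == mu_b:
            return DprimeResult(mu_a, mu_b, 0.0, 0.0)
        return DprimeResult(mu_a, mu_b, 0.0, math.inf, infinite=True)
    return DprimeResult(mu_a, mu_b, sigma_rms, abs(mu_a - mu_b) / sigma_rms)


def unit_dprimes(
    session: RecordingSession,
    unit_id: str,
    windows: AnalysisWindows | None = None,
) -> pd.DataFrame:
    """d′ for all odour pairs of one unit (spike counts in the odour window)."""
    windows = windows or AnalysisWindows()
    unit = session.unit(unit_id)
    carbons = session.odour_carbons
    counts = {
        c: _trial_counts(unit, _odour_onsets(session, c), windows.odour_window)
        for c in carbons
    }
    rows = []
    for a, b in itertools.combinations(carbons, 2):
        r = pairwise_dprime(counts[a], counts[b])
        rows.append(
            dict(unit_id=unit_id, carbon_a=a, carbon_b=b, mu_a=r.mu_a,
                 mu_b=r.mu_b, sigma_rms=r.sigma_rms, dprime=r.dprime,
                 infinite=r.infinite)
        )
    return pd.DataFrame(rows)


def dprime_summary(session: RecordingSession, windows: AnalysisWindows | None = None) -> pd.DataFrame:
    """Per-unit mean and max d′ over all odour pairs (infinite pairs excluded)."""
    rows = []
    for u in session.units:
        df = unit_dprimes(session, u.unit_id, windows)
        finite = df.loc[~df["infinite"], "dprime"]
        rows.append(
            dict(unit_id=u.unit_id,
                 mean_dprime=finite.mean() if len(finite) else math.nan,
                 max_dprime=finite.max() if len(finite) else math.nan,
                 n_infinite=int(df["infinite"].sum()))
        )
    return pd.DataFrame(rows)


def response_strengths(session: RecordingSession, windows: AnalysisWindows | None = None) -> pd.DataFrame:
    """Trial-averaged spike rate (Hz) in the odour window per unit-odour.

    This raw rate is the "response strength" used for the relative-response
    normalization of the similarity analyses.
    """
    windows = windows or AnalysisWindows()
    w = windows.odour_window
    dur = w[1] - w[0]
    rows = []
    for u in session.units:
        for c in session.odour_carbons:
            counts = _trial_counts(u, _odour_onsets(session, c), w)
            rows.append(dict(unit_id=u.unit_id, odour_carbon=c,
                             response_strength=counts.mean() / dur))
    return pd.DataFrame(rows)


def unit_odour_table(session: RecordingSession, windows: AnalysisWindows | None = None) -> pd.DataFrame:
    """Tidy per unit-odour table: label, mean-window z, peak features, strength."""
    windows = windows or AnalysisWindows()
    strengths = response_strengths(session, windows).set_index(["unit_id", "odour_carbon"])
    rows = []
    for z in session_zresponses(session, windows):
        feat = (
            peak_features(z, z.label, windows.feature_window)
            if z.label in ("excited", "inhibited")
            else ResponseFeatures(math.nan, math.nan, math.nan, missing=True)
        )
        rows.append(
            dict(
                session_id=session.session_id,
                genotype=session.genotype,
                region=session.region,
                unit_id=z.unit_id,
                odour_carbon=z.odour_carbon,
                label=z.label,
                degenerate=z.degenerate,
                mean_window_z=z.mean_window_z,
                peak_z=feat.peak_z,
                peak_width=feat.peak_width,
                time_to_peak=feat.time_to_peak,
                response_strength=strengths.loc[(z.unit_id, z.odour_carbon), "response_strength"],
            )
        )
    return pd.DataFrame(rows)


def compare_feature_distributions(
    values_a,
    values_b,
    test: str = "auto",
    normality_gate: bool = True,
) -> dict:
    """Two-sample comparison of a response-feature distribution.

    With the normality gate on, a Shapiro-Wilk test at α = 0.05 on each
    group selects a two-tailed two-sample t test (both normal) or a
    two-tailed Mann-Whitney U test otherwise.  ``test`` may force
    ``"t_test"`` or ``"mann_whitney"``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need >= 3 values per group")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        raise ValueError("degenerate input: all values identical in both groups")
    if test == "auto":
        if normality_gate:
            normal = (
                _stats.shapiro(a).pvalue > 0.05 and _stats.shapiro(b).pvalue > 0.05
            )
            test = "t_test" if normal else "mann_whitney"
        else:
            test = "mann_whitney"
    if test == "t_test":
        res = _stats.ttest_ind(a, b)
        return {"test": "t_test", "statistic": float(res.statistic), "p": float(res.pvalue)}
    if test == "mann_whitney":
        from .stats import mann_whitney_u

        res = mann_whitney_u(a, b)
        return {"test": "mann_whitney", "statistic": res.statistic, "p": res.p}
    raise ValueError(f"unknown test {test!r}")
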