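"""Endogenous-oscillation detection and the 26-frequency resonance analysis.

``detect_endogenous`` parameterizes a baseline power spectrum as an
aperiodic 1/f component (offset, exponent, in log10 power) plus up to five
Gaussian peaks in log-power space, under the detection constraints used
throughout: peak width 2-10 Hz, minimum peak height 0.6 (log10 units),
frequency range 2-100 Hz.  Peak amplitude is also reported as the
fold-change of the modeled PSD over the aperiodic fit at the peak center.

``frequency_profile`` runs the steady-state quantification at every
stimulation frequency of the 26-frequency session and tabulates, per
contact, which frequencies drive significant power fold-change / PLV and
which frequency drives the strongest response.  ``entrainment_match`` asks
whether that top frequency falls within 5 Hz of an endogenous oscillation.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import sem  # noqa: F401  (re-exported convenience)

from .io import Recording, TrialTensor, condition_key
from .preprocess import balance_trials, filter_flicker, segment_trials
from .steady_state import multitaper_psd, quantify_steady_state
from .synth import FLICKER_26_FREQS

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class OscillationPeak:
    center: float             # Hz
    height: float             # log10 power above the aperiodic fit
    width: float              # Hz (2 x Gaussian sd)
    fold_vs_aperiodic: float  # model(center)/aperiodic(center) - 1


@dataclasses.dataclass
class SpectralFit:
    offset: float
    exponent: float
    peaks: list[OscillationPeak]
    freqs: np.ndarray
    log_psd: np.ndarray
    aperiodic_log: np.ndarray
    model_log: np.ndarray

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


def _gaussian(f, center, height, sd):
    return height * np.exp(-((f - center) ** 2) / (2.0 * sd ** 2))


def _fit_aperiodic(logf: np.ndarray, logp: np.ndarray) -> tuple[float, float]:
    """Robust linear fit in log-log space: iteratively drop peak-inflated points."""
    mask = np.ones(len(logf), bool)
    slope, intercept = np.polyfit(logf, logp, 1)
    for _ in range(3):
        resid = logp - (intercept + slope * logf)
        thresh = np.quantile(resid[mask], 0.6)
        mask = resid <= thresh
        if mask.sum() < 8:
            break
        slope, intercept = np.polyfit(logf[mask], logp[mask], 1)
    return intercept, -slope  # offset, exponent


def detect_endogenous(
    freqs: np.ndarray,
    psd: np.ndarray,
    max_peaks: int = 5,
    width_limits: tuple[float, float] = (2.0, 10.0),
    min_height: float = 0.6,
    freq_range: tuple[float, float] = (2.0, 100.0),
) -> SpectralFit:
    """Aperiodic + peaks parameterization of a mean baseline PSD.

    Peaks are extracted iteratively from the aperiodic-flattened log
    spectrum (largest first), each refined by a bounded Gaussian fit, then
    the aperiodic component is refit on the peak-subtracted spectrum.  A fit
    failure is logged and yields zero peaks rather than raising.
    """
    freqs = np.asarray(freqs, float)
    psd = np.asarray(psd, float)
    sel = (freqs >= freq_range[0]) & (freqs <= freq_range[1])
    f = freqs[sel]
    logp = np.log10(np.maximum(psd[sel], np.finfo(float).tiny))
    logf = np.log10(f)
    sd_lo, sd_hi = width_limits[0] / 2.0, width_limits[1] / 2.0

    offset, exponent = _fit_aperiodic(logf, logp)
    flat = logp - (offset - exponent * logf)

    raw_peaks: list[tuple[float, float, float]] = []
    work = flat.copy()
    try:
        for _ in range(max_peaks):
            i = int(np.argmax(work))
            h0 = work[i]
            if h0 < min_height:
                break
            c0 = f[i]
            # half-height extent as the width guess
            half = h0 / 2.0
            j = i
            while j > 0 and work[j] > half:
                j -= 1
            k = i
            while k < len(work) - 1 and work[k] > half:
                k += 1
            fwhm = max(f[k] - f[j], 1e-3)
            sd0 = float(np.clip(fwhm / 2.355, sd_lo, sd_hi))
            try:
                popt, _ = curve_fit(
                    _gaussian, f, work, p0=[c0, h0, sd0],
                    bounds=([max(c0 - 2 * sd0, f[0]), 0.5 * h0, sd_lo],
                            [min(c0 + 2 * sd0, f[-1]), 1.5 * h0 + 1e-9, sd_hi]),
                    maxfev=2000,
                )
            except RuntimeError:
                popt = [c0, h0, sd0]
            raw_peaks.append(tuple(popt))
            work = work - _gaussian(f, *popt)

        peaks_sum = np.zeros_like(f)
        for c, h, s in raw_peaks:
            peaks_sum += _gaussian(f, c, h, s)
        # refit aperiodic with peaks removed, then re-measure peak heights
        offset, exponent = _fit_aperiodic(logf, logp - peaks_sum)
        flat = logp - (offset - exponent * logf)
        if raw_peaks:
            p0, lo, hi = [], [], []
            for c, h, s in raw_peaks:
                p0 += [c, h, s]
                lo += [f[0], 0.0, sd_lo]
                hi += [f[-1], np.inf, sd_hi]

            def _multi(fx, *params):
                out = np.zeros_like(fx)
                for m in range(0, len(params), 3):
                    out = out + _gaussian(fx, *params[m:m + 3])
                return out

            try:
                popt, _ = curve_fit(_multi, f, flat, p0=p0, bounds=(lo, hi), maxfev=5000)
                raw_peaks = [tuple(popt[m:m + 3]) for m in range(0, len(popt), 3)]
            except RuntimeError:
                pass
    except Exception:  # pragma: no cover - fit failure path
        logger.exception("spectral parameterization failed; reporting zero peaks")
        raw_peaks = []

    peaks = []
    for c, h, s in raw_peaks:
        if h < min_height or not (freq_range[0] <= c <= freq_range[1]):
            continue
        peaks.append(OscillationPeak(
            center=float(c), height=float(h), width=float(2 * s),
            fold_vs_aperiodic=float(10.0 ** h - 1.0),
        ))
    peaks.sort(key=lambda p: p.center)
    aperiodic_log = offset - exponent * logf
    model_log = aperiodic_log + sum(
        (_gaussian(f, p.center, p.height, p.width / 2) for p in peaks), np.zeros_like(f)
    )
    return SpectralFit(offset=float(offset), exponent=float(exponent), peaks=peaks,
                       freqs=f, log_psd=logp, aperiodic_log=aperiodic_log,
                       model_log=model_log)


def baseline_fit(
    baseline_seg: TrialTensor, channel: int = 0, **kwargs
) -> SpectralFit:
    """Parameterize a contact's mean baseline PSD (trials averaged first)."""
    res = multitaper_psd(baseline_seg)
    mean_psd = res.psd[:, channel, :].mean(axis=0)
    return detect_endogenous(res.freqs, mean_psd, **kwargs)


@dataclasses.dataclass
class FrequencyProfile:
    """Per-contact response metrics over the 26-frequency stimulation set."""

    freqs: tuple[float, ...]
    table: pd.DataFrame     # contact_id x frequency rows with fold_change, p_perm, plv, rayleigh_p
    summary: pd.DataFrame   # per contact: significance counts and top frequencies

    def heatmap(self, metric: str = "fold_change") -> pd.DataFrame:
        """Per-channel min-max normalized (rows in [0, 1]) contact x frequency matrix."""
        mat = self.table.pivot(index="contact_id", columns="frequency", values=metric)
        mat = mat[list(self.freqs)]
        lo = mat.min(axis=1)
        rng = (mat.max(axis=1) - lo).replace(0.0, np.nan)
        return mat.sub(lo, axis=0).div(rng, axis=0).fillna(0.0)


def _top_frequency(sub: pd.DataFrame, metric: str, p_col: str, alpha: float) -> float:
    sig = sub[sub[p_col] < alpha]
    if sig.empty:
        return float("nan")
    best = sig[metric].max()
    tied = sorted(sig.loc[sig[metric] == best, "frequency"])
    if len(tied) > 1:
        logger.info("top-frequency tie at %s; taking lowest", tied)
    return float(tied[0])


def frequency_profile(
    rec: Recording,
    trials: pd.DataFrame,
    freqs: tuple[float, ...] = FLICKER_26_FREQS,
    modality: str = "visual",
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    pad: float = 1.0,
) -> FrequencyProfile:
    """Steady-state metrics at every stimulation frequency of a session.

    ``rec`` is an analysis-ready (already re-referenced) recording.  Trials
    are segmented, band-pass filtered, balanced across conditions, and the
    fold-change/PLV quantification is run per frequency against the session's
    baseline trials.
    """
    tensors = segment_trials(rec, trials, pad=pad)
    tensors = {k: filter_flicker(v) for k, v in tensors.items()}
    tensors, _ = balance_trials(tensors, seed=seed)
    if "baseline" not in tensors:
        raise ValueError("session has no baseline trials")
    baseline = tensors["baseline"]
    ids = rec.contact_ids(baseline.channel_rows)

    frames = []
    for i, f in enumerate(freqs):
        key = condition_key(modality, f)
        if key not in tensors:
            raise ValueError(f"missing condition {key}")
        df = quantify_steady_state(
            tensors[key], baseline, f_stim=float(f),
            n_perm=n_perm, seed=seed + 1 + i, contact_ids=ids,
        )
        df["frequency"] = float(f)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)

    rows = []
    for cid, sub in table.groupby("contact_id", sort=False):
        rows.append(dict(
            contact_id=cid,
            n_significant_power=int((sub["p_perm"] < alpha).sum()),
            n_significant_plv=int((sub["rayleigh_p"] < alpha).sum()),
            top_freq_power=_top_frequency(sub, "fold_change", "p_perm", alpha),
            top_freq_plv=_top_frequency(sub, "plv", "rayleigh_p", alpha),
        ))
    return FrequencyProfile(freqs=tuple(float(f) for f in freqs),
                            table=table, summary=pd.DataFrame(rows))


def entrainment_match(
    summary_row: pd.Series | dict,
    peaks: list[OscillationPeak],
    tol: float = 5.0,
    min_significant: int = 6,
    metric: str = "power",
) -> dict:
    """Does the top stimulation frequency sit within ``tol`` Hz of an endogenous peak?

    Only contacts significant at more than ``min_significant`` of the tested
    frequencies and showing at least one endogenous oscillation are eligible.
    """
    n_sig = summary_row[f"n_significant_{metric}"]
    top = summary_row[f"top_freq_{metric}"]
    eligible = bool(n_sig > min_significant and len(peaks) > 0 and np.isfinite(top))
    if not eligible:
        return dict(eligible=False, matched=False, top_freq=top, nearest_endog=float("nan"))
    centers = np.array([p.center for p in peaks])
    nearest = float(centers[np.argmin(np.abs(centers - top))])
    return dict(eligible=True, matched=bool(abs(nearest - top) <= tol),
                top_freq=float(top), nearest_endog=nearest)
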