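"""Per-observation measures from stimulus-locked raw signals.

Each modality goes through its own chain (filter -> epoch -> align ->
measure):

* EEG: zero-phase 0.5-70 Hz band-pass with a 50 Hz notch, epoched to
  [-0.5, 1.0) s and baseline-corrected to the prestimulus mean; the evoked
  response is quantified both by projecting a canonical template onto the
  Woody-aligned trial (``EEGt``) and by an automated peak-to-peak
  amplitude (``EEGa``).
* EMG (each leg): 10-500 Hz band-pass with 50 Hz notch and harmonics,
  epoched to [-2, 14.5) s; quantified by the mean RMS over the first
  poststimulus second and by the duration/amplitude of the detected
  reflex burst.
* Heart rate: a per-second bpm series from RR intervals, summarised by a
  4 x 6 grid of change measures ({mean, max, normalised mean, normalised
  max} x {5..30 s} windows).
* SpO2: the analogous 4 x 6 grid with minima instead of maxima.
* Facial actions: brow bulge, eye squeeze and nasolabial-furrow durations
  pass through unchanged.

Missing modalities (or degenerate measures, e.g. a zero prestimulus SD)
yield missing values, never a pipeline abort.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, iirnotch, sosfiltfilt

from .core import Epoch, Trace
from .synthetic import Cohort, PairedRecording, Template, make_template

logger = logging.getLogger(__name__)

_warned_caps: set[tuple[float, float]] = set()

WINDOWS_S = (5, 10, 15, 20, 25, 30)

#: names of the 24 heart-rate measures, in grid order
HR_MEASURES = tuple(
    f"HR_{kind}_{w}" for w in WINDOWS_S for kind in ("mean", "max", "norm_mean", "norm_max")
)
#: names of the 24 oxygen-saturation measures
SAT_MEASURES = tuple(
    f"SAT_{kind}_{w}" for w in WINDOWS_S for kind in ("mean", "min", "norm_mean", "norm_min")
)
FACIAL_MEASURES = ("BB", "ES", "NF")
EEG_MEASURES = ("EEGt", "EEGa")
EMG_MEASURES = ("RMSi", "DURi", "AMPi", "RMSc", "DURc", "AMPc")

#: every per-observation measure, in canonical column order
FEATURE_NAMES = FACIAL_MEASURES + HR_MEASURES + SAT_MEASURES + EEG_MEASURES + EMG_MEASURES

_MEASURES_BY_MODALITY = {
    "facial": FACIAL_MEASURES,
    "heart_rate": HR_MEASURES,
    "spo2": SAT_MEASURES,
    "eeg": EEG_MEASURES,
    "emg_ipsi": ("RMSi", "DURi", "AMPi"),
    "emg_contra": ("RMSc", "DURc", "AMPc"),
}


# ----------------------------------------------------------------------
# filtering and epoching
# ----------------------------------------------------------------------
def bandpass_notch_filter(trace: Trace, low_hz: float, high_hz: float,
                          notch_base_hz: float = 50.0, order: int = 4,
                          notch_q: float = 30.0) -> Trace:
    """Zero-phase Butterworth band-pass plus mains notches.

    Notches are applied at ``notch_base_hz`` and its integer harmonics up
    to the (possibly capped) upper band edge.  A nominal upper edge at or
    above Nyquist is capped at 0.95 x Nyquist with a logged warning.
    """
    nyq = trace.fs / 2.0
    cap = 0.95 * nyq
    if high_hz > cap:
        if (high_hz, trace.fs) not in _warned_caps:  # warn once per setting
            _warned_caps.add((high_hz, trace.fs))
            logger.warning(
                "upper band edge %.1f Hz exceeds 0.95 x Nyquist at fs=%.0f Hz; "
                "capping to %.1f Hz", high_hz, trace.fs, cap)
        high_hz = cap
    if not 0 < low_hz < high_hz:
        raise ValueError(f"invalid band [{low_hz}, {high_hz}] Hz after capping")
    sos = butter(order, [low_hz, high_hz], btype="bandpass", fs=trace.fs,
                 output="sos")
    y = sosfiltfilt(sos, trace.samples)
    if notch_base_hz > 0:
        f = notch_base_hz
        while f < min(high_hz, cap):
            b, a = iirnotch(f, notch_q, fs=trace.fs)
            y = filtfilt(b, a, y)
            f += notch_base_hz
    return Trace(y, trace.fs, trace.t_start)


def epoch_and_baseline(trace: Trace, t_start: float, t_end: float,
                       baseline_window: tuple[float, float] | None = None
                       ) -> Epoch:
    """Cut ``[t_start, t_end)`` from a trace, optionally subtracting the
    mean over ``baseline_window`` (e.g. the prestimulus mean)."""
    if not trace.covers(t_start, t_end):
        missing_lo = max(0.0, trace.t_start - t_start)
        missing_hi = max(0.0, t_end - trace.t_end)
        raise ValueError(
            f"trace covers [{trace.t_start:g}, {trace.t_end:g}) s; epoch "
            f"[{t_start:g}, {t_end:g}) s is short by {missing_lo:g} s at the "
            f"start and {missing_hi:g} s at the end")
    ep = trace.slice(t_start, t_end)
    if baseline_window is not None:
        base = trace.window(*baseline_window)
        if base.size == 0:
            raise ValueError("baseline window contains no samples")
        ep.samples -= base.mean()
    return ep


# ----------------------------------------------------------------------
# EEG measures
# ----------------------------------------------------------------------
def woody_align(epoch: Epoch, reference: Trace,
                search_window: tuple[float, float] = (0.4, 0.7),
                max_shift_ms: float = 100.0) -> tuple[float, Epoch]:
    """Latency-align a trial to a reference by bounded cross-correlation.

    The trial is translated by integer sample shifts within
    ``[-max_shift_ms, +max_shift_ms]``; the shift maximising the Pearson
    correlation between the translated trial and the reference over
    ``search_window`` is chosen (ties: smallest absolute shift, then the
    negative one).  Translation moves samples without wrapping; vacated
    edge samples are zero-filled and never enter the correlation.

    Returns ``(shift_ms, aligned_epoch)``.  A trial that is a delayed copy
    of the reference gets a negative shift.
    """
    fs = epoch.fs
    max_k = int(round(max_shift_ms / 1000.0 * fs))
    w0, w1 = search_window
    if not epoch.covers(w0 - max_k / fs, w1 + max_k / fs):
        raise ValueError(
            f"epoch [{epoch.t_start:g}, {epoch.t_end:g}) s cannot cover the "
            f"search window [{w0:g}, {w1:g}) s under +/-{max_shift_ms:g} ms shifts")
    ref = reference.window(w0, w1).astype(float)
    i0, i1 = epoch.index_range(w0, w1)
    L = i1 - i0
    if ref.size != L:
        # resample grids differ by construction only through rounding
        raise ValueError("reference and epoch disagree on the search window length")
    ref_c = ref - ref.mean()
    ref_nrm = np.sqrt(np.sum(ref_c ** 2))

    best_k = 0
    best_r = -np.inf
    order = [0]
    for k in range(1, max_k + 1):
        order.extend([-k, k])
    for k in order:
        seg = epoch.samples[i0 - k:i1 - k]
        seg_c = seg - seg.mean()
        nrm = np.sqrt(np.sum(seg_c ** 2))
        if nrm == 0 or ref_nrm == 0:
            r = -np.inf
        else:
            r = float(np.dot(seg_c, ref_c) / (nrm * ref_nrm))
        if r > best_r:
            best_r, best_k = r, k

    out = np.zeros_like(epoch.samples)
    if best_k > 0:
        out[best_k:] = epoch.samples[:-best_k]
    elif best_k < 0:
        out[:best_k] = epoch.samples[-best_k:]
    else:
        out[:] = epoch.samples
    return best_k / fs * 1000.0, Trace(out, fs, epoch.t_start)


def template_magnitude(epoch: Epoch, template: Template,
                       window: tuple[float, float] = (0.4, 0.7)) -> float:
    """Least-squares scaling of the template against a (Woody-aligned)
    trial over ``window``: beta = <x, T> / <T, T>, sign preserved."""
    if not math.isclose(epoch.fs, template.fs):
        raise ValueError(
            f"epoch fs={epoch.fs} differs from template fs={template.fs}")
    x = epoch.window(*window)
    t = template.as_trace().window(*window)
    if x.size != t.size:
        raise ValueError("epoch and template disagree on the projection window")
    denom = float(np.dot(t, t))
    if denom == 0:
        raise ValueError("template has no energy in the projection window")
    return float(np.dot(x, t) / denom)


def auto_peak_to_peak(epoch: Epoch,
                      neg_window: tuple[float, float] = (0.35, 0.45),
                      pos_window: tuple[float, float] = (0.45, 0.65)) -> float:
    """Automated peak-to-peak amplitude: the maximum over the positive-peak
    window minus the minimum over the negative-peak window.  Negative when
    the waveform is inverted."""
    neg = epoch.window(*neg_window)
    pos = epoch.window(*pos_window)
    if neg.size == 0 or pos.size == 0:
        raise ValueError("peak windows not covered by the epoch")
    return float(pos.max() - neg.min())


# ----------------------------------------------------------------------
# EMG measures
# ----------------------------------------------------------------------
def emg_rms(epoch: Epoch, window_s: float = 0.25, n_windows: int = 4) -> float:
    """Mean of the RMS over the first ``n_windows`` poststimulus windows of
    ``window_s`` seconds (default: four 250 ms windows, i.e. [0, 1) s)."""
    vals = []
    for i in range(n_windows):
        seg = epoch.window(i * window_s, (i + 1) * window_s)
        if seg.size == 0:
            raise ValueError("epoch does not cover the RMS windows")
        vals.append(np.sqrt(np.mean(seg ** 2)))
    return float(np.mean(vals))


@dataclass(frozen=True)
class BurstMetrics:
    """Reflex burst duration and amplitude; ``no_endpoint`` flags a burst
    still above threshold at the end of the epoch (excluded downstream)."""

    duration_s: float
    amplitude: float
    no_endpoint: bool = False


def emg_burst_metrics(epoch: Epoch, threshold_sd: float = 3.0,
                      window_s: float = 0.25, step_s: float = 0.05,
                      offset_run: int = 4) -> BurstMetrics:
    """Detect the poststimulus reflex burst by a running-RMS threshold.

    The threshold is mean + ``threshold_sd`` x SD of the RMS of
    ``window_s`` windows stepped by ``step_s`` over the [-2, 0) s baseline.
    Onset is the start of the first poststimulus window whose RMS exceeds
    the threshold; offset is the start of the first subsequent window that
    begins a run of at least ``offset_run`` consecutive sub-threshold
    windows.  No onset -> (0, 0); onset without an offset before the epoch
    ends -> the no-endpoint flag.
    """
    if epoch.t_start > -2.0 + 0.5 / epoch.fs:
        raise ValueError(
            f"burst detection needs >= 2 s of prestimulus baseline; epoch "
            f"starts at {epoch.t_start:g} s")
    fs = epoch.fs
    wlen = int(round(window_s * fs))
    step = max(1, int(round(step_s * fs)))

    x2 = epoch.samples ** 2
    cum = np.concatenate([[0.0], np.cumsum(x2)])

    def rms_at(starts_idx: np.ndarray) -> np.ndarray:
        return np.sqrt((cum[starts_idx + wlen] - cum[starts_idx]) / wlen)

    ib0, _ = epoch.index_range(-2.0, 0.0)
    izero, _ = epoch.index_range(0.0, epoch.t_end)
    base_starts = np.arange(ib0, izero - wlen + 1, step)
    base_rms = rms_at(base_starts)
    thr = base_rms.mean() + threshold_sd * base_rms.std(ddof=1)

    post_starts = np.arange(izero, epoch.n - wlen + 1, step)
    if post_starts.size == 0:
        raise ValueError("epoch has no poststimulus windows")
    post_rms = rms_at(post_starts)
    above = post_rms > thr
    if not above.any():
        return BurstMetrics(0.0, 0.0)
    on = int(np.argmax(above))
    below = ~above
    off = None
    for j in range(on + 1, post_starts.size - offset_run + 1):
        if below[j:j + offset_run].all():
            off = j
            break
    if off is None:
        return BurstMetrics(float("nan"), float("nan"), no_endpoint=True)
    t_on = (post_starts[on] - izero) / fs
    t_off = (post_starts[off] - izero) / fs
    seg = epoch.samples[post_starts[on]:post_starts[off]]
    return BurstMetrics(float(t_off - t_on), float(np.max(np.abs(seg))))


# ----------------------------------------------------------------------
# heart rate and oxygen saturation
# ----------------------------------------------------------------------
@dataclass
class HeartRateSeries:
    """Beats-per-minute at each integer second in [-15, 30]; a value is
    defined only when at least one full RR interval ends in the trailing
    5 s window, and is NaN otherwise."""

    times: np.ndarray
    values: np.ndarray


def heart_rate_series(beat_times: np.ndarray,
                      t_range: tuple[int, int] = (-15, 30),
                      lookback_s: float = 5.0) -> HeartRateSeries:
    """Per-second heart rate: bpm(t) = 60 / mean(RR intervals ending in
    (t - lookback, t])."""
    beats = np.asarray(beat_times, dtype=float)
    if beats.ndim != 1 or beats.size < 2:
        raise ValueError("need at least two beat times")
    rr = np.diff(beats)
    if np.any(rr <= 0):
        raise ValueError("beat times must be strictly increasing")
    ends = beats[1:]
    times = np.arange(t_range[0], t_range[1] + 1)
    values = np.full(times.size, np.nan)
    for i, t in enumerate(times):
        mask = (ends > t - lookback_s) & (ends <= t)
        if mask.any():
            values[i] = 60.0 / rr[mask].mean()
    return HeartRateSeries(times.astype(float), values)


def windowed_change_features(times: np.ndarray, values: np.ndarray,
                             direction: str, prefix: str,
                             windows: tuple[int, ...] = WINDOWS_S,
                             baseline_window: tuple[float, float] = (-15.0, 0.0),
                             ) -> dict[str, float]:
    """The 4 x 6 grid of poststimulus change measures for a sampled series.

    For each window W: mean change = mean over [0, W) minus the baseline
    mean; extreme change = (max for ``direction='max'``, min for
    ``direction='min'``) over [0, W) minus the baseline mean; normalised
    variants divide by the prestimulus SD.  Normalised measures are
    missing when the prestimulus SD is zero; everything is missing when
    the baseline is entirely missing.  Missing samples are skipped.
    """
    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    ext = direction
    out: dict[str, float] = {}
    names = [(f"{prefix}_mean_{w}", f"{prefix}_{ext}_{w}",
              f"{prefix}_norm_mean_{w}", f"{prefix}_norm_{ext}_{w}") for w in windows]

    base_mask = (times >= baseline_window[0]) & (times < baseline_window[1]) \
        & np.isfinite(values)
    if not base_mask.any():
        for group in names:
            for n in group:
                out[n] = float("nan")
        return out
    base = values[base_mask]
    base_mean = base.mean()
    base_sd = base.std(ddof=1) if base.size > 1 else float("nan")

    for w, (n_mean, n_ext, n_nmean, n_next) in zip(windows, names):
        post_mask = (times >= 0) & (times < w) & np.isfinite(values)
        if not post_mask.any():
            out[n_mean] = out[n_ext] = out[n_nmean] = out[n_next] = float("nan")
            continue
        post = values[post_mask]
        mean_change = post.mean() - base_mean
        ext_change = (post.max() if ext == "max" else post.min()) - base_mean
        out[n_mean] = float(mean_change)
        out[n_ext] = float(ext_change)
        if not np.isfinite(base_sd) or base_sd == 0:
            out[n_nmean] = out[n_next] = float("nan")
        else:
            out[n_nmean] = float(mean_change / base_sd)
            out[n_next] = float(ext_change / base_sd)
    return out


# ----------------------------------------------------------------------
# full per-observation assembly
# ----------------------------------------------------------------------
EEG_BAND = (0.5, 70.0)
EMG_BAND = (10.0, 500.0)
EEG_EPOCH = (-0.5, 1.0)
EEG_BASELINE = (-0.5, 0.0)
EMG_EPOCH = (-2.0, 14.5)


def eeg_epoch(recording: PairedRecording) -> Epoch:
    """EEG chain up to the aligned-measure stage: filter, epoch, baseline."""
    filt = bandpass_notch_filter(recording.eeg, *EEG_BAND)
    return epoch_and_baseline(filt, *EEG_EPOCH, baseline_window=EEG_BASELINE)


def filtered_template(template: Template,
                      span: tuple[float, float] = (-1.0, 1.5)) -> Template:
    """The template as seen through the EEG measurement chain.

    The projection reference is passed through the same band-pass/notch
    filters as the data, so the filter's distortion of the waveform
    cancels in the least-squares magnitude ratio and an injected
    deflection of amplitude ``a`` projects back to ``a``.  The returned
    waveform is deliberately not re-normalised: :func:`template_magnitude`
    divides by its energy.
    """
    fs = template.fs
    t0, t1 = span
    n = int(round((t1 - t0) * fs))
    carrier = Trace(np.zeros(n), fs, t0)
    i0, _ = carrier.index_range(template.t_start, template.t_end)
    carrier.samples[i0:i0 + template.waveform.size] = template.waveform
    filt = bandpass_notch_filter(carrier, *EEG_BAND)
    ep = epoch_and_baseline(filt, template.t_start, template.t_end)
    return Template(ep.samples, fs, template.t_start)


def _emg_epoch(trace: Trace) -> Epoch:
    filt = bandpass_notch_filter(trace, *EMG_BAND)
    return epoch_and_baseline(filt, *EMG_EPOCH)


def extract_feature_vector(recording: PairedRecording,
                           template: Template | None = None,
                           eega_reference: Trace | None = None,
                           ) -> tuple[dict[str, float], list[str]]:
    """All per-observation measures for one recording.

    ``eega_reference`` is the Woody reference for the automated
    peak-to-peak measure (normally the cohort-average noxious epoch); the
    template itself is used as a fallback.  Unavailable modalities yield
    missing values for all their measures.  Returns the measure dict and a
    list of per-modality exclusion reasons.
    """
    features: dict[str, float] = {name: float("nan") for name in FEATURE_NAMES}
    exclusions: list[str] = []

    def note(modality: str, reason: str) -> None:
        msg = f"{recording.subject_id}/{recording.condition}/{modality}: {reason}"
        logger.info("excluded %s", msg)
        exclusions.append(msg)

    # facial actions pass through
    if recording.available.get("facial"):
        features["BB"] = float(recording.brow_bulge_s)
        features["ES"] = float(recording.eye_squeeze_s)
        features["NF"] = float(recording.nasolabial_furrow_s)
    else:
        note("facial", "modality unavailable")

    # heart rate
    if recording.available.get("heart_rate"):
        try:
            hr = heart_rate_series(recording.beat_times)
            features.update(windowed_change_features(hr.times, hr.values,
                                                     "max", "HR"))
        except ValueError as err:
            note("heart_rate", str(err))
    else:
        note("heart_rate", "modality unavailable")

    # oxygen saturation
    if recording.available.get("spo2"):
        try:
            tr = recording.spo2
            features.update(windowed_change_features(tr.times(), tr.samples,
                                                     "min", "SAT"))
        except ValueError as err:
            note("spo2", str(err))
    else:
        note("spo2", "modality unavailable")

    # EEG
    if recording.available.get("eeg"):
        try:
            if template is None:
                template = make_template(recording.eeg.fs)
            proj = filtered_template(template)
            ep = eeg_epoch(recording)
            _, aligned_t = woody_align(ep, proj.as_trace())
            features["EEGt"] = template_magnitude(aligned_t, proj)
            ref = eega_reference if eega_reference is not None \
                else proj.as_trace()
            _, aligned_a = woody_align(ep, ref)
            features["EEGa"] = auto_peak_to_peak(aligned_a)
        except ValueError as err:
            note("eeg", str(err))
    else:
        note("eeg", "modality unavailable")

    # EMG per leg
    for mod, (n_rms, n_dur, n_amp) in (("emg_ipsi", ("RMSi", "DURi", "AMPi")),
                                       ("emg_contra", ("RMSc", "DURc", "AMPc"))):
        if not recording.available.get(mod):
            note(mod, "modality unavailable")
            continue
        try:
            ep = _emg_epoch(getattr(recording, mod))
            features[n_rms] = emg_rms(ep)
            burst = emg_burst_metrics(ep)
            if burst.no_endpoint:
                note(mod, "no reflex endpoint identified")
            else:
                features[n_dur] = burst.duration_s
                features[n_amp] = burst.amplitude
        except ValueError as err:
            note(mod, str(err))

    return features, exclusions


def cohort_average_noxious_epoch(cohort: Cohort) -> Trace | None:
    """Average filtered, baseline-corrected noxious EEG epoch (the Woody
    reference for the automated peak-to-peak measure)."""
    epochs = [eeg_epoch(rec) for rec in cohort.recordings
              if rec.condition == "noxious" and rec.available.get("eeg")]
    if not epochs:
        return None
    stack = np.stack([ep.samples for ep in epochs])
    return Trace(stack.mean(axis=0), epochs[0].fs, epochs[0].t_start)


def extract_feature_table(cohort: Cohort, template: Template | None = None,
                          eega_reference: Trace | None = None,
                          ) -> tuple[pd.DataFrame, dict]:
    """Feature table for a whole cohort: one row per observation.

    Columns: ``subject_id``, ``condition``, ``gestational_age_weeks``,
    availability flags, then the measures of :data:`FEATURE_NAMES`.
    Returns the table and a metadata dict (extraction settings plus
    per-row exclusion reasons).
    """
    if template is None:
        template = make_template(cohort.config.fs_eeg_hz)
    if eega_reference is None:
        eega_reference = cohort_average_noxious_epoch(cohort)
    rows = []
    meta: dict = {
        "eeg_band_hz": EEG_BAND, "emg_band_hz": EMG_BAND,
        "template_fs_hz": template.fs,
        "eega_reference": "cohort_average_noxious" if eega_reference is not None
                          else "template",
        "exclusions": [],
    }
    for rec in cohort.recordings:
        feats, excl = extract_feature_vector(rec, template, eega_reference)
        meta["exclusions"].extend(excl)
        row = {"subject_id": rec.subject_id, "condition": rec.condition,
               "gestational_age_weeks": rec.gestational_age_weeks}
        row.update({f"avail_{m}": bool(rec.available.get(m))
                    for m in _MEASURES_BY_MODALITY})
        row.update(feats)
        rows.append(row)
    return pd.DataFrame(rows), meta


def write_feature_table(table: pd.DataFrame, path: str, meta: dict | None = None
                        ) -> None:
    """Write a feature table as CSV (missing -> empty cell) with a JSON
    sidecar of extraction metadata."""
    table.to_csv(path, index=False)
    if meta is not None:
        import json
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump(meta, fh, indent=1, default=str)


def read_feature_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path)
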