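"""Synthetic paired noxious/control multimodal cohorts.

The study design emulated here: each subject (a neonate) receives one
noxious stimulus (a heel lance) and one non-noxious control stimulus, and
five response modalities are recorded around each stimulus -- EEG at the
vertex, bilateral leg EMG, heartbeat (RR-interval) times, oxygen
saturation, and durations of three facial actions scored over the 30 s
poststimulus window.

A per-subject latent "responsiveness" factor multiplies every noxious
effect size, which induces between-modality correlation within subjects:
strong responders respond strongly across modalities.  Control recordings
contain the same baseline processes with every noxious effect set to zero.

Randomness is organised as one top-level seed that keys independent
per-subject, per-modality, per-condition streams, so a subject's signals
do not depend on the size of the cohort they are generated in.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import Trace

MODALITIES = ("facial", "heart_rate", "spo2", "eeg", "emg_ipsi", "emg_contra")

CONDITIONS = ("noxious", "control")

# stream tags: (modality-ish label, condition) -> small integer, hashed into
# the SeedSequence key of each substream
_STREAM_TAGS = {
    "subject": 0,
    ("eeg", "noxious"): 1,
    ("eeg", "control"): 2,
    ("emg", "noxious"): 3,
    ("emg", "control"): 4,
    ("heart_rate", "noxious"): 5,
    ("heart_rate", "control"): 6,
    ("spo2", "noxious"): 7,
    ("spo2", "control"): 8,
    ("facial", "noxious"): 9,
    ("facial", "control"): 10,
    "missingness": 11,
}


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------
@dataclass
class CohortConfig:
    """Generator parameters for one synthetic cohort.

    Effect sizes are the mean noxious-evoked responses for a subject of
    unit responsiveness; each is multiplied by the subject's latent
    responsiveness factor, and all are zero in control recordings.
    """

    n_subjects: int = 77
    seed: int = 0

    # sampling rates
    fs_eeg_hz: float = 500.0
    fs_emg_hz: float = 500.0
    spo2_rate_hz: float = 1.0

    # noxious effect sizes (per unit responsiveness); the defaults are
    # calibrated so that single-measure discrimination sits at the
    # moderate levels observed for real heel-lance responses (facial and
    # EMG measures in the 0.65-0.77 accuracy range, saturation near
    # chance, the multimodal combination clearly higher)
    eeg_amp_uv: float = 6.5         # magnitude of the evoked EEG deflection
    emg_amp_uv: float = 4.5         # ipsilateral reflex burst amplitude
    hr_rise_bpm: float = 8.0        # peak heart-rate rise
    spo2_dip_pct: float = 1.0       # depth of the saturation dip, % points
    facial_mean_s: float = 4.0      # added mean facial-action duration

    latency_jitter_ms: float = 50.0  # half-range of uniform EEG latency jitter

    # noise levels
    eeg_noise_sd_uv: float = 3.0
    emg_noise_sd_uv: float = 3.0
    hr_noise_sd_bpm: float = 3.0
    spo2_noise_sd_pct: float = 0.5

    # baseline processes (shared between a subject's two conditions)
    hr_baseline_bpm: float = 140.0
    hr_baseline_sd_bpm: float = 8.0
    spo2_baseline_pct: float = 97.0
    spo2_baseline_sd_pct: float = 1.0
    facial_baseline_mean_s: float = 2.0
    spo2_dip_prob: float = 0.5      # probability a noxious trial shows a dip
    emg_contra_ratio: float = 0.55  # contralateral/ipsilateral burst amplitude

    responsiveness_sd: float = 0.3  # SD of the per-subject latent factor

    # per-modality whole-modality missingness probabilities
    missing_facial: float = 0.0
    missing_heart_rate: float = 0.0
    missing_spo2: float = 0.0
    missing_eeg: float = 0.0
    missing_emg_ipsi: float = 0.0
    missing_emg_contra: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("fs_eeg_hz", "fs_emg_hz", "spo2_rate_hz"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("eeg_amp_uv", "emg_amp_uv", "hr_rise_bpm",
                     "spo2_dip_pct", "facial_mean_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for mod in MODALITIES:
            p = getattr(self, f"missing_{mod}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"missing_{mod} must be in [0, 1]")
        if not 0.0 <= self.spo2_dip_prob <= 1.0:
            raise ValueError("spo2_dip_prob must be in [0, 1]")

    def missingness(self) -> dict[str, float]:
        return {m: getattr(self, f"missing_{m}") for m in MODALITIES}


# ----------------------------------------------------------------------
# evoked-response template
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class Template:
    """Canonical biphasic noxious-evoked EEG waveform on [0.35, 0.70) s.

    The waveform is a difference of two Gaussians (negative lobe centred at
    400 ms, SD 25 ms; positive lobe centred at 530 ms, SD 45 ms), with lobe
    weights chosen so the extrema magnitudes stand in ratio 5:7, then
    normalised to unit sum of squared samples.
    """

    waveform: np.ndarray
    fs: float
    t_start: float = 0.35

    @property
    def t_end(self) -> float:
        return self.t_start + self.waveform.size / self.fs

    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.waveform.size) / self.fs

    def as_trace(self) -> Trace:
        return Trace(self.waveform.copy(), self.fs, self.t_start)


_TPL_SUPPORT = (0.35, 0.70)
_TPL_NEG = (0.400, 0.025)   # centre, SD of the negative lobe
_TPL_POS = (0.530, 0.045)   # centre, SD of the positive lobe


@lru_cache(maxsize=1)
def _lobe_weights() -> tuple[float, float]:
    """Lobe weights giving extrema magnitudes in ratio 5:7 (fixed point)."""
    t = np.linspace(_TPL_SUPPORT[0], _TPL_SUPPORT[1], 20001)
    g_neg = np.exp(-0.5 * ((t - _TPL_NEG[0]) / _TPL_NEG[1]) ** 2)
    g_pos = np.exp(-0.5 * ((t - _TPL_POS[0]) / _TPL_POS[1]) ** 2)
    a, b = 5.0, 7.0
    for _ in range(60):
        w = -a * g_neg + b * g_pos
        a *= 5.0 / -w.min()
        b *= 7.0 / w.max()
    return a, b


def template_curve(t: np.ndarray) -> np.ndarray:
    """Unnormalised template shape at arbitrary times (0 outside support)."""
    t = np.asarray(t, dtype=float)
    a, b = _lobe_weights()
    w = (-a * np.exp(-0.5 * ((t - _TPL_NEG[0]) / _TPL_NEG[1]) ** 2)
         + b * np.exp(-0.5 * ((t - _TPL_POS[0]) / _TPL_POS[1]) ** 2))
    return np.where((t >= _TPL_SUPPORT[0]) & (t < _TPL_SUPPORT[1]), w, 0.0)


def _template_grid(fs: float) -> np.ndarray:
    n = int(round((_TPL_SUPPORT[1] - _TPL_SUPPORT[0]) * fs))
    return _TPL_SUPPORT[0] + np.arange(n) / fs


def _template_norm(fs: float) -> float:
    """Unit-energy normalisation constant at a given sampling rate."""
    w = template_curve(_template_grid(fs))
    return float(np.sqrt(np.sum(w ** 2)))


def make_template(fs: float) -> Template:
    """Build the evoked-response template sampled at ``fs`` Hz.

    Raises ``ValueError`` when ``fs`` < 200 Hz (too coarse to resolve the
    narrow negative lobe).
    """
    if fs < 200:
        raise ValueError(f"fs={fs} Hz is too low to resolve the template (need >= 200)")
    grid = _template_grid(fs)
    w = template_curve(grid)
    return Template(w / np.sqrt(np.sum(w ** 2)), float(fs))


# ----------------------------------------------------------------------
# recordings
# ----------------------------------------------------------------------
@dataclass
class PairedRecording:
    """One subject's stimulus-locked signals for a single condition."""

    subject_id: str
    condition: str
    gestational_age_weeks: float
    eeg: Trace | None = None
    emg_ipsi: Trace | None = None
    emg_contra: Trace | None = None
    beat_times: np.ndarray | None = None
    spo2: Trace | None = None
    brow_bulge_s: float | None = None
    eye_squeeze_s: float | None = None
    nasolabial_furrow_s: float | None = None
    available: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if not self.available:
            self.available = {
                "facial": self.brow_bulge_s is not None,
                "heart_rate": self.beat_times is not None,
                "spo2": self.spo2 is not None,
                "eeg": self.eeg is not None,
                "emg_ipsi": self.emg_ipsi is not None,
                "emg_contra": self.emg_contra is not None,
            }

    def validate(self) -> None:
        """Check the declared invariants; raise ``ValueError`` on violation."""
        rec = f"{self.subject_id}/{self.condition}"
        if self.available.get("eeg") and not self.eeg.covers(-0.5, 1.0):
            raise ValueError(f"{rec}: EEG must cover [-0.5, 1.0) s")
        for leg in ("emg_ipsi", "emg_contra"):
            tr = getattr(self, leg)
            if self.available.get(leg) and not tr.covers(-2.0, 14.5):
                raise ValueError(f"{rec}: {leg} must cover [-2, 14.5) s")
        if self.available.get("heart_rate"):
            beats = np.asarray(self.beat_times, dtype=float)
            if beats.size < 2 or np.any(np.diff(beats) <= 0):
                raise ValueError(f"{rec}: beat_times must be strictly increasing")
            if beats[0] > -20.0 or beats[-1] < 30.0:
                raise ValueError(f"{rec}: beat_times must span [-20, 30] s")
        if self.available.get("spo2"):
            if not self.spo2.covers(-15.0, 30.0):
                raise ValueError(f"{rec}: SpO2 must cover [-15, 30) s")
            if np.any(self.spo2.samples < 0) or np.any(self.spo2.samples > 100):
                raise ValueError(f"{rec}: SpO2 values must lie in [0, 100]")
        if self.available.get("facial"):
            for name in ("brow_bulge_s", "eye_squeeze_s", "nasolabial_furrow_s"):
                v = getattr(self, name)
                if v is None or not 0.0 <= v <= 30.0:
                    raise ValueError(f"{rec}: {name} must lie in [0, 30] s")


@dataclass
class Cohort:
    """A list of paired recordings plus the generator config that made it."""

    config: CohortConfig
    recordings: list[PairedRecording]

    def manifest(self) -> list[dict]:
        out = []
        for rec in self.recordings:
            out.append({
                "subject_id": rec.subject_id,
                "condition": rec.condition,
                "gestational_age_weeks": rec.gestational_age_weeks,
                "available": dict(rec.available),
                "facial": {
                    "brow_bulge_s": rec.brow_bulge_s,
                    "eye_squeeze_s": rec.eye_squeeze_s,
                    "nasolabial_furrow_s": rec.nasolabial_furrow_s,
                },
            })
        return out

    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.recordings:
            seen.setdefault(rec.subject_id, None)
        return list(seen)


# ----------------------------------------------------------------------
# simulation
# ----------------------------------------------------------------------
def _stream(cfg: CohortConfig, subject_index: int, tag) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((cfg.seed, subject_index, _STREAM_TAGS[tag]))
    )


def _simulate_eeg(cfg: CohortConfig, rng: np.random.Generator, amp: float) -> Trace:
    fs = cfg.fs_eeg_hz
    t0, t1 = -1.0, 1.5
    t = t0 + np.arange(int(round((t1 - t0) * fs))) / fs
    jitter = rng.uniform(-cfg.latency_jitter_ms, cfg.latency_jitter_ms) / 1000.0
    x = rng.normal(0.0, cfg.eeg_noise_sd_uv, t.size)
    if amp != 0.0:
        x = x + amp * template_curve(t - jitter) / _template_norm(fs)
    return Trace(x, fs, t0)


def _simulate_emg_leg(cfg: CohortConfig, rng: np.random.Generator, amp: float) -> Trace:
    fs = cfg.fs_emg_hz
    t0, t1 = -3.0, 15.5
    n = int(round((t1 - t0) * fs))
    t = t0 + np.arange(n) / fs
    x = rng.normal(0.0, cfg.emg_noise_sd_uv, n)
    # burst parameters are drawn even for amp == 0 so the stream layout is
    # identical between conditions
    onset = rng.uniform(0.05, 0.5)
    dur = rng.uniform(0.5, 3.0)
    carrier = rng.normal(0.0, 1.0, n)
    if amp != 0.0:
        env = np.zeros(n)
        inside = (t >= onset) & (t < onset + dur)
        phase = (t[inside] - onset) / dur
        env[inside] = np.sin(np.pi * phase) ** 2  # Hann-shaped burst envelope
        x = x + amp * env * carrier
    return Trace(x, fs, t0)


def _hr_rise_shape(t: np.ndarray) -> np.ndarray:
    """Unit-peak poststimulus heart-rate rise, peaking at 12 s then decaying."""
    s = np.zeros_like(t)
    pos = t > 0
    s[pos] = (t[pos] / 12.0) * np.exp(1.0 - t[pos] / 12.0)
    return s


def _simulate_beats(cfg: CohortConfig, rng: np.random.Generator,
                    base_bpm: float, rise: float) -> np.ndarray:
    dt = 0.05
    t = np.arange(-26.0, 37.0 + dt, dt)
    hr = base_bpm + rise * _hr_rise_shape(t)
    if cfg.hr_noise_sd_bpm > 0:
        noise = gaussian_filter1d(rng.normal(0.0, 1.0, t.size), sigma=2.0 / dt)
        sd = noise.std()
        if sd > 0:
            hr = hr + noise * (cfg.hr_noise_sd_bpm / sd)
    hr = np.clip(hr, 30.0, None)
    # time-rescaling: beats occur where the integrated rate crosses integers
    lam = hr / 60.0
    cum = np.concatenate([[0.0], np.cumsum((lam[1:] + lam[:-1]) / 2.0 * dt)])
    phase = rng.uniform(0.0, 1.0)
    levels = np.arange(phase, cum[-1], 1.0)
    return np.interp(levels, cum, t)


def _simulate_spo2(cfg: CohortConfig, rng: np.random.Generator,
                   base_pct: float, dip: float) -> Trace:
    rate = cfg.spo2_rate_hz
    t0, t1 = -20.0, 36.0
    n = int(round((t1 - t0) * rate))
    t = t0 + np.arange(n) / rate
    x = base_pct + rng.normal(0.0, cfg.spo2_noise_sd_pct, n)
    centre = rng.uniform(8.0, 20.0)
    width = rng.uniform(3.0, 8.0)
    has_dip = rng.uniform() < cfg.spo2_dip_prob
    if dip != 0.0 and has_dip:
        x = x - dip * np.exp(-0.5 * ((t - centre) / width) ** 2)
    return Trace(np.clip(x, 0.0, 100.0), rate, t0)


def _simulate_facial(cfg: CohortConfig, rng: np.random.Generator,
                     mean_s: float) -> tuple[float, float, float]:
    if mean_s <= 0:
        # keep the stream layout identical regardless of the mean
        rng.gamma(3.0, 1.0)
        rng.lognormal(0.0, 0.25, 3)
        return 0.0, 0.0, 0.0
    intensity = rng.gamma(3.0, mean_s / 3.0)
    # the three facial actions share the per-trial intensity, which makes
    # them strongly correlated, as facial-action durations are in practice
    mult = rng.lognormal(-0.25 ** 2 / 2.0, 0.25, 3)
    bb, es, nf = np.clip(intensity * mult, 0.0, 30.0)
    return float(bb), float(es), float(nf)


def simulate_subject(cfg: CohortConfig, subject_index: int,
                     subject_id: str | None = None
                     ) -> tuple[PairedRecording, PairedRecording]:
    """Simulate one subject's (noxious, control) pair of recordings.

    All draws come from per-subject, per-modality, per-condition streams
    keyed by ``(cfg.seed, subject_index, tag)``, so results do not depend
    on cohort size or simulation order.
    """
    if subject_id is None:
        subject_id = f"S{subject_index:03d}"
    srng = _stream(cfg, subject_index, "subject")
    responsiveness = max(0.05, 1.0 + srng.normal(0.0, cfg.responsiveness_sd))
    base_bpm = srng.normal(cfg.hr_baseline_bpm, cfg.hr_baseline_sd_bpm)
    base_spo2 = float(np.clip(
        srng.normal(cfg.spo2_baseline_pct, cfg.spo2_baseline_sd_pct), 85.0, 100.0))
    ga_weeks = srng.uniform(34.0, 42.9)

    out = []
    for cond in CONDITIONS:
        r = responsiveness if cond == "noxious" else 0.0
        eeg = _simulate_eeg(cfg, _stream(cfg, subject_index, ("eeg", cond)),
                            cfg.eeg_amp_uv * r)
        emg_rng = _stream(cfg, subject_index, ("emg", cond))
        emg_i = _simulate_emg_leg(cfg, emg_rng, cfg.emg_amp_uv * r)
        emg_c = _simulate_emg_leg(cfg, emg_rng,
                                  cfg.emg_amp_uv * cfg.emg_contra_ratio * r)
        beats = _simulate_beats(cfg, _stream(cfg, subject_index, ("heart_rate", cond)),
                                base_bpm, cfg.hr_rise_bpm * r)
        spo2 = _simulate_spo2(cfg, _stream(cfg, subject_index, ("spo2", cond)),
                              base_spo2, cfg.spo2_dip_pct * r)
        mean_facial = cfg.facial_baseline_mean_s + cfg.facial_mean_s * r
        bb, es, nf = _simulate_facial(
            cfg, _stream(cfg, subject_index, ("facial", cond)), mean_facial)
        rec = PairedRecording(
            subject_id=subject_id, condition=cond,
            gestational_age_weeks=float(ga_weeks),
            eeg=eeg, emg_ipsi=emg_i, emg_contra=emg_c,
            beat_times=beats, spo2=spo2,
            brow_bulge_s=bb, eye_squeeze_s=es, nasolabial_furrow_s=nf,
        )
        out.append(rec)
    return out[0], out[1]


_MODALITY_FIELDS = {
    "facial": ("brow_bulge_s", "eye_squeeze_s", "nasolabial_furrow_s"),
    "heart_rate": ("beat_times",),
    "spo2": ("spo2",),
    "eeg": ("eeg",),
    "emg_ipsi": ("emg_ipsi",),
    "emg_contra": ("emg_contra",),
}


def _inject_missingness(cfg: CohortConfig, subject_index: int,
                        nox: PairedRecording, con: PairedRecording) -> None:
    rng = _stream(cfg, subject_index, "missingness")
    probs = cfg.missingness()
    for rec in (nox, con):
        for mod in MODALITIES:
            if rng.uniform() < probs[mod]:
                for f in _MODALITY_FIELDS[mod]:
                    setattr(rec, f, None)
                rec.available[mod] = False


def simulate_cohort(cfg: CohortConfig, subject_prefix: str = "S") -> Cohort:
    """Simulate a full cohort of paired recordings with missingness."""
    recordings: list[PairedRecording] = []
    for i in range(cfg.n_subjects):
        nox, con = simulate_subject(cfg, i, subject_id=f"{subject_prefix}{i:03d}")
        _inject_missingness(cfg, i, nox, con)
        recordings.append(nox)
        recordings.append(con)
    return Cohort(config=cfg, recordings=recordings)


# ----------------------------------------------------------------------
# cohort I/O
# ----------------------------------------------------------------------
def _write_trace_csv(path: Path, trace: Trace) -> None:
    times = trace.times()
    lines = ["time_s,value"]
    lines.extend(f"{t!r},{v!r}" for t, v in zip(times.tolist(), trace.samples.tolist()))
    path.write_text("\n".join(lines) + "\n")


def _read_value_column(path: Path) -> np.ndarray:
    lines = path.read_text().strip().splitlines()
    return np.array([float(l.split(",")[-1]) for l in lines[1:]], dtype=float)


def write_cohort(cohort: Cohort, directory: str | Path) -> None:
    """Write a cohort as a JSON manifest plus per-record CSV signal files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = []
    for rec in cohort.recordings:
        stem = f"{rec.subject_id}_{rec.condition}"
        entry: dict = {
            "subject_id": rec.subject_id,
            "condition": rec.condition,
            "gestational_age_weeks": rec.gestational_age_weeks,
            "available": dict(rec.available),
            "facial": {
                "brow_bulge_s": rec.brow_bulge_s,
                "eye_squeeze_s": rec.eye_squeeze_s,
                "nasolabial_furrow_s": rec.nasolabial_furrow_s,
            },
            "files": {},
            "trace_meta": {},
        }
        for name in ("eeg", "emg_ipsi", "emg_contra", "spo2"):
            tr = getattr(rec, name)
            if tr is not None:
                fname = f"{stem}_{name}.csv"
                _write_trace_csv(directory / fname, tr)
                entry["files"][name] = fname
                entry["trace_meta"][name] = {"fs": tr.fs, "t_start": tr.t_start}
        if rec.beat_times is not None:
            fname = f"{stem}_beats.csv"
            lines = ["beat_time_s"]
            lines.extend(f"{b!r}" for b in np.asarray(rec.beat_times).tolist())
            (directory / fname).write_text("\n".join(lines) + "\n")
            entry["files"]["beat_times"] = fname
        records.append(entry)
    manifest = {"config": asdict(cohort.config), "records": records}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_cohort(directory: str | Path) -> Cohort:
    """Load a cohort written by :func:`write_cohort`; validates on load."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {directory}")
    manifest = json.loads(manifest_path.read_text())
    cfg = CohortConfig(**manifest["config"])
    recordings = []
    for entry in manifest["records"]:
        rec_name = f"{entry['subject_id']}/{entry['condition']}"
        kwargs: dict = {
            "subject_id": entry["subject_id"],
            "condition": entry["condition"],
            "gestational_age_weeks": entry["gestational_age_weeks"],
            "available": dict(entry["available"]),
        }
        for key, val in entry["facial"].items():
            kwargs[key] = val
        for name, fname in entry["files"].items():
            fpath = directory / fname
            if not fpath.exists():
                raise FileNotFoundError(
                    f"record {rec_name}: referenced file {fname} is missing")
            values = _read_value_column(fpath)
            if name == "beat_times":
                kwargs["beat_times"] = values
            else:
                meta = entry["trace_meta"][name]
                kwargs[name] = Trace(values, meta["fs"], meta["t_start"])
        rec = PairedRecording(**kwargs)
        rec.validate()
        recordings.append(rec)
    return Cohort(config=cfg, recordings=recordings)
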