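"""EEG processing chain: from continuous recordings to averaged ERPs.

Stages, in session order: polyphase downsampling to the analysis rate,
zero-phase IIR band limiting (0.5-18 Hz, 48 dB/oct slope realized as an
8th-order Butterworth per side), optional spherical-spline interpolation of
a missing electrode, segmentation around stimulus markers with behavioral
exclusion rules, the four automated artifact-rejection criteria, baseline
correction, per-condition averaging cropped to the 0-1000 ms analysis
window, and (on averages) the spherical-spline current source density
transform.

All stages except rejection are linear operators, so superposition holds
through the chain to numerical tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from numpy.polynomial.legendre import legval
from scipy import signal as sps

from .datasets import CONDITIONS, ChannelLayout, ERPDataset, window_slice
from .simulate import GO, NOGO, RawRecording


@dataclass(frozen=True)
class FilterSpec:
    """Band-limiting filter: IIR high-pass + low-pass, zero-phase."""

    highpass_hz: float = 0.5
    lowpass_hz: float = 18.0
    family: str = "butterworth"
    slope_db_oct: int = 48

    def __post_init__(self):
        if not 0 < self.highpass_hz < self.lowpass_hz:
            raise ValueError("need 0 < highpass < lowpass")
        if self.slope_db_oct <= 0 or self.slope_db_oct % 6:
            raise ValueError("slope must be a positive multiple of 6 dB/oct")

    @property
    def order(self) -> int:
        # a Butterworth rolls off at 6 dB/oct per order
        return self.slope_db_oct // 6


@dataclass(frozen=True)
class RejectionCriteria:
    """The four automated artifact-rejection rules (all in µV)."""

    max_step: float = 50.0
    max_diff_200ms: float = 100.0
    abs_limit: float = 100.0
    min_range_100ms: float = 0.5

    def __post_init__(self):
        if min(self.max_step, self.max_diff_200ms, self.abs_limit, self.min_range_100ms) <= 0:
            raise ValueError("all rejection thresholds must be positive")


@dataclass(frozen=True)
class CsdSpec:
    """Spherical-spline surface-Laplacian parameters.

    ``precision`` is the spline regularization added to the diagonal of the
    g-matrix; the default is e^-7.
    """

    spline_order: int = 4  # m
    legendre_degree: int = 10  # n, series truncation
    precision: float = float(np.exp(-7.0))
    head_radius_m: float = 0.085

    def __post_init__(self):
        if self.spline_order < 2 or self.legendre_degree < 2:
            raise ValueError("need spline_order >= 2 and legendre_degree >= 2")


@dataclass(frozen=True)
class EpochSpec:
    """Epoch geometry in ms relative to stimulus onset."""

    pre_ms: float = 2000.0
    post_ms: float = 2000.0
    baseline_ms: tuple[float, float] = (-200.0, 0.0)
    analysis_window_ms: tuple[float, float] = (0.0, 1000.0)

    def __post_init__(self):
        if self.pre_ms <= 0 or self.post_ms <= 0:
            raise ValueError("pre and post must be positive")
        for lo, hi in (self.baseline_ms, self.analysis_window_ms):
            if lo < -self.pre_ms or hi > self.post_ms:
                raise ValueError("window must lie inside the epoch")


@dataclass
class Epochs:
    """One subject's segmented trials: condition -> (n_epochs, n_ch, n_t)."""

    data: dict[str, np.ndarray]
    fs: float
    t0_ms: float
    layout: ChannelLayout
    log: dict = field(default_factory=dict)

    def n_epochs(self, condition: str) -> int:
        return self.data[condition].shape[0]


# ---------------------------------------------------------------------------
# filtering and resampling


def design_filter(spec: FilterSpec, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """(highpass_sos, lowpass_sos) for single-pass evaluation/application."""
    if fs <= 2 * spec.lowpass_hz:
        raise ValueError(f"fs={fs} too low for lowpass {spec.lowpass_hz} Hz")
    hp = sps.butter(spec.order, spec.highpass_hz, btype="highpass", fs=fs, output="sos")
    lp = sps.butter(spec.order, spec.lowpass_hz, btype="lowpass", fs=fs, output="sos")
    return hp, lp


def filter_gain_db(spec: FilterSpec, fs: float, freq_hz: float) -> float:
    """Single-pass magnitude response of the designed cascade at ``freq_hz``."""
    hp, lp = design_filter(spec, fs)
    _, h1 = sps.sosfreqz(hp, worN=[freq_hz], fs=fs)
    _, h2 = sps.sosfreqz(lp, worN=[freq_hz], fs=fs)
    return float(20 * np.log10(np.abs(h1[0] * h2[0])))


def bandpass_filter(data: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Zero-phase (forward-backward) band limiting along the last axis."""
    hp, lp = design_filter(spec, fs)
    out = sps.sosfiltfilt(hp, np.asarray(data, dtype=float), axis=-1)
    return sps.sosfiltfilt(lp, out, axis=-1)


def downsample(data: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    """Rational-ratio polyphase resampling along the last axis."""
    if target_fs >= fs:
        raise ValueError(f"target_fs {target_fs} must be below fs {fs}")
    ratio = Fraction(target_fs / fs).limit_denominator(10000)
    return sps.resample_poly(np.asarray(data, dtype=float), ratio.numerator, ratio.denominator, axis=-1)


def filter_recording(rec: RawRecording, spec: FilterSpec = FilterSpec()) -> RawRecording:
    return RawRecording(bandpass_filter(rec.data, rec.fs, spec), rec.fs, rec.layout, rec.trials, rec.onsets)


def downsample_recording(rec: RawRecording, target_fs: float) -> RawRecording:
    data = downsample(rec.data, rec.fs, target_fs)
    onsets = np.round(rec.onsets * target_fs / rec.fs).astype(int)
    return RawRecording(data, target_fs, rec.layout, rec.trials, onsets)


# ---------------------------------------------------------------------------
# segmentation


def segment(rec: RawRecording, spec: EpochSpec = EpochSpec(),
            go_deadline_ms: float = 1200.0) -> Epochs:
    """Cut epochs around correct-trial markers.

    Exclusions: incorrect trials; Go trials with no response or a response
    at/after the Go deadline; Nogo trials with any response; markers whose
    epoch would cross a recording edge (counted in the log).
    """
    n_pre = int(round(spec.pre_ms * rec.fs / 1000.0))
    n_post = int(round(spec.post_ms * rec.fs / 1000.0))
    out = {c: [] for c in CONDITIONS}
    log = {"edge_dropped": 0, "behavior_excluded": 0, "segmented": 0}
    for tr, onset in zip(rec.trials, rec.onsets):
        if tr.condition == GO:
            ok = tr.correct and tr.rt_ms is not None and tr.rt_ms < go_deadline_ms
        else:
            ok = tr.correct and tr.rt_ms is None
        if not ok:
            log["behavior_excluded"] += 1
            continue
        lo, hi = onset - n_pre, onset + n_post
        if lo < 0 or hi > rec.n_samples:
            log["edge_dropped"] += 1
            continue
        out[tr.condition].append(rec.data[:, lo:hi])
        log["segmented"] += 1
    data = {
        c: np.stack(v) if v else np.empty((0, rec.layout.n_channels, n_pre + n_post))
        for c, v in out.items()
    }
    return Epochs(data, rec.fs, -spec.pre_ms, rec.layout, log)


# ---------------------------------------------------------------------------
# artifact rejection


def _window_len(ms: float, fs: float) -> int:
    return max(int(round(ms * fs / 1000.0)), 2)


def artifact_flags(epoch: np.ndarray, fs: float,
                   criteria: RejectionCriteria = RejectionCriteria()) -> dict[str, bool]:
    """Evaluate the four rules on one (n_ch, n_t) epoch.

    Sliding windows advance one sample at a time; a rule fires if it holds
    on any channel in any window.
    """
    epoch = np.asarray(epoch, dtype=float)
    w200 = _window_len(200.0, fs)
    w100 = _window_len(100.0, fs)
    step = np.abs(np.diff(epoch, axis=-1)).max() if epoch.shape[-1] > 1 else 0.0
    win200 = np.lib.stride_tricks.sliding_window_view(epoch, w200, axis=-1)
    win100 = np.lib.stride_tricks.sliding_window_view(epoch, w100, axis=-1)
    range200 = win200.max(axis=-1) - win200.min(axis=-1)
    range100 = win100.max(axis=-1) - win100.min(axis=-1)
    return {
        "step": bool(step > criteria.max_step),
        "diff_200ms": bool(range200.max() > criteria.max_diff_200ms),
        "amplitude": bool(np.abs(epoch).max() > criteria.abs_limit),
        "flat_100ms": bool(range100.min() < criteria.min_range_100ms),
    }


def reject_artifacts(epochs: Epochs,
                     criteria: RejectionCriteria = RejectionCriteria()) -> Epochs:
    """Drop whole epochs on which any rule fires on any channel."""
    min_len = _window_len(200.0, epochs.fs)
    kept, log = {}, {}
    for cond, arr in epochs.data.items():
        if arr.shape[0] and arr.shape[-1] < min_len:
            raise ValueError("epochs shorter than 200 ms cannot be screened")
        keep = []
        reasons = []
        for i in range(arr.shape[0]):
            flags = artifact_flags(arr[i], epochs.fs, criteria)
            if any(flags.values()):
                reasons.append((i, [k for k, v in flags.items() if v]))
            else:
                keep.append(i)
        kept[cond] = arr[keep] if keep else arr[:0]
        log[cond] = {
            "n_in": int(arr.shape[0]),
            "n_kept": len(keep),
            "rejected": reasons,
        }
    new_log = dict(epochs.log)
    new_log["rejection"] = log
    return Epochs(kept, epochs.fs, epochs.t0_ms, epochs.layout, new_log)


# ---------------------------------------------------------------------------
# baseline and averaging


def baseline_correct(epochs: Epochs, window_ms: tuple[float, float] | None = None) -> Epochs:
    """Subtract the per-channel mean of the baseline window from each epoch."""
    if window_ms is None:
        window_ms = (-200.0, 0.0)
    sl = window_slice(window_ms, epochs.fs, epochs.t0_ms)
    data = {}
    for cond, arr in epochs.data.items():
        if arr.shape[0]:
            data[cond] = arr - arr[..., sl].mean(axis=-1, keepdims=True)
        else:
            data[cond] = arr
    return Epochs(data, epochs.fs, epochs.t0_ms, epochs.layout, dict(epochs.log))


def average_and_crop(epochs: Epochs, analysis_window_ms: tuple[float, float] = (0.0, 1000.0),
                     subject: str = "S000") -> ERPDataset:
    """Per-condition mean across epochs, cropped to the analysis window."""
    sl = window_slice(analysis_window_ms, epochs.fs, epochs.t0_ms)
    data = {}
    for cond, arr in epochs.data.items():
        if arr.shape[0] == 0:
            raise ValueError(f"no surviving epochs for condition {cond!r}")
        data[cond] = arr.mean(axis=0)[None, :, sl]
    return ERPDataset([subject], data, epochs.fs, analysis_window_ms[0], epochs.layout,
                      units="uV", meta={"log": epochs.log})


def combine_subjects(datasets: list[ERPDataset]) -> ERPDataset:
    """Stack single-subject datasets that share layout, fs and time axis."""
    first = datasets[0]
    subjects: list[str] = []
    data = {c: [] for c in first.conditions}
    for i, ds in enumerate(datasets):
        if ds.fs != first.fs or ds.n_times != first.n_times or ds.layout.names != first.layout.names:
            raise ValueError(f"dataset {i} does not match the first dataset's axes")
        subjects.extend(s if s not in subjects else f"{s}_{i}" for s in ds.subjects)
        for c in first.conditions:
            data[c].append(ds.data[c])
    return ERPDataset(subjects, {c: np.concatenate(v) for c, v in data.items()},
                      first.fs, first.t0_ms, first.layout, first.units)


# ---------------------------------------------------------------------------
# spherical-spline operators (Perrin-style)


def _legendre_series(cosang: np.ndarray, order: int, degree: int) -> np.ndarray:
    n = np.arange(1, degree + 1)
    coef = np.zeros(degree + 1)
    coef[1:] = (2 * n + 1) / (n * (n + 1.0)) ** order / (4 * np.pi)
    return legval(np.clip(cosang, -1.0, 1.0), coef)


def csd_matrix(layout: ChannelLayout, spec: CsdSpec = CsdSpec()) -> np.ndarray:
    """Linear operator mapping scalp potentials (µV) to CSD (µV/m²).

    Solves the regularized spherical-spline system with a zero-sum
    constraint and applies the surface-Laplacian kernel; the head radius
    converts from the unit sphere to physical units.
    """
    cosang = layout.pos3d @ layout.pos3d.T
    g = _legendre_series(cosang, spec.spline_order, spec.legendre_degree)
    h = _legendre_series(cosang, spec.spline_order - 1, spec.legendre_degree)
    n_ch = layout.n_channels
    g_reg = g + np.eye(n_ch) * spec.precision
    if np.linalg.cond(g_reg) > 1e12:
        raise np.linalg.LinAlgError("singular spline system (duplicate electrode positions?)")
    # augmented system [G 1; 1' 0] [c; c0] = [v; 0]
    aug = np.zeros((n_ch + 1, n_ch + 1))
    aug[:n_ch, :n_ch] = g_reg
    aug[:n_ch, n_ch] = 1.0
    aug[n_ch, :n_ch] = 1.0
    solve = np.linalg.inv(aug)[:n_ch, :n_ch]  # v -> c
    return (h @ solve) / spec.head_radius_m**2


def csd_transform(dataset: ERPDataset, spec: CsdSpec = CsdSpec()) -> ERPDataset:
    """Current source density transform of every subject average."""
    op = csd_matrix(dataset.layout, spec)
    out = dataset.copy()
    for cond in out.conditions:
        out.data[cond] = np.einsum("ij,sjt->sit", op, out.data[cond])
    out.units = "uV/m2"
    return out


def interpolation_weights(layout: ChannelLayout, target: str,
                          order: int = 4, degree: int = 50,
                          precision: float = 1e-5) -> np.ndarray:
    """Spherical-spline weights reconstructing ``target`` from the others."""
    ti = layout.index(target)
    good = [i for i in range(layout.n_channels) if i != ti]
    if len(good) < 4:
        raise ValueError("need at least 4 other electrodes for interpolation")
    pos = layout.pos3d
    g_gg = _legendre_series(pos[good] @ pos[good].T, order, degree)
    g_tg = _legendre_series(pos[ti] @ pos[good].T, order, degree)
    n = len(good)
    aug = np.zeros((n + 1, n + 1))
    aug[:n, :n] = g_gg + np.eye(n) * precision
    aug[:n, n] = 1.0
    aug[n, :n] = 1.0
    inv = np.linalg.inv(aug)
    # value at target = g_tg @ c + c0, both linear in v
    w = np.concatenate([g_tg, [1.0]]) @ inv[:, :n]
    full = np.zeros(layout.n_channels)
    full[good] = w
    return full


def interpolate_electrode(dataset: ERPDataset, target: str) -> ERPDataset:
    """Replace one channel by its spherical-spline reconstruction."""
    w = interpolation_weights(dataset.layout, target)
    ti = dataset.layout.index(target)
    out = dataset.copy()
    for cond in out.conditions:
        out.data[cond][:, ti, :] = np.einsum("j,sjt->st", w, out.data[cond])
    return out


def interpolate_recording(rec: RawRecording, target: str) -> RawRecording:
    w = interpolation_weights(rec.layout, target)
    ti = rec.layout.index(target)
    data = rec.data.copy()
    data[ti] = w @ rec.data
    return RawRecording(data, rec.fs, rec.layout, rec.trials, rec.onsets)


# ---------------------------------------------------------------------------
# ingestion of recorded data (BrainVision / EDF via mne)


def read_raw(path, condition_markers: dict[str, str],
             assume_go_rt_ms: float = 350.0) -> RawRecording:
    """Load a BrainVision (.vhdr) or EDF recording into the internal container.

    ``condition_markers`` maps annotation descriptions to conditions, e.g.
    ``{"S  1": "Go", "S  2": "Nogo"}``. Recorded files carry no behavioral
    log, so every trial is taken as correct; Go trials are tagged with
    ``assume_go_rt_ms`` as a placeholder response time so the segmentation
    deadline rule passes them through. Channel names must follow the 10-05
    system so electrode positions can be attached.
    """
    import mne

    from .simulate import Trial

    raw = mne.io.read_raw(str(path), preload=True, verbose="error")
    picks = mne.pick_types(raw.info, eeg=True)
    names = [raw.ch_names[i] for i in picks]
    data = raw.get_data(picks=picks) * 1e6  # volts -> µV
    layout = ChannelLayout.standard(names)
    trials, onsets = [], []
    for ann in raw.annotations:
        desc = str(ann["description"])
        if desc not in condition_markers:
            continue
        cond = condition_markers[desc]
        rt = assume_go_rt_ms if cond == GO else None
        trials.append(Trial(cond, 0.0, correct=True, rt_ms=rt))
        onsets.append(int(round(ann["onset"] * raw.info["sfreq"])))
    return RawRecording(data, float(raw.info["sfreq"]), layout, trials,
                        np.asarray(onsets, dtype=int))


# ---------------------------------------------------------------------------
# whole-session convenience chain


def preprocess_session(
    rec: RawRecording,
    subject: str = "S000",
    target_fs: float = 256.0,
    filter_spec: FilterSpec = FilterSpec(),
    epoch_spec: EpochSpec = EpochSpec(),
    criteria: RejectionCriteria = RejectionCriteria(),
    interpolate: str | None = None,
    csd: CsdSpec | None = None,
) -> ERPDataset:
    """Run the full chain on one session and return the subject's averages.

    Manual raw-data inspection and ocular ICA have no synthetic counterpart
    here; the chain logs them as skipped stages.
    """
    if rec.fs > target_fs:
        rec = downsample_recording(rec, target_fs)
    rec = filter_recording(rec, filter_spec)
    if interpolate is not None:
        rec = interpolate_recording(rec, interpolate)
    epochs = segment(rec, epoch_spec)
    epochs.log["skipped_stages"] = ["manual_inspection", "ica"]
    epochs = reject_artifacts(epochs, criteria)
    epochs = baseline_correct(epochs, epoch_spec.baseline_ms)
    ds = average_and_crop(epochs, epoch_spec.analysis_window_ms, subject=subject)
    if csd is not None:
        ds = csd_transform(ds, csd)
    return ds
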