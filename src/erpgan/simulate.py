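"""Synthetic Go/Nogo ERP cohorts and single-trial EEG sessions.

The generator emulates the statistical structure of averaged event-related
potentials in a response-inhibition (Go/Nogo) experiment: a sequence of
Gaussian-shaped components (P1, N1, N2, fronto-central and parietal P3) with
fixed scalp topographies, condition effects expressed as amplitude (or,
optionally, latency) modulations, additive between-subject amplitude
variability shared across conditions (the cohort is paired), and white
residual noise on the subject averages whose standard deviation can differ
between conditions to emulate unequal trial counts.

Amplitude defaults follow the component quantifications reported for real
Go/Nogo cohorts (N2 at Cz around -4 µV/m² in Go vs -7 µV/m² in Nogo, a
fronto-central P3 around +2 vs +8 µV/m², a parietal P3 slightly larger in
Go), so the "paper_like" fixture carries the canonical inhibition effects:
a larger Nogo N2 and fronto-central Nogo P3, and a smaller parietal Nogo P3.

A single-trial mode produces a continuous multichannel recording with event
markers, behavioral responses, 1/f background noise, and optionally injected
rule-triggering artifacts, so the preprocessing chain can be validated end
to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .datasets import CONDITIONS, DEFAULT_8, GO, NOGO, ChannelLayout, ERPDataset

AMPLITUDE_MODULATION = "amplitude_modulation"
LATENCY_SHIFT = "latency_shift"

PRESETS = ("paper_like", "latency_shift", "asymmetric_noise", "identity")


@dataclass(frozen=True)
class TaskDesign:
    """Timing and composition of one Go/Nogo session.

    Defaults reproduce the standard speeded-inhibition paradigm: 450 trials
    at a 70/30 Go/Nogo ratio, 200 ms stimuli, response deadlines of 1200 ms
    (Go) and 2200 ms (Nogo), and a 1000-1300 ms jittered inter-trial
    interval.
    """

    n_trials: int = 450
    go_proportion: float = 0.70
    stimulus_duration_ms: float = 200.0
    response_deadline_go_ms: float = 1200.0
    response_deadline_nogo_ms: float = 2200.0
    iti_range_ms: tuple[float, float] = (1000.0, 1300.0)

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0.0 <= self.go_proportion <= 1.0:
            raise ValueError("go_proportion must be in [0, 1]")
        if self.iti_range_ms[0] > self.iti_range_ms[1]:
            raise ValueError("iti_range low must be <= high")

    @property
    def n_go(self) -> int:
        # round-to-nearest, half away from zero: 450 * 0.70 -> 315
        return int(np.floor(self.n_trials * self.go_proportion + 0.5))

    @property
    def n_nogo(self) -> int:
        return self.n_trials - self.n_go


@dataclass(frozen=True)
class BehaviorModel:
    """Descriptive response model: accuracies and a lognormal RT."""

    go_accuracy: float = 0.9875
    nogo_false_alarm: float = 0.1186
    rt_mean_ms: float = 348.76
    rt_sd_ms: float = 45.0


@dataclass
class Trial:
    condition: str
    iti_ms: float
    correct: bool = True
    rt_ms: float | None = None  # None = no response


@dataclass(frozen=True)
class ComponentSpec:
    """One ERP component: a Gaussian bump with a fixed scalp topography.

    ``latency_ms`` and ``amplitude`` may be scalars (identical in both
    conditions) or ``{"Go": ..., "Nogo": ...}`` mappings.
    """

    name: str
    latency_ms: float | dict
    width_ms: float
    amplitude: float | dict
    topography: tuple

    def __post_init__(self):
        if self.width_ms <= 0:
            raise ValueError(f"{self.name}: width must be positive")
        topo = np.asarray(self.topography, dtype=float)
        if np.any(np.abs(topo) > 1.0):
            raise ValueError(f"{self.name}: topography weights must lie in [-1, 1]")

    def latency(self, condition: str) -> float:
        v = self.latency_ms
        return float(v[condition]) if isinstance(v, dict) else float(v)

    def amp(self, condition: str) -> float:
        v = self.amplitude
        return float(v[condition]) if isinstance(v, dict) else float(v)

    @property
    def topo(self) -> np.ndarray:
        return np.asarray(self.topography, dtype=float)


@dataclass
class ScenarioConfig:
    """Full description of one synthetic averaged-ERP cohort."""

    n_subjects: int
    layout: ChannelLayout
    fs: float
    window_ms: tuple[float, float]
    components: list[ComponentSpec]
    between_subject_sd: float = 2.0
    latency_jitter_sd: float = 0.0
    noise_sd_go: float = 1.0
    noise_sd_nogo: float = 1.0
    mode: str = AMPLITUDE_MODULATION
    seed: int = 0
    units: str = "uV/m2"

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.noise_sd_go < 0 or self.noise_sd_nogo < 0 or self.between_subject_sd < 0 \
                or self.latency_jitter_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.mode not in (AMPLITUDE_MODULATION, LATENCY_SHIFT):
            raise ValueError(f"unknown mode {self.mode!r}")
        for comp in self.components:
            if comp.topo.shape != (self.layout.n_channels,):
                raise ValueError(
                    f"component {comp.name}: topography length {comp.topo.size} "
                    f"!= channel count {self.layout.n_channels}"
                )
        shifted = [c for c in self.components if c.latency(GO) != c.latency(NOGO)]
        if self.mode == AMPLITUDE_MODULATION and shifted:
            raise ValueError(
                "amplitude_modulation mode requires equal per-condition latencies; "
                f"violated by {[c.name for c in shifted]}"
            )
        if self.mode == LATENCY_SHIFT and not shifted:
            raise ValueError("latency_shift mode requires a latency difference")

    @property
    def times_ms(self) -> np.ndarray:
        lo, hi = self.window_ms
        n = int(np.floor((hi - lo) * self.fs / 1000.0))
        return lo + np.arange(n) * 1000.0 / self.fs


def design_trial_sequence(
    design: TaskDesign, seed: int, behavior: BehaviorModel | None = None
) -> list[Trial]:
    """Shuffled trial labels with jittered ITIs and simulated responses.

    Exactly ``round(n_trials * go_proportion)`` Go trials; order and ITIs are
    deterministic given the seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    labels = [GO] * design.n_go + [NOGO] * design.n_nogo
    rng.shuffle(labels)
    itis = rng.uniform(*design.iti_range_ms, size=design.n_trials)
    trials = [Trial(c, float(iti)) for c, iti in zip(labels, itis)]
    if behavior is not None:
        _simulate_responses(trials, design, behavior, rng)
    return trials


def _simulate_responses(trials, design, behavior, rng):
    mu = np.log(behavior.rt_mean_ms**2 / np.sqrt(behavior.rt_mean_ms**2 + behavior.rt_sd_ms**2))
    sigma = np.sqrt(np.log(1 + behavior.rt_sd_ms**2 / behavior.rt_mean_ms**2))
    for tr in trials:
        if tr.condition == GO:
            if rng.random() < behavior.go_accuracy:
                tr.rt_ms = float(min(rng.lognormal(mu, sigma), design.response_deadline_go_ms - 1))
                tr.correct = True
            else:  # miss
                tr.rt_ms = None
                tr.correct = False
        else:
            if rng.random() < behavior.nogo_false_alarm:
                tr.rt_ms = float(rng.lognormal(mu, sigma))
                tr.correct = False
            else:
                tr.rt_ms = None
                tr.correct = True


def _component_waveform(times_ms, latency, width):
    return np.exp(-0.5 * ((times_ms - latency) / width) ** 2)


def _check_window(scenario: ScenarioConfig, on_truncation: str = "warn"):
    lo, hi = scenario.window_ms
    for comp in scenario.components:
        for cond in CONDITIONS:
            lat = comp.latency(cond)
            if lat - 3 * comp.width_ms < lo or lat + 3 * comp.width_ms > hi:
                msg = (
                    f"component {comp.name} ({cond}) is truncated: window {scenario.window_ms}"
                    f" does not contain latency {lat} +/- 3 x width {comp.width_ms}"
                )
                if on_truncation == "raise":
                    raise ValueError(msg)
                if on_truncation == "warn":
                    warnings.warn(msg)


def subject_template(
    scenario: ScenarioConfig,
    condition: str,
    offsets: np.ndarray | None = None,
    latency_offsets: np.ndarray | None = None,
) -> np.ndarray:
    """Noise-free channel x time signal.

    ``offsets`` / ``latency_offsets`` are per-component amplitude (µV) and
    latency (ms) deviations; zero gives the population-level template.
    """
    times = scenario.times_ms
    out = np.zeros((scenario.layout.n_channels, times.size))
    if offsets is None:
        offsets = np.zeros(len(scenario.components))
    if latency_offsets is None:
        latency_offsets = np.zeros(len(scenario.components))
    for comp, off, lat_off in zip(scenario.components, offsets, latency_offsets):
        wave = _component_waveform(times, comp.latency(condition) + lat_off, comp.width_ms)
        out += (comp.amp(condition) + off) * np.outer(comp.topo, wave)
    return out


def _subject_offsets(scenario: ScenarioConfig, subject_index: int) -> np.ndarray:
    rng = np.random.default_rng(
        np.random.SeedSequence([int(scenario.seed), int(subject_index), 101])
    )
    return rng.normal(0.0, scenario.between_subject_sd, size=len(scenario.components))


def _subject_latency_offsets(scenario: ScenarioConfig, subject_index: int) -> np.ndarray:
    """Per-subject component-latency deviations (ms), shared across conditions."""
    rng = np.random.default_rng(
        np.random.SeedSequence([int(scenario.seed), int(subject_index), 102])
    )
    return rng.normal(0.0, scenario.latency_jitter_sd, size=len(scenario.components))


def generate_subject_average(
    scenario: ScenarioConfig,
    subject_index: int,
    condition: str,
    on_truncation: str = "warn",
) -> np.ndarray:
    """One subject's averaged ERP for one condition, channel x time.

    Deterministic given (scenario.seed, subject_index, condition); the
    per-component amplitude offsets are shared between conditions so the
    cohort is paired.
    """
    if not 0 <= subject_index < scenario.n_subjects:
        raise IndexError(f"subject_index {subject_index} out of range")
    _check_window(scenario, on_truncation)
    offsets = _subject_offsets(scenario, subject_index)
    lat_offsets = _subject_latency_offsets(scenario, subject_index)
    signal = subject_template(scenario, condition, offsets, lat_offsets)
    noise_sd = scenario.noise_sd_go if condition == GO else scenario.noise_sd_nogo
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [int(scenario.seed), int(subject_index), 202, CONDITIONS.index(condition)]
        )
    )
    return signal + rng.normal(0.0, noise_sd, size=signal.shape)


def generate_dataset(scenario: ScenarioConfig, on_truncation: str = "warn") -> ERPDataset:
    """Full paired cohort as an :class:`ERPDataset`."""
    _check_window(scenario, on_truncation)
    data = {
        cond: np.stack(
            [
                generate_subject_average(scenario, i, cond, on_truncation="ignore")
                for i in range(scenario.n_subjects)
            ]
        )
        for cond in CONDITIONS
    }
    return ERPDataset(
        [f"S{i:03d}" for i in range(scenario.n_subjects)],
        data,
        scenario.fs,
        scenario.window_ms[0],
        scenario.layout,
        units=scenario.units,
        meta={"mode": scenario.mode, "seed": scenario.seed},
    )


# ---------------------------------------------------------------------------
# single-trial mode


@dataclass
class RawRecording:
    """Continuous multichannel recording with event markers.

    ``markers`` rows: (onset_sample, condition, correct, rt_ms or nan).
    """

    data: np.ndarray  # (n_channels, n_samples), µV
    fs: float
    layout: ChannelLayout
    trials: list[Trial]
    onsets: np.ndarray  # (n_trials,) sample indices

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def _pink_noise(rng, n_channels, n_samples, sd):
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    pink = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    pink *= sd / pink.std(axis=1, keepdims=True)
    return pink


def generate_single_trial_eeg(
    design: TaskDesign,
    scenario: ScenarioConfig,
    seed: int,
    raw_fs: float = 500.0,
    noise_sd_white: float = 4.0,
    noise_sd_pink: float = 6.0,
    behavior: BehaviorModel | None = None,
    artifacts: Sequence[tuple[int, str]] = (),
    edge_pad_ms: float = 3000.0,
) -> RawRecording:
    """Continuous session: per-trial ERP templates + white and 1/f noise.

    ``artifacts`` is a list of ``(trial_index, kind)`` with kind one of
    ``step`` (a >50 µV voltage step), ``amplitude`` (excursion beyond
    ±100 µV), ``flat`` (a 100 ms near-constant stretch) or ``diff`` (slow
    >100 µV swing within 200 ms); each is injected shortly after that
    trial's stimulus onset so the rejection rules can be validated.
    """
    if behavior is None:
        behavior = BehaviorModel()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 303]))
    trials = design_trial_sequence(design, seed, behavior)

    # trial onsets: previous trial ends at response (or nogo deadline), then ITI
    onset_times = []
    t = edge_pad_ms
    for tr in trials:
        onset_times.append(t)
        trial_end = tr.rt_ms if tr.rt_ms is not None else design.response_deadline_nogo_ms
        t += trial_end + tr.iti_ms
    total_ms = t + edge_pad_ms
    n_samples = int(np.ceil(total_ms * raw_fs / 1000.0))
    onsets = np.asarray([int(round(ot * raw_fs / 1000.0)) for ot in onset_times])

    n_ch = scenario.layout.n_channels
    data = rng.standard_normal((n_ch, n_samples)) * noise_sd_white
    data += _pink_noise(rng, n_ch, n_samples, noise_sd_pink)

    # per-trial evoked template at the raw sampling rate, window 0..1000 ms
    tmpl_times = np.arange(int(raw_fs)) * 1000.0 / raw_fs  # 1 s worth
    templates = {}
    for cond in CONDITIONS:
        tpl = np.zeros((n_ch, tmpl_times.size))
        for comp in scenario.components:
            wave = _component_waveform(tmpl_times, comp.latency(cond), comp.width_ms)
            tpl += comp.amp(cond) * np.outer(comp.topo, wave)
        templates[cond] = tpl
    for tr, onset in zip(trials, onsets):
        seg = templates[tr.condition]
        data[:, onset : onset + seg.shape[1]] += seg

    for trial_index, kind in artifacts:
        onset = onsets[trial_index]
        at = onset + int(0.30 * raw_fs)  # 300 ms post-stimulus
        if kind == "step":
            data[0, at : at + int(0.05 * raw_fs)] += 60.0
        elif kind == "amplitude":
            # sustained so it still exceeds +/-100 µV after band limiting
            data[0, at : at + int(0.20 * raw_fs)] += 150.0
        elif kind == "flat":
            data[:, at : at + int(0.12 * raw_fs)] = data[:, at, None] * 0.0
        elif kind == "diff":
            ramp = np.linspace(0.0, 120.0, int(0.15 * raw_fs))
            data[0, at : at + ramp.size] += ramp
        else:
            raise ValueError(f"unknown artifact kind {kind!r}")

    return RawRecording(data, raw_fs, scenario.layout, trials, onsets)


# ---------------------------------------------------------------------------
# fixture presets


def _paper_like_components(layout: ChannelLayout) -> list[ComponentSpec]:
    def topo(**weights):
        w = np.zeros(layout.n_channels)
        for name, val in weights.items():
            if name in layout.names:
                w[layout.index(name)] = val
        return tuple(w)

    return [
        ComponentSpec("P1", 100.0, 12.0, {GO: 6.5, NOGO: 6.3},
                      topo(P7=0.8, P8=1.0, P1=0.3, Pz=0.3)),
        ComponentSpec("N1", 160.0, 15.0, {GO: -9.0, NOGO: -9.0},
                      topo(P7=1.0, P8=0.8, P1=0.3, Pz=0.3)),
        ComponentSpec("N2", 265.0, 18.0, {GO: -3.9, NOGO: -7.09},
                      topo(Cz=1.0, FC1=0.85, FC2=0.85, Fz=0.7, P1=0.1)),
        ComponentSpec("P3f", 387.0, 35.0, {GO: 1.86, NOGO: 8.25},
                      topo(FC1=1.0, FC2=0.9, Cz=0.8, Fz=0.6)),
        ComponentSpec("P3p", 387.0, 45.0, {GO: 9.26, NOGO: 8.32},
                      topo(P1=1.0, Pz=0.9, P7=0.3, P8=0.3, Cz=0.2)),
    ]


def make_scenario(
    preset: str,
    n_subjects: int = 40,
    channels: Sequence[str] = DEFAULT_8,
    fs: float = 256.0,
    seed: int = 0,
    **overrides,
) -> ScenarioConfig:
    """ScenarioConfig for one of the named fixture presets.

    - ``paper_like``: amplitude-only N2/P3 condition effects, equal noise.
    - ``latency_shift``: conditions share amplitudes; both P3 components are
      shifted 150 ms later in Nogo (a significant shift, several bump widths;
      small sub-width shifts are not harder than amplitude recoloring for
      this architecture).
    - ``asymmetric_noise``: paper_like with Go noise = Nogo noise / sqrt(3),
      standing in for the 3:1 Go/Nogo trial-count ratio.
    - ``identity``: both conditions identical (Go parameters), zero noise --
      the translation task becomes the identity map.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; expected one of {PRESETS}")
    layout = ChannelLayout.standard(channels)
    comps = _paper_like_components(layout)
    kwargs = dict(
        n_subjects=n_subjects,
        layout=layout,
        fs=fs,
        window_ms=(0.0, 1000.0),
        components=comps,
        between_subject_sd=2.0,
        latency_jitter_sd=20.0,
        noise_sd_go=1.0,
        noise_sd_nogo=1.0,
        mode=AMPLITUDE_MODULATION,
        seed=seed,
    )
    if preset == "latency_shift":
        flat = []
        for c in comps:
            amp = c.amp(NOGO) if c.name != "P3p" else c.amp(GO)
            if c.name in ("P3f", "P3p"):
                c = replace(c, latency_ms={GO: 387.0, NOGO: 537.0}, amplitude=amp)
            else:
                c = replace(c, amplitude=amp)
            flat.append(c)
        kwargs["components"] = flat
        kwargs["mode"] = LATENCY_SHIFT
    elif preset == "asymmetric_noise":
        kwargs["noise_sd_nogo"] = 1.0
        kwargs["noise_sd_go"] = 1.0 / np.sqrt(3.0)
    elif preset == "identity":
        kwargs["components"] = [
            replace(c, amplitude=c.amp(GO), latency_ms=c.latency(GO)) for c in comps
        ]
        kwargs["noise_sd_go"] = 0.0
        kwargs["noise_sd_nogo"] = 0.0
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)


def make_fixture_cohort(preset: str, n_subjects: int = 40, seed: int = 0, **overrides) -> ERPDataset:
    """Paired (Go, Nogo) cohort for one of the named presets."""
    scenario = make_scenario(preset, n_subjects=n_subjects, seed=seed, **overrides)
    ds = generate_dataset(scenario)
    ds.meta["preset"] = preset
    return ds
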