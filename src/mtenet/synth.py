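"""Synthetic oddball EEG generator with known directed ground truth.

Produces two-group 16-channel cohorts: autoregressive background activity,
lagged linear directed coupling along a base network shared by both groups,
extra frontal/prefrontal -> parietal edges active (or stronger) only in the
control group, and a P300-like centro-parietal deflection after target
stimuli whose amplitude also differs by group.  Everything is deterministic
under a root seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np

from .eeg import MONTAGE_16
from .estimators import MultiChannelSeries
from .simbench import GroundTruthNetwork
from .util import substream

__all__ = [
    "ParadigmSpec",
    "GroupEffectSpec",
    "SubjectData",
    "default_base_network",
    "generate_paradigm",
    "generate_subject",
    "inject_artifacts",
    "generate_cohorts",
]


@dataclass
class ParadigmSpec:
    """Oddball run layout: stimulus counts and trial timing."""

    n_stimuli: int = 100
    n_targets: int = 20
    n_runs: int = 4
    cue_ms: float = 750.0
    stimulus_ms: float = 150.0
    break_ms: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_targets < self.n_stimuli:
            raise ValueError("need 0 < n_targets < n_stimuli")
        if min(self.cue_ms, self.stimulus_ms, self.break_ms) <= 0:
            raise ValueError("durations must be positive")

    @property
    def trial_ms(self) -> float:
        return self.cue_ms + self.stimulus_ms + self.break_ms

    @property
    def run_ms(self) -> float:
        return self.cue_ms + self.n_stimuli * self.trial_ms


def generate_paradigm(spec: ParadigmSpec) -> List[List[Tuple[float, str]]]:
    """Event sequences per run: (stimulus onset ms, label).

    Exactly ``n_targets`` targets among ``n_stimuli`` stimuli, randomly
    ordered under the spec seed; consecutive onsets are one trial length
    (cue + stimulus + break) apart.
    """
    runs: List[List[Tuple[float, str]]] = []
    for r in range(spec.n_runs):
        rng = substream(spec.seed, "paradigm", r)
        labels = np.array(
            ["target"] * spec.n_targets
            + ["standard"] * (spec.n_stimuli - spec.n_targets)
        )
        rng.shuffle(labels)
        events = [
            (spec.cue_ms + i * spec.trial_ms, str(lab))
            for i, lab in enumerate(labels)
        ]
        runs.append(events)
    return runs


# Base edges avoid using the planted HC-extra targets (P3, P4, C3) as
# sources or sinks: a planted edge changes its target's dynamics, and any
# shared edge leaving or entering that target would then differ between
# groups as a side effect, contaminating the null edges of the contrast.
_DEFAULT_BASE_EDGES = [
    ("F7", "F3"), ("F8", "F4"), ("O1", "T5"), ("O2", "T6"),
    ("T3", "T5"), ("T4", "T6"), ("Fp2", "C4"), ("C4", "O2"),
]
_DEFAULT_HC_EXTRA = [
    ("Fp1", "P3"), ("F3", "P3"), ("F4", "P4"), ("F3", "C3"),
]


def default_base_network() -> GroundTruthNetwork:
    adj = np.zeros((16, 16), dtype=int)
    for s, t in _DEFAULT_BASE_EDGES:
        adj[MONTAGE_16.index(s), MONTAGE_16.index(t)] = 1
    return GroundTruthNetwork(adj, name="eeg-base", labels=list(MONTAGE_16))


@dataclass
class GroupEffectSpec:
    """Planted group difference: extra HC edges and P300 morphology."""

    base: GroundTruthNetwork = field(default_factory=default_base_network)
    hc_extra_edges: Tuple[Tuple[str, str], ...] = tuple(_DEFAULT_HC_EXTRA)
    base_gain: float = 0.25
    # calibrated so 20 subjects/group detect the planted edges with high
    # power while the filter-induced reverse ghosts of those edges stay
    # mostly below the FDR threshold
    extra_gain: Dict[str, float] = field(
        default_factory=lambda: {"hc": 0.32, "scz": 0.0}
    )
    self_coeff: float = 0.55
    background_sd_uv: float = 4.0
    p300_amplitude_uv: Dict[str, float] = field(
        default_factory=lambda: {"hc": 8.0, "scz": 4.0}
    )
    p300_latency_ms: Dict[str, float] = field(
        default_factory=lambda: {"hc": 350.0, "scz": 380.0}
    )
    p300_width_ms: float = 70.0
    p300_channels: Tuple[str, ...] = ("C3", "C4", "P3", "P4")
    artifact_rate: float = 0.0
    artifact_amplitude_uv: float = 150.0
    nonlinear: bool = False  # pass couplings through a logistic squash

    def __post_init__(self) -> None:
        base_edges = {
            (self.base.labels[i], self.base.labels[j])
            for i, j in zip(*np.nonzero(self.base.adjacency))
        }
        if base_edges & set(self.hc_extra_edges):
            raise ValueError("hc_extra_edges must be disjoint from the base network")
        if min(self.extra_gain.values()) < 0 or self.base_gain < 0:
            raise ValueError("gains must be >= 0")
        if not 0.0 <= self.artifact_rate < 1.0:
            raise ValueError("artifact_rate must lie in [0, 1)")


@dataclass
class SubjectData:
    """One synthetic recording: signal, events, and the planted network."""

    recording: MultiChannelSeries
    events: List[Tuple[float, str]]       # global (time_ms, label)
    truth: GroundTruthNetwork
    group: str
    injected_trials: List[int] = field(default_factory=list)


def _coupling_matrix(
    effects: GroupEffectSpec, group: str, gain_scale: float = 1.0
) -> Tuple[np.ndarray, GroundTruthNetwork]:
    labels = list(effects.base.labels)
    n = len(labels)
    A = np.zeros((n, n))
    A[effects.base.adjacency.astype(bool)] = effects.base_gain * gain_scale
    truth = effects.base.adjacency.copy()
    g = effects.extra_gain.get(group, 0.0) * gain_scale
    for s, t in effects.hc_extra_edges:
        i, j = labels.index(s), labels.index(t)
        if g > 0:
            A[i, j] = g
            truth[i, j] = 1
    A = A + np.eye(n) * effects.self_coeff
    radius = float(np.max(np.abs(np.linalg.eigvals(A))))
    if radius > 0.95:
        A *= 0.95 / radius
    return A, GroundTruthNetwork(truth, name=f"{group}-truth", labels=labels)


def _var1_from_innovations(M: np.ndarray, eps: np.ndarray, n_terms: int = 60) -> np.ndarray:
    """x_t = sum_k M^k eps_{t-k}, truncated; M is the j<-i effect matrix."""
    acc = eps.copy()
    term = eps
    for _ in range(n_terms):
        shifted = np.zeros_like(term)
        shifted[:, 1:] = term[:, :-1]
        term = M @ shifted
        acc += term
        if np.max(np.abs(term)) < 1e-12:
            break
    return acc


def generate_subject(
    group: str,
    effects: GroupEffectSpec = GroupEffectSpec(),
    paradigm: ParadigmSpec = ParadigmSpec(),
    seed: int = 0,
    gain_scale: float = 1.0,
) -> SubjectData:
    """Continuous 16-channel recording + events + planted ground truth.

    Background is an AR(1)-coupled vector process at 1,000 Hz driven by
    white innovations; targets add a Gaussian-bump P300-like deflection on
    centro-parietal channels with group-specific amplitude and latency.
    """
    if group not in ("hc", "scz"):
        raise ValueError("group must be 'hc' or 'scz'")
    fs = 1000.0
    labels = list(effects.base.labels)
    n = len(labels)
    A, truth = _coupling_matrix(effects, group, gain_scale)
    run_samples = int(round(paradigm.run_ms * fs / 1000.0))
    T = paradigm.n_runs * run_samples
    rng = substream(seed, "subject", group)
    eps = rng.normal(0.0, effects.background_sd_uv, size=(n, T))
    M = A.T  # M[j, i]: effect of i on j
    if effects.nonlinear:
        # logistic squash on the coupled drive, iterated explicitly
        x = np.zeros((n, T))
        diag = np.diag(M).copy()
        off = M - np.diag(diag)
        sd = effects.background_sd_uv
        for t in range(1, T):
            prev = x[:, t - 1]
            squash = sd * (2.0 / (1.0 + np.exp(-prev / sd)) - 1.0)
            x[:, t] = diag * prev + off @ squash + eps[:, t]
    else:
        x = _var1_from_innovations(M, eps)
    # assemble events across runs and add evoked responses
    runs = generate_paradigm(replace(paradigm, seed=paradigm.seed + seed))
    events: List[Tuple[float, str]] = []
    for r, run_events in enumerate(runs):
        offset_ms = r * paradigm.run_ms
        events.extend((offset_ms + t_ms, lab) for t_ms, lab in run_events)
    amp = effects.p300_amplitude_uv[group]
    lat = effects.p300_latency_ms[group]
    width = effects.p300_width_ms
    chan_idx = [labels.index(c) for c in effects.p300_channels]
    bump_t = np.arange(0, int(0.8 * fs))  # within the post-stimulus second
    for t_ms, lab in events:
        if lab != "target":
            continue
        onset = int(round(t_ms * fs / 1000.0))
        sl = bump_t[onset + bump_t < T]
        shape = amp * np.exp(-0.5 * ((sl - lat * fs / 1000.0) / (width * fs / 1000.0)) ** 2)
        jitter = 1.0 + 0.1 * rng.standard_normal()
        for ci in chan_idx:
            x[ci, onset + sl] += shape * jitter
    recording = MultiChannelSeries(x, labels, sample_rate=fs)
    subject = SubjectData(recording, events, truth, group)
    if effects.artifact_rate > 0:
        subject = inject_artifacts(
            subject,
            rate=effects.artifact_rate,
            amplitude_uv=effects.artifact_amplitude_uv,
            seed=seed,
        )
    return subject


def inject_artifacts(
    subject: SubjectData,
    rate: float,
    amplitude_uv: float = 150.0,
    seed: int = 0,
) -> SubjectData:
    """Add transient high-amplitude excursions to random target trials.

    Each target trial is hit independently with probability ``rate``; the
    excursion is a 100-ms raised-cosine bump of the given amplitude on one
    random channel inside the post-stimulus window.  Returns a new
    SubjectData with the injected target-trial indices recorded.
    """
    if amplitude_uv <= 0:
        raise ValueError("amplitude_uv must be positive")
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    values = subject.recording.values.copy()
    fs = subject.recording.sample_rate or 1000.0
    rng = substream(seed, "artifacts", subject.group)
    hit: List[int] = []
    target_idx = -1
    width = int(0.1 * fs)
    bump = amplitude_uv * 0.5 * (1 - np.cos(2 * np.pi * np.arange(width) / width))
    n_ch, T = values.shape
    for t_ms, lab in subject.events:
        if lab != "target":
            continue
        target_idx += 1
        if rate == 0.0 or rng.random() >= rate:
            continue
        onset = int(round(t_ms * fs / 1000.0))
        start = onset + int(rng.integers(0, max(int(0.7 * fs) - width, 1)))
        if start + width > T:
            continue
        ch = int(rng.integers(0, n_ch))
        values[ch, start : start + width] += bump
        hit.append(target_idx)
    recording = MultiChannelSeries(
        values, list(subject.recording.labels), subject.recording.sample_rate
    )
    return SubjectData(
        recording, list(subject.events), subject.truth, subject.group, hit
    )


def generate_cohorts(
    n_hc: int = 25,
    n_scz: int = 23,
    effects: GroupEffectSpec = GroupEffectSpec(),
    paradigm: ParadigmSpec = ParadigmSpec(),
    seed: int = 0,
) -> Tuple[List[SubjectData], List[SubjectData], Dict]:
    """Two cohorts with per-subject seeds and mild between-subject jitter.

    Returns (hc_subjects, scz_subjects, ground_truth_summary).
    """
    if n_hc < 2 or n_scz < 2:
        raise ValueError("need at least two subjects per group")
    hc: List[SubjectData] = []
    scz: List[SubjectData] = []
    jrng = substream(seed, "cohort-jitter")
    for group, count, bucket in (("hc", n_hc, hc), ("scz", n_scz, scz)):
        for s in range(count):
            gain_scale = float(np.clip(1.0 + 0.05 * jrng.standard_normal(), 0.8, 1.2))
            sub_seed = seed * 1009 + (0 if group == "hc" else 500) + s
            bucket.append(
                generate_subject(group, effects, paradigm, sub_seed, gain_scale)
            )
    summary = {
        "hc_extra_edges": list(effects.hc_extra_edges),
        "base_edges": [
            (effects.base.labels[i], effects.base.labels[j])
            for i, j in zip(*np.nonzero(effects.base.adjacency))
        ],
        "n_hc": n_hc,
        "n_scz": n_scz,
        "seed": seed,
    }
    return hc, scz, summary
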