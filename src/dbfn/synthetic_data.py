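"""Synthetic multichannel EEG with planted, class-dependent coupling graphs.

The generator emulates what the mutual-information connectivity stage is
meant to detect: each channel carries independent band-limited background
activity, and every planted edge adds a shared band-limited source to both of
its endpoints, so coupled channels co-vary inside the chosen rhythm.  Trials
of different affective classes are generated from different planted graphs
(typically differing in edge density), and each trial's 1-9 ratings are drawn
on the correct side of the midpoint so label binarization recovers the class.

Inter-subject variability is emulated by a per-subject log-normal gain and
noise-floor multiplier, which makes subject-dependent protocols easier than
leave-one-subject-out, as with real recordings.  All randomness flows from a
single integer seed through ``numpy.random.SeedSequence``, so regeneration is
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core_data import SubjectDataset, TrialRecording
from .spectral import DEFAULT_BANDS, BandDefinition

__all__ = [
    "CouplingSpec",
    "SyntheticStudy",
    "generate_trial",
    "generate_study",
    "two_class_fixture",
    "write_study",
]

_BAND_BY_NAME: dict[str, BandDefinition] = {b.name: b for b in DEFAULT_BANDS}


@dataclass(frozen=True)
class CouplingSpec:
    """Ground-truth coupling structure for one class of trials.

    Parameters
    ----------
    n_channels
        Number of EEG channels to synthesize.
    planted_edges
        Unordered channel-index pairs receiving a shared source.
    coupling_strength
        Mixing weight of the shared source, in [0, 1] relative to the
        unit-variance per-channel background; 0 means mutual independence.
    band
        Rhythm name carrying both the background and the shared sources.
    noise_sd
        SD of the additive white measurement noise.
    gate_s
        Timescale (seconds) of coupling non-stationarity: each shared source
        is switched on and off by an independent Bernoulli(``gate_duty``)
        gate resampled every ``gate_s`` seconds, emulating the second-scale
        reconfiguration of functional connectivity that dynamic (windowed)
        network analysis exists to capture.  ``None`` keeps the coupling
        stationary.
    gate_duty
        Fraction of gate segments in which a source is active.  Small duty
        cycles model transient synchronization events: a long analysis window
        averages the rare active episodes into its estimator noise floor,
        while second-scale windows resolve them at full strength.
    community_sources
        When True, every connected component of the planted graph shares a
        single latent source (a transiently synchronizing assembly), gated as
        a unit, instead of one source per edge.  For isolated edges the two
        models coincide; for larger components the community model keeps
        pairwise correlations strong, where per-edge sources would dilute
        them as node degrees grow.
    background_band
        Frequency range (Hz) of the per-channel background activity.  The
        default spans all analysed rhythms (4-42 Hz), mirroring the broadband
        character of scalp EEG: only a small fraction of background power
        falls inside any one rhythm, so a narrowband shared source dominates
        its own band after wavelet filtering.
    """

    n_channels: int
    planted_edges: frozenset = frozenset()
    coupling_strength: float = 0.8
    band: str = "alpha"
    noise_sd: float = 0.3
    gate_s: float | None = None
    gate_duty: float = 0.5
    community_sources: bool = False
    background_band: tuple[float, float] = (4.0, 42.0)

    def __post_init__(self) -> None:
        edges = frozenset(
            (min(i, j), max(i, j)) for i, j in self.planted_edges
        )
        object.__setattr__(self, "planted_edges", edges)
        for i, j in edges:
            if i == j or not (0 <= i < self.n_channels) \
                    or not (0 <= j < self.n_channels):
                raise ValueError(f"invalid planted edge ({i}, {j})")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must be in [0, 1]")
        if self.band not in _BAND_BY_NAME:
            raise ValueError(f"unknown band {self.band!r}")

    def adjacency(self) -> np.ndarray:
        """Ground-truth 0/1 adjacency matrix of the planted graph."""
        adj = np.zeros((self.n_channels, self.n_channels), dtype=np.int8)
        for i, j in self.planted_edges:
            adj[i, j] = adj[j, i] = 1
        return adj


@dataclass(frozen=True)
class SyntheticStudy:
    """A multi-subject synthetic dataset with known per-class coupling."""

    subjects: tuple[SubjectDataset, ...]
    truth: Mapping[str, CouplingSpec]
    classes: tuple[tuple[str, ...], ...]  # per subject, per trial
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "subjects", tuple(self.subjects))
        object.__setattr__(self, "classes", tuple(map(tuple, self.classes)))


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                band: BandDefinition) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [low, high] Hz."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < band.low) | (freqs > band.high)] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_trial(
    spec: CouplingSpec,
    duration_s: float = 60.0,
    fs: float = 128.0,
    seed: int = 0,
    channel_names: Sequence[str] | None = None,
) -> TrialRecording:
    """Synthesize one trial from a coupling specification.

    Each channel carries independent broadband background activity
    (``background_band``); every planted edge adds ``coupling_strength``
    times a shared source band-limited to ``band`` to both endpoints
    (optionally gated in time); white noise of SD ``noise_sd`` is added
    throughout.  Deterministic given ``seed``.
    """
    band = _BAND_BY_NAME[spec.band]
    if band.high >= fs / 2:
        raise ValueError(
            f"band {spec.band} ({band.high} Hz) exceeds Nyquist at fs={fs}"
        )
    n = int(round(duration_s * fs))
    if abs(duration_s * fs - n) > 1e-9:
        raise ValueError("duration_s * fs must be an integer sample count")
    lo, hi = spec.background_band
    if hi >= fs / 2:
        raise ValueError(
            f"background band upper edge {hi} Hz exceeds Nyquist at fs={fs}"
        )
    bg_band = BandDefinition("background", lo, hi)
    rng = np.random.default_rng(seed)
    data = np.stack([_band_noise(rng, n, fs, bg_band)
                     for _ in range(spec.n_channels)])

    def _gated(shared: np.ndarray) -> np.ndarray:
        if spec.gate_s is None:
            return shared
        n_seg = max(1, int(round(duration_s / spec.gate_s)))
        on = rng.random(n_seg) < spec.gate_duty
        gate = np.repeat(on.astype(float), -(-n // n_seg))[:n]
        return shared * gate

    if spec.community_sources:
        for members in _components(spec):
            shared = _gated(_band_noise(rng, n, fs, band))
            for node in members:
                data[node] += spec.coupling_strength * shared
    else:
        for i, j in sorted(spec.planted_edges):
            shared = _gated(_band_noise(rng, n, fs, band))
            data[i] += spec.coupling_strength * shared
            data[j] += spec.coupling_strength * shared
    data += spec.noise_sd * rng.standard_normal(data.shape)
    if channel_names is None:
        channel_names = tuple(f"ch{i:02d}" for i in range(spec.n_channels))
    return TrialRecording(data, fs, tuple(channel_names))


def _components(spec: CouplingSpec) -> list[tuple[int, ...]]:
    """Connected components of the planted graph, deterministically ordered."""
    parent = list(range(spec.n_channels))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in sorted(spec.planted_edges):
        parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for node in range(spec.n_channels):
        groups.setdefault(find(node), []).append(node)
    comps = [tuple(sorted(m)) for m in groups.values() if len(m) > 1]
    return sorted(comps)


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_study(
    n_subjects: int,
    n_trials: int,
    class_specs: Mapping[str, CouplingSpec],
    rating_map: Mapping[str, tuple[float, float]],
    seed: int = 0,
    duration_s: float = 60.0,
    fs: float = 128.0,
    subject_gain_sd: float = 0.2,
    subject_noise_sd: float = 0.3,
    channel_names: Sequence[str] | None = None,
) -> SyntheticStudy:
    """Generate a balanced multi-subject study with class-dependent coupling.

    Parameters
    ----------
    class_specs
        Per-class ground-truth coupling; all classes must agree on
        ``n_channels``.
    rating_map
        Per-class (valence, arousal) rating centres on the 1-9 scale.  Drawn
        ratings are jittered by +-0.5 but clipped to the centre's side of the
        midpoint, so label binarization always recovers the intended class.
    subject_gain_sd, subject_noise_sd
        SDs (log scale) of the per-subject gain and noise-floor multipliers
        emulating inter-subject variability.

    Classes are balanced within each subject to +-1 trial and shuffled in a
    seeded order.  Every trial gets its own child seed, so studies are
    reproducible bit-for-bit and grow consistently with ``n_trials``.
    """
    names = sorted(class_specs)
    n_ch = {s.n_channels for s in class_specs.values()}
    if len(n_ch) != 1:
        raise ValueError(f"class specs disagree on channel count: {n_ch}")
    missing = set(names) - set(rating_map)
    if missing:
        raise ValueError(f"rating_map missing classes: {sorted(missing)}")

    root = np.random.SeedSequence(seed)
    subject_seqs = root.spawn(n_subjects)
    subjects: list[SubjectDataset] = []
    classes: list[tuple[str, ...]] = []
    for s, sub_ss in enumerate(subject_seqs):
        sub_rng = np.random.default_rng(sub_ss)
        gain = float(np.exp(sub_rng.normal(0.0, subject_gain_sd)))
        noise_mult = float(np.exp(sub_rng.normal(0.0, subject_noise_sd)))

        order = [names[t % len(names)] for t in range(n_trials)]
        sub_rng.shuffle(order)

        trials: list[TrialRecording] = []
        ratings = np.empty((n_trials, 2))
        for t, cls in enumerate(order):
            base = class_specs[cls]
            spec = replace(base, noise_sd=base.noise_sd * noise_mult)
            tr = generate_trial(
                spec, duration_s, fs,
                seed=_child_seed(sub_ss.spawn(1)[0]),
                channel_names=channel_names,
            )
            trials.append(TrialRecording(gain * tr.data, fs, tr.channel_names))
            for col, centre in enumerate(rating_map[cls]):
                r = centre + sub_rng.uniform(-0.5, 0.5)
                r = np.clip(r, 5.0, 9.0) if centre >= 5.0 else np.clip(r, 1.0, 4.99)
                ratings[t, col] = r
        subjects.append(
            SubjectDataset(tuple(trials), ratings, subject_id=f"syn{s + 1:02d}")
        )
        classes.append(tuple(order))
    return SyntheticStudy(tuple(subjects), dict(class_specs), tuple(classes), seed)


def two_class_fixture(
    seed: int = 0,
    n_subjects: int = 6,
    n_trials: int = 20,
    n_channels: int = 16,
    coupling_strength: float = 0.8,
    noise_sd: float = 0.3,
    band: str = "alpha",
    gate_s: float | None = 1.0,
    gate_duty: float = 0.5,
    community_sources: bool = False,
) -> SyntheticStudy:
    """The standard two-class recovery fixture used throughout the test-bench.

    Low-valence trials carry a sparse planted graph (2 edges); high-valence
    trials a dense one (a clique on half the channels).  Both classes share
    band, strength and noise level, so only coupling density separates them.
    Channels carry broadband (4-42 Hz) background while coupling is confined
    to the alpha band, so the planted structure stands out sharply after
    wavelet filtering; each edge's source is gated on a 1 s timescale at 50%
    duty, so a trial's connectivity genuinely reconfigures from second to
    second — the regime windowed (dynamic) network analysis is designed for.
    """
    sparse = frozenset({(0, 1), (2, 3)})
    clique_nodes = range(n_channels // 2)
    dense = frozenset(
        (i, j) for i in clique_nodes for j in clique_nodes if i < j
    )
    specs = {
        "low": CouplingSpec(n_channels, sparse, coupling_strength, band,
                            noise_sd, gate_s, gate_duty, community_sources),
        "high": CouplingSpec(n_channels, dense, coupling_strength, band,
                             noise_sd, gate_s, gate_duty, community_sources),
    }
    rating_map = {"low": (2.5, 2.5), "high": (7.5, 7.5)}
    return generate_study(
        n_subjects, n_trials, specs, rating_map, seed=seed
    )


def write_study(
    study: SyntheticStudy, out_dir: str | Path, dialect: str = "matlab"
) -> list[Path]:
    """Write a DEAP-layout file per subject, readable by ``load_subject``.

    Requires 32-channel, 60 s @ 128 Hz trials.  Each trial is padded to the
    DEAP raw layout: 3 s of zero baseline in front and 8 dummy peripheral
    channels of white noise below the EEG block, giving 40 x 8,064 per trial;
    ratings fill the first two of four label columns.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    rng = np.random.default_rng(study.seed)
    for subject in study.subjects:
        if subject.n_trials == 0:
            raise ValueError("cannot write a subject with no trials")
        fs = subject.trials[0].fs
        n_eeg = subject.trials[0].n_channels
        if n_eeg != 32 or subject.trials[0].n_samples != int(60 * fs):
            raise ValueError(
                "DEAP layout needs 32-channel, 60 s trials; generate the "
                "study with n_channels=32, duration_s=60"
            )
        n_base = int(3 * fs)
        data = np.zeros((subject.n_trials, 40, n_base + int(60 * fs)))
        for t, tr in enumerate(subject.trials):
            data[t, :32, n_base:] = tr.data
            data[t, 32:, :] = rng.standard_normal((8, data.shape[2]))
        labels = np.ones((subject.n_trials, 4))
        labels[:, :2] = subject.ratings

        if dialect == "matlab":
            from scipy.io import savemat

            path = out_dir / f"{subject.subject_id}.mat"
            savemat(str(path), {"data": data, "labels": labels})
        elif dialect == "pickle":
            import pickle

            path = out_dir / f"{subject.subject_id}.pickle"
            with open(path, "wb") as fh:
                pickle.dump({"data": data, "labels": labels}, fh)
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
        paths.append(path)
    return paths
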