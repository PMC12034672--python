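"""Data model for multichannel EEG trials and DEAP-format reading.

The DEAP preprocessed release stores, per subject, a ``data`` array of
40 trials x 40 channels x 8,064 samples (63 s at 128 Hz: 3 s of baseline
followed by the 60 s stimulus) and a ``labels`` array of 40 x 4 self-assessment
ratings (valence, arousal, dominance, liking on a continuous 1-9 scale).
Channels 1-32 are EEG in the DEAP montage order; channels 33-40 are peripheral
physiological signals and are dropped during preprocessing.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "DEAP_EEG_CHANNELS",
    "DEFAULT_REGION_MAP",
    "TrialRecording",
    "SubjectDataset",
    "LabelSet",
    "RegionMask",
    "FOUR_CLASS_CODES",
    "load_subject",
    "preprocess_trial",
    "binarize_labels",
    "select_region",
    "load_region_map",
]

#: EEG channel names in the DEAP recording order (10-20 system, 32 electrodes).
DEAP_EEG_CHANNELS: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)

#: Five-region partition of the 32 DEAP electrodes: frontal, left/right
#: temporal, central, and merged parietal-occipital.  The exact assignment is a
#: documented convention of this package (standard 10-20 lobe membership with
#: the parietal and occipital rows merged and the temporal strip split by
#: hemisphere); it is configurable through :func:`load_region_map`.
DEFAULT_REGION_MAP: dict[str, tuple[str, ...]] = {
    "F": ("Fp1", "Fp2", "AF3", "AF4", "F7", "F3", "Fz", "F4", "F8"),
    "LT": ("FC5", "T7", "CP5"),
    "RT": ("FC6", "T8", "CP6"),
    "C": ("FC1", "FC2", "C3", "Cz", "C4", "CP1", "CP2"),
    "PO": ("P7", "P3", "Pz", "P4", "P8", "PO3", "PO4", "O1", "Oz", "O2"),
}

#: Fixed encoding of the four valence/arousal quadrants.
FOUR_CLASS_CODES: dict[str, int] = {"LVLA": 0, "LVHA": 1, "HVLA": 2, "HVHA": 3}

_DEAP_N_TRIALS = 40
_DEAP_N_CHANNELS_RAW = 40
_DEAP_N_SAMPLES_RAW = 8064
_DEAP_FS = 128.0
_BASELINE_S = 3.0
_STIMULUS_S = 60.0


@dataclass(frozen=True)
class TrialRecording:
    """One trial: a channels x samples matrix with its sampling rate.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)``.
    fs
        Sampling rate in Hz.
    channel_names
        Ordered channel labels; must be unique and match ``data``'s first axis.
    """

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if data.ndim != 2:
            raise ValueError(f"trial data must be 2-D, got shape {data.shape}")
        if len(self.channel_names) != data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class SubjectDataset:
    """All trials of one subject plus the per-trial self-assessment ratings."""

    trials: tuple[TrialRecording, ...]
    ratings: np.ndarray  # (n_trials, >=2): columns valence, arousal, ...
    subject_id: str = "s01"

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(self.trials))
        ratings = np.asarray(self.ratings, dtype=float)
        object.__setattr__(self, "ratings", ratings)
        if ratings.ndim != 2 or ratings.shape[1] < 2:
            raise ValueError("ratings must be (n_trials, >=2)")
        if len(self.trials) != ratings.shape[0]:
            raise ValueError(
                f"{len(self.trials)} trials but {ratings.shape[0]} rating rows"
            )
        if ratings.size and (ratings.min() < 1.0 or ratings.max() > 9.0):
            raise ValueError("ratings must lie in [1, 9]")

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class LabelSet:
    """Binary valence/arousal labels and the derived four-quadrant code."""

    valence_bin: np.ndarray
    arousal_bin: np.ndarray
    four_class: np.ndarray  # integer codes per FOUR_CLASS_CODES

    def class_names(self) -> list[str]:
        inv = {v: k for k, v in FOUR_CLASS_CODES.items()}
        return [inv[int(c)] for c in self.four_class]


@dataclass(frozen=True)
class RegionMask:
    """A named subset of electrodes (one of F/LT/RT/C/PO, or ALL)."""

    region_id: str
    channels: tuple[str, ...]

    @classmethod
    def from_map(
        cls, region_id: str, region_map: Mapping[str, Sequence[str]] | None = None
    ) -> "RegionMask":
        region_map = DEFAULT_REGION_MAP if region_map is None else region_map
        if region_id == "ALL":
            chans: tuple[str, ...] = tuple(
                c for names in region_map.values() for c in names
            )
            return cls("ALL", chans)
        if region_id not in region_map:
            raise KeyError(f"unknown region {region_id!r}")
        return cls(region_id, tuple(region_map[region_id]))


def load_region_map(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a region -> channel-list mapping from a JSON or YAML file."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    region_map = {str(k): tuple(map(str, v)) for k, v in raw.items()}
    all_chans = [c for v in region_map.values() for c in v]
    if len(all_chans) != len(set(all_chans)):
        raise ValueError("region map regions overlap")
    return region_map


def load_subject(path: str | Path, dialect: str = "matlab") -> SubjectDataset:
    """Load one subject file of the DEAP preprocessed release.

    Parameters
    ----------
    path
        Per-subject file holding a ``data`` array of shape (40, 40, 8064) and a
        ``labels`` array of shape (40, 4).
    dialect
        ``"matlab"`` for the MATLAB v7 ``.mat`` release (read with
        :func:`scipy.io.loadmat`), ``"pickle"`` for the pickled-Python release
        (a dict with ``data``/``labels`` keys).

    Returns
    -------
    SubjectDataset
        Raw (still baselined) 40-channel trials of 8,064 samples at 128 Hz,
        trial order preserved.  Only the first two rating columns (valence,
        arousal) are retained.
    """
    path = Path(path)
    if dialect == "matlab":
        from scipy.io import loadmat

        mat = loadmat(str(path))
        missing = [k for k in ("data", "labels") if k not in mat]
        if missing:
            raise ValueError(f"{path.name}: missing array(s) {missing}")
        data, labels = mat["data"], mat["labels"]
    elif dialect == "pickle":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        missing = [k for k in ("data", "labels") if k not in obj]
        if missing:
            raise ValueError(f"{path.name}: missing array(s) {missing}")
        data, labels = np.asarray(obj["data"]), np.asarray(obj["labels"])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    expected = (_DEAP_N_TRIALS, _DEAP_N_CHANNELS_RAW, _DEAP_N_SAMPLES_RAW)
    if data.ndim != 3:
        raise ValueError(f"{path.name}: data must be 3-D, got {data.ndim}-D")
    for axis, (got, want) in enumerate(zip(data.shape, expected)):
        if got != want:
            raise ValueError(
                f"{path.name}: data axis {axis} has size {got}, expected {want}"
            )
    if labels.shape[0] != data.shape[0] or labels.shape[1] < 2:
        raise ValueError(
            f"{path.name}: labels shape {labels.shape} does not match "
            f"{data.shape[0]} trials with >=2 rating columns"
        )

    names = DEAP_EEG_CHANNELS + tuple(
        f"PHYS{i}" for i in range(1, _DEAP_N_CHANNELS_RAW - 32 + 1)
    )
    trials = tuple(
        TrialRecording(data[t].astype(float), _DEAP_FS, names)
        for t in range(data.shape[0])
    )
    return SubjectDataset(trials, labels[:, :2].astype(float), subject_id=path.stem)


def preprocess_trial(
    raw: TrialRecording,
    baseline_s: float = _BASELINE_S,
    stimulus_s: float = _STIMULUS_S,
    n_eeg_channels: int = 32,
) -> TrialRecording:
    """Baseline-correct one trial and drop the non-EEG channels.

    The per-channel mean of the leading ``baseline_s`` seconds is subtracted
    from the final ``stimulus_s`` seconds; channels beyond ``n_eeg_channels``
    (DEAP's 8 peripheral leads) are removed.  A DEAP-shaped input
    (40 x 8,064 @ 128 Hz) yields 32 x 7,680.
    """
    n_base = int(round(baseline_s * raw.fs))
    n_stim = int(round(stimulus_s * raw.fs))
    if raw.n_samples < n_base + n_stim:
        raise ValueError(
            f"trial holds {raw.n_samples} samples; need >= {n_base + n_stim} "
            f"({baseline_s} s baseline + {stimulus_s} s stimulus at {raw.fs} Hz)"
        )
    keep = min(n_eeg_channels, raw.n_channels)
    baseline_mean = raw.data[:keep, :n_base].mean(axis=1, keepdims=True)
    out = raw.data[:keep, -n_stim:] - baseline_mean
    return TrialRecording(out, raw.fs, raw.channel_names[:keep])


def binarize_labels(ratings: np.ndarray, threshold: float = 5.0) -> LabelSet:
    """Binarize 1-9 valence/arousal ratings at the scale midpoint.

    A score >= ``threshold`` (default 5) is high (1); below is low (0).  The
    four-quadrant code pairs the two binary labels per ``FOUR_CLASS_CODES``.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[1] < 2:
        raise ValueError("ratings must be (n_trials, >=2) [valence, arousal]")
    if ratings.size and (ratings.min() < 1.0 or ratings.max() > 9.0):
        raise ValueError("ratings must lie in [1, 9]")
    val = (ratings[:, 0] >= threshold).astype(int)
    aro = (ratings[:, 1] >= threshold).astype(int)
    four = 2 * val + aro  # LVLA=0, LVHA=1, HVLA=2, HVHA=3
    return LabelSet(val, aro, four)


def select_region(tr: TrialRecording, mask: RegionMask) -> TrialRecording:
    """Restrict a recording to one region's electrodes, keeping recording order."""
    wanted = set(mask.channels)
    unknown = wanted - set(tr.channel_names)
    if unknown:
        raise KeyError(f"channels not in recording: {sorted(unknown)}")
    idx = [i for i, c in enumerate(tr.channel_names) if c in wanted]
    return TrialRecording(
        tr.data[idx], tr.fs, tuple(tr.channel_names[i] for i in idx)
    )
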