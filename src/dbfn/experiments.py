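"""Evaluation protocols, ablations and paired significance testing.

Three cross-validation designs probe increasingly hard generalization:

* **subject-dependent** — per subject, a stratified 3:1 trial split; the
  model sees other trials of the same person;
* **subject-independent (LOSO)** — leave-one-subject-out: train on every
  trial of the remaining subjects, test on all trials of the held-out one;
* **subject-and-trial-independent** — per held-out subject, a random half of
  the trial indices forms the test set (that subject's trials); training uses
  only the *complementary* trial indices of the other subjects, so no trial
  index appears on both sides.

In every fold, feature selection, standardization and grid search touch
training rows only; an :class:`AccessLog` records the global row ids each
stage reads so leakage is auditable after the fact.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import wilcoxon as _scipy_wilcoxon

from .connectivity import DEFAULT_N_BINS, mi_matrix_stack, threshold_stack
from .core_data import (
    RegionMask,
    SubjectDataset,
    binarize_labels,
    select_region,
)
from .model import ClassifierProtocolConfig, fit_and_predict, mrmr_select
from .network_features import assemble_trial_features
from .spectral import BAND_PAIRS, DEFAULT_BANDS, segment_windows, \
    trial_difference_signals
from .synthetic_data import SyntheticStudy

__all__ = [
    "AccessLog",
    "FoldAudit",
    "ProtocolSpec",
    "ExperimentResult",
    "StudyFeatures",
    "extract_study_features",
    "restrict_band_pair",
    "run_subject_dependent",
    "run_loso",
    "run_subject_trial_independent",
    "run_protocol",
    "region_ablation",
    "band_pair_ablation",
    "wilcoxon_compare",
    "WilcoxonResult",
]

_TRAIN_STAGES = ("mrmr", "standardize", "grid_search", "fit")


class AccessLog:
    """Records which global data rows each pipeline stage read."""

    def __init__(self) -> None:
        self.records: list[tuple[str, frozenset[int]]] = []

    def record(self, stage: str, rows: Iterable[int]) -> None:
        self.records.append((stage, frozenset(int(r) for r in rows)))

    def rows_for(self, stages: Sequence[str]) -> frozenset[int]:
        out: set[int] = set()
        for stage, rows in self.records:
            if stage in stages:
                out |= rows
        return frozenset(out)


@dataclass(frozen=True)
class FoldAudit:
    """One fold's row bookkeeping for the leakage audit."""

    fold_id: str
    train_rows: frozenset
    test_rows: frozenset
    log: AccessLog

    def training_stages_clean(self) -> bool:
        """True iff no training-side stage read a test row."""
        return not (self.log.rows_for(_TRAIN_STAGES) & self.test_rows)


@dataclass(frozen=True)
class ProtocolSpec:
    """Configuration of one experiment run."""

    mode: str = "subject_dependent"
    dimension: str = "valence"  # valence | arousal | four_class
    window_s: float = 1.0
    threshold_q: float = 0.3
    region: RegionMask | None = None
    band_pair: str = "ALL"
    n_bins: int = DEFAULT_N_BINS
    k_features: int = 256
    mrmr_bins: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("subject_dependent", "subject_independent",
                             "subject_trial_independent"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.dimension not in ("valence", "arousal", "four_class"):
            raise ValueError(f"unknown dimension {self.dimension!r}")


@dataclass(frozen=True)
class ExperimentResult:
    """Per-subject accuracies with their mean and standard deviation."""

    per_subject_accuracy: tuple[float, ...]
    config: Mapping[str, object]
    folds: tuple[FoldAudit, ...] = ()

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_subject_accuracy))

    @property
    def std(self) -> float:
        return float(np.std(self.per_subject_accuracy))

    def summary(self) -> str:
        return (f"{100 * self.mean:.2f} +- {100 * self.std:.2f} % "
                f"(n={len(self.per_subject_accuracy)} subjects)")


@dataclass(frozen=True)
class StudyFeatures:
    """Per-trial network-attribute feature matrix of a whole study."""

    X: np.ndarray  # (n_total_trials, n_features)
    ratings: np.ndarray  # (n_total_trials, 2)
    subject_index: np.ndarray  # (n_total_trials,)
    trial_index: np.ndarray  # within-subject trial number
    layout: tuple[str, ...]
    window_s: float
    subject_ids: tuple[str, ...]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def labels(self, dimension: str) -> np.ndarray:
        ls = binarize_labels(self.ratings)
        return {"valence": ls.valence_bin, "arousal": ls.arousal_bin,
                "four_class": ls.four_class}[dimension]

    def to_hdf5(self, path) -> None:
        """Persist the feature matrix and its bookkeeping to one HDF5 file."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("X", data=self.X, compression="gzip")
            f.create_dataset("ratings", data=self.ratings)
            f.create_dataset("subject_index", data=self.subject_index)
            f.create_dataset("trial_index", data=self.trial_index)
            f.create_dataset(
                "layout", data=np.array(self.layout, dtype="S"))
            f.attrs["window_s"] = self.window_s
            f.attrs["subject_ids"] = list(self.subject_ids)

    @classmethod
    def from_hdf5(cls, path) -> "StudyFeatures":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                f["X"][()], f["ratings"][()], f["subject_index"][()],
                f["trial_index"][()],
                tuple(s.decode() for s in f["layout"][()]),
                float(f.attrs["window_s"]),
                tuple(f.attrs["subject_ids"]),
            )


def _subjects_of(study) -> tuple[SubjectDataset, ...]:
    if isinstance(study, SyntheticStudy):
        return study.subjects
    return tuple(study)


def extract_study_features(
    study,
    window_s: float = 1.0,
    q: float = 0.3,
    n_bins: int = DEFAULT_N_BINS,
    region: RegionMask | None = None,
    wrap_phases: bool = True,
    bands=DEFAULT_BANDS,
) -> StudyFeatures:
    """Run the network pipeline over every trial of a study.

    Per trial: band decomposition into the 12 difference signals, windowing
    at ``window_s``, per-window MI connectivity (``n_bins`` histogram bins),
    positional thresholding at ``q``, and graph-feature extraction.  The
    per-trial feature length is ``12 * (duration / window_s) * (1 + 2 n_ch)``.
    """
    subjects = _subjects_of(study)
    if not subjects:
        raise ValueError("study holds no subjects")
    rows, ratings, subj_idx, trial_idx = [], [], [], []
    layout: tuple[str, ...] | None = None
    for s, subject in enumerate(subjects):
        for t, tr in enumerate(subject.trials):
            if region is not None and region.region_id != "ALL":
                tr = select_region(tr, region)
            diffs = trial_difference_signals(tr, bands=bands,
                                             wrap_phases=wrap_phases)
            adj_blocks = []
            for d in diffs:
                wins = segment_windows(d.values, window_s, tr.fs)
                mi = mi_matrix_stack(wins, n_bins)
                adj_blocks.append(threshold_stack(mi, q))
            networks = np.concatenate(adj_blocks, axis=0)
            feats = assemble_trial_features(
                networks, window_s,
                signal_names=[d.name for d in diffs],
                channel_names=tr.channel_names,
                duration_s=tr.duration_s,
            )
            if layout is None:
                layout = feats.layout
            rows.append(feats.vector)
            ratings.append(subject.ratings[t])
            subj_idx.append(s)
            trial_idx.append(t)
    return StudyFeatures(
        np.asarray(rows), np.asarray(ratings), np.asarray(subj_idx),
        np.asarray(trial_idx), layout, window_s,
        tuple(sub.subject_id for sub in subjects),
    )


def restrict_band_pair(features: StudyFeatures, pair: str) -> StudyFeatures:
    """Keep only the two difference signals (amplitude + phase) of one pair.

    ``pair`` is a name like ``"gamma_beta"`` (or ``"ALL"`` for the identity).
    Column restriction is exact: per-signal networks are independent, so this
    equals re-running the pipeline on that pair alone.
    """
    if pair == "ALL":
        return features
    valid = {f"{hi}_{lo}" for hi, lo in BAND_PAIRS}
    if pair not in valid:
        raise KeyError(f"unknown band pair {pair!r}; expected one of "
                       f"{sorted(valid)} or 'ALL'")
    cols = [i for i, name in enumerate(features.layout)
            if name.startswith(pair + ":")]
    return replace(
        features, X=features.X[:, cols],
        layout=tuple(features.layout[i] for i in cols),
    )


def _fold_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF]


def _run_fold(
    features: StudyFeatures,
    y: np.ndarray,
    train_rows: np.ndarray,
    test_rows: np.ndarray,
    spec: ProtocolSpec,
    cfg: ClassifierProtocolConfig,
    fold_seed: int,
    fold_id: str,
) -> tuple[float, FoldAudit]:
    log = AccessLog()
    k = min(spec.k_features, features.X.shape[1])
    sel = mrmr_select(
        features.X[train_rows], y[train_rows], k, n_bins=spec.mrmr_bins,
        row_ids=train_rows, access_log=log,
    )
    cols = list(sel.selected_indices)
    pred = fit_and_predict(
        features.X[np.ix_(train_rows, cols)], y[train_rows],
        features.X[np.ix_(test_rows, cols)],
        replace(cfg, seed=fold_seed),
        train_row_ids=train_rows, test_row_ids=test_rows, access_log=log,
    )
    acc = float(np.mean(pred.labels == y[test_rows]))
    audit = FoldAudit(fold_id, frozenset(map(int, train_rows)),
                      frozenset(map(int, test_rows)), log)
    return acc, audit


def _stratified_split(
    rows: np.ndarray, y: np.ndarray, test_frac: float, seed: int,
    max_retries: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified split; falls back to resampled shuffles when a class
    is too rare to stratify, erroring after bounded retries."""
    from sklearn.model_selection import train_test_split

    present = np.unique(y)
    if np.bincount(np.searchsorted(present, y)).min() >= 2:
        tr, te = train_test_split(rows, test_size=test_frac,
                                  stratify=y, random_state=seed)
        return np.sort(tr), np.sort(te)
    rng = np.random.default_rng(seed)
    n_test = max(1, int(round(test_frac * rows.size)))
    for _ in range(max_retries):
        perm = rng.permutation(rows.size)
        tr, te = rows[perm[n_test:]], rows[perm[:n_test]]
        if np.isin(present, y[np.isin(rows, tr)]).all():
            return np.sort(tr), np.sort(te)
    raise ValueError("could not build a training split holding every class")


def run_subject_dependent(
    features: StudyFeatures, spec: ProtocolSpec, cfg: ClassifierProtocolConfig
) -> ExperimentResult:
    """Per-subject stratified 3:1 trial split, one accuracy per subject."""
    y = features.labels(spec.dimension)
    seeds = _fold_seeds(spec.seed, features.n_subjects)
    accs, folds = [], []
    for s in range(features.n_subjects):
        rows = np.flatnonzero(features.subject_index == s)
        tr, te = _stratified_split(rows, y[rows], 0.25, seeds[s])
        acc, audit = _run_fold(features, y, tr, te, spec, cfg, seeds[s],
                               f"subject_dependent:{features.subject_ids[s]}")
        accs.append(acc)
        folds.append(audit)
    return ExperimentResult(tuple(accs), _echo(spec, cfg), tuple(folds))


def run_loso(
    features: StudyFeatures, spec: ProtocolSpec, cfg: ClassifierProtocolConfig
) -> ExperimentResult:
    """Leave-one-subject-out: train on the rest, test on every held-out trial."""
    if features.n_subjects < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    y = features.labels(spec.dimension)
    seeds = _fold_seeds(spec.seed, features.n_subjects)
    accs, folds = [], []
    for s in range(features.n_subjects):
        te = np.flatnonzero(features.subject_index == s)
        tr = np.flatnonzero(features.subject_index != s)
        acc, audit = _run_fold(features, y, tr, te, spec, cfg, seeds[s],
                               f"loso:{features.subject_ids[s]}")
        accs.append(acc)
        folds.append(audit)
    return ExperimentResult(tuple(accs), _echo(spec, cfg), tuple(folds))


def run_subject_trial_independent(
    features: StudyFeatures, spec: ProtocolSpec, cfg: ClassifierProtocolConfig
) -> ExperimentResult:
    """Held-out subject *and* disjoint trial indices between train and test.

    Per held-out subject a seeded random half of the trial indices (the floor
    half when the count is odd) forms the test set, taken from that subject's
    trials; training uses only the complementary trial indices of the other
    subjects, so no trial index appears on both sides of a fold.
    """
    if features.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    y = features.labels(spec.dimension)
    seeds = _fold_seeds(spec.seed, features.n_subjects)
    n_trials = int(features.trial_index.max()) + 1
    accs, folds = [], []
    for s in range(features.n_subjects):
        rng = np.random.default_rng(seeds[s])
        test_trials = np.sort(
            rng.choice(n_trials, size=n_trials // 2, replace=False)
        )
        in_test = np.isin(features.trial_index, test_trials)
        te = np.flatnonzero((features.subject_index == s) & in_test)
        tr = np.flatnonzero((features.subject_index != s) & ~in_test)
        acc, audit = _run_fold(
            features, y, tr, te, spec, cfg, seeds[s],
            f"subject_trial_independent:{features.subject_ids[s]}")
        accs.append(acc)
        folds.append(audit)
    return ExperimentResult(tuple(accs), _echo(spec, cfg), tuple(folds))


_PROTOCOLS = {
    "subject_dependent": run_subject_dependent,
    "subject_independent": run_loso,
    "subject_trial_independent": run_subject_trial_independent,
}


def run_protocol(
    study_or_features,
    spec: ProtocolSpec,
    cfg: ClassifierProtocolConfig | None = None,
) -> ExperimentResult:
    """Extract features if needed, then dispatch on ``spec.mode``."""
    cfg = cfg or ClassifierProtocolConfig()
    if isinstance(study_or_features, StudyFeatures):
        features = study_or_features
    else:
        features = extract_study_features(
            study_or_features, window_s=spec.window_s, q=spec.threshold_q,
            n_bins=spec.n_bins, region=spec.region,
        )
    features = restrict_band_pair(features, spec.band_pair)
    return _PROTOCOLS[spec.mode](features, spec, cfg)


def region_ablation(
    study,
    spec: ProtocolSpec,
    regions: Sequence[RegionMask],
    cfg: ClassifierProtocolConfig | None = None,
) -> dict[str, ExperimentResult]:
    """Re-run the full pipeline restricted to each electrode region."""
    out: dict[str, ExperimentResult] = {}
    for mask in regions:
        if mask.region_id != "ALL" and len(mask.channels) < 2:
            raise ValueError(
                f"region {mask.region_id} has < 2 channels; "
                "connectivity needs at least 2"
            )
        out[mask.region_id] = run_protocol(
            study, replace(spec, region=mask), cfg
        )
    return out


def band_pair_ablation(
    study_or_features,
    spec: ProtocolSpec,
    pair: str,
    cfg: ClassifierProtocolConfig | None = None,
) -> ExperimentResult:
    """Run one protocol using only one band pair's difference signals."""
    return run_protocol(study_or_features, replace(spec, band_pair=pair), cfg)


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    n_nonzero: int
    degenerate: bool  # True when every paired difference is zero


def wilcoxon_compare(
    a: Sequence[float], b: Sequence[float]
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired per-subject accuracies.

    Zero differences are dropped (the classical 'wilcox' policy); if every
    pair ties, the result is flagged degenerate with p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diffs = a - b
    n_nonzero = int(np.count_nonzero(diffs))
    if n_nonzero == 0:
        return WilcoxonResult(float("nan"), 1.0, 0, True)
    stat, p = _scipy_wilcoxon(a, b, zero_method="wilcox",
                              alternative="two-sided")
    return WilcoxonResult(float(stat), float(p), n_nonzero, False)


def _echo(spec: ProtocolSpec, cfg: ClassifierProtocolConfig) -> dict:
    return {
        "mode": spec.mode, "dimension": spec.dimension,
        "window_s": spec.window_s, "threshold_q": spec.threshold_q,
        "region": spec.region.region_id if spec.region else "ALL",
        "band_pair": spec.band_pair, "n_bins": spec.n_bins,
        "k_features": spec.k_features, "mrmr_bins": spec.mrmr_bins,
        "seed": spec.seed, "n_repeats": cfg.n_repeats,
        "c_grid": list(cfg.c_grid), "kernels": list(cfg.kernel_set),
    }
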