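"""Multi-voxel pattern analysis: preprocessing, voxel selection, decoding.

The decoding chain mirrors the standard event-related recipe: voxel time
courses are z-scored within each run, the series is shifted by 3 volumes
(4.5 s at TR 1.5 s) to absorb the hemodynamic delay, the two volumes of each
3-s trial are averaged into one pattern, and a linear support-vector machine
is trained to tell radial from concentric patterns under leave-one-run-out
cross-validation.  Voxel selection (t-ranked stimulus-vs-fixation, up to 100
voxels) is recomputed inside every fold from the training runs only, so no
information from the held-out run leaks into selection or fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = ["TrialDataset", "DecodingResult", "extract_trial_patterns",
           "select_voxels", "cross_validated_decode"]

FIXATION = "fixation"
CATEGORIES = ("radial", "concentric")


@dataclass
class TrialDataset:
    """Labeled multivoxel trial patterns grouped by run.

    ``labels`` holds 'radial'/'concentric' for stimulus trials and
    'fixation' for the non-informative baseline condition; ``signal_level``
    is NaN for fixation trials.  ``motion_flag`` marks trials excluded
    upstream for excessive head motion (>1 mm translation / 1 deg rotation);
    flagged trials never enter training or testing.
    """

    patterns: np.ndarray               # (n_trials, n_voxels)
    labels: np.ndarray                 # object/str array
    signal_level: np.ndarray           # float, NaN for fixation
    run_id: np.ndarray                 # int
    session_label: str = "pre"
    voxel_ids: np.ndarray | None = None
    voxel_coords: np.ndarray | None = None   # (n_voxels, 3) int grid indices
    grid_shape: tuple | None = None
    motion_flag: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.patterns)
        self.patterns = np.asarray(self.patterns, float)
        self.labels = np.asarray(self.labels, object)
        self.signal_level = np.asarray(self.signal_level, float)
        self.run_id = np.asarray(self.run_id, int)
        if not (len(self.labels) == len(self.signal_level)
                == len(self.run_id) == n):
            raise ValueError("per-trial fields must share length")
        if self.voxel_ids is None:
            self.voxel_ids = np.arange(self.patterns.shape[1])
        if self.motion_flag is None:
            self.motion_flag = np.zeros(n, bool)
        self.motion_flag = np.asarray(self.motion_flag, bool)

    @property
    def n_trials(self) -> int:
        return len(self.patterns)

    @property
    def n_voxels(self) -> int:
        return self.patterns.shape[1]

    @property
    def runs(self) -> np.ndarray:
        return np.unique(self.run_id)

    def subset(self, trial_mask=None, voxel_idx=None) -> "TrialDataset":
        t = np.ones(self.n_trials, bool) if trial_mask is None else trial_mask
        new = replace(
            self,
            patterns=self.patterns[np.ix_(t, np.arange(self.n_voxels))]
            if voxel_idx is None else self.patterns[np.ix_(t, voxel_idx)],
            labels=self.labels[t],
            signal_level=self.signal_level[t],
            run_id=self.run_id[t],
            voxel_ids=self.voxel_ids if voxel_idx is None
            else self.voxel_ids[voxel_idx],
            voxel_coords=self.voxel_coords if self.voxel_coords is None
            or voxel_idx is None else self.voxel_coords[voxel_idx],
            motion_flag=self.motion_flag[t],
        )
        return new

    def stimulus_mask(self) -> np.ndarray:
        return (self.labels != FIXATION) & ~self.motion_flag

    def validate(self) -> None:
        if len(self.runs) < 2:
            raise ValueError("need at least 2 runs for cross-validation")
        for r in self.runs:
            in_run = self.run_id == r
            labs = set(self.labels[in_run & self.stimulus_mask()])
            if not set(CATEGORIES) <= labs:
                raise ValueError(f"run {r} lacks a stimulus category")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.patterns,
                          columns=[f"v{int(i)}" for i in self.voxel_ids])
        df.insert(0, "run_id", self.run_id)
        df.insert(1, "label", self.labels)
        df.insert(2, "signal_level", self.signal_level)
        df.insert(3, "motion_flag", self.motion_flag.astype(int))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, session_label: str = "pre"
                   ) -> "TrialDataset":
        vcols = [c for c in df.columns if c.startswith("v")]
        return cls(df[vcols].to_numpy(float), df["label"].to_numpy(object),
                   df["signal_level"].to_numpy(float),
                   df["run_id"].to_numpy(int), session_label=session_label,
                   voxel_ids=np.array([int(c[1:]) for c in vcols]),
                   motion_flag=df.get("motion_flag", pd.Series(0, index=df.index)
                                      ).to_numpy(bool))


@dataclass
class DecodingResult:
    """Per-signal-level classifier accuracy from leave-one-run-out folds."""

    levels: np.ndarray
    accuracy: np.ndarray               # fraction correct per level, pooled
    n_trials: np.ndarray               # tested trials per level
    fold_accuracy: list                # overall accuracy per fold
    n_voxels_used: int
    scheme: str = "all_levels"
    session_label: str = ""
    per_category: pd.DataFrame | None = None

    @property
    def overall_accuracy(self) -> float:
        return float(np.sum(self.accuracy * self.n_trials)
                     / np.sum(self.n_trials))

    def to_dict(self) -> dict:
        return {
            "levels": list(map(float, self.levels)),
            "accuracy": list(map(float, self.accuracy)),
            "n_trials": list(map(int, self.n_trials)),
            "fold_accuracy": list(map(float, self.fold_accuracy)),
            "n_voxels_used": int(self.n_voxels_used),
            "scheme": self.scheme,
            "session_label": self.session_label,
            "overall_accuracy": self.overall_accuracy,
        }


def _zscore_within_run(ts: np.ndarray) -> np.ndarray:
    """Z-score each voxel's time course; flat voxels are a hard error."""
    mean = ts.mean(axis=0)
    sd = ts.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant voxel time series cannot be z-scored")
    return (ts - mean) / sd


def extract_trial_patterns(runs, lag_volumes: int = 3, tr_s: float = 1.5,
                           trial_duration_s: float = 3.0,
                           session_label: str = "pre",
                           mask: np.ndarray | None = None,
                           voxel_coords: np.ndarray | None = None,
                           grid_shape: tuple | None = None) -> TrialDataset:
    """Turn per-run time series plus events into one pattern per trial.

    ``runs`` is a list of ``(timeseries, events)`` pairs, where the time
    series is (T, V) (or a 4-D array with ``mask`` giving the voxel set) and
    ``events`` has columns onset, condition and optionally signal_level,
    category, motion_flag.  Each voxel is z-scored within run, the series is
    shifted by ``lag_volumes`` volumes, and the trial's 2 volumes (3-s trial
    at TR 1.5 s) are averaged into one pattern.  Trials whose shifted
    volumes run past the end of the run are dropped and logged.
    """
    vols_per_trial = int(round(trial_duration_s / tr_s))
    pats, labels, levels, run_ids, motion = [], [], [], [], []
    for ridx, (ts, events) in enumerate(runs):
        ts = np.asarray(ts, float)
        if ts.ndim == 4:
            if mask is None:
                raise ValueError("4-D time series requires a mask")
            if voxel_coords is None:
                voxel_coords = np.argwhere(mask)
                grid_shape = mask.shape
            ts = ts[mask].T                       # (T, V)
        z = _zscore_within_run(ts)
        n_vol = len(z)
        dropped = 0
        for _, ev in events.iterrows():
            v0 = int(round(ev["onset"] / tr_s)) + lag_volumes
            v1 = v0 + vols_per_trial
            if v1 > n_vol:
                dropped += 1
                continue
            pats.append(z[v0:v1].mean(axis=0))
            labels.append(ev["condition"] if "category" not in ev
                          or pd.isna(ev.get("category")) else ev["category"])
            levels.append(float(ev.get("signal_level", np.nan))
                          if not pd.isna(ev.get("signal_level", np.nan))
                          else np.nan)
            run_ids.append(ridx)
            motion.append(bool(ev.get("motion_flag", False)))
        if dropped:
            logger.info("run %d: dropped %d trial(s) past run end after "
                        "hemodynamic shift", ridx, dropped)
    return TrialDataset(np.array(pats), np.array(labels, object),
                        np.array(levels), np.array(run_ids),
                        session_label=session_label,
                        voxel_coords=voxel_coords, grid_shape=grid_shape)


def select_voxels(train: TrialDataset, max_n: int = 100,
                  alpha: float = 0.05) -> np.ndarray:
    """Indices of up to ``max_n`` voxels most activated by stimuli vs fixation.

    A two-sample t-test per voxel on the *training folds only* compares all
    stimulus trials against fixation trials; significant voxels (p < alpha,
    uncorrected, positive t) are ranked by t and the top ``max_n`` returned.
    If none pass, the top ``max_n`` by t are returned with a warning.
    """
    stim = train.patterns[train.stimulus_mask()]
    fix = train.patterns[(train.labels == FIXATION) & ~train.motion_flag]
    if len(fix) == 0:
        raise ValueError("voxel selection requires fixation trials")
    t, p = stats.ttest_ind(stim, fix, axis=0)
    sig = np.flatnonzero((p < alpha) & (t > 0))
    if len(sig) == 0:
        logger.warning("no voxel passed selection; falling back to top-%d by t",
                       max_n)
        sig = np.arange(train.n_voxels)
    order = sig[np.argsort(t[sig])[::-1]]
    return order[:max_n]


def _make_classifier(C: float = 1.0) -> SVC:
    # fixed regularization: the decoder is a plain linear maximum-margin
    # classifier, no hyperparameter search
    return SVC(kernel="linear", C=C)


def cross_validated_decode(data: TrialDataset, scheme: str = "all_levels",
                           select: int | None = None, alpha: float = 0.05,
                           C: float = 1.0) -> DecodingResult:
    """Leave-one-run-out linear-SVM decoding of radial vs concentric.

    For every fold one run is held out; the classifier is trained on the
    stimulus trials of the remaining runs (all signal levels pooled for
    ``scheme='all_levels'``, only 100%-signal trials for
    ``scheme='train_100_only'``) and tested on the held-out run's stimulus
    trials at every level.  With ``select`` set, t-ranked voxel selection is
    applied per fold on the training runs.  Folds whose training set lacks a
    category are skipped with a log entry.
    """
    if scheme not in ("all_levels", "train_100_only"):
        raise ValueError(f"unknown scheme {scheme!r}")
    runs = data.runs
    if len(runs) < 2:
        raise ValueError("need at least 2 runs")
    stim = data.stimulus_mask()
    lvl_key = np.where(np.isnan(data.signal_level), -1.0, data.signal_level)
    levels = np.unique(lvl_key[stim])
    correct = {lev: 0 for lev in levels}
    total = {lev: 0 for lev in levels}
    cat_rows = []
    fold_acc = []
    n_vox_used = data.n_voxels
    n_skipped = 0
    for test_run in runs:
        is_test = data.run_id == test_run
        train_mask = stim & ~is_test
        if scheme == "train_100_only":
            train_mask &= data.signal_level == 100.0
        y_train = data.labels[train_mask]
        if len(set(y_train)) < 2:
            logger.info("fold %s skipped: training lacks a category", test_run)
            n_skipped += 1
            continue
        if select is not None:
            fold_train = data.subset(~is_test)
            vox = select_voxels(fold_train, max_n=select, alpha=alpha)
            n_vox_used = len(vox)
        else:
            vox = np.arange(data.n_voxels)
        clf = _make_classifier(C)
        clf.fit(data.patterns[np.ix_(train_mask, vox)], y_train.astype(str))
        test_mask = stim & is_test
        X_test = data.patterns[np.ix_(test_mask, vox)]
        pred = clf.predict(X_test)
        truth = data.labels[test_mask].astype(str)
        hits = pred == truth
        fold_acc.append(float(hits.mean()))
        for lev, cat, h in zip(lvl_key[test_mask], truth, hits):
            correct[lev] += int(h)
            total[lev] += 1
            cat_rows.append((lev, cat, int(h)))
    if not fold_acc:
        raise ValueError("all folds skipped; cannot decode")
    if n_skipped:
        logger.info("%d fold(s) skipped", n_skipped)
    levels_arr = np.array(sorted(total))
    acc = np.array([correct[k] / total[k] for k in levels_arr])
    n_arr = np.array([total[k] for k in levels_arr])
    per_cat = (pd.DataFrame(cat_rows, columns=["level", "category", "correct"])
               .groupby(["level", "category"])["correct"].mean().reset_index())
    return DecodingResult(levels_arr, acc, n_arr, fold_acc,
                          n_voxels_used=int(n_vox_used), scheme=scheme,
                          session_label=data.session_label,
                          per_category=per_cat)
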