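"""Synthetic observers, trial patterns, volumes and calibration runs.

Every downstream stage of the analysis (psychometric fitting, MVPA,
searchlight mapping, fMR-metric functions, calibration controls) can be
exercised on data from this module, whose generators encode the statistical
structure the analysis assumes:

* ``ObserverModel`` — a cumulative-Gaussian observer with separate pre- and
  post-training parameters; group-level defaults are derived from the
  published young/older thresholds-at-78% and slopes.
* ``VoxelPatternModel`` — trial patterns in which a radial-vs-concentric
  category signal grows linearly with stimulus signal level and with
  training (gain kappa_post >= kappa_pre), carried by a unit-norm weight
  vector over an informative subset of voxels, in iid Gaussian noise.
  Fixation trials are pure noise.
* ``SyntheticVolumeSpec`` — 4-D volumes at 2.5 x 2.5 x 4 mm / TR 1.5 s with
  HRF-convolved condition responses, category contrast confined to
  informative blobs, plus breath-hold and checkerboard calibration runs.

All generators are seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import stats

from .design import build_run, scan_conditions
from .hrf import convolve_regressor, double_gamma_hrf
from .mvpa import TrialDataset
from .psychometric import BehavioralSession, params_from_threshold_slope

__all__ = [
    "ObserverModel", "VoxelPatternModel", "SyntheticVolumeSpec",
    "simulate_behavior", "simulate_trial_patterns",
    "simulate_volume_timeseries", "simulate_calibration",
    "scan_run_table", "GROUP_NORMS",
]

# published group psychometric summaries (threshold at 78% correct, slope)
GROUP_NORMS = {
    ("young", "pre"): {"threshold": 71.2, "slope": 2.1},
    ("young", "post"): {"threshold": 40.6, "slope": 3.2},
    ("older", "pre"): {"threshold": 81.1, "slope": 1.8},
    ("older", "post"): {"threshold": 43.6, "slope": 3.0},
}


@dataclass
class ObserverModel:
    """Cumulative-Gaussian observer with pre/post-training parameters."""

    mu_pre: float
    sigma_pre: float
    mu_post: float
    sigma_post: float
    guess_rate: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma_pre <= 0 or self.sigma_post <= 0:
            raise ValueError("sigmas must be positive")

    @classmethod
    def from_group_norms(cls, group: str = "young", seed: int | None = None
                         ) -> "ObserverModel":
        """Observer matching a group's published threshold and slope."""
        pre = GROUP_NORMS[(group, "pre")]
        post = GROUP_NORMS[(group, "post")]
        mu0, s0 = params_from_threshold_slope(pre["threshold"], pre["slope"])
        mu1, s1 = params_from_threshold_slope(post["threshold"], post["slope"])
        return cls(mu0, s0, mu1, s1, seed=seed)

    def params(self, session: str) -> tuple[float, float]:
        if session == "pre":
            return self.mu_pre, self.sigma_pre
        if session == "post":
            return self.mu_post, self.sigma_post
        raise ValueError(f"unknown session {session!r}")

    def p_correct(self, signal_level, session: str) -> np.ndarray:
        mu, sigma = self.params(session)
        g = self.guess_rate
        s = np.asarray(signal_level, float)
        return g + (1.0 - g) * stats.norm.cdf((s - mu) / sigma)


def simulate_behavior(observer: ObserverModel, session_design: pd.DataFrame,
                      session: str = "post", setting: str = "lab",
                      seed: int | None = None) -> BehavioralSession:
    """Simulate one session's responses from a design trial table.

    Each trial is answered correctly with probability
    ``gamma + (1 - gamma) * Phi((s - mu) / sigma)``; errors flip the
    response to the opposite category.
    """
    rng = np.random.default_rng(observer.seed if seed is None else seed)
    df = session_design.copy()
    p = observer.p_correct(df["signal_level"].to_numpy(float), session)
    correct = rng.random(len(df)) < p
    other = np.where(df["category"] == "radial", "concentric", "radial")
    df["response"] = np.where(correct, df["category"], other)
    return BehavioralSession(df, session_label=session, setting=setting)


def scan_run_table(group: str = "young", seed: int | None = None,
                   reps: int = 16, **timing) -> pd.DataFrame:
    """Events for one history-balanced scanner run.

    Conditions are signal levels plus fixation; within each level the
    trials are split as evenly as possible between radial and concentric,
    assigned at random.  Columns: onset, duration, condition, signal_level,
    category (NaN for fixation), run metadata in attrs.
    """
    rng = np.random.default_rng(seed)
    run = build_run(scan_conditions(group), reps=reps,
                    seed=int(rng.integers(2**31)), **timing)
    ev = run.to_events()
    ev["signal_level"] = [float(c[1:]) if c != "fixation" else np.nan
                          for c in ev["condition"]]
    cats = np.full(len(ev), None, object)
    for cond in run.conditions:
        if cond == "fixation":
            continue
        idx = np.flatnonzero(ev["condition"] == cond)
        half = len(idx) // 2
        assign = np.array(["radial"] * half + ["concentric"] * (len(idx) - half),
                          object)
        rng.shuffle(assign)
        cats[idx] = assign
    ev["category"] = cats
    # cued-delay response metadata: young adults get a random green/red cue
    # that switches the stimulus-response key mapping; older adults always
    # see green (fixed mapping, hand swapped halfway through the session)
    is_stim = ev["condition"] != "fixation"
    if group == "young":
        cue = np.where(rng.random(len(ev)) < 0.5, "green", "red")
    else:
        cue = np.full(len(ev), "green")
    ev["response_cue"] = np.where(is_stim, cue, "none")
    ev.attrs.update(group=group, n_trials=run.n_trials,
                    n_volumes=run.n_volumes, tr_s=run.tr_s,
                    duration_s=run.duration_s,
                    exactly_balanced=run.exactly_balanced)
    return ev


@dataclass
class VoxelPatternModel:
    """Generative model of trial-wise voxel patterns.

    A trial at signal level ``s`` with category sign ``c`` (+1 concentric,
    -1 radial) has mean pattern ``c * kappa * (s / 100) * w`` on the
    informative voxels plus iid Gaussian noise everywhere; ``kappa`` is the
    session gain (``kappa_post >= kappa_pre`` under learning) and ``w`` a
    unit-norm weight vector whose signs alternate, so the category code is
    multivoxel only (no univariate offset).  Any stimulus trial additionally
    evokes a category-independent response of ``stim_response`` (in noise-sd
    units) in a fraction ``active_fraction`` of voxels — the
    stimulus-vs-fixation activation that drives voxel selection.
    ``saturating=True`` replaces the linear ramp with
    ``Phi((s - mu_sat) / sigma_sat)`` to mimic sigmoid fMR-metric shapes.
    """

    n_voxels: int = 100
    informative_fraction: float = 0.3
    kappa_pre: float = 1.0
    kappa_post: float = 2.0
    noise_sd: float = 1.0
    stim_response: float = 0.5
    active_fraction: float = 1.0
    n_runs: int = 8
    trials_per_condition: int = 16
    hemodynamic_lag_volumes: int = 3
    saturating: bool = False
    sat_mu: float = 40.0
    sat_sigma: float = 15.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.informative_fraction <= 1.0:
            raise ValueError("informative_fraction must lie in [0, 1]")

    def weights(self, rng: np.random.Generator) -> np.ndarray:
        """Unit-norm weight vector supported on the informative voxels.

        Signs alternate so the pattern signal is balanced across voxels and
        carries no univariate (mean-across-voxels) category offset.
        """
        n_inf = max(1, int(round(self.informative_fraction * self.n_voxels)))
        w = np.zeros(self.n_voxels)
        mag = rng.uniform(0.5, 1.0, n_inf)
        sign = np.where(np.arange(n_inf) % 2 == 0, 1.0, -1.0)
        w[:n_inf] = sign * mag
        return w / np.linalg.norm(w)

    def gain(self, session: str) -> float:
        return {"pre": self.kappa_pre, "post": self.kappa_post}[session]

    def signal_ramp(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, float)
        if self.saturating:
            return stats.norm.cdf((s - self.sat_mu) / self.sat_sigma)
        return s / 100.0


def simulate_trial_patterns(model: VoxelPatternModel, session: str = "pre",
                            runs: list[pd.DataFrame] | None = None,
                            group: str = "young",
                            seed: int | None = None) -> TrialDataset:
    """Simulate a multi-run TrialDataset of category-coded voxel patterns.

    ``runs`` may supply explicit event tables (columns condition,
    signal_level, category); by default history-balanced scanner runs for
    ``group`` are generated.  Fixation trials are pure noise.
    """
    rng = np.random.default_rng(model.seed if seed is None else seed)
    w = model.weights(rng)
    kappa = model.gain(session)
    active = np.zeros(model.n_voxels)
    n_act = int(round(model.active_fraction * model.n_voxels))
    active[:n_act] = model.stim_response * model.noise_sd
    if runs is None:
        runs = [scan_run_table(group, seed=int(rng.integers(2**31)),
                               reps=model.trials_per_condition)
                for _ in range(model.n_runs)]
    pats, labels, levels, run_ids = [], [], [], []
    for ridx, ev in enumerate(runs):
        for _, row in ev.iterrows():
            noise = rng.normal(0.0, model.noise_sd, model.n_voxels)
            if row["condition"] == "fixation" or pd.isna(row.get("category")):
                pats.append(noise)
                labels.append("fixation")
                levels.append(np.nan)
            else:
                c = 1.0 if row["category"] == "concentric" else -1.0
                amp = kappa * model.signal_ramp(row["signal_level"])
                pats.append(active + c * amp * w + noise)
                labels.append(row["category"])
                levels.append(float(row["signal_level"]))
            run_ids.append(ridx)
    return TrialDataset(np.array(pats), np.array(labels, object),
                        np.array(levels), np.array(run_ids),
                        session_label=session)


@dataclass
class SyntheticVolumeSpec:
    """Geometry and physiology of a synthetic 4-D acquisition."""

    grid_shape: tuple = (12, 12, 6)
    voxel_size_mm: tuple = (2.5, 2.5, 4.0)
    gray_mask: np.ndarray | None = None         # default: full grid
    informative_blobs: list = field(default_factory=list)
    # each blob: dict(center_mm=(x, y, z), radius_mm=r, gain=g)
    tr_s: float = 1.5
    baseline: float = 100.0
    stim_response_pct: float = 1.0              # stimulus-vs-fixation, % baseline
    noise_sd_pct: float = 0.5                   # % of baseline, iid
    hrf_peak_delay_s: float = 6.0

    def __post_init__(self) -> None:
        if self.gray_mask is None:
            self.gray_mask = np.ones(self.grid_shape, bool)
        if self.gray_mask.shape != tuple(self.grid_shape):
            raise ValueError("gray_mask shape mismatch")

    @property
    def affine(self) -> np.ndarray:
        return np.diag(list(self.voxel_size_mm) + [1.0])

    def voxel_centers_mm(self) -> np.ndarray:
        idx = np.indices(self.grid_shape).reshape(3, -1).T
        return idx * np.asarray(self.voxel_size_mm)

    def blob_mask(self, blob: dict) -> np.ndarray:
        centers = self.voxel_centers_mm()
        d = np.linalg.norm(centers - np.asarray(blob["center_mm"], float),
                           axis=1)
        m = (d <= blob["radius_mm"]).reshape(self.grid_shape)
        if not (m & self.gray_mask).any() or (m & ~self.gray_mask).any():
            raise ValueError("informative blob must lie inside the gray mask")
        return m

    def hrf(self) -> np.ndarray:
        return double_gamma_hrf(self.tr_s, peak_delay_s=self.hrf_peak_delay_s)


def _category_weights(spec: SyntheticVolumeSpec, blob: dict,
                      rng: np.random.Generator) -> np.ndarray:
    m = spec.blob_mask(blob)
    w = np.zeros(spec.grid_shape)
    n = int(m.sum())
    mag = rng.uniform(0.5, 1.0, n)
    sign = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    w[m] = sign * mag
    return w * blob.get("gain", 1.0) / np.linalg.norm(w[m])


def simulate_volume_timeseries(spec: SyntheticVolumeSpec,
                               runs: list[pd.DataFrame],
                               model: VoxelPatternModel | None = None,
                               session: str = "pre",
                               seed: int | None = None):
    """4-D BOLD volumes for event tables, plus the aligned event listing.

    Every gray-matter voxel responds to any stimulus trial (vs fixation)
    with ``stim_response_pct`` of baseline; category contrast, scaled by
    ``kappa * s / 100``, is confined to the informative blobs with
    sign-balanced weights (so a univariate contrast is null by
    construction).  Neural boxcars are convolved with the double-gamma HRF.

    Returns (list of nibabel images, concatenated events with a run column).
    """
    rng = np.random.default_rng(seed)
    model = model or VoxelPatternModel()
    kappa = model.gain(session)
    wmaps = [_category_weights(spec, b, rng) for b in spec.informative_blobs]
    hrf = spec.hrf()
    imgs, ev_frames = [], []
    for ridx, ev in enumerate(runs):
        dur_s = float(ev.attrs.get("duration_s",
                                   ev["onset"].max() + 3.0 + 9.0))
        n_vol = int(round(dur_s / spec.tr_s))
        stim_box = np.zeros(n_vol)
        cat_box = np.zeros(n_vol)
        for _, row in ev.iterrows():
            v0 = int(round(row["onset"] / spec.tr_s))
            v1 = min(v0 + int(round(row["duration"] / spec.tr_s)), n_vol)
            if row["condition"] == "fixation" or pd.isna(row.get("category")):
                continue
            stim_box[v0:v1] = 1.0
            c = 1.0 if row["category"] == "concentric" else -1.0
            cat_box[v0:v1] = c * kappa * model.signal_ramp(row["signal_level"])
        stim_reg = convolve_regressor(stim_box, hrf)
        cat_reg = convolve_regressor(cat_box, hrf)
        base = spec.baseline
        data = np.zeros(spec.grid_shape + (n_vol,), np.float32)
        data += base
        gm = spec.gray_mask[..., None]
        data += gm * (base * spec.stim_response_pct / 100.0) * stim_reg
        for w in wmaps:
            data += (base / 100.0) * w[..., None] * cat_reg
        data += rng.normal(0.0, base * spec.noise_sd_pct / 100.0,
                           data.shape).astype(np.float32)
        imgs.append(nib.Nifti1Image(data, spec.affine))
        evr = ev.copy()
        evr["run"] = ridx
        ev_frames.append(evr)
    return imgs, pd.concat(ev_frames, ignore_index=True)


def simulate_calibration(spec: SyntheticVolumeSpec, age_group: str = "young",
                         reactivity: dict | None = None,
                         n_breath_holds: int = 6,
                         n_checkerboard_trials: int = 10,
                         task_amplitude_pct: float = 1.5,
                         seed: int | None = None) -> dict:
    """Breath-hold and checkerboard calibration runs with known ground truth.

    The breath-hold run has 10-s hypercapnia blocks whose per-voxel response
    amplitude is ``2% x reactivity``; by default reactivity is 1.0 for young
    and 0.5 for older adults, uniform over the volume.  The checkerboard run
    has brief 8 Hz-reversal stimulation events whose HRF peaks at the spec's
    ``hrf_peak_delay_s`` with amplitude ``task_amplitude_pct``.
    """
    rng = np.random.default_rng(seed)
    if reactivity is None:
        reactivity = {"young": 1.0, "older": 0.5}
    react = float(reactivity[age_group])
    hrf = spec.hrf()
    base = spec.baseline
    out = {"reactivity_factor": react}

    # breath-hold run: 10-s blocks, 45-s spacing, 20-s lead-in
    bh_onsets = 20.0 + 45.0 * np.arange(n_breath_holds)
    dur_s = bh_onsets[-1] + 45.0
    n_vol = int(round(dur_s / spec.tr_s))
    box = np.zeros(n_vol)
    for t0 in bh_onsets:
        v0 = int(round(t0 / spec.tr_s))
        box[v0:v0 + int(round(10.0 / spec.tr_s))] = 1.0
    reg = convolve_regressor(box, hrf)
    reg = reg / reg.max()                   # unit peak: amp is the measured peak
    data = np.full(spec.grid_shape + (n_vol,), base, np.float32)
    amp = base * 2.0 * react / 100.0        # 2% peak BOLD at unit reactivity
    data += spec.gray_mask[..., None] * amp * reg
    data += rng.normal(0.0, base * spec.noise_sd_pct / 100.0,
                       data.shape).astype(np.float32)
    out["breath_hold"] = (
        nib.Nifti1Image(data, spec.affine),
        pd.DataFrame({"onset": bh_onsets, "duration": 10.0,
                      "condition": "breath_hold"}),
    )

    # checkerboard run: brief events, 24-s spacing
    cb_onsets = 20.0 + 24.0 * np.arange(n_checkerboard_trials)
    dur_s = cb_onsets[-1] + 24.0
    n_vol = int(round(dur_s / spec.tr_s))
    box = np.zeros(n_vol)
    for t0 in cb_onsets:
        box[int(round(t0 / spec.tr_s))] = 1.0
    reg = convolve_regressor(box, hrf)
    reg = reg / reg.max()
    data = np.full(spec.grid_shape + (n_vol,), base, np.float32)
    data += spec.gray_mask[..., None] * (base * task_amplitude_pct / 100.0) * reg
    data += rng.normal(0.0, base * spec.noise_sd_pct / 100.0,
                       data.shape).astype(np.float32)
    out["checkerboard"] = (
        nib.Nifti1Image(data, spec.affine),
        pd.DataFrame({"onset": cb_onsets, "duration": 0.2,
                      "condition": "checkerboard", "reversal_hz": 8.0}),
    )
    # task-evoked %BOLD map: the same vascular reactivity scales the
    # task-evoked and hypercapnia-evoked signals, which is exactly what the
    # breath-hold normalization is meant to divide out
    task = np.full(spec.grid_shape, task_amplitude_pct * react)
    task += rng.normal(0.0, 0.01 * task_amplitude_pct, spec.grid_shape)
    out["task_pct"] = task
    out["hrf_peak_s"] = spec.hrf_peak_delay_s
    out["task_amplitude_pct"] = task_amplitude_pct
    return out
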