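"""fMR-metric functions: psychometric-style fits to classifier accuracy.

The decoder's per-signal-level accuracy is treated exactly like behavioral
proportion-correct data and fitted with the same cumulative Gaussian
(gamma = 0.5).  The resulting *fMR-metric function*'s slope indexes neural
sensitivity; its post-minus-pre difference (the slope index, with a
bootstrap 95% CI) quantifies learning-dependent change per region of
interest.  A label-permutation control verifies that significant fits do
not arise from chance correlations in the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mvpa import TrialDataset, cross_validated_decode, DecodingResult
from .psychometric import CumulativeGaussianModel, PsychometricResults

__all__ = ["AccuracyCurve", "fit_fmr_metric", "slope_index_with_ci",
           "permutation_control"]


@dataclass
class AccuracyCurve:
    """Per-signal-level classifier accuracy for one ROI and session."""

    levels: np.ndarray
    accuracy: np.ndarray
    n_trials: np.ndarray
    roi_label: str = ""
    session_label: str = ""

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, float)
        self.accuracy = np.asarray(self.accuracy, float)
        self.n_trials = np.asarray(self.n_trials, int)
        if len(np.unique(self.levels)) != len(self.levels):
            raise ValueError("one accuracy value per level required")
        if (self.n_trials <= 0).any():
            raise ValueError("n_trials must be positive")

    @classmethod
    def from_decoding(cls, result: DecodingResult, roi_label: str = ""
                      ) -> "AccuracyCurve":
        return cls(result.levels, result.accuracy, result.n_trials,
                   roi_label=roi_label, session_label=result.session_label)

    def n_correct(self) -> np.ndarray:
        return np.round(self.accuracy * self.n_trials).astype(int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "roi": self.roi_label, "session": self.session_label,
            "signal_level": self.levels, "accuracy": self.accuracy,
            "n_trials": self.n_trials,
        })


def fit_fmr_metric(curve: AccuracyCurve,
                   guess_rate: float = 0.5) -> PsychometricResults:
    """Cumulative-Gaussian fit to a classifier accuracy curve.

    Shares the behavioral fitting path end to end: per-level (correct,
    total) counts enter the same maximum-likelihood model, and goodness is
    the significance of the data-fit correlation.  A flat (chance-level)
    curve yields a flagged non-significant fit, not an exception.
    """
    model = CumulativeGaussianModel(curve.levels, curve.n_correct(),
                                    curve.n_trials, guess_rate=guess_rate)
    res = model.fit()
    if not res.is_significant():
        warnings.warn(
            f"fMR-metric fit not significant (roi={curve.roi_label!r}, "
            f"session={curve.session_label!r})")
    return res


def slope_index_with_ci(pre: AccuracyCurve, post: AccuracyCurve,
                        n_boot: int = 2000, seed: int | None = None,
                        alpha: float = 0.05):
    """Slope index (post - pre) with a percentile bootstrap CI.

    Trials are resampled within level for both sessions independently and
    both curves refit per iteration.  Returns ``(index, (lo, hi))``; the
    index is NaN when either point fit is non-significant, since a slope
    from an uninformative curve has no interpretation.
    """
    fit_pre = fit_fmr_metric(pre)
    fit_post = fit_fmr_metric(post)
    if not (fit_pre.is_significant() and fit_post.is_significant()):
        warnings.warn("slope index undefined: non-significant component fit")
        return float("nan"), (float("nan"), float("nan"))
    index = fit_post.slope - fit_pre.slope
    rng = np.random.default_rng(seed)
    diffs = []
    for _ in range(n_boot):
        diff_parts = []
        for curve, fit in ((pre, fit_pre), (post, fit_post)):
            n = curve.n_trials
            k = rng.binomial(n, np.clip(curve.accuracy, 0.0, 1.0))
            m = CumulativeGaussianModel(curve.levels, k, n,
                                        guess_rate=fit.guess_rate)
            diff_parts.append(m.fit(start=(fit.mu, fit.sigma)).slope)
        diffs.append(diff_parts[1] - diff_parts[0])
    lo, hi = np.percentile(diffs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(index), (float(lo), float(hi))


def _permute_labels_within_run(data: TrialDataset,
                               rng: np.random.Generator) -> TrialDataset:
    """Shuffle category labels among stimulus trials, separately per run.

    Run structure and per-run label counts are preserved; fixation trials
    are untouched.  Signal levels stay attached to trials, so the permuted
    data retain the condition marginals while destroying the
    pattern-category correspondence.
    """
    labels = data.labels.copy()
    stim = data.stimulus_mask()
    for r in data.runs:
        idx = np.flatnonzero(stim & (data.run_id == r))
        labels[idx] = labels[rng.permutation(idx)]
    out = TrialDataset(data.patterns, labels, data.signal_level, data.run_id,
                       session_label=data.session_label,
                       voxel_ids=data.voxel_ids,
                       voxel_coords=data.voxel_coords,
                       grid_shape=data.grid_shape,
                       motion_flag=data.motion_flag)
    return out


def permutation_control(data: TrialDataset, n_perm: int = 200,
                        seed: int | None = None, alpha: float = 0.05,
                        select: int | None = None,
                        scheme: str = "all_levels") -> dict:
    """Rate of significant fMR-metric fits under label permutation.

    Each permutation shuffles the pattern-label correspondence within run,
    re-runs the full decode, and fits the resulting accuracy curve; with no
    real correspondence the fraction of significant fits should be near the
    nominal alpha.  Returns the rate, the per-permutation overall
    accuracies, and the unshuffled fit for reference.
    """
    rng = np.random.default_rng(seed)
    n_sig = 0
    accs = []
    for _ in range(n_perm):
        perm = _permute_labels_within_run(data, rng)
        res = cross_validated_decode(perm, scheme=scheme, select=select)
        accs.append(res.overall_accuracy)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_fmr_metric(AccuracyCurve.from_decoding(res))
        n_sig += int(fit.is_significant(alpha))
    true_res = cross_validated_decode(data, scheme=scheme, select=select)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        true_fit = fit_fmr_metric(AccuracyCurve.from_decoding(true_res))
    return {
        "significant_fit_rate": n_sig / n_perm if n_perm else float("nan"),
        "n_perm": n_perm,
        "alpha": alpha,
        "permuted_overall_accuracy": accs,
        "unshuffled_fit_significant": true_fit.is_significant(alpha),
        "unshuffled_overall_accuracy": true_res.overall_accuracy,
    }
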