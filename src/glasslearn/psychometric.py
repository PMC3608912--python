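"""Cumulative-Gaussian psychometric fitting.

The observer model is

    P(s) = gamma + (1 - gamma) * Phi((s - mu) / sigma)

where ``s`` is the stimulus signal level in percent, ``gamma`` the lower
asymptote (0.5 for two-alternative proportion-correct data, 0 for a signed
"proportion concentric" axis), ``mu`` the location and ``sigma`` the spread
of the underlying Gaussian.  Parameters are estimated by maximising the
binomial log-likelihood of per-level correct counts.

Two derived quantities are the interface the learning analysis works with:

* ``threshold(p)`` — the signal level at which the fitted function reaches a
  criterion performance ``p`` (78% correct by convention here):
  ``mu + sigma * Phi^{-1}((p - gamma) / (1 - gamma))``.
* ``slope`` — the steepness of the function at its inflection point ``mu``,
  scaled to percent-correct change per percent signal times 100:
  ``100 * (1 - gamma) / (sigma * sqrt(2 * pi))``.  The difference of slopes
  between post- and pre-training sessions (the *slope index*) is the
  learning measure; positive values mean enhanced sensitivity.

Goodness of fit is the significance of the Pearson correlation between the
observed per-level proportions and the fitted curve; fits whose correlation
is not significant are flagged rather than raised.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CumulativeGaussianModel",
    "PsychometricResults",
    "BehavioralSession",
    "slope_index",
    "criterion_bias",
    "params_from_threshold_slope",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)


def params_from_threshold_slope(
    threshold: float,
    slope: float,
    guess_rate: float = 0.5,
    criterion: float = 0.78,
) -> tuple[float, float]:
    """Invert the threshold/slope formulas to recover (mu, sigma).

    Useful for parameterising a generative observer from published group
    threshold-at-criterion and slope values.
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    sigma = 100.0 * (1.0 - guess_rate) / (slope * _SQRT_2PI)
    z = stats.norm.ppf((criterion - guess_rate) / (1.0 - guess_rate))
    mu = threshold - sigma * z
    return mu, sigma


@dataclass
class BehavioralSession:
    """Per-trial radial/concentric discrimination data for one session.

    ``trials`` columns: ``signal_level`` (percent, 0-100), ``category``
    (true category, 'radial'/'concentric'), ``response`` (same coding).
    """

    trials: pd.DataFrame
    session_label: str = "pre"
    setting: str = "lab"

    def __post_init__(self) -> None:
        t = self.trials
        if len(t) == 0:
            raise ValueError("session has no trials")
        s = np.asarray(t["signal_level"], float)
        if (s < 0).any() or (s > 100).any():
            raise ValueError("signal levels must lie in [0, 100]")

    def performance(self) -> pd.DataFrame:
        """Aggregate to per-level (n_correct, n_total)."""
        t = self.trials
        correct = (t["category"] == t["response"]).astype(int)
        g = t.assign(correct=correct).groupby("signal_level")["correct"]
        out = g.agg(n_correct="sum", n_total="count").reset_index()
        return out

    def proportion_concentric(self) -> pd.DataFrame:
        t = self.trials
        conc = (t["response"] == "concentric").astype(int)
        g = t.assign(conc=conc).groupby("signal_level")["conc"]
        return g.agg(n_concentric="sum", n_total="count").reset_index()


class CumulativeGaussianModel:
    """Maximum-likelihood cumulative-Gaussian model of binomial choice data.

    Parameters
    ----------
    levels : array-like
        Stimulus signal levels in percent, one entry per condition.
    n_correct, n_total : array-like
        Correct counts and totals per level (or "concentric" counts when
        fitting the signed-axis variant with ``guess_rate=0``).
    guess_rate : float
        Lower asymptote gamma, fixed (not estimated).  0.5 for
        proportion-correct data, 0.0 for proportion-concentric data.
    """

    def __init__(self, levels, n_correct, n_total, guess_rate: float = 0.5):
        self.levels = np.asarray(levels, dtype=float)
        self.n_correct = np.asarray(n_correct, dtype=float)
        self.n_total = np.asarray(n_total, dtype=float)
        if not (self.levels.shape == self.n_correct.shape == self.n_total.shape):
            raise ValueError("levels, n_correct, n_total must have equal length")
        if len(np.unique(self.levels)) < 4:
            raise ValueError("need at least 4 distinct signal levels")
        if (self.n_total <= 0).any():
            raise ValueError("n_total must be positive at every level")
        if (self.n_correct < 0).any() or (self.n_correct > self.n_total).any():
            raise ValueError("n_correct must lie in [0, n_total]")
        if not 0.0 <= guess_rate < 1.0:
            raise ValueError("guess_rate must lie in [0, 1)")
        self.guess_rate = float(guess_rate)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_session(
        cls, session: BehavioralSession, guess_rate: float = 0.5
    ) -> "CumulativeGaussianModel":
        perf = session.performance()
        return cls(
            perf["signal_level"], perf["n_correct"], perf["n_total"], guess_rate
        )

    @classmethod
    def from_trials(
        cls,
        trials: pd.DataFrame,
        guess_rate: float = 0.5,
        scoring: str = "correct",
    ) -> "CumulativeGaussianModel":
        """Build from a trial table (columns signal_level, category, response).

        ``scoring='correct'`` counts category==response per level (gamma
        typically 0.5); ``scoring='concentric'`` counts concentric responses
        on a signed axis where radial trials get negative signal levels
        (gamma typically 0).
        """
        if scoring == "correct":
            sess = BehavioralSession(trials)
            return cls.from_session(sess, guess_rate)
        if scoring == "concentric":
            t = trials.copy()
            sign = np.where(t["category"] == "concentric", 1.0, -1.0)
            t["signed_level"] = sign * np.asarray(t["signal_level"], float)
            conc = (t["response"] == "concentric").astype(int)
            g = t.assign(conc=conc).groupby("signed_level")["conc"]
            agg = g.agg(n="sum", total="count").reset_index()
            return cls(agg["signed_level"], agg["n"], agg["total"], guess_rate)
        raise ValueError(f"unknown scoring {scoring!r}")

    # -- likelihood --------------------------------------------------------

    def predict(self, params, levels=None) -> np.ndarray:
        mu, sigma = params
        s = self.levels if levels is None else np.asarray(levels, float)
        g = self.guess_rate
        return g + (1.0 - g) * stats.norm.cdf((s - mu) / sigma)

    def loglike(self, params) -> float:
        p = np.clip(self.predict(params), 1e-9, 1.0 - 1e-9)
        k, n = self.n_correct, self.n_total
        return float(np.sum(k * np.log(p) + (n - k) * np.log(1.0 - p)))

    def _nll(self, theta) -> float:
        return -self.loglike(theta)

    def _nll_grad(self, theta) -> tuple[float, np.ndarray]:
        """Negative log-likelihood and its analytic gradient in (mu, sigma)."""
        mu, sigma = theta
        g = self.guess_rate
        z = (self.levels - mu) / sigma
        p = np.clip(g + (1.0 - g) * stats.norm.cdf(z), 1e-9, 1.0 - 1e-9)
        k, n = self.n_correct, self.n_total
        nll = -float(np.sum(k * np.log(p) + (n - k) * np.log(1.0 - p)))
        resid = k / p - (n - k) / (1.0 - p)
        phi = (1.0 - g) * stats.norm.pdf(z)
        d_mu = float(np.sum(resid * phi / sigma))        # -dLL/dmu
        d_sigma = float(np.sum(resid * phi * z / sigma))  # -dLL/dsigma
        return nll, np.array([d_mu, d_sigma])

    def fit(self, start=None, n_starts: int | None = None) -> "PsychometricResults":
        """Maximise the binomial likelihood from multiple starting points.

        Starts cover the level range for mu and a log-spaced grid for sigma;
        ties are broken by likelihood then by smaller sigma.  Degenerate
        (flat or reversed) data yield a converged but non-significant fit
        rather than an exception.
        """
        lo, hi = self.levels.min(), self.levels.max()
        span = max(hi - lo, 1.0)
        # plausible sigma range given the sampling grid: spreads narrower
        # than half the closest level spacing are unresolvable, spreads
        # beyond 3x the sampled range unidentifiable
        spacing = np.min(np.diff(np.sort(np.unique(self.levels))))
        bounds = [(lo - 2.0 * span, hi + 2.0 * span),
                  (max(1e-2, 0.5 * spacing), 3.0 * span)]
        if start is not None:
            starts = [tuple(start)]
        else:
            mus = np.quantile(self.levels, [0.25, 0.5, 0.75])
            sigmas = [2.0, 6.0, 18.0, 54.0]
            starts = [(m, s) for m in mus for s in sigmas]
            if n_starts is not None:
                starts = starts[:n_starts]
        best = None
        for theta0 in starts:
            res = optimize.minimize(
                self._nll_grad, theta0, method="L-BFGS-B", jac=True,
                bounds=bounds
            )
            if not np.isfinite(res.fun):
                continue
            key = (round(res.fun, 6), res.x[1])
            if best is None or key < best[0]:
                best = (key, res)
        if best is None:  # pragma: no cover - pathological
            raise RuntimeError("all optimisation starts failed")
        res = best[1]
        return PsychometricResults(self, float(res.x[0]), float(res.x[1]),
                                   loglike=-float(res.fun))


@dataclass
class PsychometricResults:
    """Fitted cumulative-Gaussian parameters and derived sensitivity measures."""

    model: CumulativeGaussianModel
    mu: float
    sigma: float
    loglike: float = np.nan
    _ci: dict = field(default_factory=dict, repr=False)

    # -- derived quantities ------------------------------------------------

    @property
    def guess_rate(self) -> float:
        return self.model.guess_rate

    def threshold(self, criterion: float = 0.78) -> float:
        """Signal level at which the fitted curve reaches ``criterion``."""
        g = self.guess_rate
        if not g < criterion < 1.0:
            raise ValueError("criterion must lie in (guess_rate, 1)")
        z = stats.norm.ppf((criterion - g) / (1.0 - g))
        return self.mu + self.sigma * z

    @property
    def threshold_78(self) -> float:
        return self.threshold(0.78)

    @property
    def slope(self) -> float:
        """Steepness at mu: 100 * (1 - gamma) / (sigma * sqrt(2 pi))."""
        return 100.0 * (1.0 - self.guess_rate) / (self.sigma * _SQRT_2PI)

    def predict(self, levels=None) -> np.ndarray:
        return self.model.predict((self.mu, self.sigma), levels)

    # -- goodness ----------------------------------------------------------

    @property
    def observed_proportions(self) -> np.ndarray:
        return self.model.n_correct / self.model.n_total

    def goodness(self) -> tuple[float, float]:
        """Pearson r between data and fit, and its p-value.

        Constant data or a flat fitted curve give (0, 1): the fit is valid
        but carries no evidence of a dependence on signal level.
        """
        obs = self.observed_proportions
        fit = self.predict()
        if np.std(obs) < 1e-12 or np.std(fit) < 1e-12:
            return 0.0, 1.0
        r, p = stats.pearsonr(obs, fit)
        return float(r), float(p)

    @property
    def goodness_r(self) -> float:
        return self.goodness()[0]

    @property
    def goodness_p(self) -> float:
        return self.goodness()[1]

    def is_significant(self, alpha: float = 0.05) -> bool:
        r, p = self.goodness()
        return bool(p < alpha and r > 0)

    @property
    def at_boundary(self) -> bool:
        """True for all-correct / all-wrong data where location is unidentified."""
        obs = self.observed_proportions
        return bool(np.all(obs == obs[0]))

    # -- bootstrap ---------------------------------------------------------

    def bootstrap_ci(
        self,
        n_iter: int = 2000,
        seed: int | None = None,
        alpha: float = 0.05,
        criterion: float = 0.78,
    ) -> dict:
        """Percentile bootstrap intervals for threshold and slope.

        Trials are resampled with replacement within each signal level
        (equivalently, per-level correct counts are redrawn binomially at the
        observed proportion) and the model refit from the point estimate.
        """
        key = (n_iter, seed, alpha, criterion)
        if key in self._ci:
            return self._ci[key]
        rng = np.random.default_rng(seed)
        m = self.model
        phat = m.n_correct / m.n_total
        n = m.n_total.astype(int)
        thr, slp = [], []
        n_failed = 0
        for _ in range(n_iter):
            k = rng.binomial(n, phat)
            bm = CumulativeGaussianModel(m.levels, k, n, m.guess_rate)
            try:
                r = bm.fit(start=(self.mu, self.sigma))
                thr.append(r.threshold(criterion))
                slp.append(r.slope)
            except Exception:
                n_failed += 1
        if n_iter and n_failed > 0.05 * n_iter:
            warnings.warn(
                f"{n_failed}/{n_iter} bootstrap refits failed; "
                "intervals may be wider than nominal"
            )
        qs = [100 * alpha / 2, 100 * (1 - alpha / 2)]
        out = {
            "threshold": tuple(np.percentile(thr, qs)),
            "slope": tuple(np.percentile(slp, qs)),
            "n_failed": n_failed,
        }
        self._ci[key] = out
        return out

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        r, p = self.goodness()
        lines = [
            "Cumulative Gaussian psychometric fit",
            "=" * 44,
            f"{'mu (location, % signal)':34s}{self.mu:10.3f}",
            f"{'sigma (spread, % signal)':34s}{self.sigma:10.3f}",
            f"{'guess rate (fixed)':34s}{self.guess_rate:10.3f}",
            f"{'threshold @ 78% correct':34s}{self.threshold_78:10.3f}",
            f"{'slope (x100 dP/ds at mu)':34s}{self.slope:10.3f}",
            f"{'log-likelihood':34s}{self.loglike:10.3f}",
            f"{'goodness r':34s}{r:10.3f}",
            f"{'goodness p':34s}{p:10.4g}",
            f"{'n levels':34s}{len(self.model.levels):10d}",
            f"{'n trials':34s}{int(self.model.n_total.sum()):10d}",
        ]
        if self.at_boundary:
            lines.append("Note: data at performance boundary; location weakly identified.")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        r, p = self.goodness()
        return {
            "mu": self.mu,
            "sigma": self.sigma,
            "guess_rate": self.guess_rate,
            "threshold_78": self.threshold_78,
            "slope": self.slope,
            "loglike": self.loglike,
            "goodness_r": r,
            "goodness_p": p,
            "significant": self.is_significant(),
        }

    def plot(self, ax=None, **kwargs):  # pragma: no cover - visual helper
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.model.levels
        grid = np.linspace(s.min(), s.max(), 200)
        ax.plot(s, self.observed_proportions, "o", **kwargs)
        ax.plot(grid, self.predict(grid), "-")
        ax.set_xlabel("signal level (%)")
        ax.set_ylabel("proportion correct")
        return ax


def slope_index(pre: PsychometricResults, post: PsychometricResults) -> float:
    """Post-minus-pre slope; positive means enhanced sensitivity after training.

    Returns NaN (with a warning) when either component fit is not a
    significant description of its data.
    """
    if not (pre.is_significant() and post.is_significant()):
        warnings.warn("slope index undefined: component fit not significant")
        return float("nan")
    return post.slope - pre.slope


def criterion_bias(session: BehavioralSession, levels=(0.0, 100.0)) -> dict:
    """Deviation of %concentric responses from 50% chance at the anchor levels.

    At 0% signal there is no correct answer, so any deviation from 50% is
    response bias; at 100% the same statistic mixes bias and (near-ceiling)
    sensitivity.  Levels absent from the session are omitted with a notice.
    """
    pc = session.proportion_concentric().set_index("signal_level")
    out = {}
    for lev in levels:
        if lev not in pc.index:
            warnings.warn(f"signal level {lev} absent from session; omitted")
            continue
        row = pc.loc[lev]
        out[float(lev)] = 100.0 * row["n_concentric"] / row["n_total"] - 50.0
    return out
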