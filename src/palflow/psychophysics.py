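"""Psychometric analysis: up/down judgments, cumulative-normal fits, PSE.

Heading estimates are reduced to a binary "lifting up" vs "sinking in"
judgment by the sign of the world-vertical component; the proportion of
upward answers as a function of the vertical heading angle is fitted with

    p(a) = lambda + (1 - 2*lambda) * Phi((a - pse) / sigma),

a cumulative normal with free but equal asymptotes (a single shared lapse
parameter lambda in [0, 0.1]).  The 50% point of the fitted curve -- by the
equal-asymptote symmetry, the Gaussian mean itself -- is the point of
subjective equality (PSE): the vertical heading angle perceived as motion
parallel to the ground.  Shifts of the PSE between distorted and undistorted
conditions (delta-PSE) quantify the induced heading illusion.

The fit maximizes the binomial likelihood with bounded L-BFGS-B from
multiple starts.  Fractional response counts are allowed: an estimate that
is exactly ground-parallel counts half up, half down, and enters the
likelihood as a fractional success.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .heading import HeadingEstimate

__all__ = [
    "PsychometricFit",
    "FitError",
    "heading_to_answer",
    "aggregate_responses",
    "fit_psychometric",
    "delta_pse",
    "ttest_one_sample",
]

_MIN_SPREAD = 1e-3
_MAX_LAPSE = 0.1


class FitError(RuntimeError):
    """Raised for non-identifiable psychometric data."""


@dataclass(frozen=True)
class PsychometricFit:
    pse: float          # deg, 50% point of the fitted curve
    spread: float       # deg, sigma of the cumulative normal
    lapse: float        # shared asymptote parameter
    log_likelihood: float
    converged: bool
    n_trials: float

    def predict(self, angles) -> np.ndarray:
        z = (np.asarray(angles, dtype=float) - self.pse) / self.spread
        return self.lapse + (1 - 2 * self.lapse) * stats.norm.cdf(z)


def heading_to_answer(est: HeadingEstimate, scenario=None) -> float:
    """Upward-answer fraction for one heading estimate: 1 (up), 0 (down),
    or 0.5 when the estimate is exactly parallel to the ground (counted for
    both categories)."""
    vertical = est.world_vertical
    if scenario is not None:
        vertical = est.elevation - scenario.gaze_depression
    if vertical > 1e-12:
        return 1.0
    if vertical < -1e-12:
        return 0.0
    return 0.5


def aggregate_responses(trials: Iterable[tuple[float, float]]) -> pd.DataFrame:
    """Sum per-trial up-fractions into a response table.

    ``trials`` yields (vertical angle deg, up-fraction) pairs; the result has
    one row per distinct angle, sorted, with columns angle, n_trials, n_up.
    """
    frame = pd.DataFrame(list(trials), columns=["angle", "up"])
    if frame.empty:
        return pd.DataFrame(columns=["angle", "n_trials", "n_up"])
    bad = frame[(frame["up"] < 0) | (frame["up"] > 1)]
    if len(bad):
        raise ValueError(f"up-fractions outside [0, 1]: {bad['up'].tolist()}")
    table = (frame.groupby("angle")["up"].agg(n_trials="count", n_up="sum")
             .reset_index())
    table["n_trials"] = table["n_trials"].astype(float)
    return table


def _nll(params: np.ndarray, angles, n_trials, n_up) -> float:
    pse, spread, lapse = params
    p = lapse + (1 - 2 * lapse) * stats.norm.cdf((angles - pse) / spread)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -float(np.sum(n_up * np.log(p) + (n_trials - n_up) * np.log1p(-p)))


def fit_psychometric(table: pd.DataFrame) -> PsychometricFit:
    """Maximum-likelihood cumulative-normal fit with equal asymptotes.

    Requires at least three distinct angles and both response categories
    present.  Multi-start bounded optimization; the start grid includes the
    empirical 50% crossing.
    """
    angles = np.asarray(table["angle"], dtype=float)
    n_trials = np.asarray(table["n_trials"], dtype=float)
    n_up = np.asarray(table["n_up"], dtype=float)
    if len(np.unique(angles)) < 3:
        raise FitError("need at least 3 distinct angles to fit")
    if n_up.sum() <= 0 or n_up.sum() >= n_trials.sum():
        raise FitError("all responses in one category; PSE not identifiable")
    rng_span = float(angles.max() - angles.min())
    prop = n_up / n_trials
    # Empirical 50% crossing by linear interpolation of the proportions.
    crossings = [angles[0] if prop[0] >= 0.5 else angles[-1]]
    for i in range(len(angles) - 1):
        lo, hi = prop[i], prop[i + 1]
        if (lo - 0.5) * (hi - 0.5) <= 0 and lo != hi:
            crossings.append(angles[i] + (0.5 - lo) / (hi - lo)
                             * (angles[i + 1] - angles[i]))
    bounds = [(angles.min() - rng_span, angles.max() + rng_span),
              (_MIN_SPREAD, 10 * max(rng_span, 1.0)),
              (0.0, _MAX_LAPSE)]
    starts = []
    for pse0 in {round(float(c), 6) for c in crossings} | {float(np.median(angles))}:
        for spread0 in (0.1 * max(rng_span, 1.0), 0.5, 2.0):
            starts.append((pse0, spread0, 0.01))
    best = None
    for start in starts:
        res = optimize.minimize(
            _nll, np.asarray(start), args=(angles, n_trials, n_up),
            method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    pse, spread, lapse = best.x
    return PsychometricFit(pse=float(pse), spread=float(spread),
                           lapse=float(lapse), log_likelihood=-float(best.fun),
                           converged=bool(best.success),
                           n_trials=float(n_trials.sum()))


def delta_pse(fit: PsychometricFit, reference: PsychometricFit) -> float:
    """PSE shift of a distorted condition relative to the undistorted one."""
    return fit.pse - reference.pse


def ttest_one_sample(values: Sequence[float]) -> tuple[float, float]:
    """Classical one-sample t-test of the mean against zero (two-sided)."""
    arr = np.asarray(values, dtype=float)
    if len(arr) < 2:
        raise ValueError("need at least two values")
    if np.var(arr, ddof=1) == 0:
        raise ValueError("zero sample variance: t statistic undefined")
    t, p = stats.ttest_1samp(arr, 0.0)
    return float(t), float(p)
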