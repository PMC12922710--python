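"""Adaptive staircase, trial curation, binning, and Weibull threshold fits.

Acuity is measured in a four-alternative forced-choice Tumbling-E task.
Stimulus size (stroke width, arcsec) follows an adaptive staircase: from
48 arcsec, size shrinks by a factor 1.75 after each correct response until
the first error; thereafter a two-down/one-up rule applies multiplicative
steps of 0.82 (after two consecutive correct) and 1.5 (after any error).
Every sixth trial is a motivational catch trial at 48 arcsec that does not
advance the staircase.

Pooled, curated trials are binned (smallest width in [5, 11] arcsec giving
at least seven non-empty bins) and fit by maximum likelihood with a Weibull
psychometric function

    Psi(x) = gamma + (1 - gamma - lambda) * (1 - exp(-(x / alpha)^beta))

with guess rate gamma = 0.25 (4AFC) and lapse rate lambda in [0, 0.05].
The acuity threshold is the size where Psi = 0.625, halfway between guess
rate and perfect performance.  Confidence intervals come from a trial-level
bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import BinningError, DegenerateInputError, FitError

GUESS_RATE = 0.25
CRITERION = 0.625
START_SIZE = 48.0
DESCEND_FACTOR = 1.75
UP_FACTOR = 1.5
DOWN_FACTOR = 0.82
MOTIVATIONAL_EVERY = 6
LAPSE_MAX = 0.05


def weibull(x, alpha, beta, gamma=GUESS_RATE, lam=0.0):
    """Weibull psychometric function of stimulus size."""
    x = np.asarray(x, float)
    out = gamma + (1.0 - gamma - lam) * (1.0 - np.exp(-((x / alpha) ** beta)))
    return float(out) if out.ndim == 0 else out


def weibull_threshold(alpha, beta, gamma=GUESS_RATE, lam=0.0,
                      criterion=CRITERION):
    """Size where the fitted curve crosses the criterion (closed form)."""
    q = (criterion - gamma) / (1.0 - gamma - lam)
    if not 0 < q < 1:
        raise FitError("criterion unreachable for these parameters")
    return float(alpha * (-np.log1p(-q)) ** (1.0 / beta))


# ---------------------------------------------------------------------------
# staircase

@dataclass
class StaircaseState:
    """State of the adaptive staircase after ``trial_index`` trials."""

    current_size: float = START_SIZE
    phase: str = "descend"            # 'descend' (pre-reversal) or 'main'
    consecutive_correct: int = 0
    trial_index: int = 0              # trials completed
    history: list = field(default_factory=list)  # (size, correct, motivational)

    @property
    def next_is_motivational(self) -> bool:
        return (self.trial_index + 1) % MOTIVATIONAL_EVERY == 0

    @property
    def next_size(self) -> float:
        """Size to present on the upcoming trial."""
        return START_SIZE if self.next_is_motivational else self.current_size


def staircase_next(state: StaircaseState, correct: bool,
                   min_size: float = 1.0) -> StaircaseState:
    """Record the response to the upcoming trial and step the staircase.

    Motivational trials (every sixth, at 48 arcsec) are recorded but leave
    the staircase size and the two-down counter untouched.
    """
    if state.current_size <= 0:
        raise DegenerateInputError("staircase size must be positive")
    motivational = state.next_is_motivational
    shown = state.next_size
    size = state.current_size
    phase = state.phase
    streak = state.consecutive_correct
    if not motivational:
        if phase == "descend":
            if correct:
                size /= DESCEND_FACTOR
            else:
                phase = "main"
                size *= UP_FACTOR
                streak = 0
        else:
            if correct:
                streak += 1
                if streak >= 2:
                    size *= DOWN_FACTOR
                    streak = 0
            else:
                size *= UP_FACTOR
                streak = 0
        size = max(size, min_size)
    return StaircaseState(
        current_size=size, phase=phase, consecutive_correct=streak,
        trial_index=state.trial_index + 1,
        history=state.history + [(shown, bool(correct), motivational)])


def simulate_observer(size: float, alpha: float, beta: float,
                      lam: float, rng: np.random.Generator,
                      gamma: float = GUESS_RATE):
    """One 4AFC response from a Weibull observer.

    Returns ``(correct, reported_offset)`` where ``reported_offset`` is 0
    for the true orientation and 1-3 for one of the three foils.
    """
    if size <= 0:
        raise DegenerateInputError("size must be positive")
    p = weibull(size, alpha, beta, gamma, lam)
    correct = bool(rng.random() < p)
    report = 0 if correct else int(rng.integers(1, 4))
    return correct, report


def run_staircase(n_trials: int, respond, min_size: float = 1.0) -> pd.DataFrame:
    """Drive a staircase for ``n_trials`` trials.

    ``respond(size, trial_index)`` returns a bool (correct).  Returns the
    trial log as a DataFrame with columns size, correct, motivational.
    """
    state = StaircaseState()
    for i in range(n_trials):
        correct = respond(state.next_size, i + 1)
        state = staircase_next(state, correct, min_size=min_size)
    return pd.DataFrame(state.history,
                        columns=["size", "correct", "motivational"])


# ---------------------------------------------------------------------------
# curation

def curate(trials: pd.DataFrame, flag_columns=("microsaccade", "blink",
                                               "delivery_failed")) -> tuple:
    """Remove trials with motion or delivery artifacts.

    Returns ``(kept, exclusion_log)``: the log has one row per excluded
    trial with its triggering rule(s).  Raises if nothing survives.
    """
    flags = [c for c in flag_columns if c in trials.columns]
    bad = trials[flags].any(axis=1) if flags else pd.Series(False, index=trials.index)
    excluded = trials[bad].copy()
    reasons = []
    for _, row in excluded.iterrows():
        reasons.append(",".join(c for c in flags if row[c]))
    excluded["reason"] = reasons
    kept = trials[~bad].copy()
    if len(kept) == 0:
        raise DegenerateInputError("curation removed every trial")
    return kept, excluded


# ---------------------------------------------------------------------------
# binning and fitting

@dataclass
class Bins:
    edges: np.ndarray
    center: np.ndarray   # mean stimulus size of members, arcsec
    n: np.ndarray        # trials per bin
    k: np.ndarray        # correct per bin
    width: float
    fallback: bool = False


def bin_trials(sizes: np.ndarray, correct: np.ndarray,
               width_range=(5.0, 11.0), min_bins: int = 7,
               width_step: float = 0.5) -> Bins:
    """Bin pooled trials by stimulus size.

    The smallest width in ``width_range`` yielding at least ``min_bins``
    non-empty bins is chosen.  If none qualifies, quantile bins are used
    and flagged as a fallback.
    """
    sizes = np.asarray(sizes, float)
    correct = np.asarray(correct, bool)
    if len(sizes) < min_bins:
        raise BinningError("too few trials to form bins")
    lo = sizes.min()
    for width in np.arange(width_range[0], width_range[1] + 1e-9, width_step):
        edges = np.arange(lo - 1e-9, sizes.max() + width, width)
        which = np.digitize(sizes, edges) - 1
        occupied = np.unique(which)
        if len(occupied) >= min_bins:
            return _fill_bins(sizes, correct, edges, which, width)
    # fallback: quantile bins
    qs = np.linspace(0, 1, min_bins + 1)
    edges = np.unique(np.quantile(sizes, qs))
    if len(edges) - 1 < min_bins:
        raise BinningError("cannot form enough non-empty bins")
    which = np.clip(np.digitize(sizes, edges) - 1, 0, len(edges) - 2)
    b = _fill_bins(sizes, correct, edges, which, float(np.diff(edges).mean()))
    b.fallback = True
    return b


def _fill_bins(sizes, correct, edges, which, width) -> Bins:
    occupied = np.unique(which)
    center = np.array([sizes[which == i].mean() for i in occupied])
    n = np.array([(which == i).sum() for i in occupied])
    k = np.array([correct[which == i].sum() for i in occupied])
    order = np.argsort(center)
    return Bins(edges=np.asarray(edges), center=center[order], n=n[order],
                k=k[order], width=float(width))


@dataclass
class PsychometricFit:
    alpha: float
    beta: float
    lam: float
    gamma: float
    threshold: float           # size at the 62.5% criterion, arcsec
    bins: Bins
    nll: float
    ci: tuple | None = None    # bootstrap CI on the threshold

    def predict(self, x):
        return weibull(x, self.alpha, self.beta, self.gamma, self.lam)


def _fit_ml(center, n, k, gamma, x0=None):
    center = np.asarray(center, float)
    n = np.asarray(n, float)
    k = np.asarray(k, float)

    def nll(theta):
        la, lb, lam = theta
        p = weibull(center, np.exp(la), np.exp(lb), gamma, lam)
        p = np.clip(p, 1e-9, 1 - 1e-9)
        return -(k * np.log(p) + (n - k) * np.log1p(-p)).sum()

    if x0 is None:
        # initial alpha: first size where observed rate crosses ~62.5%
        rate = k / np.maximum(n, 1)
        above = center[rate >= CRITERION]
        a0 = float(above.min()) if len(above) else float(np.median(center))
        x0 = (np.log(max(a0, 1e-3)), np.log(3.0), 0.01)
    res = minimize(nll, x0, method="L-BFGS-B",
                   bounds=[(np.log(1e-2), np.log(1e3)),
                           (np.log(0.2), np.log(20.0)),
                           (0.0, LAPSE_MAX)])
    return res


def fit_psychometric(bins: Bins, gamma: float = GUESS_RATE,
                     n_boot: int = 0, rng=None,
                     sizes=None, correct=None) -> PsychometricFit:
    """Maximum-likelihood Weibull fit to binned 4AFC data.

    ``n_boot`` > 0 adds a trial-level bootstrap 95% CI on the threshold
    (requires the raw ``sizes``/``correct`` vectors; bin edges are reused).
    """
    if np.all(bins.k == bins.n):
        raise FitError("all responses correct: psychometric fit is degenerate")
    if np.all(bins.k / np.maximum(bins.n, 1) <= gamma):
        raise FitError("performance never exceeds chance: degenerate fit")
    res = _fit_ml(bins.center, bins.n, bins.k, gamma)
    if not res.success and not np.isfinite(res.fun):
        raise FitError(f"psychometric fit did not converge: {res.message}")
    la, lb, lam = res.x
    alpha, beta = float(np.exp(la)), float(np.exp(lb))
    thr = weibull_threshold(alpha, beta, gamma, lam)
    fit = PsychometricFit(alpha, beta, float(lam), gamma, thr, bins,
                          float(res.fun))
    if n_boot and sizes is not None:
        rng = rng or np.random.default_rng()
        sizes = np.asarray(sizes, float)
        correct = np.asarray(correct, bool)
        edges = bins.edges
        thrs = []
        m = len(sizes)
        for _ in range(n_boot):
            idx = rng.integers(0, m, m)
            s, c = sizes[idx], correct[idx]
            which = np.clip(np.digitize(s, edges) - 1, 0, len(edges) - 2)
            b = _fill_bins(s, c, edges, which, bins.width)
            try:
                r = _fit_ml(b.center, b.n, b.k, gamma, x0=res.x)
                thrs.append(weibull_threshold(float(np.exp(r.x[0])),
                                              float(np.exp(r.x[1])),
                                              gamma, float(r.x[2])))
            except (FitError, FloatingPointError):
                continue
        if thrs:
            fit.ci = (float(np.percentile(thrs, 2.5)),
                      float(np.percentile(thrs, 97.5)))
    return fit
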