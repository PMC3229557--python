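"""Maximum-likelihood 2AFC psychometric fitting and inversion.

Fits a Weibull (default) or log-logistic psychometric function to
orientation-discrimination data with the guess rate fixed at 0.5 and the
lapse rate bounded in [0, 0.06], then inverts the fitted function to find
the contrasts producing target correctness levels (the 60%/90% calibration
used to pick the low- and high-contrast stimuli).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

GUESS_RATE_2AFC = 0.5
MAX_LAPSE_RATE = 0.06
FAMILIES = ("weibull", "logistic")

_SLOPE_BOUNDS = (0.05, 50.0)


@dataclass(frozen=True)
class PsychometricDataset:
    """Per-contrast counts of presented and correct 2AFC trials."""

    contrast_levels: tuple[float, ...]
    n_presented: tuple[int, ...]
    n_correct: tuple[int, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.contrast_levels, dtype=float)
        n = np.asarray(self.n_presented)
        k = np.asarray(self.n_correct)
        if not (len(c) == len(n) == len(k)):
            raise ValueError("contrast_levels, n_presented and n_correct must align")
        if len(c) < 2 or len(np.unique(c)) < 2:
            raise ValueError("need at least two distinct contrast levels")
        if np.any(np.diff(c) <= 0):
            raise ValueError("contrast levels must be strictly increasing")
        if np.any(c <= 0) or np.any(c > 1):
            raise ValueError("contrast levels must lie in (0, 1]")
        if np.any(n < 1):
            raise ValueError("n_presented must be >= 1 at every level")
        if np.any(k < 0) or np.any(k > n):
            raise ValueError("n_correct must satisfy 0 <= n_correct <= n_presented")

    @property
    def proportions(self) -> np.ndarray:
        return np.asarray(self.n_correct) / np.asarray(self.n_presented)


@dataclass(frozen=True)
class PsychometricFit:
    """A fitted (or user-specified) 2AFC psychometric function."""

    family: str = "weibull"
    threshold: float = 0.1
    slope: float = 3.0
    guess_rate: float = GUESS_RATE_2AFC
    lapse_rate: float = 0.0
    log_likelihood: float = float("nan")
    converged: bool = True
    message: str = ""

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.converged:
            if not self.threshold > 0:
                raise ValueError("threshold must be positive")
            if not self.slope > 0:
                raise ValueError("slope must be positive")
        if not 0.0 <= self.lapse_rate <= MAX_LAPSE_RATE:
            raise ValueError(f"lapse_rate must be in [0, {MAX_LAPSE_RATE}]")

    def predict(self, contrast) -> np.ndarray:
        """Probability correct at the given contrast(s)."""
        return _predict(
            np.asarray(contrast, dtype=float),
            self.family,
            self.threshold,
            self.slope,
            self.guess_rate,
            self.lapse_rate,
        )


def _predict(c, family, threshold, slope, guess, lapse):
    c = np.asarray(c, dtype=float)
    if family == "weibull":
        core = 1.0 - np.exp(-((c / threshold) ** slope))
    elif family == "logistic":
        # logistic in log-contrast; P(threshold) is the midpoint
        core = 1.0 / (1.0 + np.exp(-slope * (np.log(c) - np.log(threshold))))
    else:  # pragma: no cover - guarded by dataclass validation
        raise ValueError(f"unknown family {family!r}")
    return guess + (1.0 - guess - lapse) * core


def simulate_2afc_data(
    true_fit: PsychometricFit,
    levels,
    n_per_level: int,
    seed: int,
) -> PsychometricDataset:
    """Draw binomial 2AFC counts from a known psychometric function."""
    levels = np.asarray(levels, dtype=float)
    if np.any(levels <= 0) or np.any(levels > 1):
        raise ValueError("contrast levels must lie in (0, 1]")
    if n_per_level < 1:
        raise ValueError("n_per_level must be >= 1")
    rng = np.random.default_rng(seed)
    p = true_fit.predict(levels)
    k = rng.binomial(n_per_level, p)
    return PsychometricDataset(
        contrast_levels=tuple(levels),
        n_presented=tuple([int(n_per_level)] * len(levels)),
        n_correct=tuple(int(x) for x in k),
    )


def _negative_log_likelihood(params, c, n, k, family, guess):
    threshold, slope, lapse = params
    p = _predict(c, family, threshold, slope, guess, lapse)
    p = np.clip(p, 1e-10, 1 - 1e-10)
    return -float(np.sum(k * np.log(p) + (n - k) * np.log(1.0 - p)))


def fit_psychometric(data: PsychometricDataset, family: str = "weibull") -> PsychometricFit:
    """Binomial maximum-likelihood fit with fixed 0.5 guess rate.

    Runs five deterministic multi-starts of L-BFGS-B; ties are broken by the
    highest log-likelihood, then the lowest threshold.  Degenerate data
    (all-correct, or no level above chance) yield a flagged non-convergence
    result rather than a silent fit.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}, got {family!r}")
    c = np.asarray(data.contrast_levels, dtype=float)
    n = np.asarray(data.n_presented, dtype=float)
    k = np.asarray(data.n_correct, dtype=float)
    prop = k / n

    if np.all(prop >= 1 - 1e-12):
        return PsychometricFit(
            family=family,
            threshold=float("nan"),
            slope=float("nan"),
            log_likelihood=float("nan"),
            converged=False,
            message="degenerate data: all responses correct at every level",
        )
    if np.max(prop) <= GUESS_RATE_2AFC:
        return PsychometricFit(
            family=family,
            threshold=float("nan"),
            slope=float("nan"),
            log_likelihood=float("nan"),
            converged=False,
            message="degenerate data: no level performs above the 2AFC guess rate",
        )

    lo, hi = float(c.min()), float(c.max())
    bounds = [(lo / 100.0, hi * 10.0), _SLOPE_BOUNDS, (0.0, MAX_LAPSE_RATE)]
    # deterministic multi-starts spanning the stimulus range
    starts = [
        (np.exp(np.log(lo) + f * (np.log(hi) - np.log(lo))), s, 0.01)
        for f, s in ((0.2, 2.0), (0.4, 3.0), (0.5, 1.0), (0.6, 3.0), (0.8, 2.0))
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            _negative_log_likelihood,
            x0=np.asarray(x0),
            args=(c, n, k, family, GUESS_RATE_2AFC),
            method="L-BFGS-B",
            bounds=bounds,
        )
        key = (-res.fun, -res.x[0])  # max LL, then min threshold
        if best is None or key > best[0]:
            best = (key, res)
    res = best[1]
    threshold, slope, lapse = (float(v) for v in res.x)
    return PsychometricFit(
        family=family,
        threshold=threshold,
        slope=slope,
        lapse_rate=lapse,
        log_likelihood=-float(res.fun),
        converged=bool(res.success),
        message=str(res.message),
    )


def contrast_at_correctness(fit: PsychometricFit, target: float, tol: float = 1e-8) -> float:
    """Invert the psychometric function: the contrast with predicted correctness ``target``.

    Monotone inversion by bracketed root finding to ``tol`` in contrast.
    """
    if not fit.converged or not np.isfinite(fit.threshold):
        raise ValueError(f"cannot invert a non-converged fit: {fit.message}")
    lo_bound = fit.guess_rate
    hi_bound = 1.0 - fit.lapse_rate
    if not lo_bound < target < hi_bound:
        raise ValueError(
            f"target {target} outside the attainable range "
            f"({lo_bound}, {hi_bound}) of this fit"
        )
    lo = fit.threshold * 1e-9
    hi = fit.threshold
    while fit.predict(hi) < target:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover - unreachable for valid fits
            raise RuntimeError("failed to bracket the target correctness")
    return float(
        optimize.brentq(lambda x: float(fit.predict(x)) - target, lo, hi, xtol=tol)
    )


# ---------------------------------------------------------------------------
# CSV / JSON interchange
# ---------------------------------------------------------------------------

def dataset_to_frame(data: PsychometricDataset):
    import pandas as pd

    return pd.DataFrame(
        {
            "contrast": data.contrast_levels,
            "n_presented": data.n_presented,
            "n_correct": data.n_correct,
        }
    )


def read_dataset_csv(path) -> PsychometricDataset:
    import pandas as pd

    frame = pd.read_csv(path)
    return PsychometricDataset(
        contrast_levels=tuple(float(x) for x in frame["contrast"]),
        n_presented=tuple(int(x) for x in frame["n_presented"]),
        n_correct=tuple(int(x) for x in frame["n_correct"]),
    )


def fit_to_dict(fit: PsychometricFit) -> dict:
    return {
        "family": fit.family,
        "threshold": fit.threshold,
        "slope": fit.slope,
        "guess_rate": fit.guess_rate,
        "lapse_rate": fit.lapse_rate,
        "log_likelihood": fit.log_likelihood,
        "converged": fit.converged,
        "message": fit.message,
    }
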