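"""Five-regressor GLM: design construction, AR(1)-prewhitened fitting, stats.

The design has two event regressors (stimulus presentation, liquid
delivery) and three parametric modulators (predicted value at the stimulus,
prediction error at delivery, binary reward at delivery), all convolved with
a canonical double-gamma HRF, plus a discrete-cosine high-pass basis
(128 s cutoff) and an intercept.  Fitting is two-pass: OLS, lag-1 residual
autocorrelation, prewhitening, refit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .task_design import SessionDesign

TASK_COLUMNS = (
    "stimulus_event",
    "delivery_event",
    "v_modulator",
    "delta_modulator",
    "reward_modulator",
)

HRF_PEAK_DELAY_S = 6.0
HRF_UNDERSHOOT_DELAY_S = 16.0
HRF_DISPERSION = 1.0
HRF_UNDERSHOOT_RATIO = 1.0 / 6.0
HRF_LENGTH_S = 32.0

DEFAULT_HIGHPASS_CUTOFF_S = 128.0
DEFAULT_OVERSAMPLING = 20

CENTERING_POLICIES = ("center_scale", "center", "none")


def hrf_curve(t) -> np.ndarray:
    """Unnormalized canonical double-gamma HRF evaluated at times ``t`` (s)."""
    t = np.asarray(t, dtype=float)
    peak = stats.gamma.pdf(t, HRF_PEAK_DELAY_S, scale=HRF_DISPERSION)
    undershoot = stats.gamma.pdf(t, HRF_UNDERSHOOT_DELAY_S, scale=HRF_DISPERSION)
    return peak - HRF_UNDERSHOOT_RATIO * undershoot


def _fine_kernel(dt: float) -> np.ndarray:
    t = np.arange(0.0, HRF_LENGTH_S, dt)
    k = hrf_curve(t)
    return k / k.max()


def hrf_kernel(tr: float, oversampling: int = DEFAULT_OVERSAMPLING) -> np.ndarray:
    """Double-gamma HRF sampled on a fine grid then decimated to ``tr``.

    Normalized to unit peak on the fine grid; length ceil(32 / tr) samples.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    fine = _fine_kernel(tr / oversampling)
    return fine[::oversampling]


def highpass_basis(
    n_volumes: int, tr: float, cutoff_s: float = DEFAULT_HIGHPASS_CUTOFF_S
) -> np.ndarray:
    """Orthonormal discrete-cosine basis for periods >= ``cutoff_s``.

    Excludes the constant term (carried by the intercept).  The number of
    columns is floor(2 * n_volumes * tr / cutoff_s).
    """
    if n_volumes < 4:
        raise ValueError("n_volumes must be >= 4")
    if cutoff_s < 2 * tr:
        raise ValueError(f"cutoff {cutoff_s} s is shorter than 2 * tr = {2 * tr} s")
    n_basis = int(np.floor(2.0 * n_volumes * tr / cutoff_s))
    t = np.arange(n_volumes)
    cols = [
        np.sqrt(2.0 / n_volumes) * np.cos(np.pi * k * (2 * t + 1) / (2.0 * n_volumes))
        for k in range(1, n_basis + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_volumes, 0))


@dataclass
class DesignMatrix:
    """GLM design: five task regressors, high-pass basis, intercept."""

    tr: float
    n_volumes: int
    values: np.ndarray
    column_names: list[str]

    def __post_init__(self) -> None:
        if self.values.shape != (self.n_volumes, len(self.column_names)):
            raise ValueError("values shape inconsistent with n_volumes / column_names")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.column_names.index(name)]

    @property
    def task_values(self) -> np.ndarray:
        idx = [self.column_names.index(c) for c in TASK_COLUMNS]
        return self.values[:, idx]

    @property
    def highpass_values(self) -> np.ndarray:
        idx = [i for i, c in enumerate(self.column_names) if c.startswith("highpass_")]
        return self.values[:, idx] if idx else np.empty((self.n_volumes, 0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.column_names)


def _impulse_heights(trace, centering_policy: str):
    v = np.asarray(trace.v, dtype=float)
    delta = np.asarray(trace.delta, dtype=float)
    r = np.asarray(trace.r, dtype=float)
    heights = {"v_modulator": v, "delta_modulator": delta, "reward_modulator": r}
    if centering_policy == "none":
        return heights
    out = {}
    for name, h in heights.items():
        centered = h - h.mean()
        sd = centered.std()
        if sd < 1e-12:
            raise ValueError(
                f"{name} is constant across trials; the centered regressor would be "
                "all-zero and the design matrix singular"
            )
        if centering_policy == "center_scale":
            centered = centered / sd
        out[name] = centered
    return out


def build_design_matrix(
    design: SessionDesign,
    trace,
    centering_policy: str = "center_scale",
    *,
    orthogonalize: bool = False,
    cutoff_s: float = DEFAULT_HIGHPASS_CUTOFF_S,
    oversampling: int = DEFAULT_OVERSAMPLING,
) -> DesignMatrix:
    """Build the five-regressor design for one session.

    Events are unit impulses at their onsets; modulator impulse heights are
    the per-trial model quantities, mean-centered within session (and scaled
    to unit SD under the default ``center_scale`` policy, which makes raw
    betas comparable across model variants).  All impulse trains are
    convolved with the canonical HRF on a fine grid and sampled at volume
    acquisition times.  With ``orthogonalize=True`` each modulator is
    residualized against the event regressors and the modulators entered
    before it (order: value, prediction error, reward).
    """
    if centering_policy not in CENTERING_POLICIES:
        raise ValueError(f"centering_policy must be one of {CENTERING_POLICIES}")
    n_trials = len(design.trials)
    if len(trace) != n_trials:
        raise ValueError(
            f"trace has {len(trace)} trials but design has {n_trials}; "
            "pass the per-session slice of the trace"
        )
    sessions = np.unique(np.asarray(trace.session_index))
    if len(sessions) != 1 or int(sessions[0]) != design.session_index:
        raise ValueError("trace sessions do not match the design session")

    dt = design.tr / oversampling
    n_fine = design.n_volumes * oversampling
    kernel = _fine_kernel(dt)
    stim_idx = np.array(
        [int(round(t.stimulus_onset / dt)) for t in design.trials]
    )
    deliv_idx = np.array(
        [int(round(t.delivery_onset / dt)) for t in design.trials]
    )
    if stim_idx.max() >= n_fine or deliv_idx.max() >= n_fine:
        raise ValueError("trial onsets fall outside the scan duration")

    heights = _impulse_heights(trace, centering_policy)
    trains = np.zeros((n_fine, len(TASK_COLUMNS)))
    trains[stim_idx, 0] = 1.0
    trains[deliv_idx, 1] = 1.0
    np.add.at(trains[:, 2], stim_idx, heights["v_modulator"])
    np.add.at(trains[:, 3], deliv_idx, heights["delta_modulator"])
    np.add.at(trains[:, 4], deliv_idx, heights["reward_modulator"])

    convolved = sps.fftconvolve(trains, kernel[:, None], mode="full", axes=0)[:n_fine]
    task = convolved[::oversampling]

    for j, name in enumerate(TASK_COLUMNS):
        if np.max(np.abs(task[:, j])) < 1e-12:
            raise ValueError(f"design column {name} is all-zero")

    if orthogonalize:
        events = task[:, :2]
        base = [events[:, 0], events[:, 1], np.ones(design.n_volumes)]
        for j in (2, 3, 4):
            x = np.column_stack(base)
            beta, *_ = np.linalg.lstsq(x, task[:, j], rcond=None)
            task[:, j] = task[:, j] - x @ beta
            base.append(task[:, j])

    hp = highpass_basis(design.n_volumes, design.tr, cutoff_s)
    intercept = np.ones((design.n_volumes, 1))
    values = np.hstack([task, hp, intercept])
    names = list(TASK_COLUMNS) + [f"highpass_{k + 1}" for k in range(hp.shape[1])] + [
        "intercept"
    ]
    return DesignMatrix(
        tr=design.tr, n_volumes=design.n_volumes, values=values, column_names=names
    )


@dataclass
class GLMResult:
    """Whitened-model estimates for one voxel and one design."""

    column_names: list[str]
    betas: np.ndarray
    beta_se: np.ndarray
    t_stats: np.ndarray
    ar1_estimate: float
    residual_variance: float
    df_resid: int

    def beta(self, name: str) -> float:
        return float(self.betas[self.column_names.index(name)])

    def t_stat(self, name: str) -> float:
        return float(self.t_stats[self.column_names.index(name)])

    @property
    def effect_size_delta(self) -> float:
        """The fitted coefficient of the prediction-error regressor."""
        return self.beta("delta_modulator")


def _check_rank(x: np.ndarray, names: list[str]) -> None:
    _, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    bad = diag < 1e-10 * max(diag.max(), 1.0)
    if bad.any():
        culprits = [names[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {culprits}")


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return beta, y - x @ beta


def _whiten(arr: np.ndarray, rho: float) -> np.ndarray:
    out = arr.astype(float).copy()
    out[0] = arr[0] * np.sqrt(1.0 - rho**2)
    out[1:] = arr[1:] - rho * arr[:-1]
    return out


def fit_glm(ts, x: DesignMatrix, prewhiten: bool = True) -> GLMResult:
    """Two-pass AR(1)-prewhitened GLM fit.

    OLS first; the AR(1) coefficient is the small-sample-bias-corrected lag-1
    autocorrelation of the OLS residuals (Yule-Walker); both sides are then
    prewhitened and refitted.  With ``prewhiten=False`` the plain OLS
    estimates are returned.
    """
    y = np.asarray(getattr(ts, "values", ts), dtype=float)
    mat = x.values
    n, p = mat.shape
    if y.shape != (n,):
        raise ValueError(f"time series has length {y.shape}, design expects {n}")
    if n <= p:
        raise ValueError(f"not enough volumes ({n}) for {p} regressors")
    _check_rank(mat, x.column_names)

    if prewhiten:
        _, resid = _ols(mat, y)
        denom = float(resid @ resid)
        if denom < 1e-20:
            rho = 0.0
        else:
            rho = float(resid[1:] @ resid[:-1] / denom)
            # small-sample bias correction: residual autocorrelation is biased
            # low by ~(1 + 3 rho)/n (Marriott-Pope) plus ~p/n from projection
            rho = rho + (1.0 + 3.0 * rho) / n + p / n
        rho = float(np.clip(rho, -0.95, 0.95))
    else:
        rho = 0.0

    yw = _whiten(y, rho)
    xw = _whiten(mat, rho)
    beta, resid_w = _ols(xw, yw)
    df = n - p
    sigma2 = float(resid_w @ resid_w) / df
    xtx_inv = np.linalg.inv(xw.T @ xw)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    return GLMResult(
        column_names=list(x.column_names),
        betas=beta,
        beta_se=se,
        t_stats=t,
        ar1_estimate=rho,
        residual_variance=sigma2,
        df_resid=df,
    )


def _paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    diff = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if np.allclose(diff, diff[0]):
        # zero-variance differences: degenerate paired t
        if np.isclose(diff[0], 0.0):
            return 0.0, 1.0
        return float(np.sign(diff[0]) * np.inf), 0.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ModelComparison:
    """Paired WITH-vs-WITHOUT effect-size tests."""

    per_alpha: pd.DataFrame
    per_session: pd.DataFrame
    sessions: tuple[int, ...]
    session_alpha: float


REQUIRED_EFFECT_COLUMNS = {"subject", "session", "alpha", "variant", "effect_size"}


def compare_models(
    effects: pd.DataFrame,
    sessions=(1, 2, 3),
    alpha_values=None,
    session_alpha: float | None = None,
) -> ModelComparison:
    """Paired tests of the prediction-error effect size between variants.

    Per learning rate: each subject's effect size is averaged over the
    selected sessions, then WITH vs WITHOUT is compared by a two-tailed
    paired t-test.  Per session (at ``session_alpha``): the same test on
    single-session effect sizes.
    """
    missing = REQUIRED_EFFECT_COLUMNS - set(effects.columns)
    if missing:
        raise ValueError(f"effects table is missing columns: {sorted(missing)}")
    sessions = tuple(int(s) for s in sessions)
    if alpha_values is None:
        alpha_values = sorted(effects["alpha"].unique())
    if session_alpha is None:
        session_alpha = min(alpha_values, key=lambda a: abs(a - 0.05))

    sub = effects[effects["session"].isin(sessions)]
    n_subjects = sub["subject"].nunique()
    if n_subjects < 2:
        raise ValueError("paired model comparison requires at least 2 subjects")

    rows = []
    for alpha in alpha_values:
        cell = sub[np.isclose(sub["alpha"], alpha)]
        pivot = cell.pivot_table(
            index="subject", columns="variant", values="effect_size", aggfunc="mean"
        )
        for variant in ("WITH", "WITHOUT"):
            if variant not in pivot.columns or pivot[variant].isna().any():
                raise ValueError(
                    f"missing {variant} effect sizes for some subjects at alpha={alpha}"
                )
        w = pivot["WITH"].to_numpy()
        wo = pivot["WITHOUT"].to_numpy()
        t, pval = _paired_t(w, wo)
        rows.append(
            {
                "alpha": alpha,
                "n_subjects": len(pivot),
                "mean_with": w.mean(),
                "sem_with": w.std(ddof=1) / np.sqrt(len(w)),
                "mean_without": wo.mean(),
                "sem_without": wo.std(ddof=1) / np.sqrt(len(wo)),
                "mean_diff": (w - wo).mean(),
                "t": t,
                "p": pval,
                "df": len(pivot) - 1,
            }
        )
    per_alpha = pd.DataFrame(rows)

    rows = []
    cell = effects[np.isclose(effects["alpha"], session_alpha)]
    for sess in sorted(effects["session"].unique()):
        pivot = cell[cell["session"] == sess].pivot_table(
            index="subject", columns="variant", values="effect_size"
        )
        w = pivot["WITH"].to_numpy()
        wo = pivot["WITHOUT"].to_numpy()
        t, pval = _paired_t(w, wo)
        rows.append(
            {
                "session": int(sess),
                "n_subjects": len(pivot),
                "mean_diff": (w - wo).mean(),
                "sem_diff": (w - wo).std(ddof=1) / np.sqrt(len(w)),
                "t": t,
                "p": pval,
                "df": len(pivot) - 1,
            }
        )
    per_session = pd.DataFrame(rows)
    return ModelComparison(
        per_alpha=per_alpha,
        per_session=per_session,
        sessions=sessions,
        session_alpha=float(session_alpha),
    )


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up: boolean rejection flags at level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("p_values is empty")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    passed = np.flatnonzero(ranked <= (np.arange(1, m + 1) / m) * q)
    if passed.size == 0:
        return np.zeros(m, dtype=bool)
    threshold = ranked[passed[-1]]
    return p <= threshold
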