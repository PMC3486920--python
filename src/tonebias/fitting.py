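"""Model fitting by mean-squared-error minimization, and JND estimation.

Every fit follows the same convention: the model produces a per-trial
probability of responding "tone 1 higher" via the normal CDF, and its
parameters are chosen to minimize the mean squared distance between the
probability vector and the 0/1 response vector. MSE (not likelihood) is
the objective throughout.

Models
------
* linear-nonlinear (LN) history kernel: P_t = Phi(a*l1_t + b*l2_t
  + sum_k c_k*l1_{t-k} + sum_k d_k*l2_{t-k} + e*lnfbar_t), where lnfbar_t
  is the running log-geometric mean of all tones presented before trial t
  in the block. 2 + 2K + 1 coefficients, no intercept (9 at K = 3).
* implicit-memory observer (sigma, gamma) per block.
* Bayesian observer (sigma1, sigma2) per block, prior fixed to the
  design's stimulus marginal.
* single-slope probit psychometric curve, from which the JND follows as
  the percent frequency difference at 79.4% correct (the 3-down-1-up
  asymptote).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr  # fast vectorized normal CDF

from .observers import imm_noise_sd
from .simulate import Block

#: Phi^{-1}(0.794): z-score of the staircase's asymptotic percent correct.
Z_CRITERION = float(stats.norm.ppf(0.794))

_SQRT2PI = math.sqrt(2.0 * math.pi)


def jnd_pct_from_slope(slope_a: float) -> float:
    """JND in percent frequency difference from a probit slope (per ln-ratio)."""
    if slope_a <= 0:
        raise ValueError("slope must be positive")
    return 100.0 * math.expm1(Z_CRITERION / slope_a)


def naive_jnd_pct(sigma: float) -> float:
    """Analytic 79.4%-correct threshold of a naive observer with noise SD sigma."""
    return 100.0 * math.expm1(Z_CRITERION * sigma)


# ---------------------------------------------------------------------------
# probit-MSE core


def _probit_mse(theta: np.ndarray, X: np.ndarray, r: np.ndarray) -> float:
    return float(np.mean((ndtr(X @ theta) - r) ** 2))


def _probit_mse_grad(
    theta: np.ndarray, X: np.ndarray, r: np.ndarray
) -> np.ndarray:
    xb = X @ theta
    resid = ndtr(xb) - r
    pdf = np.exp(-0.5 * xb * xb) / _SQRT2PI
    return (2.0 / len(r)) * (X.T @ (resid * pdf))


def _fit_probit_mse(
    X: np.ndarray,
    r: np.ndarray,
    n_starts: int = 10,
    seed: int = 0,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Minimize the probit MSE from multiple seeded starts; return best."""
    rng = np.random.default_rng(seed)
    p = X.shape[1]
    starts = [np.zeros(p) if x0 is None else np.asarray(x0, dtype=float)]
    starts += [rng.normal(0.0, 0.05, size=p) for _ in range(max(n_starts - 1, 0))]
    best_theta, best_mse = starts[0], np.inf
    for start in starts:
        res = optimize.minimize(
            _probit_mse,
            start,
            args=(X, r),
            jac=_probit_mse_grad,
            method="L-BFGS-B",
        )
        if res.fun < best_mse:
            best_theta, best_mse = res.x, float(res.fun)
    return best_theta, best_mse


# ---------------------------------------------------------------------------
# LN history-kernel model


@dataclass
class LNFit:
    """Fitted LN history-kernel coefficients plus fit quality."""

    K: int
    coef: np.ndarray  # ordered [a, b, c_1..c_K, d_1..d_K, e]
    mse: float
    n_rows: int
    ci68: np.ndarray | None = None  # shape (2, n_params): 16th/84th pct
    column_names: list[str] = field(default_factory=list)

    @property
    def coef_l1_now(self) -> float:
        return float(self.coef[0])

    @property
    def coef_l2_now(self) -> float:
        return float(self.coef[1])

    @property
    def coef_l1_past(self) -> np.ndarray:
        return self.coef[2 : 2 + self.K]

    @property
    def coef_l2_past(self) -> np.ndarray:
        return self.coef[2 + self.K : 2 + 2 * self.K]

    @property
    def coef_global(self) -> float:
        return float(self.coef[-1])

    def to_dict(self) -> dict:
        out = {
            "K": self.K,
            "coef": dict(zip(self.column_names, map(float, self.coef))),
            "mse": self.mse,
            "n_rows": self.n_rows,
        }
        if self.ci68 is not None:
            out["ci68"] = {
                name: [float(lo), float(hi)]
                for name, lo, hi in zip(
                    self.column_names, self.ci68[0], self.ci68[1]
                )
            }
        return out


def _column_names(K: int) -> list[str]:
    return (
        ["l1_now", "l2_now"]
        + [f"l1_lag{k}" for k in range(1, K + 1)]
        + [f"l2_lag{k}" for k in range(1, K + 1)]
        + ["ln_global_mean"]
    )


def ln_design_matrix(
    trials: pd.DataFrame, K: int = 3, center: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build (X, r, block_ids) for the LN model from a trial table.

    Response rows are analysis-eligible trials with at least K within-block
    predecessors; earlier trials still contribute as lagged regressors and
    to the running log-geometric mean (computed over both tones of all
    strictly previous trials of the same block).
    """
    rows_X, rows_r, rows_b = [], [], []
    for block_id, g in trials.groupby("block_id", sort=True):
        g = g.sort_values("trial_index")
        l1 = np.log(g["f1_hz"].to_numpy(dtype=float))
        l2 = np.log(g["f2_hz"].to_numpy(dtype=float))
        r = g["response_first_higher"].to_numpy(dtype=float)
        eligible = g["analysis_eligible"].to_numpy(dtype=bool)
        n = len(g)
        # running mean of all tone log-frequencies of trials 1..t-1
        cum = np.cumsum(l1 + l2)
        fbar = np.full(n, np.nan)
        idx = np.arange(1, n)
        fbar[1:] = cum[:-1] / (2.0 * idx)
        for t in range(n):
            if not eligible[t] or t < K or t < 1:
                continue
            lags1 = [l1[t - k] for k in range(1, K + 1)]
            lags2 = [l2[t - k] for k in range(1, K + 1)]
            rows_X.append([l1[t], l2[t], *lags1, *lags2, fbar[t]])
            rows_r.append(r[t])
            rows_b.append(block_id)
    X = np.asarray(rows_X, dtype=float)
    r = np.asarray(rows_r, dtype=float)
    b = np.asarray(rows_b)
    if center and len(X):
        X = X - X.mean(axis=0)
    return X, r, b


def fit_ln_model(
    trials: pd.DataFrame,
    K: int = 3,
    n_boot: int = 1000,
    seed: int = 0,
    n_starts: int = 10,
    center: bool = False,
) -> LNFit:
    """Fit the LN history-kernel model by probit-MSE minimization.

    68% confidence intervals per coefficient come from a nonparametric
    bootstrap over blocks (resampling whole blocks with replacement and
    refitting from the point estimate). Deterministic given (data, seed).
    Raises when the response rows are fewer than 10x the parameter count
    or when all responses are identical (complete separation).
    """
    X, r, block_ids = ln_design_matrix(trials, K=K, center=center)
    n_params = 2 + 2 * K + 1
    if len(r) < 10 * n_params:
        raise ValueError(
            f"under-determined fit: {len(r)} rows for {n_params} parameters"
        )
    if r.min() == r.max():
        raise ValueError("degenerate data: all responses identical")
    theta, mse = _fit_probit_mse(X, r, n_starts=n_starts, seed=seed)

    ci68 = None
    if n_boot > 0:
        rng = np.random.default_rng(seed + 1)
        unique_blocks = np.unique(block_ids)
        by_block = {b: np.flatnonzero(block_ids == b) for b in unique_blocks}
        boots = np.empty((n_boot, n_params))
        for i in range(n_boot):
            chosen = rng.choice(unique_blocks, size=len(unique_blocks))
            idx = np.concatenate([by_block[b] for b in chosen])
            bt, _ = _fit_probit_mse(X[idx], r[idx], n_starts=1, x0=theta)
            boots[i] = bt
        ci68 = np.percentile(boots, [16.0, 84.0], axis=0)

    return LNFit(
        K=K,
        coef=theta,
        mse=mse,
        n_rows=len(r),
        ci68=ci68,
        column_names=_column_names(K),
    )


# ---------------------------------------------------------------------------
# cross-validated nested-model comparison

#: Nested LN variants, as column selectors on the full design matrix:
#: naive uses only the current tones; "global" adds the running mean;
#: past_l1/past_l2 add one family of lagged tones; full uses everything.
MODEL_SPECS = {
    "naive": lambda K: [0, 1],
    "global": lambda K: [0, 1, 2 + 2 * K],
    "full": lambda K: list(range(2 + 2 * K + 1)),
    "past_l1": lambda K: [0, 1, *range(2, 2 + K), 2 + 2 * K],
    "past_l2": lambda K: [0, 1, *range(2 + K, 2 + 2 * K), 2 + 2 * K],
}


@dataclass
class CVResult:
    """Leave-one-block-out MSE per model, with paired sign-rank tests."""

    mse: pd.DataFrame  # index: block_id, columns: model names

    def mean_mse(self) -> pd.Series:
        return self.mse.mean(axis=0)

    def wilcoxon(
        self, worse: str, better: str, alternative: str = "greater"
    ) -> float:
        """p-value that held-out MSE of ``worse`` exceeds that of ``better``."""
        d = self.mse[worse] - self.mse[better]
        if np.allclose(d, 0):
            return 1.0
        return float(
            stats.wilcoxon(d, alternative=alternative).pvalue
        )

    def pairwise_pvalues(self) -> pd.DataFrame:
        names = list(self.mse.columns)
        out = pd.DataFrame(np.nan, index=names, columns=names)
        for a in names:
            for b in names:
                if a != b:
                    out.loc[a, b] = self.wilcoxon(a, b)
        return out


def crossval_compare(
    trials: pd.DataFrame,
    model_names: Sequence[str] = ("naive", "global", "full", "past_l1", "past_l2"),
    K: int = 3,
    seed: int = 0,
    n_starts: int = 3,
) -> CVResult:
    """Leave-one-block-out comparison of nested LN variants.

    For each held-out block, every model's coefficients are estimated on
    the pooled remaining blocks and scored by MSE on the held-out block.
    """
    if len(model_names) < 2:
        raise ValueError("need at least two models to compare")
    unknown = [m for m in model_names if m not in MODEL_SPECS]
    if unknown:
        raise ValueError(f"unknown model specs: {unknown}")
    X, r, block_ids = ln_design_matrix(trials, K=K)
    blocks = np.unique(block_ids)
    if len(blocks) < 10:
        raise ValueError("cross-validation requires at least 10 blocks")

    records = {}
    for name in model_names:
        cols = MODEL_SPECS[name](K)
        held_out = np.empty(len(blocks))
        for i, b in enumerate(blocks):
            test = block_ids == b
            theta, _ = _fit_probit_mse(
                X[~test][:, cols], r[~test], n_starts=n_starts, seed=seed
            )
            held_out[i] = _probit_mse(theta, X[test][:, cols], r[test])
        records[name] = held_out
    mse = pd.DataFrame(records, index=pd.Index(blocks, name="block_id"))
    # a model listed twice keeps one fitted column per label
    mse = mse.loc[:, list(model_names)]
    return CVResult(mse=mse)


# ---------------------------------------------------------------------------
# implicit-memory and Bayesian per-block fits


@dataclass
class ImmFit:
    sigma: float
    gamma: float
    mse: float


@dataclass
class BayesFit:
    sigma1: float
    sigma2: float
    mse: float


MIN_ELIGIBLE_TRIALS = 30


def _block_arrays(block: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    block = block.sort_values("trial_index")
    l1 = np.log(block["f1_hz"].to_numpy(dtype=float))
    l2 = np.log(block["f2_hz"].to_numpy(dtype=float))
    r = block["response_first_higher"].to_numpy(dtype=float)
    eligible = block["analysis_eligible"].to_numpy(dtype=bool)
    return l1, l2, r, eligible


def _imm_signals_multi(l1: np.ndarray, gammas: np.ndarray) -> np.ndarray:
    """Noise-free memory traces, shape (len(gammas), len(l1))."""
    out = np.empty((len(gammas), len(l1)))
    out[:, 0] = l1[0]
    for t in range(1, len(l1)):
        out[:, t] = gammas * out[:, t - 1] + (1.0 - gammas) * l1[t]
    return out


def fit_imm(
    block: pd.DataFrame,
    gammas: np.ndarray | None = None,
    sigmas: np.ndarray | None = None,
    refine: bool = True,
) -> ImmFit:
    """Fit (sigma, gamma) of the implicit-memory model to one block.

    Coarse grid search (gamma in {0, 0.05, ..., 0.95} x log-spaced sigma)
    followed by bounded local refinement. The full within-block tone-1
    history (including burn-in trials) feeds the memory trace; only
    analysis-eligible trials enter the MSE.
    """
    l1, l2, r, eligible = _block_arrays(block)
    if l1.size == 0:
        raise ValueError("empty block: no tone-1 history")
    if eligible.sum() < MIN_ELIGIBLE_TRIALS:
        raise ValueError(
            f"need >= {MIN_ELIGIBLE_TRIALS} eligible trials, got {int(eligible.sum())}"
        )
    if gammas is None:
        gammas = np.arange(0.0, 0.951, 0.05)
    if sigmas is None:
        sigmas = np.geomspace(0.005, 0.6, 16)

    signals = _imm_signals_multi(l1, gammas)[:, eligible]  # (G, n_elig)
    diffs = signals - l2[eligible]
    resp = r[eligible]
    best = (np.inf, 0.0, 0.0)
    for gi, g in enumerate(gammas):
        scale = math.sqrt((1.0 - g) / (1.0 + g))
        for s in sigmas:
            p = ndtr(diffs[gi] / (s * scale))
            mse = float(np.mean((p - resp) ** 2))
            if mse < best[0]:
                best = (mse, float(s), float(g))
    mse, sigma, gamma = best

    if refine:

        def objective(theta: np.ndarray) -> float:
            s, g = theta
            sig = _imm_signals_multi(l1, np.array([g]))[0, eligible]
            p = ndtr((sig - l2[eligible]) / imm_noise_sd(s, g))
            return float(np.mean((p - resp) ** 2))

        res = optimize.minimize(
            objective,
            np.array([sigma, gamma]),
            method="L-BFGS-B",
            bounds=[(1e-4, 2.0), (0.0, 0.99)],
        )
        if res.fun <= mse:
            mse, (sigma, gamma) = float(res.fun), map(float, res.x)
            sigma, gamma = float(res.x[0]), float(res.x[1])
    return ImmFit(sigma=sigma, gamma=gamma, mse=mse)


def _bayes_probs(
    l1: np.ndarray,
    l2: np.ndarray,
    sigma1: float,
    sigma2: float,
    prior_mean: float,
    prior_sd: float,
) -> np.ndarray:
    sp2 = prior_sd**2
    w1 = sp2 / (sp2 + sigma1**2)
    w2 = sp2 / (sp2 + sigma2**2)
    num = w1 * l1 - w2 * l2 + (w2 - w1) * prior_mean
    den = math.hypot(w1 * sigma1, w2 * sigma2)
    return ndtr(num / den)


def fit_bayes(
    block: pd.DataFrame,
    prior_mean: float,
    prior_sd: float,
    sigmas: np.ndarray | None = None,
    refine: bool = True,
) -> BayesFit:
    """Fit (sigma1, sigma2) of the Bayesian observer to one block.

    The Gaussian prior is fixed to the design's stimulus marginal (treated
    as known to the observer); grid search over both noise SDs with
    bounded local refinement, minimizing probit MSE on eligible trials.
    """
    l1, l2, r, eligible = _block_arrays(block)
    if l1.size == 0:
        raise ValueError("empty block")
    if eligible.sum() < MIN_ELIGIBLE_TRIALS:
        raise ValueError(
            f"need >= {MIN_ELIGIBLE_TRIALS} eligible trials, got {int(eligible.sum())}"
        )
    if sigmas is None:
        sigmas = np.geomspace(0.005, 0.6, 14)
    l1e, l2e, re = l1[eligible], l2[eligible], r[eligible]

    best = (np.inf, 0.0, 0.0)
    for s1 in sigmas:
        for s2 in sigmas:
            p = _bayes_probs(l1e, l2e, s1, s2, prior_mean, prior_sd)
            mse = float(np.mean((p - re) ** 2))
            if mse < best[0]:
                best = (mse, float(s1), float(s2))
    mse, sigma1, sigma2 = best

    if refine:

        def objective(theta: np.ndarray) -> float:
            p = _bayes_probs(l1e, l2e, theta[0], theta[1], prior_mean, prior_sd)
            return float(np.mean((p - re) ** 2))

        res = optimize.minimize(
            objective,
            np.array([sigma1, sigma2]),
            method="L-BFGS-B",
            bounds=[(1e-4, 2.0), (1e-4, 2.0)],
        )
        if res.fun <= mse:
            mse = float(res.fun)
            sigma1, sigma2 = float(res.x[0]), float(res.x[1])
    return BayesFit(sigma1=sigma1, sigma2=sigma2, mse=mse)


# ---------------------------------------------------------------------------
# psychometric curve and staircase JND


@dataclass
class PsychometricFit:
    """Single-slope probit psychometric fit and the derived JND."""

    slope_a: float
    jnd_pct: float
    mse: float
    n_trials: int
    capped: bool = False  # slope hit the search ceiling (near-separation)


MAX_SLOPE = 500.0


def fit_psychometric(
    delta_log: np.ndarray | Sequence[float],
    responses: np.ndarray | Sequence[float],
    max_slope: float = MAX_SLOPE,
) -> PsychometricFit:
    """Fit P("tone 1 higher") = Phi(a * (l1 - l2)); no bias term.

    The slope minimizes the squared error against the 0/1 responses (grid
    scan plus bounded Brent refinement). The JND in percent follows as
    100*(exp(Phi^{-1}(0.794)/a) - 1). A slope at the search ceiling is
    flagged ``capped`` (perfect separation) rather than reported infinite.
    """
    dl = np.asarray(delta_log, dtype=float)
    r = np.asarray(responses, dtype=float)
    if dl.size != r.size:
        raise ValueError("delta_log and responses must have equal length")
    if dl.size < 2:
        raise ValueError("need at least 2 trials")

    def mse_at(a: float) -> float:
        return float(np.mean((ndtr(a * dl) - r) ** 2))

    grid = np.geomspace(0.05, max_slope, 60)
    losses = [mse_at(a) for a in grid]
    a0 = grid[int(np.argmin(losses))]
    lo, hi = a0 / 4.0, min(a0 * 4.0, max_slope)
    res = optimize.minimize_scalar(mse_at, bounds=(lo, hi), method="bounded")
    slope = float(res.x)
    capped = slope >= 0.98 * max_slope
    return PsychometricFit(
        slope_a=slope,
        jnd_pct=jnd_pct_from_slope(slope),
        mse=float(res.fun),
        n_trials=int(dl.size),
        capped=capped,
    )


def fit_psychometric_frame(trials: pd.DataFrame) -> PsychometricFit:
    """Convenience wrapper: psychometric fit from a trial table."""
    dl = np.log(trials["f1_hz"].to_numpy(float)) - np.log(
        trials["f2_hz"].to_numpy(float)
    )
    return fit_psychometric(dl, trials["response_first_higher"].to_numpy(float))


def staircase_jnd(block: Block | Sequence[float], n_reversals: int = 6) -> float:
    """Average staircase difference (%) over the final reversals.

    Accepts a simulated block or a raw sequence of reversal deltas; raises
    with the available count when fewer than ``n_reversals`` occurred.
    """
    deltas = getattr(block, "reversal_deltas", block)
    deltas = list(deltas)
    if len(deltas) < n_reversals:
        raise ValueError(
            f"need {n_reversals} reversals, block has {len(deltas)}"
        )
    return float(np.mean(deltas[-n_reversals:]))
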