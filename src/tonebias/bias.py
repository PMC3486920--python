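"""Contraction-bias analyses: regions, accuracy maps, permutation tests.

The (f1, f2) plane splits, relative to the 1000 Hz median, into a Bias+
region where pulling the remembered first tone toward the centre of the
stimulus distribution *helps* the comparison (both tones above the median
with the first tone lower, or both below with the first tone higher), a
mirrored Bias- region where the pull *hurts*, and straddle trials that
span the median. Accuracy differences between the two regions quantify
the contraction bias; significance comes from a Monte Carlo permutation
test that randomly swaps the within-trial tone labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import PsychometricFit, fit_psychometric
from .stimuli import MEDIAN_HZ

BIAS_PLUS = "bias_plus"
BIAS_MINUS = "bias_minus"
STRADDLE = "straddle"


def classify_region(
    f1_hz: float, f2_hz: float, median_hz: float = MEDIAN_HZ
) -> str:
    """Label one trial's (f1, f2) pair.

    Strict inequalities throughout; a tone exactly at the median makes the
    trial a straddle (measure-zero in simulation).
    """
    if median_hz <= 0:
        raise ValueError("median_hz must be positive")
    if f1_hz > median_hz and f2_hz > median_hz:
        if f1_hz < f2_hz:
            return BIAS_PLUS
        if f1_hz > f2_hz:
            return BIAS_MINUS
        return STRADDLE
    if f1_hz < median_hz and f2_hz < median_hz:
        if f1_hz > f2_hz:
            return BIAS_PLUS
        if f1_hz < f2_hz:
            return BIAS_MINUS
        return STRADDLE
    return STRADDLE


def region_codes(
    f1_hz: np.ndarray, f2_hz: np.ndarray, median_hz: float = MEDIAN_HZ
) -> np.ndarray:
    """Vectorized regions: +1 Bias+, -1 Bias-, 0 straddle."""
    f1 = np.asarray(f1_hz, dtype=float)
    f2 = np.asarray(f2_hz, dtype=float)
    both_above = (f1 > median_hz) & (f2 > median_hz)
    both_below = (f1 < median_hz) & (f2 < median_hz)
    plus = (both_above & (f1 < f2)) | (both_below & (f1 > f2))
    minus = (both_above & (f1 > f2)) | (both_below & (f1 < f2))
    return plus.astype(int) - minus.astype(int)


@dataclass
class RegionStats:
    """Per-region trial counts, accuracy and binomial SEM."""

    table: pd.DataFrame  # index: region, columns: n, frac_correct, sem
    fisher_p: float | None = None  # Bias+ vs Bias- correct/incorrect counts

    def __getitem__(self, region: str) -> pd.Series:
        return self.table.loc[region]


def region_performance(
    trials: pd.DataFrame,
    median_hz: float = MEDIAN_HZ,
    fisher: bool = False,
) -> RegionStats:
    """Accuracy per region over analysis-eligible trials.

    Empty regions are reported with NaN accuracy, never zero. The optional
    Fisher exact test compares Bias+ and Bias- correct/incorrect counts.
    """
    codes = region_codes(
        trials["f1_hz"].to_numpy(), trials["f2_hz"].to_numpy(), median_hz
    )
    correct = trials["correct"].to_numpy(dtype=float)
    rows = {}
    for name, code in ((BIAS_PLUS, 1), (BIAS_MINUS, -1), (STRADDLE, 0)):
        mask = codes == code
        n = int(mask.sum())
        if n:
            p = float(correct[mask].mean())
            sem = float(np.sqrt(p * (1.0 - p) / n))
        else:
            p, sem = np.nan, np.nan
        rows[name] = {"n": n, "frac_correct": p, "sem": sem}
    table = pd.DataFrame(rows).T[["n", "frac_correct", "sem"]]

    fisher_p = None
    if fisher:
        cp = int(correct[codes == 1].sum())
        np_ = int((codes == 1).sum())
        cm = int(correct[codes == -1].sum())
        nm = int((codes == -1).sum())
        _, fisher_p = stats.fisher_exact(
            [[cp, np_ - cp], [cm, nm - cm]]
        )
        fisher_p = float(fisher_p)
    return RegionStats(table=table, fisher_p=fisher_p)


@dataclass
class BiasMap:
    """Binned accuracy over the (f1, f2) plane.

    ``frac_correct`` is NaN wherever a bin holds fewer than ``min_count``
    trials (under-sampled bins are not analyzed).
    """

    bin_edges: np.ndarray  # log-spaced frequency edges, Hz
    counts: np.ndarray  # (n_bins, n_bins), f1 rows x f2 columns
    frac_correct: np.ndarray
    min_count: int


def bias_map(
    trials: pd.DataFrame,
    n_bins: int = 10,
    min_count: int = 50,
    percentile_span: tuple[float, float] = (2.5, 97.5),
    bin_edges: np.ndarray | None = None,
) -> BiasMap:
    """Two-dimensional histogram of performance rate.

    Default grid: ``n_bins`` log-spaced bins spanning the 2.5th-97.5th
    percentile of all tone frequencies (both tones pooled).
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    f1 = trials["f1_hz"].to_numpy(dtype=float)
    f2 = trials["f2_hz"].to_numpy(dtype=float)
    correct = trials["correct"].to_numpy(dtype=float)
    if bin_edges is None:
        pooled = np.concatenate([f1, f2])
        lo, hi = np.percentile(pooled, percentile_span)
        bin_edges = np.geomspace(lo, hi, n_bins + 1)
    counts, _, _ = np.histogram2d(f1, f2, bins=[bin_edges, bin_edges])
    hits, _, _ = np.histogram2d(
        f1, f2, bins=[bin_edges, bin_edges], weights=correct
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = hits / counts
    frac[counts < min_count] = np.nan
    return BiasMap(
        bin_edges=np.asarray(bin_edges),
        counts=counts,
        frac_correct=frac,
        min_count=min_count,
    )


# ---------------------------------------------------------------------------
# Monte Carlo permutation tests (within-trial tone-label swaps)


@dataclass
class PermutationResult:
    p_value: float
    observed: float
    n_perm: int
    n_dropped_blocks: int = 0


def _accuracy_diff(codes: np.ndarray, correct: np.ndarray) -> float:
    return float(
        correct[codes == 1].mean() - correct[codes == -1].mean()
    )


def permutation_test_accuracy(
    trials: pd.DataFrame,
    n_perm: int = 1_000_000,
    seed: int = 0,
    median_hz: float = MEDIAN_HZ,
    chunk: int = 20_000,
) -> PermutationResult:
    """One-sided permutation test of accuracy(Bias+) - accuracy(Bias-).

    Each permutation independently swaps the tone labels of every trial
    with probability 1/2. A swap flips the trial's region while leaving
    its correctness unchanged (the swap also flips which response the
    recorded choice refers to, so correctness semantics are preserved).
    The p-value uses the add-one estimator (1 + #{perm >= obs})/(1 + n),
    so it is never exactly zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    codes = region_codes(
        trials["f1_hz"].to_numpy(), trials["f2_hz"].to_numpy(), median_hz
    )
    correct = trials["correct"].to_numpy(dtype=float)
    if not (codes == 1).any() or not (codes == -1).any():
        raise ValueError("a bias region is empty in the observed data")
    observed = _accuracy_diff(codes, correct)

    rng = np.random.default_rng(seed)
    n_ge = 0
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # sign matrix: -1 swaps the trial's labels, +1 keeps them
        signs = rng.integers(0, 2, size=(m, codes.size)) * 2 - 1
        perm_codes = codes * signs
        plus = perm_codes == 1
        minus = perm_codes == -1
        acc_plus = (plus * correct).sum(axis=1) / plus.sum(axis=1)
        acc_minus = (minus * correct).sum(axis=1) / minus.sum(axis=1)
        n_ge += int(np.sum(acc_plus - acc_minus >= observed))
        done += m
    p = (1 + n_ge) / (1 + n_perm)
    return PermutationResult(p_value=float(p), observed=observed, n_perm=n_perm)


def _region_jnd_medians(
    codes: np.ndarray,
    block_ids: np.ndarray,
    delta_log: np.ndarray,
    responses: np.ndarray,
    min_trials: int,
) -> tuple[float, float, int]:
    """Per-block psychometric JNDs per region; medians across blocks.

    A block contributes only if both regions support a fit (enough trials
    and an uncapped slope); returns (median JND+, median JND-, n dropped).
    """
    jnd_plus, jnd_minus, dropped = [], [], 0
    for b in np.unique(block_ids):
        in_block = block_ids == b
        fits: list[PsychometricFit] = []
        ok = True
        for code in (1, -1):
            mask = in_block & (codes == code)
            if mask.sum() < min_trials:
                ok = False
                break
            fit = fit_psychometric(delta_log[mask], responses[mask])
            if fit.capped:
                ok = False
                break
            fits.append(fit)
        if not ok:
            dropped += 1
            continue
        jnd_plus.append(fits[0].jnd_pct)
        jnd_minus.append(fits[1].jnd_pct)
    if not jnd_plus:
        raise ValueError("no block supports region-wise psychometric fits")
    return float(np.median(jnd_plus)), float(np.median(jnd_minus)), dropped


def permutation_test_jnd(
    trials: pd.DataFrame,
    n_perm: int = 100_000,
    seed: int = 0,
    median_hz: float = MEDIAN_HZ,
    min_trials: int = 5,
) -> PermutationResult:
    """One-sided permutation test of median JND(Bias-) - median JND(Bias+).

    JNDs come from per-block single-slope psychometric fits within each
    region; the statistic is the across-block median difference. The null
    swaps tone labels per trial as in :func:`permutation_test_accuracy`
    (a swap negates the log-difference regressor and flips the response,
    leaving each trial's squared-error contribution invariant, so only
    region membership changes). Blocks where a region's fit fails are
    dropped from that computation, with the observed-data count reported.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    codes = region_codes(
        trials["f1_hz"].to_numpy(), trials["f2_hz"].to_numpy(), median_hz
    )
    block_ids = trials["block_id"].to_numpy()
    dl = np.log(trials["f1_hz"].to_numpy(float)) - np.log(
        trials["f2_hz"].to_numpy(float)
    )
    r = trials["response_first_higher"].to_numpy(dtype=float)

    jp, jm, dropped = _region_jnd_medians(codes, block_ids, dl, r, min_trials)
    observed = jm - jp

    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        signs = rng.integers(0, 2, size=codes.size) * 2 - 1
        try:
            pjp, pjm, _ = _region_jnd_medians(
                codes * signs, block_ids, dl, r, min_trials
            )
        except ValueError:
            continue  # no usable block under this permutation
        n_ge += int(pjm - pjp >= observed)
    p = (1 + n_ge) / (1 + n_perm)
    return PermutationResult(
        p_value=float(p),
        observed=float(observed),
        n_perm=n_perm,
        n_dropped_blocks=dropped,
    )
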