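"""Significance tests for frequency-tagged responses.

Power test
    Under the null (no response above the local background), the normalized
    power of a grand average over ``n`` subjects follows a scaled F
    distribution: each subject's evoked power at a bin is proportional to a
    chi-square with 2 degrees of freedom (real and imaginary coefficient
    parts), so the subject-averaged target bin carries ``2n`` dof and the 14
    neighbouring bins pool ``2 * 14 * n`` dof. Hence
    ``2 * bins_per_side * En ~ F(2n, 4n * bins_per_side)`` — F(32, 448)
    for 16 subjects and 7 bins per side.

Phase test
    The inter-trial phase coherence R over K trials is the Rayleigh Z; under
    uniform phases its p-value uses the standard small-sample correction
    ``p = exp(-Z) * (1 + (2Z - Z^2) / (4K))``.

Empirical null
    For channel-averaged statistics whose parametric null is spoiled by
    inter-channel correlation, a null pool is built from the same statistic
    at frequencies not harmonically related to the sentential rate, and the
    p-value is the add-one rank ``(1 + #{null >= observed}) / (1 + #null)``.

Also here: Benjamini-Hochberg FDR across subjects, the between-condition
evoked-power ratio test against F(2n, 2n), split-half topography
classification with a per-subject binomial score, and the neural-behavior
Pearson correlation with a >3 SD behavioral outlier rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "ftest_normalized_power",
    "rayleigh_test",
    "empirical_null_test",
    "null_bin_pool",
    "fdr_correct",
    "compare_conditions",
    "classify_topographies",
    "correlate_behavior",
    "behavioral_outlier_mask",
]


@dataclass
class TestResult:
    """One hypothesis-test outcome with its provenance."""

    method: str
    statistic: float
    dof: tuple | int | None
    p: float
    q: float | None = None
    target: str | None = None
    scope: str = "grand"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def ftest_normalized_power(
    en_at_target: float,
    n_subjects: int,
    bins_per_side: int = 7,
    target: str | None = None,
    scope: str = "grand",
) -> TestResult:
    """F-test on normalized evoked power.

    ``statistic = 2 * bins_per_side * En`` referred to
    ``F(2 n, 2 * bins_per_side * 2 n)`` — F(32, 448) at n=16 — with an
    upper-tail p. ``n_subjects=1`` gives the per-subject F(2, 28) variant.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not np.isfinite(en_at_target):
        raise ValueError("En at target is not finite (edge bin?)")
    d1 = 2 * n_subjects
    d2 = 2 * bins_per_side * 2 * n_subjects
    statistic = 2 * bins_per_side * float(en_at_target)
    p = float(stats.f.sf(statistic, d1, d2))
    return TestResult(
        method="f_norm_power", statistic=statistic, dof=(d1, d2), p=p,
        target=target, scope=scope,
    )


def rayleigh_test(
    r_at_target: float, K: int, target: str | None = None, scope: str = "grand"
) -> TestResult:
    """Rayleigh test of phase uniformity on the coherence statistic.

    The inter-trial phase coherence is exactly the Rayleigh Z for K trials.
    """
    if K < 2:
        raise ValueError("Rayleigh test needs K >= 2 trials")
    z = float(r_at_target)
    p = np.exp(-z) * (1.0 + (2.0 * z - z**2) / (4.0 * K))
    p = float(np.clip(p, 0.0, 1.0))
    return TestResult(
        method="rayleigh", statistic=z, dof=K, p=p, target=target, scope=scope
    )


def null_bin_pool(
    freqs: np.ndarray,
    sentential_bin: int,
    freq_range: tuple[float, float] = (0.3, 5.5),
    guard_bins: int = 1,
) -> np.ndarray:
    """Indices of bins usable as an empirical null.

    All bins inside ``freq_range`` except integer multiples of the
    sentential bin and a ``guard_bins``-wide margin around each.
    """
    idx = np.flatnonzero((freqs >= freq_range[0]) & (freqs <= freq_range[1]))
    harmonics = np.arange(sentential_bin, freqs.size, sentential_bin)
    excluded = np.concatenate(
        [harmonics + d for d in range(-guard_bins, guard_bins + 1)]
    )
    return np.setdiff1d(idx, excluded)


def empirical_null_test(
    observed: float,
    null_values: np.ndarray,
    min_pool: int = 50,
    target: str | None = None,
    scope: str = "grand",
    method: str = "empirical_null",
) -> TestResult:
    """Add-one rank p-value of ``observed`` against a pooled null.

    ``p = (1 + #{null >= observed}) / (1 + #null)``; the pool typically
    spans non-harmonic frequency bins and, for subject-level tests, all
    subjects. NaNs in the pool (normalization edge bins) are dropped.
    """
    null_values = np.asarray(null_values, dtype=float).ravel()
    null_values = null_values[np.isfinite(null_values)]
    if null_values.size < min_pool:
        raise ValueError(
            f"null pool has {null_values.size} values; need >= {min_pool}"
        )
    n_ge = int(np.sum(null_values >= observed))
    p = (1.0 + n_ge) / (1.0 + null_values.size)
    return TestResult(
        method=method, statistic=float(observed), dof=null_values.size, p=p,
        target=target, scope=scope,
    )


def fdr_correct(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted q-values, discovery mask)."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, q_adj, _, _ = multipletests(p_values, alpha=q, method="fdr_bh")
    return q_adj, reject


def compare_conditions(
    e_sentence: float,
    e_control: float,
    n_subjects: int,
    target: str | None = None,
) -> TestResult:
    """Between-condition evoked-power ratio at one target bin.

    ``F = E_sentence / E_control`` on grand-averaged, channel-averaged
    evoked power, referred to ``F(2n, 2n)`` (F(32, 32) at n=16), upper tail.
    """
    if e_control <= 0:
        raise ValueError("control-condition power must be positive")
    d = 2 * n_subjects
    statistic = float(e_sentence) / float(e_control)
    p = float(stats.f.sf(statistic, d, d))
    return TestResult(
        method="f_condition", statistic=statistic, dof=(d, d), p=p,
        target=target, scope="grand",
    )


def _ridge_lda_weights(
    x0: np.ndarray, x1: np.ndarray, ridge_scale: float
) -> tuple[np.ndarray, float]:
    """Two-class linear discriminant with a ridge-stabilized pooled covariance.

    The ridge is ``ridge_scale * mean pooled feature variance`` added to the
    covariance diagonal, which keeps the solve well-posed when features
    (channels) outnumber samples (subjects).
    """
    mu0, mu1 = x0.mean(axis=0), x1.mean(axis=0)
    centered = np.vstack([x0 - mu0, x1 - mu1])
    cov = centered.T @ centered / max(centered.shape[0] - 2, 1)
    mean_var = float(np.trace(cov)) / cov.shape[0]
    # zero-variance training data: any positive ridge leaves w along mu1-mu0
    ridge = ridge_scale * mean_var if mean_var > 0 else 1.0
    cov_r = cov + ridge * np.eye(cov.shape[0])
    w = np.linalg.solve(cov_r, mu1 - mu0)
    b = -0.5 * float(w @ (mu0 + mu1))
    return w, b


def classify_topographies(
    first_half: np.ndarray,
    second_half: np.ndarray,
    ridge_scale: float = 1e-3,
) -> tuple[float, TestResult]:
    """Split-half linear classification of per-subject topographies.

    Parameters
    ----------
    first_half, second_half : ndarray, shape (n_subjects, 2, n_channels)
        Per-subject topographic maps of the two classes (two frequencies or
        two conditions), averaged over the first and second half of trials.

    A ridge-regularized linear discriminant is trained on all subjects'
    first-half maps (one sample per subject per class). Each subject then
    contributes one Bernoulli outcome on their held-out second-half pair:
    correct iff assigning the higher classifier score to class 1 matches the
    true labels. Returns (accuracy, binomial test vs. 0.5 over N subjects,
    one-sided).
    """
    first_half = np.asarray(first_half, dtype=float)
    second_half = np.asarray(second_half, dtype=float)
    if first_half.shape != second_half.shape or first_half.ndim != 3 \
            or first_half.shape[1] != 2:
        raise ValueError("maps must both be (n_subjects, 2, n_channels)")
    n_subjects = first_half.shape[0]
    w, b = _ridge_lda_weights(first_half[:, 0], first_half[:, 1], ridge_scale)
    score0 = second_half[:, 0] @ w + b
    score1 = second_half[:, 1] @ w + b
    correct = score1 > score0
    k = int(correct.sum())
    accuracy = k / n_subjects
    bt = stats.binomtest(k, n_subjects, 0.5, alternative="greater")
    result = TestResult(
        method="binomial_classifier", statistic=float(k), dof=n_subjects,
        p=float(bt.pvalue), scope="grand",
        extra={"accuracy": accuracy},
    )
    return accuracy, result


def behavioral_outlier_mask(scores: np.ndarray, sd_threshold: float = 3.0) -> np.ndarray:
    """Flag scores more than ``sd_threshold`` SDs from the mean of the rest.

    Leave-one-out form: a subject is an outlier if their score deviates by
    more than the threshold from the mean of the other subjects, in units of
    the other subjects' SD. This matches flagging a single 33 %-scoring
    subject inside a tight high-performing cluster.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    mask = np.zeros(n, dtype=bool)
    if n < 3:  # cannot assess deviation against fewer than 2 references
        return mask
    for i in range(n):
        rest = np.delete(scores, i)
        sd = rest.std(ddof=1)
        if sd == 0:
            mask[i] = scores[i] != rest.mean()
        else:
            mask[i] = abs(scores[i] - rest.mean()) > sd_threshold * sd
    return mask


def correlate_behavior(
    neural: np.ndarray,
    behavior: np.ndarray,
    exclude_outliers: bool = True,
    sd_threshold: float = 3.0,
    target: str | None = None,
) -> TestResult:
    """Pearson correlation between a neural measure and behavioral scores.

    Two-sided t-test p. With ``exclude_outliers`` behavioral outliers (see
    :func:`behavioral_outlier_mask`) are removed first; excluded indices are
    reported in ``extra``.
    """
    neural = np.asarray(neural, dtype=float)
    behavior = np.asarray(behavior, dtype=float)
    if neural.shape != behavior.shape:
        raise ValueError("neural and behavior must be paired")
    excluded: list[int] = []
    if exclude_outliers:
        mask = behavioral_outlier_mask(behavior, sd_threshold)
        excluded = list(np.flatnonzero(mask))
        neural, behavior = neural[~mask], behavior[~mask]
    if neural.size < 3:
        raise ValueError("need at least 3 paired observations")
    if neural.std() == 0 or behavior.std() == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = stats.pearsonr(neural, behavior)
    return TestResult(
        method="pearson", statistic=float(r), dof=neural.size - 2, p=float(p),
        target=target, scope="grand",
        extra={"n": int(neural.size), "excluded_subjects": excluded},
    )
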