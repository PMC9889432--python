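"""Agreement statistics for CPR image-quality ratings.

The study design rates each case's CPR image on a four-point ordinal
scale (1 not evaluable, 2 poor, 3 fair, 4 good), once per method (or per
rater), and quantifies agreement with weighted Cohen's κ: disagreements
are penalized by their category distance, either linearly or
quadratically.  κ bands follow the conventional classification: poor
(0.0 ≤ κ ≤ 0.2), fair (0.2 < κ ≤ 0.4), moderate (0.4 < κ ≤ 0.6), good
(0.6 < κ ≤ 0.8), excellent (0.8 < κ ≤ 1.0).

Confidence intervals are case-resampling BCa bootstrap intervals (the CI
method is otherwise an open modeling choice; the bootstrap is
assumption-light and seedable).  Continuous endpoints (generation time,
MPD length) are compared with paired t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .grid import DegenerateInputError

GRADES = (1, 2, 3, 4)
GRADE_LABELS = {1: "not evaluable", 2: "poor", 3: "fair", 4: "good"}


class InfeasibleError(ValueError):
    """The requested design cannot be met (e.g. threshold ≥ assumed κ)."""


@dataclass
class RatingTable:
    """Per-case ordinal scores for two methods (or two raters)."""

    case_id: np.ndarray
    score_a: np.ndarray
    score_b: np.ndarray
    categories: tuple[int, ...] = GRADES

    def __post_init__(self):
        self.case_id = np.asarray(self.case_id)
        self.score_a = np.asarray(self.score_a, dtype=int)
        self.score_b = np.asarray(self.score_b, dtype=int)
        if not (len(self.case_id) == len(self.score_a) == len(self.score_b)):
            raise ValueError("case_id, score_a, score_b must have equal length")
        cats = set(self.categories)
        for name, s in (("score_a", self.score_a), ("score_b", self.score_b)):
            bad = set(np.unique(s)) - cats
            if bad:
                raise ValueError(f"{name} contains scores outside {self.categories}: {bad}")

    def __len__(self) -> int:
        return len(self.case_id)

    @classmethod
    def from_scores(cls, score_a, score_b, categories=GRADES) -> "RatingTable":
        n = len(score_a)
        return cls(np.arange(1, n + 1), score_a, score_b, categories)

    @classmethod
    def from_csv(cls, path, categories=GRADES) -> "RatingTable":
        df = pd.read_csv(path)
        return cls(df["case_id"].to_numpy(), df["score_a"].to_numpy(),
                   df["score_b"].to_numpy(), categories)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"case_id": self.case_id, "score_a": self.score_a, "score_b": self.score_b}
        ).to_csv(path, index=False)

    def contingency(self) -> np.ndarray:
        """k×k counts, rows = method A category, cols = method B category."""
        k = len(self.categories)
        lut = {c: i for i, c in enumerate(self.categories)}
        ai = np.vectorize(lut.get)(self.score_a)
        bi = np.vectorize(lut.get)(self.score_b)
        return np.bincount(ai * k + bi, minlength=k * k).reshape(k, k).astype(float)


@dataclass
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    weight_scheme: str
    band: str
    below_chance: bool = False
    n_cases: int = 0


@dataclass
class PairedTestResult:
    t_statistic: float
    p_value: float
    mean_difference: float
    n: int


# ---------------------------------------------------------------------------
# weighted kappa
# ---------------------------------------------------------------------------

def disagreement_weights(k: int, scheme: str) -> np.ndarray:
    i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    if scheme == "linear":
        return np.abs(i - j) / (k - 1)
    if scheme == "quadratic":
        return ((i - j) / (k - 1)) ** 2
    raise ValueError(f"unknown weight scheme {scheme!r}")


def kappa_from_counts(counts: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """κ = 1 − Σw·p_obs / Σw·p_exp, vectorized over leading axes.

    ``counts`` is (..., k, k); degenerate tables (no expected
    disagreement mass) yield NaN.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum(axis=(-2, -1), keepdims=True)
    p = counts / total
    row = p.sum(axis=-1)
    col = p.sum(axis=-2)
    e = row[..., :, None] * col[..., None, :]
    num = (weights * p).sum(axis=(-2, -1))
    den = (weights * e).sum(axis=(-2, -1))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, 1.0 - num / den, np.nan)


def _bootstrap_kappas(
    ai: np.ndarray, bi: np.ndarray, k: int, weights: np.ndarray,
    n_boot: int, rng: np.random.Generator,
) -> np.ndarray:
    n = len(ai)
    joint = ai * k + bi
    idx = rng.integers(0, n, size=(n_boot, n))
    flat = joint[idx] + np.arange(n_boot)[:, None] * (k * k)
    counts = np.bincount(flat.ravel(), minlength=n_boot * k * k).reshape(n_boot, k, k)
    return kappa_from_counts(counts, weights)


def _bca_interval(boots, estimate, counts, ai, bi, k, weights, ci_level):
    """Bias-corrected and accelerated (BCa) bootstrap interval for κ.

    The plain percentile interval undercovers for κ at moderate n (the
    sampling distribution is skewed toward 1); the BCa correction — bias
    from the fraction of bootstrap replicates below the estimate,
    acceleration from a leave-one-case-out jackknife — restores coverage
    close to nominal.  Jackknifed κ values are computed per distinct
    contingency cell and weighted by multiplicity, so the jackknife is
    O(k²) rather than O(n).
    """
    n_boot = boots.size
    cells, mult = np.unique(ai * k + bi, return_counts=True)
    loo = np.empty(len(cells))
    for i, cell in enumerate(cells):
        cc = counts.copy()
        cc[cell // k, cell % k] -= 1
        loo[i] = kappa_from_counts(cc, weights)
    loo_full = np.repeat(loo, mult)
    dev = loo_full.mean() - loo_full
    denom = 6.0 * (np.sum(dev**2)) ** 1.5
    accel = float(np.sum(dev**3) / denom) if denom > 0 else 0.0

    frac_below = np.clip(np.mean(boots < estimate), 1.0 / n_boot, 1 - 1.0 / n_boot)
    z0 = sps.norm.ppf(frac_below)
    z_alpha = sps.norm.ppf((1.0 - ci_level) / 2.0)
    alphas = []
    for z in (z_alpha, -z_alpha):
        adj = z0 + (z0 + z) / (1.0 - accel * (z0 + z))
        alphas.append(float(np.clip(sps.norm.cdf(adj), 1e-4, 1 - 1e-4)))
    lo, hi = np.quantile(boots, sorted(alphas))
    return float(lo), float(hi)


def weighted_kappa(
    table: RatingTable,
    weight_scheme: str = "linear",
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> KappaResult:
    """Weighted Cohen's κ with a case-resampling bootstrap 95% CI.

    Expected disagreement comes from the marginal products; observed and
    expected disagreements are weighted by category distance (linear or
    quadratic).  Raises for degenerate tables where chance disagreement
    is zero (all cases in a single identical category pair).
    """
    if len(table) < 2:
        raise ValueError("weighted_kappa needs >= 2 cases")
    k = len(table.categories)
    w = disagreement_weights(k, weight_scheme)
    counts = table.contingency()
    kappa = float(kappa_from_counts(counts, w))
    if np.isnan(kappa):
        raise DegenerateInputError(
            "degenerate agreement table: no chance-expected disagreement"
        )
    lut = {c: i for i, c in enumerate(table.categories)}
    ai = np.array([lut[s] for s in table.score_a])
    bi = np.array([lut[s] for s in table.score_b])
    rng = np.random.default_rng(seed)
    boots = _bootstrap_kappas(ai, bi, k, w, n_boot, rng)
    boots = boots[~np.isnan(boots)]
    if boots.size:
        lo, hi = _bca_interval(boots, kappa, counts, ai, bi, k, w, ci_level)
    else:
        lo = hi = np.nan
    return KappaResult(
        kappa=kappa,
        ci_low=float(min(lo, kappa)),
        ci_high=float(max(hi, kappa)),
        weight_scheme=weight_scheme,
        band=classify_kappa(kappa),
        below_chance=kappa < 0,
        n_cases=len(table),
    )


def classify_kappa(kappa: float) -> str:
    """Conventional κ band; below-chance κ (< 0) reports as "poor"."""
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must lie in [-1, 1], got {kappa}")
    if kappa <= 0.2:
        return "poor"
    if kappa <= 0.4:
        return "fair"
    if kappa <= 0.6:
        return "moderate"
    if kappa <= 0.8:
        return "good"
    return "excellent"


# ---------------------------------------------------------------------------
# paired t-test
# ---------------------------------------------------------------------------

def paired_t_test(values_a, values_b) -> PairedTestResult:
    """Two-sided paired t-test on per-case differences (df = n − 1)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"paired samples must be equal-length 1D, got {a.shape}/{b.shape}")
    if len(a) < 2:
        raise ValueError("paired_t_test needs n >= 2")
    diff = a - b
    if np.ptp(diff) == 0.0:
        raise DegenerateInputError("zero-variance differences: t undefined")
    res = sps.ttest_rel(a, b)
    return PairedTestResult(
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        mean_difference=float(diff.mean()),
        n=len(a),
    )


# ---------------------------------------------------------------------------
# simulation + sample size
# ---------------------------------------------------------------------------

def simulate_rating_pairs(
    n: int,
    marginal_probs,
    kappa: float,
    rng: np.random.Generator,
    size: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw rating pairs with weighted κ exactly ``kappa`` in expectation.

    Uses the agreement-mixture model: with probability κ both raters
    emit the same category drawn from the marginals, otherwise the two
    draws are independent.  The joint distribution
    ``p_ij = κ·δ_ij·m_i + (1−κ)·m_i·m_j`` keeps the marginals at ``m``
    and has weighted κ equal to κ for *any* distance-based weight scheme
    (the observed and expected weighted disagreements share the factor
    Σ w_ij m_i m_j).
    Returns 0-based category index arrays of shape (size, n).
    """
    m = np.asarray(marginal_probs, dtype=float)
    if not np.isclose(m.sum(), 1.0):
        raise ValueError(f"marginal probabilities must sum to 1, got {m.sum()}")
    if not 0.0 <= kappa <= 1.0:
        raise ValueError("mixture model requires kappa in [0, 1]")
    k = len(m)
    a = rng.choice(k, size=(size, n), p=m)
    indep = rng.choice(k, size=(size, n), p=m)
    same = rng.random(size=(size, n)) < kappa
    return a, np.where(same, a, indep)


def kappa_sample_size(
    assumed_kappa: float,
    marginal_probs,
    threshold: float = 0.6,
    alpha: float = 0.05,
    n_grid=(40, 60, 80, 100, 140, 200),
    seed: int = 0,
    n_cohorts: int = 500,
    n_boot: int = 2000,
    weight_scheme: str = "linear",
) -> int:
    """Smallest cohort size whose κ CI lower bound clears a threshold.

    For each candidate n, simulates ``n_cohorts`` rating cohorts at the
    assumed κ, bootstraps the 100(1−α)% CI of each cohort's weighted κ,
    and returns the smallest n whose *median* lower CI bound exceeds
    ``threshold``.  Mirrors designs that size a study so the κ CI lower
    limit exceeds a target agreement level.
    """
    if threshold >= assumed_kappa:
        raise InfeasibleError(
            f"threshold {threshold} must be below assumed kappa {assumed_kappa}"
        )
    m = np.asarray(marginal_probs, dtype=float)
    k = len(m)
    w = disagreement_weights(k, weight_scheme)
    rng = np.random.default_rng(seed)
    q = alpha / 2.0
    for n in sorted(int(x) for x in n_grid):
        a, b = simulate_rating_pairs(n, m, assumed_kappa, rng, size=n_cohorts)
        lows = np.empty(n_cohorts)
        for c in range(n_cohorts):
            boots = _bootstrap_kappas(a[c], b[c], k, w, n_boot, rng)
            boots = boots[~np.isnan(boots)]
            lows[c] = np.quantile(boots, q) if boots.size else np.nan
        if np.nanmedian(lows) > threshold:
            return n
    raise InfeasibleError(
        f"no n in {tuple(sorted(n_grid))} reaches CI lower bound > {threshold}"
    )


# ---------------------------------------------------------------------------
# score summaries
# ---------------------------------------------------------------------------

def summarize_scores(table: RatingTable) -> dict:
    """Per-method grade counts and arithmetic mean scores."""
    out = {}
    for name, s in (("method_a", table.score_a), ("method_b", table.score_b)):
        counts = {g: int((s == g).sum()) for g in table.categories}
        out[name] = {"counts": counts, "mean": float(np.mean(s)), "n": len(s)}
    return out
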