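"""Case-control rare-variant battery: score tests, C-alpha, SKAT and KBAC.

The five multivariate score tests reuse :mod:`famrare.family_tests` on the
logistic null-score components

    U = G'(y - ybar),   V = ybar (1 - ybar) * sum_i (g_i - gbar)(g_i - gbar)'

C-alpha tests for overdispersion of the case/control split of minor-allele
copies under a binomial null (direction-agnostic, one-tailed normal).  SKAT
is the weighted variance-component score statistic Q = U' W U with
Beta(MAF; a1, a2)-density weights, calibrated against the eigenvalue
mixture of chi-square(1) laws; with unit weights it coincides exactly with
SSU.  KBAC contrasts multi-variant genotype-class frequencies between cases
and controls, each class weighted by its cumulative hypergeometric
probability (the Liu & Leal small-sample kernel), with one-sided
permutation p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import beta as beta_dist
from scipy.stats import binom, chi2, hypergeom, norm

from .family_tests import ScoreComponents, TestResult
from .quadform import mixture_chisq_pvalue  # re-exported: shared null machinery
from .transform import CaseControlData

__all__ = [
    "CollapsedCounts",
    "SkatWeights",
    "KbacClasses",
    "cc_score_components",
    "single_snp_association",
    "collapse_counts",
    "calpha_statistic",
    "calpha_permutation",
    "beta_maf_weights",
    "skat_test",
    "kbac_test",
    "mixture_chisq_pvalue",
]


@dataclass
class CollapsedCounts:
    """Per-variant minor-allele copy totals (n_j) and case copies (a_j)."""

    n: np.ndarray
    a: np.ndarray
    p0: float  # case fraction of subjects

    def __post_init__(self):
        if np.any(self.a < 0) or np.any(self.a > self.n):
            raise ValueError("need 0 <= a_j <= n_j")


@dataclass
class SkatWeights:
    """Beta-density MAF weights for SKAT."""

    w: np.ndarray
    a1: float
    a2: float
    maf_hat: np.ndarray


@dataclass
class KbacClasses:
    """Distinct non-null multi-variant genotypes with case/control counts."""

    genotypes: np.ndarray  # (k, m)
    case_counts: np.ndarray
    control_counts: np.ndarray
    n_cases: int
    n_controls: int
    kernel: np.ndarray  # cumulative hypergeometric weight per class


def _check_two_classes(y: np.ndarray) -> None:
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("need both cases and controls")


def cc_score_components(cc: CaseControlData) -> ScoreComponents:
    """Logistic null-score vector and covariance from case-control data."""
    y = cc.y.astype(float)
    _check_two_classes(y)
    G = cc.G.astype(float)
    ybar = y.mean()
    yc = y - ybar
    U = G.T @ yc
    Gc = G - G.mean(axis=0)
    V = ybar * (1 - ybar) * (Gc.T @ Gc)
    rows = yc[:, None] * G
    return ScoreComponents(U=U, V=V, n=cc.n, xbar=rows.mean(axis=0), rows=rows)


def single_snp_association(cc: CaseControlData) -> TestResult:
    """Per-variant 1-df score chi-square with Bonferroni-corrected min p.

    Monomorphic variants (V_jj = 0) are excluded from both the minimum and
    the Bonferroni count.  Equivalent to the allelic trend test per variant.
    """
    sc = cc_score_components(cc)
    v = np.diag(sc.V)
    keep = v > 0
    if not keep.any():
        warnings.warn("no polymorphic variants; association p-value set to 1")
        return TestResult(0.0, 1.0, "association", {"n_informative": 0})
    stats = np.zeros_like(v)
    stats[keep] = sc.U[keep] ** 2 / v[keep]
    pvals = np.where(keep, chi2.sf(stats, df=1), 1.0)
    k = int(keep.sum())
    j = int(np.argmin(np.where(keep, pvals, np.inf)))
    return TestResult(
        float(stats[j]),
        float(min(1.0, k * pvals[j])),
        "association",
        {"n_informative": k, "per_variant_chi2": stats, "per_variant_p": pvals},
    )


def collapse_counts(cc: CaseControlData) -> CollapsedCounts:
    """Total and case minor-allele copies per variant, plus case fraction."""
    _check_two_classes(cc.y)
    n = cc.G.sum(axis=0).astype(int)
    a = cc.G[cc.y == 1].sum(axis=0).astype(int)
    p0 = float(cc.y.mean())
    return CollapsedCounts(n=n, a=a, p0=p0)


def _calpha_T(a: np.ndarray, n: np.ndarray, p0: float) -> float:
    return float(np.sum((a - n * p0) ** 2 - n * p0 * (1 - p0)))


def calpha_statistic(cc: CaseControlData) -> TestResult:
    """Analytic one-tailed C-alpha test.

    T sums, per variant, the squared deviation of the case copy count from
    its binomial expectation minus the binomial variance; the null variance
    c sums the exact second moments by enumeration over copy totals, and
    Z = T / sqrt(c) is referred to the upper standard-normal tail.
    """
    counts = collapse_counts(cc)
    n, a, p0 = counts.n, counts.a, counts.p0
    nz = n[n > 0]
    T = _calpha_T(a, n, p0)
    # variance: sum over distinct copy totals of m(n) * E[((u - n p0)^2 - var)^2]
    c = 0.0
    for tot, mult in zip(*np.unique(nz, return_counts=True)):
        u = np.arange(tot + 1)
        term = (u - tot * p0) ** 2 - tot * p0 * (1 - p0)
        c += mult * float(np.sum(term**2 * binom.pmf(u, tot, p0)))
    if c <= 0:
        warnings.warn("C-alpha null variance is zero; p-value set to 1")
        return TestResult(T, 1.0, "calpha", {"variance": 0.0})
    Z = T / np.sqrt(c)
    return TestResult(
        float(Z), float(norm.sf(Z)), "calpha", {"T": T, "variance": c}
    )


def _permuted_phenotypes(
    y: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    return rng.permuted(np.tile(y.astype(np.float64), (n_perm, 1)), axis=1)


def calpha_permutation(
    cc: CaseControlData, n_perm: int = 1000, rng: Optional[np.random.Generator] = None
) -> TestResult:
    """C-alpha with one-sided label-permutation p-value (add-one estimator).

    The asymptotic normal calibration is unreliable at very low minor-allele
    counts, which is exactly the rare-variant regime; permutation restores
    validity.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = rng if rng is not None else np.random.default_rng(0)
    counts = collapse_counts(cc)
    T_obs = _calpha_T(counts.a, counts.n, counts.p0)
    Y = _permuted_phenotypes(cc.y, n_perm, rng)
    A = Y @ cc.G.astype(float)  # (n_perm, m) case copy counts
    n, p0 = counts.n.astype(float), counts.p0
    T_perm = np.sum((A - n * p0) ** 2 - n * p0 * (1 - p0), axis=1)
    p = (1.0 + np.sum(T_perm >= T_obs)) / (n_perm + 1.0)
    return TestResult(float(T_obs), float(p), "calpha_perm", {"n_perm": n_perm})


def beta_maf_weights(maf_hat, a1: float = 1.0, a2: float = 25.0) -> SkatWeights:
    """Beta-density weights w_j = Beta(maf_j; a1, a2); Beta(1,25) upweights
    rare variants, Beta(1,1) gives unit weights."""
    maf_hat = np.asarray(maf_hat, dtype=float)
    if np.any(maf_hat < 0) or np.any(maf_hat > 1):
        raise ValueError("observed MAFs must lie in [0, 1]")
    w = beta_dist.pdf(maf_hat, a1, a2)
    return SkatWeights(w=w, a1=a1, a2=a2, maf_hat=maf_hat)


def skat_test(cc: CaseControlData, weights: Optional[SkatWeights] = None) -> TestResult:
    """Variance-component score test Q = (y - ybar)' G W G' (y - ybar).

    W = diag(w_j^2); default weights are Beta(1,25) densities at the MAFs
    observed in the combined sample.  The null law is the eigenvalue mixture
    of the weighted, centered genotype cross-product scaled by ybar(1-ybar).
    """
    _check_two_classes(cc.y)
    G = cc.G.astype(float)
    if weights is None:
        weights = beta_maf_weights(G.mean(axis=0) / 2.0)
    w = weights.w
    y = cc.y.astype(float)
    ybar = y.mean()
    U = G.T @ (y - ybar)
    Q = float(np.sum((w * U) ** 2))
    Gc = (G - G.mean(axis=0)) * w
    lam = ybar * (1 - ybar) * np.linalg.eigvalsh(Gc.T @ Gc)
    lam = lam[lam > 0]
    if lam.size == 0 or Q <= 0:
        return TestResult(Q, 1.0, "skat", {"weights": w})
    return TestResult(
        Q, float(mixture_chisq_pvalue(lam, Q)), "skat", {"weights": w, "lambdas": lam}
    )


def _kbac_classes(cc: CaseControlData) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Indices of carrier subjects, their class assignment, and class sizes."""
    carrier = cc.G.any(axis=1)
    idx = np.nonzero(carrier)[0]
    if idx.size == 0:
        return idx, np.zeros(0, dtype=int), np.zeros(0, dtype=int)
    _, inverse = np.unique(cc.G[idx], axis=0, return_inverse=True)
    sizes = np.bincount(inverse)
    return idx, inverse, sizes


def kbac_test(
    cc: CaseControlData,
    kernel: str = "hypergeometric",
    n_perm: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> TestResult:
    """Kernel-based adaptive clustering test with permutation p-values.

    statistic = sum_i k_i (n_iA / nA - n_iU / nU) over distinct non-null
    genotype classes, where k_i is the cumulative hypergeometric probability
    of observing at most n_iA cases among the class's carriers; one-sided in
    the risk direction, p by label permutation with class re-counting.
    """
    if kernel != "hypergeometric":
        raise ValueError(f"unsupported kernel {kernel!r}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    _check_two_classes(cc.y)
    rng = rng if rng is not None else np.random.default_rng(0)
    nA = int(cc.y.sum())
    nU = int(cc.n - nA)
    idx, inverse, sizes = _kbac_classes(cc)
    if idx.size == 0:
        warnings.warn("no non-null genotypes; KBAC p-value set to 1")
        return TestResult(0.0, 1.0, "kbac", {"n_classes": 0})
    k = sizes.size
    # per-class cumulative hypergeometric lookup over possible case counts
    cdf_tables = [
        hypergeom.cdf(np.arange(s + 1), cc.n, nA, s) for s in sizes
    ]

    def statistic(case_counts: np.ndarray) -> float:
        s = 0.0
        for i in range(k):
            aA = int(case_counts[i])
            s += cdf_tables[i][aA] * (aA / nA - (sizes[i] - aA) / nU)
        return s

    onehot = np.zeros((idx.size, k))
    onehot[np.arange(idx.size), inverse] = 1.0
    obs_counts = cc.y[idx].astype(float) @ onehot
    T_obs = statistic(obs_counts)

    Y = _permuted_phenotypes(cc.y, n_perm, rng)
    perm_counts = Y[:, idx] @ onehot  # (n_perm, k)
    # vectorized kernel lookup: per class, index its cdf table by the count
    T_perm = np.zeros(n_perm)
    counts_int = perm_counts.astype(int)
    for i in range(k):
        tab = cdf_tables[i]
        aA = counts_int[:, i]
        T_perm += tab[aA] * (aA / nA - (sizes[i] - aA) / nU)
    p = (1.0 + np.sum(T_perm >= T_obs)) / (n_perm + 1.0)
    classes = KbacClasses(
        genotypes=np.unique(cc.G[idx], axis=0),
        case_counts=obs_counts.astype(int),
        control_counts=(sizes - obs_counts).astype(int),
        n_cases=nA,
        n_controls=nU,
        kernel=np.array([cdf_tables[i][int(obs_counts[i])] for i in range(k)]),
    )
    return TestResult(
        float(T_obs), float(p), "kbac", {"n_perm": n_perm, "classes": classes}
    )
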