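"""Family-based score tests on transmission counts.

All five multivariate tests are functionals of a score vector U and its
empirical covariance V built from the per-trio transmission-disequilibrium
rows X (= B - C):

    U = sum_i X_i            V = sum_i (X_i - Xbar)(X_i - Xbar)^T

UminP takes the largest standardized component (joint multivariate-normal
calibration); the score test uses the full (pseudo-inverted) covariance;
SSU and SSUw use none / only the diagonal of V and are calibrated against
the matching eigenvalue mixture of chi-square(1) laws; the sum test
collapses U to one degree of freedom.  The corrected single-SNP TDT
(per-variant (b-c)^2/(b+c) with Bonferroni) is included for comparison.

The same operations serve case-control data through
:func:`famrare.rare_tests.cc_score_components`, which produces a
:class:`ScoreComponents` with the logistic-score U and V.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import chi2, multivariate_normal, norm

from .quadform import mixture_chisq_pvalue
from .transform import TransmissionCounts

__all__ = [
    "ScoreComponents",
    "TestResult",
    "score_components",
    "tdt_single_snp",
    "uminp_test",
    "score_test",
    "ssu_test",
    "ssuw_test",
    "sum_test",
]

_PINV_RTOL = 1e-8


@dataclass
class TestResult:
    """Outcome of one test: statistic, p-value and null-law descriptor."""

    __test__ = False  # not a pytest class, despite the name

    statistic: float
    pvalue: float
    method: str
    df_or_params: Optional[dict] = None

    def __post_init__(self):
        if not np.isfinite(self.statistic):
            raise ValueError("test statistic must be finite")
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass
class ScoreComponents:
    """Score vector U, covariance V, and the centered rows they came from.

    ``rows`` (n x m, optional) are the per-unit contributions whose column
    sums equal U; they enable sign-flip resampling.
    """

    U: np.ndarray
    V: np.ndarray
    n: int
    xbar: np.ndarray
    rows: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def m(self) -> int:
        return self.U.size


def score_components(X: np.ndarray) -> ScoreComponents:
    """U and V from a transmission matrix X (or any n x m score rows)."""
    if isinstance(X, TransmissionCounts):
        X = X.X
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-d matrix")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows to estimate V")
    U = X.sum(axis=0)
    xbar = X.mean(axis=0)
    Xc = X - xbar
    V = Xc.T @ Xc
    return ScoreComponents(U=U, V=V, n=n, xbar=xbar, rows=X)


def tdt_single_snp(tc: TransmissionCounts) -> TestResult:
    """Single-SNP TDT per variant with Bonferroni-corrected global p-value.

    Per variant: chi2_1 statistic (b - c)^2 / (b + c) over the summed minor
    (b) and major (c) transmissions from heterozygous parents; uninformative
    variants (b + c = 0) are excluded from both the minimum and the
    Bonferroni count.
    """
    b = tc.B.sum(axis=0).astype(float)
    c = tc.C.sum(axis=0).astype(float)
    informative = (b + c) > 0
    if not informative.any():
        warnings.warn("no informative transmissions; TDT p-value set to 1")
        return TestResult(0.0, 1.0, "tdt", {"n_informative": 0})
    stats = np.zeros_like(b)
    stats[informative] = (b[informative] - c[informative]) ** 2 / (
        b[informative] + c[informative]
    )
    pvals = np.where(informative, chi2.sf(stats, df=1), 1.0)
    k = int(informative.sum())
    j = int(np.argmin(np.where(informative, pvals, np.inf)))
    p_global = min(1.0, k * pvals[j])
    return TestResult(
        float(stats[j]),
        float(p_global),
        "tdt",
        {"n_informative": k, "per_variant_chi2": stats, "per_variant_p": pvals},
    )


def _informative(sc: ScoreComponents) -> np.ndarray:
    return np.diag(sc.V) > 0


def uminp_test(
    sc: ScoreComponents,
    method: str = "asymptotic",
    n_flips: int = 10_000,
    rng: Optional[np.random.Generator] = None,
) -> TestResult:
    """Maximum standardized single-variant statistic (UminP).

    statistic T = max_j U_j^2 / V_jj.  The asymptotic p-value is the joint
    multivariate-normal rectangle probability 1 - P(all |Z_j| <= sqrt(T))
    with correlation from V (Genz quadrature); for m > 20, or when the
    rectangle integration fails, a sign-flip Monte Carlo calibration of the
    rows is used instead.
    """
    keep = _informative(sc)
    if not keep.any():
        warnings.warn("all variants uninformative; UminP p-value set to 1")
        return TestResult(0.0, 1.0, "uminp")
    U = sc.U[keep]
    V = sc.V[np.ix_(keep, keep)]
    d = np.sqrt(np.diag(V))
    z2 = (U / d) ** 2
    T = float(np.max(z2))
    if T == 0.0:
        return TestResult(0.0, 1.0, "uminp", {"m_informative": int(keep.sum())})
    m = U.size
    if method == "asymptotic" and m <= 20:
        if m == 1:
            p = 2.0 * norm.sf(np.sqrt(T))
            return TestResult(T, float(min(1.0, p)), "uminp", {"m_informative": 1})
        R = V / np.outer(d, d)
        try:
            t = np.sqrt(T)
            rect = multivariate_normal.cdf(
                np.full(m, t),
                mean=np.zeros(m),
                cov=R,
                lower_limit=np.full(m, -t),
                allow_singular=True,
            )
            p = 1.0 - float(rect)
            if np.isfinite(p):
                return TestResult(
                    T, float(np.clip(p, 0.0, 1.0)), "uminp", {"m_informative": m}
                )
        except Exception:  # fall through to sign-flip calibration
            pass
    if sc.rows is None:
        raise ValueError("sign-flip UminP requires ScoreComponents.rows")
    rng = rng if rng is not None else np.random.default_rng(0)
    rows = sc.rows[:, keep]
    signs = rng.choice((-1.0, 1.0), size=(n_flips, rows.shape[0]))
    Ustar = signs @ rows
    Tstar = np.max(Ustar**2 / (d**2)[None, :], axis=1)
    p = (1.0 + np.sum(Tstar >= T)) / (n_flips + 1.0)
    return TestResult(T, float(p), "uminp", {"m_informative": m, "n_flips": n_flips})


def score_test(sc: ScoreComponents) -> TestResult:
    """Full quadratic-form score test T = U' V^- U, chi2 with df = rank(V)."""
    eigval, eigvec = np.linalg.eigh(sc.V)
    tol = _PINV_RTOL * max(eigval.max(), 0.0)
    keep = eigval > tol
    rank = int(keep.sum())
    if rank == 0:
        warnings.warn("V has rank 0; score-test p-value set to 1")
        return TestResult(0.0, 1.0, "score", {"df": 0})
    proj = eigvec[:, keep].T @ sc.U
    T = float(np.sum(proj**2 / eigval[keep]))
    p = float(chi2.sf(T, df=rank))
    return TestResult(T, p, "score", {"df": rank})


def ssu_test(sc: ScoreComponents) -> TestResult:
    """Sum of squared scores T = U'U; null law sum_j lambda_j chi2_1 with
    lambda_j the eigenvalues of V."""
    T = float(sc.U @ sc.U)
    lam = np.linalg.eigvalsh(sc.V)
    lam = lam[lam > 0]
    if lam.size == 0:
        warnings.warn("V is zero; SSU p-value set to 1")
        return TestResult(T, 1.0, "ssu")
    p = mixture_chisq_pvalue(lam, T) if T > 0 else 1.0
    return TestResult(T, float(p), "ssu", {"lambdas": lam})


def ssuw_test(sc: ScoreComponents) -> TestResult:
    """Variance-weighted sum of squares T = U' diag(V)^-1 U over informative
    variants; null law from eigenvalues of the correlation-scaled V."""
    keep = _informative(sc)
    if not keep.any():
        warnings.warn("all variants uninformative; SSUw p-value set to 1")
        return TestResult(0.0, 1.0, "ssuw")
    U = sc.U[keep]
    V = sc.V[np.ix_(keep, keep)]
    d = np.sqrt(np.diag(V))
    T = float(np.sum((U / d) ** 2))
    R = V / np.outer(d, d)
    lam = np.linalg.eigvalsh(R)
    lam = lam[lam > 0]
    p = mixture_chisq_pvalue(lam, T) if T > 0 else 1.0
    return TestResult(T, float(p), "ssuw", {"lambdas": lam})


def sum_test(sc: ScoreComponents) -> TestResult:
    """Burden-style one-df test T = (1'U)^2 / (1'V1), chi-square(1)."""
    denom = float(np.sum(sc.V))
    if denom <= 0:
        warnings.warn("1'V1 = 0; sum-test p-value set to 1")
        return TestResult(0.0, 1.0, "sum")
    T = float(sc.U.sum() ** 2 / denom)
    return TestResult(T, float(chi2.sf(T, df=1)), "sum", {"df": 1})
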