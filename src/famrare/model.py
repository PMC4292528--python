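"""Core domain types and the logistic disease model.

The penetrance model is the standard multi-variant logistic model: a subject
with genotype ``g`` (minor-allele counts per variant) is affected with
probability

    P(affected | g) = expit( logit(c) + sum_i beta_i * g_i )

where ``c`` is the background affection probability for a subject carrying no
minor alleles, and ``beta_i`` is the per-variant log odds ratio.  Variants are
assumed independent and in Hardy-Weinberg equilibrium in the source
population, which makes the population prevalence an exact finite expectation
over per-variant genotype counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "VariantPanel",
    "DiseaseModel",
    "Genotype",
    "hwe_genotype_probs",
    "affection_prob",
    "population_prevalence",
]


@dataclass(frozen=True)
class VariantPanel:
    """A set of biallelic variants with population minor-allele frequencies.

    Parameters
    ----------
    maf : array-like of float
        Minor-allele frequency per variant, each in (0, 0.5].
    labels : sequence of str, optional
        Unique variant identifiers; defaults to ``v1 .. vm``.
    """

    maf: np.ndarray
    labels: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        maf = np.asarray(self.maf, dtype=float)
        if maf.ndim != 1 or maf.size < 1:
            raise ValueError("maf must be a non-empty 1-d array")
        if np.any(maf <= 0) or np.any(maf > 0.5):
            raise ValueError("all MAFs must lie in (0, 0.5]")
        object.__setattr__(self, "maf", maf)
        labels = self.labels
        if labels is None:
            labels = tuple(f"v{j + 1}" for j in range(maf.size))
        else:
            labels = tuple(str(l) for l in labels)
            if len(labels) != maf.size:
                raise ValueError("labels must have one entry per variant")
            if len(set(labels)) != len(labels):
                raise ValueError("labels must be unique")
        object.__setattr__(self, "labels", labels)

    @property
    def m(self) -> int:
        """Number of variants."""
        return int(self.maf.size)


@dataclass(frozen=True)
class DiseaseModel:
    """Logistic penetrance model: background risk plus per-variant log-ORs.

    ``beta[i] == 0`` encodes a non-causal variant.  ``affection_prob`` for the
    all-zero genotype equals ``c`` exactly.
    """

    c: float
    beta: np.ndarray

    def __post_init__(self):
        if not (0.0 < self.c < 1.0):
            raise ValueError("background risk c must lie in (0, 1)")
        beta = np.asarray(self.beta, dtype=float)
        if beta.ndim != 1:
            raise ValueError("beta must be a 1-d array")
        if not np.all(np.isfinite(beta)):
            raise ValueError("beta must be finite")
        object.__setattr__(self, "beta", beta)

    @property
    def m(self) -> int:
        return int(self.beta.size)

    @property
    def odds_ratios(self) -> np.ndarray:
        """Per-variant odds ratios exp(beta)."""
        return np.exp(self.beta)

    @classmethod
    def from_odds_ratios(cls, c: float, odds_ratios: Sequence[float]) -> "DiseaseModel":
        return cls(c=c, beta=np.log(np.asarray(odds_ratios, dtype=float)))


@dataclass(frozen=True)
class Genotype:
    """Minor-allele counts per variant, each in {0, 1, 2}."""

    g: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.g)
        if g.ndim != 1:
            raise ValueError("genotype must be a 1-d vector")
        if not np.all(np.isin(g, (0, 1, 2))):
            raise ValueError("genotype entries must be in {0, 1, 2}")
        object.__setattr__(self, "g", g.astype(np.int8))


def hwe_genotype_probs(q: float | np.ndarray) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities (P(0), P(1), P(2)) for MAF q."""
    q = np.asarray(q, dtype=float)
    return np.stack([(1 - q) ** 2, 2 * q * (1 - q), q**2], axis=-1)


def _as_matrix(geno) -> np.ndarray:
    if isinstance(geno, Genotype):
        return geno.g[None, :]
    g = np.asarray(geno)
    return g[None, :] if g.ndim == 1 else g


def affection_prob(model: DiseaseModel, geno) -> float | np.ndarray:
    """Penetrance of one or more genotypes under the logistic model.

    Accepts a :class:`Genotype`, a length-m vector, or an (n, m) matrix;
    returns a scalar or length-n vector accordingly.
    """
    G = _as_matrix(geno)
    if G.shape[1] != model.m:
        raise ValueError(
            f"genotype has {G.shape[1]} variants but model expects {model.m}"
        )
    p = expit(logit(model.c) + G @ model.beta)
    if isinstance(geno, Genotype) or np.asarray(geno).ndim == 1:
        return float(p[0])
    return p


def population_prevalence(model: DiseaseModel, panel: VariantPanel) -> float:
    """Exact disease prevalence under HWE with independent variants.

    Computed by exact enumeration: variants are grouped by identical
    (MAF, beta) pairs; within a group the total minor-allele count follows a
    convolution of HWE genotype distributions, and groups combine by an outer
    product over their count distributions.  Non-causal groups (beta == 0)
    contribute a factor of 1 and are skipped.
    """
    if panel.m != model.m:
        raise ValueError("panel and model dimensions differ")
    # group variants by (q, beta); only causal groups affect the risk score
    groups: dict[tuple[float, float], int] = {}
    for q, b in zip(panel.maf, model.beta):
        groups[(float(q), float(b))] = groups.get((float(q), float(b)), 0) + 1

    # distribution of the linear predictor offset sum(beta_i g_i)
    scores = np.array([0.0])
    probs = np.array([1.0])
    for (q, b), r in groups.items():
        if b == 0.0:
            continue
        per = hwe_genotype_probs(q)  # counts 0,1,2
        dist = np.array([1.0])
        for _ in range(r):
            dist = np.convolve(dist, per)
        counts = np.arange(dist.size)
        scores = (scores[:, None] + b * counts[None, :]).ravel()
        probs = (probs[:, None] * dist[None, :]).ravel()
    prev = float(np.sum(probs * expit(logit(model.c) + scores)))
    return prev
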