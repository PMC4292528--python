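"""Simulation of ascertained nuclear families and unrelated controls.

Families are sampled *conditionally on affection of the offspring* (one
affected child for trios, both for affected sib-pairs).  Naive rejection
sampling is exact but costs O(1/prevalence) parent draws per trio and
O(1/prevalence^2) per ASP, which is prohibitive at ~1% prevalence.  The
default sampler is therefore an exact tilted sampler:

1. enumerate parental carrier configurations (the per-variant pair of
   parental genotypes) up to a total parental minor-allele count ``k``
   (rare-variant mass beyond ``k`` is negligible and is folded into the
   zero-carrier configuration; the residual is checked against a bound);
2. compute each configuration's ascertainment probability by summing the
   logistic penetrance over its Mendelian child outcomes;
3. sample configurations from the ascertainment-tilted distribution, then
   child genotypes from the conditional (affected) distribution.

The output distribution matches naive rejection sampling exactly up to the
(checked) truncation residual; the rejection sampler is retained as a
validation oracle and for high-prevalence models.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit, logit

from .model import DiseaseModel, VariantPanel, affection_prob, hwe_genotype_probs

__all__ = [
    "FamilySample",
    "CohortSample",
    "StratumSpec",
    "AscertainedFamilySampler",
    "sample_parents",
    "mendelian_transmit",
    "simulate_families",
    "simulate_controls",
    "simulate_stratified",
]

STRUCTURES = ("trio", "asp", "enriched_trio")
_CHILDREN_PER_FAMILY = {"trio": 1, "asp": 2, "enriched_trio": 1}


@dataclass
class FamilySample:
    """Ascertained nuclear families: parental and offspring genotypes.

    ``children_g`` has shape (n_families, children_per_family, m); all
    retained children are affected by construction.  ``transmitted`` (when
    present, rejection sampler only) records the per-parent transmitted
    minor-allele indicator with the same shape as ``children_g`` for each
    parent; it is used only as a cross-check of the transmission counting
    rule.
    """

    structure: str
    father_g: np.ndarray
    mother_g: np.ndarray
    children_g: np.ndarray
    stratum: Optional[np.ndarray] = None
    transmitted: Optional[tuple[np.ndarray, np.ndarray]] = None

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown family structure {self.structure!r}")
        if self.children_g.ndim != 3:
            raise ValueError("children_g must be (n_families, n_children, m)")
        k = _CHILDREN_PER_FAMILY[self.structure]
        if self.children_g.shape[1] != k:
            raise ValueError(
                f"{self.structure} families need {k} child(ren) per family"
            )

    @property
    def n_families(self) -> int:
        return self.father_g.shape[0]

    @property
    def n_children(self) -> int:
        return self.children_g.shape[1]

    @property
    def m(self) -> int:
        return self.father_g.shape[1]


@dataclass
class CohortSample:
    """Unrelated subjects: genotype matrix, affection flags, optional strata."""

    genotypes: np.ndarray
    phenotype: np.ndarray
    stratum: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def m(self) -> int:
        return self.genotypes.shape[1]


@dataclass(frozen=True)
class StratumSpec:
    """One sub-population: sampling weight, variant panel and disease model."""

    weight: float
    panel: VariantPanel
    model: DiseaseModel


def sample_parents(
    panel: VariantPanel, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n independent (father, mother) genotype pairs from HWE."""
    if n < 1:
        raise ValueError("n must be >= 1")
    shape = (n, panel.m)
    father = rng.binomial(2, panel.maf, size=shape).astype(np.int8)
    mother = rng.binomial(2, panel.maf, size=shape).astype(np.int8)
    return father, mother


def mendelian_transmit(
    father_g: np.ndarray, mother_g: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Transmit one allele per parent per variant to a child.

    Homozygous parents transmit their sole allele; heterozygous parents
    transmit the minor or major allele with probability 1/2 each.  Returns
    the child genotype(s) and the per-parent transmitted-minor indicators
    (the record used as a cross-check by the transform module).
    """
    f = np.atleast_2d(np.asarray(father_g))
    m = np.atleast_2d(np.asarray(mother_g))
    tf = np.where(f == 1, rng.integers(0, 2, size=f.shape), f // 2).astype(np.int8)
    tm = np.where(m == 1, rng.integers(0, 2, size=m.shape), m // 2).astype(np.int8)
    child = (tf + tm).astype(np.int8)
    if np.asarray(father_g).ndim == 1:
        return child[0], (tf[0], tm[0])
    return child, (tf, tm)


# per-parent-genotype probability of transmitting the minor allele
_TRANSMIT_MINOR = np.array([0.0, 0.5, 1.0])


def _child_dist(gf: int, gm: int) -> tuple[np.ndarray, np.ndarray]:
    """Support and probabilities of the child genotype given parents at one
    variant."""
    pf, pm = _TRANSMIT_MINOR[gf], _TRANSMIT_MINOR[gm]
    probs = np.zeros(3)
    for a, pa in ((0, 1 - pf), (1, pf)):
        for b, pb in ((0, 1 - pm), (1, pm)):
            probs[a + b] += pa * pb
    support = np.nonzero(probs)[0]
    return support, probs[support]


class _ResidualTooLarge(Exception):
    """Internal: enumeration budget too small for the requested tolerance."""


class AscertainedFamilySampler:
    """Exact tilted sampler for families ascertained on affected offspring.

    Parameters
    ----------
    panel, model : the variant panel and logistic disease model.
    structure : 'trio', 'asp' or 'enriched_trio'.
    max_parent_alleles : int
        Parental configurations are enumerated up to this total minor-allele
        count over both parents and all variants (default 4, ample for
        rare variants); the prior mass beyond it is folded into the
        zero-carrier configuration.  If the truncation residual exceeds
        ``residual_tol`` the budget is increased automatically (up to full
        enumeration) while the configuration count stays tractable.
    """

    _MAX_CONFIGS = 500_000

    def __init__(
        self,
        panel: VariantPanel,
        model: DiseaseModel,
        structure: str,
        max_parent_alleles: int = 4,
        residual_tol: float = 1e-4,
    ):
        if structure not in STRUCTURES:
            raise ValueError(f"unknown family structure {structure!r}")
        if panel.m != model.m:
            raise ValueError("panel and model dimensions differ")
        self.panel = panel
        self.model = model
        self.structure = structure
        k = int(max_parent_alleles)
        while True:
            try:
                self._build(k, residual_tol)
                break
            except _ResidualTooLarge:
                if k >= 4 * panel.m:
                    raise ValueError(
                        f"truncation residual {self.residual:.3g} exceeds "
                        f"{residual_tol:g} even at full enumeration; "
                        "use the rejection sampler"
                    )
                k = min(k + 2, 4 * panel.m)
        self.max_parent_alleles = k

    def _build(self, max_parent_alleles: int, residual_tol: float) -> None:
        panel, model, structure = self.panel, self.model, self.structure
        m = panel.m

        # per-variant parental-state priors under HWE
        hwe = hwe_genotype_probs(panel.maf)  # (m, 3)
        zero_prior = float(np.prod(hwe[:, 0] ** 2))

        # nonzero per-variant states (gf, gm) with gf+gm >= 1
        states = [(gf, gm) for gf in range(3) for gm in range(3) if gf + gm >= 1]
        child_dists = {s: _child_dist(*s) for s in states}

        # DFS over variants assigning nonzero states within the allele budget
        configs: list[list[tuple[int, int, int]]] = []  # [(variant, gf, gm), ...]

        def _extend(start: int, budget: int, current: list):
            if len(configs) > self._MAX_CONFIGS:
                raise ValueError(
                    "parental-configuration enumeration too large; "
                    "use the rejection sampler"
                )
            configs.append(list(current))
            for j in range(start, m):
                for gf, gm in states:
                    cost = gf + gm
                    if cost <= budget:
                        current.append((j, gf, gm))
                        _extend(j + 1, budget - cost, current)
                        current.pop()

        _extend(0, max_parent_alleles, [])

        K = len(configs)
        fathers = np.zeros((K, m), dtype=np.int8)
        mothers = np.zeros((K, m), dtype=np.int8)
        priors = np.empty(K)
        asc = np.empty(K)  # P(one child affected | config)
        self._child_rows: list[np.ndarray] = []
        self._child_cond: list[np.ndarray] = []

        base_logit = logit(model.c)
        for i, cfg in enumerate(configs):
            prior = zero_prior
            for j, gf, gm in cfg:
                fathers[i, j] = gf
                mothers[i, j] = gm
                prior *= hwe[j, gf] * hwe[j, gm] / (hwe[j, 0] ** 2)
            priors[i] = prior
            # enumerate joint Mendelian child outcomes at the nonzero variants
            if cfg:
                var_idx = [j for j, _, _ in cfg]
                supports = [child_dists[(gf, gm)] for _, gf, gm in cfg]
                combos = list(itertools.product(*(range(len(s[0])) for s in supports)))
                rows = np.zeros((len(combos), m), dtype=np.int8)
                mprob = np.ones(len(combos))
                for r, combo in enumerate(combos):
                    for (jj, (sup, pr)), pick in zip(
                        zip(var_idx, supports), combo
                    ):
                        rows[r, jj] = sup[pick]
                        mprob[r] *= pr[pick]
            else:
                rows = np.zeros((1, m), dtype=np.int8)
                mprob = np.ones(1)
            paff = expit(base_logit + rows.astype(float) @ model.beta)
            e = float(np.sum(mprob * paff))
            asc[i] = e
            cond = mprob * paff / e
            self._child_rows.append(rows)
            self._child_cond.append(cond)

        residual = 1.0 - priors.sum()
        # config 0 is the empty (zero-carrier) configuration by construction
        self.residual = residual
        if residual > residual_tol and max_parent_alleles < 4 * m:
            raise _ResidualTooLarge
        priors[0] += max(residual, 0.0)

        power = 2 if structure == "asp" or structure == "enriched_trio" else 1
        weights = priors * asc**power
        total = weights.sum()
        if total <= 0:
            raise ValueError("ascertainment probability is zero under this model")
        self._fathers = fathers
        self._mothers = mothers
        self._weights = weights / total
        self.ascertainment_prob = float(total)

    def sample(self, n_families: int, rng: np.random.Generator) -> FamilySample:
        if n_families < 1:
            raise ValueError("n_families must be >= 1")
        m = self.panel.m
        n_children = _CHILDREN_PER_FAMILY[self.structure]
        # enriched trios: an ASP is simulated and one affected child retained;
        # children of an ASP are conditionally iid given the configuration, so
        # retaining one child just draws a single outcome per family.
        idx = rng.choice(self._weights.size, size=n_families, p=self._weights)
        father = self._fathers[idx].copy()
        mother = self._mothers[idx].copy()
        children = np.zeros((n_families, n_children, m), dtype=np.int8)
        for cfg in np.unique(idx):
            where = np.nonzero(idx == cfg)[0]
            rows = self._child_rows[cfg]
            cond = self._child_cond[cfg]
            if rows.shape[0] == 1:
                children[where] = rows[0]
            else:
                picks = rng.choice(
                    rows.shape[0], size=(where.size, n_children), p=cond
                )
                children[where] = rows[picks]
        return FamilySample(
            structure=self.structure,
            father_g=father,
            mother_g=mother,
            children_g=children,
        )


_SAMPLER_CACHE: dict[tuple, AscertainedFamilySampler] = {}


def _cached_sampler(
    panel: VariantPanel, model: DiseaseModel, structure: str, max_parent_alleles: int
) -> AscertainedFamilySampler:
    key = (
        structure,
        max_parent_alleles,
        panel.maf.tobytes(),
        model.beta.tobytes(),
        model.c,
    )
    sampler = _SAMPLER_CACHE.get(key)
    if sampler is None:
        sampler = AscertainedFamilySampler(panel, model, structure, max_parent_alleles)
        if len(_SAMPLER_CACHE) > 64:
            _SAMPLER_CACHE.clear()
        _SAMPLER_CACHE[key] = sampler
    return sampler


def _simulate_families_rejection(
    structure: str,
    n_families: int,
    panel: VariantPanel,
    model: DiseaseModel,
    rng: np.random.Generator,
    max_attempts: int,
) -> FamilySample:
    n_children = _CHILDREN_PER_FAMILY[structure]
    m = panel.m
    fa, mo, ch = [], [], []
    tfs, tms = [], []
    accepted = 0
    attempts = 0
    batch = max(1024, 4 * n_families)
    while accepted < n_families:
        if attempts > max_attempts:
            raise RuntimeError(
                f"rejection sampler exceeded {max_attempts} attempts; "
                "ascertainment probability too small"
            )
        father, mother = sample_parents(panel, batch, rng)
        # ASP and enriched trios require both of two children affected
        draws = 2 if structure in ("asp", "enriched_trio") else 1
        kids, recs, ok = [], [], np.ones(batch, dtype=bool)
        for _ in range(draws):
            child, (tf, tm) = mendelian_transmit(father, mother, rng)
            p = affection_prob(model, child)
            ok &= rng.random(batch) < p
            kids.append(child)
            recs.append((tf, tm))
        attempts += batch
        keep = np.nonzero(ok)[0]
        if keep.size:
            fa.append(father[keep])
            mo.append(mother[keep])
            ch.append(np.stack([k[keep] for k in kids[:n_children]], axis=1))
            tfs.append(np.stack([r[0][keep] for r in recs[:n_children]], axis=1))
            tms.append(np.stack([r[1][keep] for r in recs[:n_children]], axis=1))
            accepted += keep.size
    father = np.concatenate(fa)[:n_families]
    mother = np.concatenate(mo)[:n_families]
    children = np.concatenate(ch)[:n_families]
    tf = np.concatenate(tfs)[:n_families]
    tm = np.concatenate(tms)[:n_families]
    return FamilySample(
        structure=structure,
        father_g=father,
        mother_g=mother,
        children_g=children,
        transmitted=(tf, tm),
    )


def simulate_families(
    structure: str,
    n_families: int,
    panel: VariantPanel,
    model: DiseaseModel,
    rng: np.random.Generator,
    method: str = "tilted",
    max_parent_alleles: int = 4,
    max_attempts: int = 10**6,
) -> FamilySample:
    """Simulate families ascertained on affected offspring.

    structure 'trio': one affected child; 'asp': both of two children
    affected; 'enriched_trio': simulate an ASP and retain one affected child.
    ``method`` is 'tilted' (exact enumeration-based sampler, default) or
    'rejection' (naive oracle; also records transmitted alleles).
    """
    if structure not in STRUCTURES:
        raise ValueError(f"unknown family structure {structure!r}")
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if method == "tilted":
        sampler = _cached_sampler(panel, model, structure, max_parent_alleles)
        return sampler.sample(n_families, rng)
    if method == "rejection":
        return _simulate_families_rejection(
            structure, n_families, panel, model, rng, max_attempts
        )
    raise ValueError(f"unknown method {method!r}")


def simulate_controls(
    panel: VariantPanel,
    model: DiseaseModel,
    n: int,
    rng: np.random.Generator,
    screened: bool = True,
    max_attempts: int = 10**6,
) -> CohortSample:
    """Sample unrelated control subjects from the population.

    With ``screened=True`` (default) affected subjects are rejected, so the
    controls are unaffected; at ~1% prevalence this differs negligibly from
    unscreened population controls.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    G = rng.binomial(2, panel.maf, size=(n, panel.m)).astype(np.int8)
    if not screened:
        y = (rng.random(n) < affection_prob(model, G)).astype(np.int8)
        return CohortSample(genotypes=G, phenotype=y)
    attempts = n
    affected = rng.random(n) < affection_prob(model, G)
    while affected.any():
        if attempts > max_attempts:
            raise RuntimeError(
                f"control screening exceeded {max_attempts} attempts; "
                "is the model's affection probability near 1?"
            )
        k = int(affected.sum())
        idx = np.nonzero(affected)[0]
        G[idx] = rng.binomial(2, panel.maf, size=(k, panel.m)).astype(np.int8)
        affected[idx] = rng.random(k) < affection_prob(model, G[idx])
        attempts += k
    return CohortSample(genotypes=G, phenotype=np.zeros(n, dtype=np.int8))


def simulate_stratified(
    strata: Sequence[StratumSpec],
    structure: str,
    n_families: int,
    n_controls: int,
    rng: np.random.Generator,
    **kwargs,
) -> tuple[FamilySample, CohortSample]:
    """Simulate families and controls from a mixture of sub-populations.

    Each family (and each control) is drawn wholly from one stratum, strata
    being chosen in proportion to their weights; stratum labels are retained.
    """
    weights = np.array([s.weight for s in strata], dtype=float)
    if not np.isclose(weights.sum(), 1.0, atol=1e-9):
        raise ValueError("stratum weights must sum to 1")
    fam_counts = rng.multinomial(n_families, weights)
    ctl_counts = rng.multinomial(n_controls, weights) if n_controls else np.zeros(
        len(strata), dtype=int
    )
    fams, fam_labels = [], []
    ctls, ctl_labels = [], []
    for lab, (spec, nf, nc) in enumerate(zip(strata, fam_counts, ctl_counts)):
        if nf:
            f = simulate_families(structure, int(nf), spec.panel, spec.model, rng, **kwargs)
            fams.append(f)
            fam_labels.append(np.full(int(nf), lab))
        if nc:
            c = simulate_controls(spec.panel, spec.model, int(nc), rng)
            ctls.append(c)
            ctl_labels.append(np.full(int(nc), lab))
    fam = FamilySample(
        structure=structure,
        father_g=np.concatenate([f.father_g for f in fams]),
        mother_g=np.concatenate([f.mother_g for f in fams]),
        children_g=np.concatenate([f.children_g for f in fams]),
        stratum=np.concatenate(fam_labels),
    )
    if ctls:
        cohort = CohortSample(
            genotypes=np.concatenate([c.genotypes for c in ctls]),
            phenotype=np.concatenate([c.phenotype for c in ctls]),
            stratum=np.concatenate(ctl_labels),
        )
    else:
        cohort = CohortSample(
            genotypes=np.zeros((0, strata[0].panel.m), dtype=np.int8),
            phenotype=np.zeros(0, dtype=np.int8),
        )
    return fam, cohort
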