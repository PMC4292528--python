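"""Scenario definitions, the replication engine and power estimation.

A :class:`ScenarioConfig` describes one simulation scenario (family
structure, panel, disease model, test roster, replicate budget).  Each
replicate simulates one ascertained family sample (plus unrelated controls
when any UCC test is requested), builds the family / pseudo-case-control /
unrelated-case-control datasets *from the same families* — mimicking the
choices available with real data — and runs the selected tests.  Rejection
proportions at the scenario's alpha, with binomial Monte-Carlo standard
errors, form the :class:`ResultTable`.

Replicates draw their randomness from per-replicate substreams derived
deterministically from (seed, replicate index), so results are independent
of execution order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import family_tests as ft
from . import rare_tests as rt
from .model import DiseaseModel, VariantPanel
from .simulate import (
    _CHILDREN_PER_FAMILY,
    StratumSpec,
    simulate_controls,
    simulate_families,
    simulate_stratified,
)
from .transform import cluster_related, extract_transmissions, make_pcc, make_ucc

__all__ = [
    "TestSpec",
    "ScenarioConfig",
    "ResultTable",
    "default_roster",
    "run_replicate",
    "estimate_power",
    "calibrate_or",
    "scenario_battery",
    "BASELINE_OR",
]

#: Baseline odds ratios that give ~90% power for the best test per structure.
BASELINE_OR = {"trio": 2.00, "asp": 1.72, "enriched_trio": 1.54}

FAMILY_TEST_NAMES = ("tdt", "uminp", "ssu", "ssuw", "score", "sum")
CC_TEST_NAMES = (
    "assoc",
    "uminp",
    "ssu",
    "ssuw",
    "score",
    "sum",
    "calpha",
    "calpha_perm",
    "skat",
    "kbac",
)


@dataclass(frozen=True)
class TestSpec:
    """One roster entry: a test applied to one data format.

    data_format is 'family', 'pcc' or 'ucc'; ``cluster`` requests summing of
    related cases (and matched controls) before testing.
    """

    __test__ = False  # not a pytest class, despite the name

    test: str
    data_format: str
    cluster: bool = False

    def __post_init__(self):
        if self.data_format not in ("family", "pcc", "ucc"):
            raise ValueError(f"unknown data format {self.data_format!r}")
        names = FAMILY_TEST_NAMES if self.data_format == "family" else CC_TEST_NAMES
        if self.test not in names:
            raise ValueError(
                f"test {self.test!r} not available for {self.data_format} data"
            )

    @property
    def key(self) -> str:
        return f"{self.test}:{self.data_format}" + (":cl" if self.cluster else "")


def default_roster(structure: str, include_ucc: bool = True) -> list[TestSpec]:
    """The full test battery: six family tests, nine case-control tests on
    PCC and (optionally) UCC data.

    For ASP-derived data, score tests on UCC data are additionally run with
    clustering (the configuration whose type-I error is controlled).
    """
    roster = [TestSpec(t, "family") for t in FAMILY_TEST_NAMES]
    cc = [t for t in CC_TEST_NAMES if t != "calpha"]  # permutation C-alpha
    roster += [TestSpec(t, "pcc") for t in cc]
    if include_ucc:
        roster += [TestSpec(t, "ucc") for t in cc]
        if structure == "asp":
            for t in ("uminp", "ssu", "ssuw", "score", "sum"):
                roster.append(TestSpec(t, "ucc", cluster=True))
    return roster


@dataclass
class ScenarioConfig:
    """All parameters of one simulation scenario."""

    structure: str = "trio"
    n_cases: int = 1200
    m: int = 10
    maf: float | Sequence[float] = 0.005
    causal_idx: Sequence[int] = (0, 1, 2, 3)
    or_values: float | Sequence[float] = 2.0
    c: float = 0.01
    n_controls: Optional[int] = None  # UCC controls; defaults to n_cases
    alpha: float = 0.05
    n_reps: int = 1000
    n_perm: int = 1000
    seed: int = 0
    strata: Optional[Sequence[StratumSpec]] = None
    tests: Optional[Sequence[TestSpec]] = None

    def __post_init__(self):
        # normalize sequence fields so configs round-trip through YAML
        self.causal_idx = tuple(int(j) for j in self.causal_idx)
        if not np.isscalar(self.or_values):
            self.or_values = tuple(float(v) for v in self.or_values)
        if not np.isscalar(self.maf):
            self.maf = tuple(float(q) for q in self.maf)
        if self.tests is not None:
            self.tests = list(self.tests)
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        k = _CHILDREN_PER_FAMILY[self.structure]
        if self.n_cases % k:
            raise ValueError(
                f"n_cases must be divisible by {k} for {self.structure} families"
            )
        if any(j < 0 or j >= self.m for j in self.causal_idx):
            raise ValueError("causal_idx out of range")

    @property
    def n_families(self) -> int:
        return self.n_cases // _CHILDREN_PER_FAMILY[self.structure]

    def panel(self) -> VariantPanel:
        maf = np.broadcast_to(np.asarray(self.maf, dtype=float), (self.m,))
        return VariantPanel(maf=maf.copy())

    def disease_model(self) -> DiseaseModel:
        beta = np.zeros(self.m)
        ors = np.broadcast_to(
            np.asarray(self.or_values, dtype=float), (len(self.causal_idx),)
        )
        beta[list(self.causal_idx)] = np.log(ors)
        return DiseaseModel(c=self.c, beta=beta)

    def roster(self) -> list[TestSpec]:
        if self.tests is not None:
            return list(self.tests)
        return default_roster(self.structure)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["causal_idx"] = list(self.causal_idx)
        d["or_values"] = (
            list(np.atleast_1d(self.or_values).astype(float))
            if not np.isscalar(self.or_values)
            else float(self.or_values)
        )
        if self.tests is not None:
            d["tests"] = [dataclasses.asdict(t) for t in self.tests]
        d.pop("strata")  # strata are programmatic objects, not serialized
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ScenarioConfig":
        d = yaml.safe_load(text)
        if "tests" in d and d["tests"] is not None:
            d["tests"] = [TestSpec(**t) for t in d["tests"]]
        return cls(**d)


@dataclass
class ResultTable:
    """Per-(test, data format) rejection proportions with MC standard errors."""

    table: pd.DataFrame  # columns: structure, data_format, test, cluster,
    #          n_reps, rejections, proportion, mc_se
    alpha: float

    def pivot(self) -> pd.DataFrame:
        """Tests x data-format layout for eyeball comparison."""
        return self.table.pivot_table(
            index="test", columns="data_format", values="proportion", sort=False
        )

    def __getitem__(self, key: str) -> float:
        row = self.table[self.table.key == key]
        if row.empty:
            raise KeyError(key)
        return float(row.proportion.iloc[0])


def _replicate_rng(seed: int, rep_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, rep_index]))


def _run_cc_battery(
    cc, specs: list[TestSpec], n_perm: int, rng: np.random.Generator
) -> dict[str, float]:
    """Run the requested case-control tests on one dataset variant."""
    out: dict[str, float] = {}
    score_specs = [s for s in specs if s.test in ("uminp", "ssu", "ssuw", "score", "sum")]
    if score_specs:
        sc = rt.cc_score_components(cc)
        for s in score_specs:
            fn = {
                "uminp": ft.uminp_test,
                "ssu": ft.ssu_test,
                "ssuw": ft.ssuw_test,
                "score": ft.score_test,
                "sum": ft.sum_test,
            }[s.test]
            if s.test == "uminp":
                out[s.key] = fn(sc, rng=rng).pvalue
            else:
                out[s.key] = fn(sc).pvalue
    for s in specs:
        if s.test == "assoc":
            out[s.key] = rt.single_snp_association(cc).pvalue
        elif s.test == "calpha":
            out[s.key] = rt.calpha_statistic(cc).pvalue
        elif s.test == "calpha_perm":
            out[s.key] = rt.calpha_permutation(cc, n_perm=n_perm, rng=rng).pvalue
        elif s.test == "skat":
            out[s.key] = rt.skat_test(cc).pvalue
        elif s.test == "kbac":
            out[s.key] = rt.kbac_test(cc, n_perm=n_perm, rng=rng).pvalue
    return out


def run_replicate(cfg: ScenarioConfig, rep_index: int) -> dict[str, float]:
    """Simulate one replicate and return p-values keyed by TestSpec.key.

    Family, PCC and UCC datasets are all built from the same simulated
    families; UCC additionally simulates unrelated (screened) controls.
    """
    rng = _replicate_rng(cfg.seed, rep_index)
    roster = cfg.roster()
    try:
        if cfg.strata is not None:
            n_controls = cfg.n_controls if cfg.n_controls is not None else cfg.n_cases
            need_ucc = any(s.data_format == "ucc" for s in roster)
            fam, controls = simulate_stratified(
                cfg.strata,
                cfg.structure,
                cfg.n_families,
                n_controls if need_ucc else 0,
                rng,
            )
        else:
            panel, model = cfg.panel(), cfg.disease_model()
            fam = simulate_families(cfg.structure, cfg.n_families, panel, model, rng)
            controls = None

        out: dict[str, float] = {}
        fam_specs = [s for s in roster if s.data_format == "family"]
        if fam_specs:
            tc = extract_transmissions(fam)
            sc = ft.score_components(tc.X)
            for s in fam_specs:
                if s.test == "tdt":
                    out[s.key] = ft.tdt_single_snp(tc).pvalue
                else:
                    fn = {
                        "uminp": ft.uminp_test,
                        "ssu": ft.ssu_test,
                        "ssuw": ft.ssuw_test,
                        "score": ft.score_test,
                        "sum": ft.sum_test,
                    }[s.test]
                    out[s.key] = (
                        fn(sc, rng=rng).pvalue if s.test == "uminp" else fn(sc).pvalue
                    )

        for fmt in ("pcc", "ucc"):
            fmt_specs = [s for s in roster if s.data_format == fmt]
            if not fmt_specs:
                continue
            if fmt == "pcc":
                cc = make_pcc(fam)
            else:
                if controls is None:
                    n_controls = (
                        cfg.n_controls if cfg.n_controls is not None else cfg.n_cases
                    )
                    controls = simulate_controls(panel, model, n_controls, rng)
                cc = make_ucc(fam, controls)
            for clustered in (False, True):
                group = [s for s in fmt_specs if s.cluster is clustered]
                if not group:
                    continue
                data = cluster_related(cc) if clustered else cc
                out.update(_run_cc_battery(data, group, cfg.n_perm, rng))
        return out
    except Exception as exc:
        raise RuntimeError(f"replicate {rep_index} failed: {exc}") from exc


def estimate_power(cfg: ScenarioConfig, progress=None) -> ResultTable:
    """Rejection proportion of each test at cfg.alpha over cfg.n_reps
    replicates (strict inequality p < alpha counts as rejection)."""
    if cfg.n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    keys = [s.key for s in cfg.roster()]
    rejections = {k: 0 for k in keys}
    for rep in range(cfg.n_reps):
        pvals = run_replicate(cfg, rep)
        for k in keys:
            if pvals[k] < cfg.alpha:
                rejections[k] += 1
        if progress is not None:
            progress(rep)
    rows = []
    for s in cfg.roster():
        r = rejections[s.key]
        prop = r / cfg.n_reps
        rows.append(
            {
                "structure": cfg.structure,
                "data_format": s.data_format + (":cl" if s.cluster else ""),
                "test": s.test,
                "cluster": s.cluster,
                "key": s.key,
                "n_reps": cfg.n_reps,
                "rejections": r,
                "proportion": prop,
                "mc_se": float(np.sqrt(prop * (1 - prop) / cfg.n_reps)),
            }
        )
    return ResultTable(table=pd.DataFrame(rows), alpha=cfg.alpha)


def calibrate_or(
    cfg: ScenarioConfig,
    target_power: float = 0.90,
    tol: float = 0.02,
    reps: int = 200,
    or_max: float = 5.0,
    max_iter: int = 12,
) -> tuple[float, float]:
    """Find the shared causal OR at which the most powerful test reaches
    ``target_power``, by coarse monotone scan then bisection.

    Power is estimated at ``reps`` replicates per evaluation (the calibrated
    OR is itself a Monte-Carlo quantity).  Returns (OR, achieved power).
    """
    if not cfg.causal_idx:
        raise ValueError("calibration needs at least one causal variant")

    def max_power(or_value: float) -> float:
        c = dataclasses.replace(cfg, or_values=or_value, n_reps=reps)
        tab = estimate_power(c).table
        return float(tab.proportion.max())

    lo, hi = 1.0, or_max
    p_lo = max_power(lo)
    if p_lo >= target_power:  # degenerate: null power already meets target
        return lo, p_lo
    # coarse scan to bracket the target (power is monotone in OR)
    grid = np.linspace(lo, hi, 6)
    prev_or, prev_p = lo, p_lo
    bracket = None
    for g in grid[1:]:
        p = max_power(float(g))
        if p >= target_power:
            bracket = (prev_or, g, prev_p, p)
            break
        prev_or, prev_p = float(g), p
    if bracket is None:
        raise ValueError(f"target power {target_power} not reached by OR {or_max}")
    lo, hi, p_lo, p_hi = bracket
    best = (hi, p_hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        p_mid = max_power(mid)
        if abs(p_mid - target_power) < abs(best[1] - target_power):
            best = (mid, p_mid)
        if abs(p_mid - target_power) <= tol:
            return mid, p_mid
        if p_mid < target_power:
            lo = mid
        else:
            hi = mid
    return best


_BATTERY_KINDS = (
    "null",
    "baseline",
    "causal_count",
    "total_variants",
    "or_sweep_1",
    "or_sweep_4",
    "protective",
    "fluctuation",
    "stratified",
    "subsample",
)


def scenario_battery(
    kind: str, strata: Optional[Sequence[StratumSpec]] = None, **overrides
) -> list[ScenarioConfig]:
    """Emit the scenario family of the given kind for all three family
    structures, with shared parameters fixed to the baseline (10 variants,
    MAF 0.5%, prevalence ~1%, 1200 cases, 1000 replicates, alpha 0.05).

    Stratified scenarios require user-supplied stratum specifications.
    """
    if kind not in _BATTERY_KINDS:
        raise ValueError(f"unknown battery kind {kind!r}")

    def base(structure: str, **kw) -> ScenarioConfig:
        params = dict(
            structure=structure,
            or_values=BASELINE_OR[structure],
        )
        params.update(kw)
        params.update(overrides)
        return ScenarioConfig(**params)

    out: list[ScenarioConfig] = []
    for structure in ("trio", "asp", "enriched_trio"):
        if kind == "null":
            out.append(base(structure, causal_idx=(), or_values=()))
        elif kind == "baseline":
            out.append(base(structure))
        elif kind == "causal_count":
            for k in range(1, 11):
                out.append(base(structure, causal_idx=tuple(range(k))))
        elif kind == "total_variants":
            for m in (10, 20, 30, 40, 50):
                out.append(base(structure, m=m))
        elif kind in ("or_sweep_1", "or_sweep_4"):
            k = 1 if kind == "or_sweep_1" else 4
            for or_value in np.arange(1.0, 3.01, 0.25):
                out.append(
                    base(
                        structure,
                        causal_idx=tuple(range(k)),
                        or_values=float(or_value),
                    )
                )
        elif kind == "protective":
            base_or = BASELINE_OR[structure]
            for n_prot in range(5):
                ors = [1 / base_or] * n_prot + [base_or] * (4 - n_prot)
                out.append(base(structure, or_values=tuple(ors)))
        elif kind == "fluctuation":
            base_or = BASELINE_OR[structure]
            # up-to-+/-20% perturbation pattern around the shared OR
            factors = (1.2, 0.8, 1.1, 0.9)
            out.append(base(structure, or_values=tuple(base_or * f for f in factors)))
        elif kind == "stratified":
            if strata is None:
                raise ValueError("stratified scenarios require stratum specs")
            out.append(base(structure, strata=strata))
        elif kind == "subsample":
            for n in range(100, 1101, 100):
                out.append(base(structure, n_cases=n))
    return out
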