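"""Reference simulation experiments: the package's headline operating
characteristics.

Each function reruns, from scratch, one block of the baseline simulation
study — type-I error under the global null and power under the baseline
causal scenarios (10 variants, MAF 0.5%, background risk 1%, 1200 cases,
alpha 0.05; four causal variants with structure-specific odds ratios for the
power runs) — and returns empirical rejection percentages.  Permutation
tests (KBAC, permutation C-alpha) default to fewer replicates with >= 1000
permutations each, which keeps a full reproduction on one CPU in minutes.

These are the quantities the repository's acceptance script reports; they
are computed, never stored.
"""

from __future__ import annotations

from .study import BASELINE_OR, ScenarioConfig, TestSpec, estimate_power

__all__ = [
    "trio_null_rates",
    "asp_ucc_null_rates",
    "asp_ucc_null_kbac_rate",
    "trio_power",
    "asp_ucc_clustered_ssu_power",
    "enriched_trio_power",
]

_ALPHA = 0.05


def _seed(base: int, k: int) -> int:
    return (base * 1009 + k) % (2**31 - 1)


def _rates(cfg: ScenarioConfig) -> dict[str, float]:
    tab = estimate_power(cfg).table
    return {row.key: 100.0 * row.proportion for row in tab.itertuples()}


def trio_null_rates(seed: int, n_reps: int = 1000) -> dict[str, float]:
    """Type-I error (%) of the corrected single-SNP TDT and the SSU test on
    family-format data from 1200 null trios."""
    cfg = ScenarioConfig(
        structure="trio",
        causal_idx=(),
        or_values=(),
        n_reps=n_reps,
        seed=_seed(seed, 1),
        tests=[TestSpec("tdt", "family"), TestSpec("ssu", "family")],
    )
    return _rates(cfg)


def asp_ucc_null_rates(
    seed: int, n_reps: int = 1000, calpha_reps: int = 300, n_perm: int = 1000
) -> dict[str, float]:
    """Type-I error (%) on unclustered UCC data from 600 null ASP families
    (1200 sib cases) plus 1200 unrelated controls: corrected single-SNP
    association, SKAT, and (at ``calpha_reps`` replicates) permutation
    C-alpha; also the clustered SSU rate for reference."""
    base = dict(
        structure="asp", causal_idx=(), or_values=(), n_perm=n_perm
    )
    closed = ScenarioConfig(
        n_reps=n_reps,
        seed=_seed(seed, 2),
        tests=[
            TestSpec("assoc", "ucc"),
            TestSpec("skat", "ucc"),
            TestSpec("ssu", "ucc", cluster=True),
        ],
        **base,
    )
    perm = ScenarioConfig(
        n_reps=calpha_reps,
        seed=_seed(seed, 3),
        tests=[TestSpec("calpha_perm", "ucc")],
        **base,
    )
    out = _rates(closed)
    out.update(_rates(perm))
    return out


def asp_ucc_null_kbac_rate(
    seed: int, n_reps: int = 1000, n_perm: int = 1000
) -> dict[str, float]:
    """Type-I error (%) of KBAC on unclustered UCC data from null ASPs."""
    cfg = ScenarioConfig(
        structure="asp",
        causal_idx=(),
        or_values=(),
        n_reps=n_reps,
        n_perm=n_perm,
        seed=_seed(seed, 4),
        tests=[TestSpec("kbac", "ucc")],
    )
    return _rates(cfg)


def trio_power(
    seed: int, n_reps: int = 1000, kbac_reps: int = 300, n_perm: int = 1000
) -> dict[str, float]:
    """Power (%) in the baseline trio scenario (OR 2.0): corrected
    single-SNP TDT on family data, KBAC on UCC data."""
    tdt = ScenarioConfig(
        structure="trio",
        or_values=BASELINE_OR["trio"],
        n_reps=n_reps,
        seed=_seed(seed, 5),
        tests=[TestSpec("tdt", "family")],
    )
    kbac = ScenarioConfig(
        structure="trio",
        or_values=BASELINE_OR["trio"],
        n_reps=kbac_reps,
        n_perm=n_perm,
        seed=_seed(seed, 6),
        tests=[TestSpec("kbac", "ucc")],
    )
    out = _rates(tdt)
    out.update(_rates(kbac))
    return out


def asp_ucc_clustered_ssu_power(seed: int, n_reps: int = 1000) -> dict[str, float]:
    """Power (%) of the SSU test with sibling-case clustering on UCC data
    from 600 baseline ASP families (OR 1.72)."""
    cfg = ScenarioConfig(
        structure="asp",
        or_values=BASELINE_OR["asp"],
        n_reps=n_reps,
        seed=_seed(seed, 7),
        tests=[TestSpec("ssu", "ucc", cluster=True)],
    )
    return _rates(cfg)


def enriched_trio_power(
    seed: int, n_reps: int = 1000, kbac_reps: int = 300, n_perm: int = 1000
) -> dict[str, float]:
    """Power (%) in the baseline enriched-trio scenario (OR 1.54): SSU on
    family-format transmissions, KBAC on pseudo-case-control data."""
    ssu = ScenarioConfig(
        structure="enriched_trio",
        or_values=BASELINE_OR["enriched_trio"],
        n_reps=n_reps,
        seed=_seed(seed, 8),
        tests=[TestSpec("ssu", "family")],
    )
    kbac = ScenarioConfig(
        structure="enriched_trio",
        or_values=BASELINE_OR["enriched_trio"],
        n_reps=kbac_reps,
        n_perm=n_perm,
        seed=_seed(seed, 9),
        tests=[TestSpec("kbac", "pcc")],
    )
    out = _rates(ssu)
    out.update(_rates(kbac))
    return out
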