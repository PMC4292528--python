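"""Transformations of family data: transmission counts, pseudo-case-control
(PCC) and unrelated-case-control (UCC) construction, and clustering of
related cases.

The transmission bookkeeping uses only unphased genotypes: for trio i and
variant j,

    B_ij = g_child - (# parents homozygous minor)     (minor transmissions
                                                       from het parents)
    C_ij = (# heterozygous parents) - B_ij            (major transmissions)
    X_ij = B_ij - C_ij

Homozygous parents transmit deterministically, so their contribution cancels
and only heterozygous parents are informative — the classic TDT accounting.
Affected sib pairs are treated as two trios sharing parents (no prior
linkage hypothesis, so transmissions to each sib are independent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import CohortSample, FamilySample

__all__ = [
    "TransmissionCounts",
    "CaseControlData",
    "extract_transmissions",
    "make_pcc",
    "make_ucc",
    "cluster_related",
]


@dataclass
class TransmissionCounts:
    """Per-trio minor (B) and major (C) transmission counts and X = B - C.

    Each of B, C, X is (n_trios, m); ASP families contribute two rows.
    ``family`` holds the originating family index of each row.
    """

    B: np.ndarray
    C: np.ndarray
    X: np.ndarray
    family: np.ndarray

    @property
    def n(self) -> int:
        return self.B.shape[0]

    @property
    def m(self) -> int:
        return self.B.shape[1]


@dataclass
class CaseControlData:
    """Minor-allele-count matrix with phenotype and relatedness clusters.

    ``cluster`` labels rows that must not be treated as independent: cases
    from the same family share a label (pseudo-controls share their case's
    label).  Unrelated controls carry unique labels.  After
    :func:`cluster_related`, counts may exceed 2 and all clusters are
    singletons.
    """

    G: np.ndarray
    y: np.ndarray
    cluster: np.ndarray

    @property
    def n(self) -> int:
        return self.G.shape[0]

    @property
    def m(self) -> int:
        return self.G.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.y.sum())


def _check_mendelian(fam: FamilySample) -> None:
    f, m = fam.father_g, fam.mother_g
    # child's count is bounded by what the parents can transmit
    lo = (f // 2) + (m // 2)
    hi = ((f + 1) // 2) + ((m + 1) // 2)
    for k in range(fam.n_children):
        child = fam.children_g[:, k, :]
        bad = (child < lo) | (child > hi)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"Mendelian inconsistency in family {i}, child {k}, variant {j}: "
                f"parents ({f[i, j]}, {m[i, j]}) cannot produce child {child[i, j]}"
            )


def extract_transmissions(fam: FamilySample) -> TransmissionCounts:
    """Transmission counts B, C and X = B - C, one row per affected child."""
    _check_mendelian(fam)
    hom = (fam.father_g == 2).astype(np.int16) + (fam.mother_g == 2).astype(np.int16)
    het = (fam.father_g == 1).astype(np.int16) + (fam.mother_g == 1).astype(np.int16)
    rows_B, rows_C, fam_idx = [], [], []
    for k in range(fam.n_children):
        B = fam.children_g[:, k, :].astype(np.int16) - hom
        C = het - B
        rows_B.append(B)
        rows_C.append(C)
        fam_idx.append(np.arange(fam.n_families))
    # interleave children so the two rows of an ASP are adjacent
    B = np.stack(rows_B, axis=1).reshape(-1, fam.m)
    C = np.stack(rows_C, axis=1).reshape(-1, fam.m)
    family = np.stack(fam_idx, axis=1).reshape(-1)
    return TransmissionCounts(B=B, C=C, X=(B - C), family=family)


def make_pcc(fam: FamilySample) -> CaseControlData:
    """Pseudo-case-control data: cases are the affected offspring, controls
    are pseudo-subjects built from both untransmitted parental alleles
    (g_pseudo = g_father + g_mother - g_case).

    One pseudo-control per case; cluster labels group each family's cases and
    pseudo-controls together.
    """
    _check_mendelian(fam)
    parents = (fam.father_g + fam.mother_g).astype(np.int8)
    cases, pseudos, labels = [], [], []
    for k in range(fam.n_children):
        child = fam.children_g[:, k, :]
        cases.append(child)
        pseudos.append((parents - child).astype(np.int8))
        labels.append(np.arange(fam.n_families))
    G = np.concatenate([np.concatenate(cases), np.concatenate(pseudos)])
    n_cases = fam.n_families * fam.n_children
    y = np.concatenate(
        [np.ones(n_cases, dtype=np.int8), np.zeros(n_cases, dtype=np.int8)]
    )
    lab = np.concatenate(labels)
    return CaseControlData(G=G, y=y, cluster=np.concatenate([lab, lab]))


def make_ucc(fam: FamilySample, controls: CohortSample) -> CaseControlData:
    """Unrelated-case-control data: affected offspring as cases plus
    population controls; parental genotypes are discarded.

    Sibling cases share a cluster label; each control gets a unique label.
    """
    if controls.m != fam.m:
        raise ValueError("controls and families are on different variant panels")
    cases, labels = [], []
    for k in range(fam.n_children):
        cases.append(fam.children_g[:, k, :])
        labels.append(np.arange(fam.n_families))
    G = np.concatenate([np.concatenate(cases), controls.genotypes])
    n_cases = fam.n_families * fam.n_children
    y = np.concatenate(
        [np.ones(n_cases, dtype=np.int8), np.zeros(controls.n, dtype=np.int8)]
    )
    ctl_labels = fam.n_families + np.arange(controls.n)
    cluster = np.concatenate([np.concatenate(labels), ctl_labels])
    return CaseControlData(G=G, y=y, cluster=cluster)


def cluster_related(cc: CaseControlData) -> CaseControlData:
    """Collapse related cases (shared cluster label) by summing minor-allele
    counts into one composite case, and sum controls in matching block sizes.

    Controls with the same label as a case cluster (PCC pseudo-controls) are
    summed with their own family; otherwise (UCC) controls are grouped in
    input order into blocks matching the case-cluster sizes — any
    exchangeable grouping yields the same null distribution.  Output clusters
    are singletons.
    """
    case_idx = np.nonzero(cc.y == 1)[0]
    ctl_idx = np.nonzero(cc.y == 0)[0]
    case_labels = cc.cluster[case_idx]
    # case clusters in order of first appearance
    uniq, first = np.unique(case_labels, return_index=True)
    order = uniq[np.argsort(first)]
    case_rows, sizes = [], []
    for lab in order:
        members = case_idx[case_labels == lab]
        case_rows.append(cc.G[members].sum(axis=0))
        sizes.append(members.size)

    ctl_labels = cc.cluster[ctl_idx]
    matched = np.isin(ctl_labels, order)
    ctl_rows = []
    if matched.all() and ctl_idx.size:
        # PCC-style: controls carry their family's label
        for lab in order:
            members = ctl_idx[ctl_labels == lab]
            if members.size == 0:
                raise ValueError(f"no matched controls for case cluster {lab}")
            ctl_rows.append(cc.G[members].sum(axis=0))
    else:
        # UCC-style: block controls in input order to mirror case-cluster sizes
        if ctl_idx.size != sum(sizes):
            raise ValueError(
                f"cannot block {ctl_idx.size} controls into case-cluster "
                f"sizes summing to {sum(sizes)}"
            )
        pos = 0
        for s in sizes:
            ctl_rows.append(cc.G[ctl_idx[pos : pos + s]].sum(axis=0))
            pos += s
    G = np.asarray(case_rows + ctl_rows)
    y = np.concatenate(
        [np.ones(len(case_rows), dtype=np.int8), np.zeros(len(ctl_rows), dtype=np.int8)]
    )
    return CaseControlData(G=G, y=y, cluster=np.arange(G.shape[0]))
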