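"""Plain-text interchange: PLINK-style PED/FAM for families, TSV for
variant panels and case-control matrices.

Genotypes in PED files are written as allele pairs with '1' = major and
'2' = minor allele; sex is unknown (0); affection is 2 for affected
offspring and 0 (unknown) for parents.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .model import VariantPanel
from .simulate import FamilySample
from .transform import CaseControlData

__all__ = [
    "write_ped",
    "read_ped",
    "write_variant_table",
    "read_variant_table",
    "write_casecontrol",
    "read_casecontrol",
]


def _geno_to_alleles(g: int) -> list[str]:
    return {0: ["1", "1"], 1: ["1", "2"], 2: ["2", "2"]}[int(g)]


def _row(fid, iid, pat, mat, pheno, geno) -> list[str]:
    fields = [fid, iid, pat, mat, "0", str(pheno)]
    for g in geno:
        fields.extend(_geno_to_alleles(g))
    return fields


def write_ped(fam: FamilySample, prefix: str | Path) -> tuple[Path, Path]:
    """Write a family sample as <prefix>.ped (with genotypes) and
    <prefix>.fam (pedigree columns only)."""
    prefix = Path(prefix)
    rows = []
    for i in range(fam.n_families):
        fid = f"F{i + 1}"
        rows.append(_row(fid, f"{fid}_P1", "0", "0", 0, fam.father_g[i]))
        rows.append(_row(fid, f"{fid}_P2", "0", "0", 0, fam.mother_g[i]))
        for k in range(fam.n_children):
            rows.append(
                _row(fid, f"{fid}_C{k + 1}", f"{fid}_P1", f"{fid}_P2", 2,
                     fam.children_g[i, k])
            )
    ped_path = prefix.with_suffix(".ped")
    fam_path = prefix.with_suffix(".fam")
    with open(ped_path, "w") as fh:
        for r in rows:
            fh.write(" ".join(r) + "\n")
    with open(fam_path, "w") as fh:
        for r in rows:
            fh.write(" ".join(r[:6]) + "\n")
    return ped_path, fam_path


def read_ped(path: str | Path, structure: str | None = None) -> FamilySample:
    """Read a PED file of nuclear families into a FamilySample.

    Families must contain exactly two founder parents and one or two
    offspring (all offspring rows are taken as the affected children).  With
    one child per family the structure is 'trio' unless overridden (an
    enriched trio is indistinguishable from a trio in the file).
    """
    records: dict[str, dict[str, tuple]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            fid, iid, pat, mat, _sex, _pheno = parts[:6]
            alleles = parts[6:]
            if len(alleles) % 2:
                raise ValueError(f"odd allele count for individual {iid}")
            g = np.array(
                [alleles[2 * j : 2 * j + 2].count("2") for j in range(len(alleles) // 2)],
                dtype=np.int8,
            )
            if fid not in records:
                records[fid] = {}
                order.append(fid)
            records[fid][iid] = (pat, mat, g)
    fathers, mothers, children = [], [], []
    n_children = None
    for fid in order:
        members = records[fid]
        founders = {iid for iid, (p, m, _) in members.items() if p == "0" and m == "0"}
        kids = [
            (iid, v) for iid, v in members.items() if iid not in founders
        ]
        if len(founders) != 2 or not 1 <= len(kids) <= 2:
            raise ValueError(
                f"family {fid}: need 2 founder parents and 1-2 offspring"
            )
        pat, mat, _ = kids[0][1]
        if pat not in members or mat not in members:
            raise ValueError(f"family {fid}: offspring parents not in family")
        fathers.append(members[pat][2])
        mothers.append(members[mat][2])
        kid_g = [v[2] for _, v in kids]
        if n_children is None:
            n_children = len(kid_g)
        elif n_children != len(kid_g):
            raise ValueError("mixed family sizes are not supported")
        children.append(np.stack(kid_g))
    if structure is None:
        structure = "asp" if n_children == 2 else "trio"
    return FamilySample(
        structure=structure,
        father_g=np.stack(fathers),
        mother_g=np.stack(mothers),
        children_g=np.stack(children),
    )


def write_variant_table(panel: VariantPanel, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"label": panel.labels, "maf": panel.maf}).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_variant_table(path: str | Path) -> VariantPanel:
    df = pd.read_csv(path, sep="\t")
    return VariantPanel(maf=df["maf"].to_numpy(), labels=tuple(df["label"]))


def write_casecontrol(cc: CaseControlData, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(cc.G, columns=[f"g{j + 1}" for j in range(cc.m)])
    df.insert(0, "subject", [f"S{i + 1}" for i in range(cc.n)])
    df.insert(1, "phenotype", cc.y)
    df.insert(2, "cluster", cc.cluster)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_casecontrol(path: str | Path) -> CaseControlData:
    df = pd.read_csv(path, sep="\t")
    gcols = [c for c in df.columns if c.startswith("g") and c[1:].isdigit()]
    return CaseControlData(
        G=df[gcols].to_numpy(),
        y=df["phenotype"].to_numpy().astype(np.int8),
        cluster=df["cluster"].to_numpy(),
    )
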