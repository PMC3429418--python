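"""CSV and GenePop readers/writers with explicit column contracts.

All pipeline exchange formats are plain CSV: ``genotypes.csv``
(individual_id, role, family, locus, allele_1, allele_2; missing calls
empty), ``design.csv`` (the planting layout with alive/genotyped flags) and
``phenotypes.csv`` (per-sapling height, ectophage damage, miner count).
Genotypes can also be exported to and read from the GenePop dialect
(3-digit allele codes, one population per plot).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from herbdiv.design import DESIGN_COLUMNS
from herbdiv.simulate import GENOTYPE_COLUMNS

__all__ = [
    "write_genotypes",
    "read_genotypes",
    "write_design",
    "read_design",
    "write_phenotypes",
    "read_phenotypes",
    "export_genepop",
    "read_genepop",
]

PHENOTYPE_COLUMNS = ["sapling_id", "height", "ecto_damage", "mine_count"]


def _require(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing columns {missing}")


def write_genotypes(genotypes: pd.DataFrame, path) -> None:
    _require(genotypes, GENOTYPE_COLUMNS, "genotype table")
    genotypes[GENOTYPE_COLUMNS].to_csv(path, index=False)


def read_genotypes(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"individual_id": str, "role": str, "family": str, "locus": str},
    )
    _require(df, GENOTYPE_COLUMNS, "genotype table")
    df["allele_1"] = pd.to_numeric(df["allele_1"], errors="coerce")
    df["allele_2"] = pd.to_numeric(df["allele_2"], errors="coerce")
    return df


def write_design(design: pd.DataFrame, path) -> None:
    _require(design, DESIGN_COLUMNS, "design table")
    design[DESIGN_COLUMNS].to_csv(path, index=False)


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sapling_id": str, "block": str, "plot": str, "family": str})
    _require(df, DESIGN_COLUMNS, "design table")
    df["alive"] = df["alive"].astype(bool)
    df["genotyped"] = df["genotyped"].astype(bool)
    return df


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    _require(phenotypes, PHENOTYPE_COLUMNS, "phenotype table")
    phenotypes[PHENOTYPE_COLUMNS].to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sapling_id": str})
    _require(df, PHENOTYPE_COLUMNS, "phenotype table")
    return df


def export_genepop(
    genotypes: pd.DataFrame,
    design: pd.DataFrame,
    path,
    title: str = "herbdiv genotype export",
) -> None:
    """Write offspring genotypes in GenePop format, one population per plot.

    Allele codes are zero-padded to 3 digits (000 = missing).  Mothers are
    not exported (GenePop has no role concept); keep them in the CSV form.
    """
    off = genotypes[genotypes["role"] == "offspring"]
    loci = sorted(off["locus"].unique())
    wide: dict[str, dict[str, str]] = {}
    for (ind, locus), grp in off.groupby(["individual_id", "locus"], sort=False):
        a1, a2 = grp["allele_1"].iloc[0], grp["allele_2"].iloc[0]
        code = "000000" if pd.isna(a1) or pd.isna(a2) else f"{int(a1):03d}{int(a2):03d}"
        wide.setdefault(str(ind), {})[str(locus)] = code
    plot_of = dict(zip(design["sapling_id"], design["plot"]))
    lines = [title]
    lines.extend(loci)
    for plot_id in pd.unique(design["plot"]):
        members = [i for i in design.loc[design["plot"] == plot_id, "sapling_id"] if i in wide]
        if not members:
            continue
        lines.append("Pop")
        for ind in members:
            codes = " ".join(wide[ind].get(l, "000000") for l in loci)
            lines.append(f"{ind} ,  {codes}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_genepop(path) -> pd.DataFrame:
    """Read a GenePop file into the long genotype-table contract.

    Handles 2- or 3-digit allele codes and locus names given one per line
    or comma-separated on one line.  All individuals get
    ``role="offspring"`` and an unknown family; populations are recorded in
    an extra ``population`` column.
    """
    lines = [l.rstrip("\n") for l in Path(path).read_text().splitlines()]
    if not lines:
        raise ValueError("empty GenePop file")
    body = lines[1:]
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        chunk = [s.strip() for s in body[i].split(",") if s.strip()]
        loci.extend(chunk)
        i += 1
    if not loci:
        raise ValueError("no locus names before the first Pop line")
    records = []
    pop = 0
    for line in body[i:]:
        token = line.strip()
        if not token:
            continue
        if token.lower() == "pop":
            pop += 1
            continue
        if "," not in token:
            raise ValueError(f"malformed GenePop individual line: {line!r}")
        ind, geno = token.split(",", 1)
        codes = geno.split()
        if len(codes) != len(loci):
            raise ValueError(f"{ind.strip()}: expected {len(loci)} genotypes, got {len(codes)}")
        for locus, code in zip(loci, codes):
            width = len(code) // 2
            if len(code) not in (4, 6):
                raise ValueError(f"{ind.strip()} at {locus}: bad genotype code {code!r}")
            a1, a2 = int(code[:width]), int(code[width:])
            records.append(
                (
                    ind.strip(),
                    "offspring",
                    None,
                    locus,
                    float(a1) if a1 else None,
                    float(a2) if a2 else None,
                    f"pop{pop}",
                )
            )
    return pd.DataFrame(records, columns=GENOTYPE_COLUMNS + ["population"])
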