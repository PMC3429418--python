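"""Genotype screening: maternity verification by Mendelian exclusion.

An offspring is compatible with a candidate mother at a locus when the two
share at least one allele there.  Offspring whose minimum mismatch count
over all candidate mothers is >= 2 loci are excluded; a single mismatch
retains the offspring under its best mother but flags the event for
per-locus genotyping-error screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MaternityCheck",
    "LocusErrorReport",
    "mendelian_mismatches",
    "assign_maternity",
    "assign_maternity_all",
    "locus_error_screen",
    "maternity_table",
]

Genotype = dict[str, tuple]  # locus -> (allele_1, allele_2); missing loci absent or NaN


@dataclass
class MaternityCheck:
    """Outcome of comparing one offspring against all candidate mothers."""

    offspring_id: str
    mismatch_counts: dict[str, int]
    co_typed_loci: dict[str, int]
    best_mother: str | None
    status: str  # assigned | flagged_one_mismatch | ambiguous | excluded
    mismatch_loci: tuple[str, ...] = ()


@dataclass
class LocusErrorReport:
    """Share of single-mismatch events attributable to one locus."""

    locus_id: str
    mismatch_rate: float
    n_events: int
    flagged: bool = field(default=False)


def _is_typed(pair) -> bool:
    a, b = pair
    return not (pd.isna(a) or pd.isna(b))


def mendelian_mismatches(offspring: Genotype, mother: Genotype) -> tuple[int, int]:
    """Count loci where offspring and mother share no allele.

    Only loci typed in both are compared; returns
    ``(mismatch_count, co_typed_loci)``.  Raises if no locus is co-typed
    (the comparison is undefined).
    """
    mismatches = 0
    co_typed = 0
    for locus, off_pair in offspring.items():
        mo_pair = mother.get(locus)
        if mo_pair is None or not _is_typed(off_pair) or not _is_typed(mo_pair):
            continue
        co_typed += 1
        if not (set(off_pair) & set(mo_pair)):
            mismatches += 1
    if co_typed == 0:
        raise ValueError("no co-typed loci: maternity comparison undefined")
    return mismatches, co_typed


def _mismatch_loci(offspring: Genotype, mother: Genotype) -> tuple[str, ...]:
    out = []
    for locus, off_pair in offspring.items():
        mo_pair = mother.get(locus)
        if mo_pair is None or not _is_typed(off_pair) or not _is_typed(mo_pair):
            continue
        if not (set(off_pair) & set(mo_pair)):
            out.append(locus)
    return tuple(out)


def assign_maternity(
    offspring_id: str,
    offspring: Genotype,
    mothers: dict[str, Genotype],
    threshold: int = 2,
) -> MaternityCheck:
    """Assign the candidate mother with fewest Mendelian mismatches.

    0 mismatches -> ``assigned``; exactly 1 -> ``flagged_one_mismatch``
    (retained, feeds the locus error screen); >= ``threshold`` against every
    candidate -> ``excluded``.  A tie between mothers at the minimum is
    ``ambiguous`` and treated as excluded downstream.
    """
    counts: dict[str, int] = {}
    co_typed: dict[str, int] = {}
    for mid, geno in mothers.items():
        counts[mid], co_typed[mid] = mendelian_mismatches(offspring, geno)
    best = min(counts.values())
    winners = [m for m, c in counts.items() if c == best]
    if best >= threshold:
        return MaternityCheck(offspring_id, counts, co_typed, None, "excluded")
    if len(winners) > 1:
        return MaternityCheck(offspring_id, counts, co_typed, None, "ambiguous")
    mother = winners[0]
    status = "assigned" if best == 0 else "flagged_one_mismatch"
    loci = _mismatch_loci(offspring, mothers[mother]) if best > 0 else ()
    return MaternityCheck(offspring_id, counts, co_typed, mother, status, loci)


def _genotypes_by_individual(genotypes: pd.DataFrame, role: str) -> dict[str, Genotype]:
    sub = genotypes[genotypes["role"] == role]
    out: dict[str, Genotype] = {}
    for ind, grp in sub.groupby("individual_id", sort=False):
        out[str(ind)] = {
            str(l): (a1, a2)
            for l, a1, a2 in zip(grp["locus"], grp["allele_1"], grp["allele_2"])
        }
    return out


def assign_maternity_all(
    genotypes: pd.DataFrame,
    threshold: int = 2,
) -> list[MaternityCheck]:
    """Run maternity assignment for every offspring in a long genotype table.

    Mothers are the rows with ``role == "mother"``.  Offspring with no
    co-typed locus against any mother (e.g. whole-genotype failures) are
    reported with status ``untyped``.
    """
    mothers = _genotypes_by_individual(genotypes, "mother")
    if not mothers:
        raise ValueError("no candidate mothers in genotype table")
    offspring = _genotypes_by_individual(genotypes, "offspring")
    checks = []
    for oid, geno in offspring.items():
        try:
            checks.append(assign_maternity(oid, geno, mothers, threshold))
        except ValueError:
            checks.append(MaternityCheck(oid, {}, {}, None, "untyped"))
    return checks


def locus_error_screen(
    flagged: list[MaternityCheck],
    rate_threshold: float = 0.02,
) -> list[LocusErrorReport]:
    """Attribute single-mismatch events to loci and flag suspect markers.

    ``mismatch_rate`` is each locus's share of all single-mismatch events
    among retained offspring; loci whose share exceeds ``rate_threshold``
    are flagged for removal or re-binning.  Returns an empty list when no
    offspring is flagged.
    """
    events: dict[str, int] = {}
    total = 0
    for check in flagged:
        if check.status != "flagged_one_mismatch":
            continue
        for locus in check.mismatch_loci:
            events[locus] = events.get(locus, 0) + 1
            total += 1
    if total == 0:
        return []
    return [
        LocusErrorReport(locus, n / total, n, flagged=(n / total) > rate_threshold)
        for locus, n in sorted(events.items())
    ]


def maternity_table(checks: list[MaternityCheck]) -> pd.DataFrame:
    """Flatten checks to the ``maternity.csv`` contract."""
    return pd.DataFrame(
        {
            "offspring_id": [c.offspring_id for c in checks],
            "best_mother": [c.best_mother for c in checks],
            "mismatches": [
                min(c.mismatch_counts.values()) if c.mismatch_counts else np.nan
                for c in checks
            ],
            "status": [c.status for c in checks],
        }
    )
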