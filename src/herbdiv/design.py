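"""Common-garden layout: blocks of every non-empty family subset.

The experimental unit is a plot of 12 saplings (4 rows x 3 columns).  Each
block contains one plot for every non-empty subset of the maternal families,
so with m families a block holds 2**m - 1 plots and the number of plots at
each diversity level k equals C(m, k).  Within a mixed plot the families are
planted at equal density in a regular alternating pattern so that two
saplings of the same family are never orthogonally adjacent.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from herbdiv._rng import substream

__all__ = ["MatingDesign", "build_design", "PLOT_ROWS", "PLOT_COLS", "PLOT_SIZE", "DESIGN_COLUMNS"]

PLOT_ROWS = 4
PLOT_COLS = 3
PLOT_SIZE = PLOT_ROWS * PLOT_COLS

#: Column contract for design tables (``design.csv``).
DESIGN_COLUMNS = [
    "sapling_id",
    "block",
    "plot",
    "row",
    "col",
    "family",
    "gd",
    "alive",
    "genotyped",
]


@dataclass(frozen=True)
class MatingDesign:
    """Mating structure of the maternal half-sib families.

    Each mother is pollinated by a finite pool of donors, so her offspring
    are a mixture of full sibs (same donor) and half sibs (different
    donors).  With donor-usage probabilities w, the expected proportion of
    full-sib pairs within a family is sum(w**2).
    """

    n_mothers: int = 4
    pollen_donors_per_mother: int = 3
    offspring_per_family: int = 270

    def __post_init__(self) -> None:
        for field in ("n_mothers", "pollen_donors_per_mother", "offspring_per_family"):
            if getattr(self, field) < 1:
                raise ValueError(f"{field} must be >= 1")

    @staticmethod
    def full_sib_proportion(donor_weights: np.ndarray) -> float:
        """Expected within-family full-sib pair proportion for given donor usage."""
        w = np.asarray(donor_weights, dtype=float)
        if w.ndim != 1 or not np.isclose(w.sum(), 1.0):
            raise ValueError("donor_weights must be a probability vector")
        return float(np.sum(w**2))

    @property
    def family_names(self) -> list[str]:
        return [f"MT{i + 1}" for i in range(self.n_mothers)]


def _layout_plot(families: tuple[str, ...], rng: np.random.Generator) -> list[str]:
    """Assign families to the 4x3 grid, equal density, no same-family adjacency.

    Uses the cyclic pattern family[(row + col) % k] with a random permutation
    of family-to-slot assignment.  For k > 1 the pattern guarantees that
    orthogonal neighbours differ: along a row the slot index steps by 1, and
    down a column it also steps by 1, and k >= 2 never maps consecutive slot
    indices to the same family.
    """
    k = len(families)
    if PLOT_SIZE % k != 0:
        raise ValueError(
            f"cannot plant {k} families at equal density in a plot of {PLOT_SIZE} positions"
        )
    perm = list(rng.permutation(np.array(families)))
    return [perm[(r + c) % k] for r in range(PLOT_ROWS) for c in range(PLOT_COLS)]


def build_design(blocks: int, mating: MatingDesign, seed: int) -> pd.DataFrame:
    """Build the full planting design table.

    Parameters
    ----------
    blocks
        Number of replicate blocks; each holds ``2**n_mothers - 1`` plots.
    mating
        Family structure; only ``n_mothers`` is used here.
    seed
        Root seed; plot order within blocks and the family arrangement in
        each plot are randomized on the ``"design"`` substream.

    Returns
    -------
    DataFrame with one row per planted sapling (columns ``DESIGN_COLUMNS``).
    ``alive`` and ``genotyped`` start True; apply
    :func:`herbdiv.simulate.apply_dropout` for mortality and genotyping
    failure.
    """
    if blocks < 1:
        raise ValueError("blocks must be >= 1")
    m = mating.n_mothers
    families = mating.family_names
    subsets = [
        combo for k in range(1, m + 1) for combo in combinations(families, k)
    ]
    for combo in subsets:
        if PLOT_SIZE % len(combo) != 0:
            raise ValueError(
                f"design infeasible: {len(combo)} families do not divide {PLOT_SIZE} positions"
            )
    rng = substream(seed, "design")
    rows: list[tuple] = []
    for b in range(1, blocks + 1):
        order = rng.permutation(len(subsets))
        for plot_idx, subset_i in enumerate(order, start=1):
            combo = subsets[subset_i]
            plot_id = f"B{b}-P{plot_idx:02d}"
            layout = _layout_plot(combo, rng)
            for pos, fam in enumerate(layout):
                r, c = divmod(pos, PLOT_COLS)
                sid = f"B{b}-P{plot_idx:02d}-S{pos + 1:02d}"
                rows.append((sid, f"B{b}", plot_id, r, c, fam, len(combo), True, True))
    df = pd.DataFrame(rows, columns=DESIGN_COLUMNS)
    _check_no_adjacency(df)
    return df


def _check_no_adjacency(design: pd.DataFrame) -> None:
    """Raise if a mixed plot has two orthogonally adjacent same-family saplings."""
    for plot_id, sub in design.groupby("plot", sort=False):
        if sub["gd"].iloc[0] == 1:
            continue
        grid = {(r, c): f for r, c, f in zip(sub["row"], sub["col"], sub["family"])}
        for (r, c), fam in grid.items():
            for dr, dc in ((0, 1), (1, 0)):
                nb = grid.get((r + dr, c + dc))
                if nb is not None and nb == fam:
                    raise AssertionError(f"same-family adjacency in plot {plot_id}")


def plot_families(design: pd.DataFrame) -> pd.DataFrame:
    """Per-plot table of block, planted family set and design diversity (GD)."""
    agg = (
        design.groupby("plot", sort=False)
        .agg(block=("block", "first"), gd=("gd", "first"), families=("family", lambda s: tuple(sorted(set(s)))))
        .reset_index()
    )
    return agg
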