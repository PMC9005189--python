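"""Cross-dataset coupling agreement and detection-threshold optimization.

Coupling calls from two (or three) datasets are compared on a common
receptor x unit grid, where a unit is either a Galpha subtype or a
family.  Agreement is the fraction of cells on which the datasets give
the same boolean coupler/non-coupler call; cells untested by either
dataset are excluded, never imputed.  Per-unit fractions are averaged
unweighted, so the reported mean matches a per-family decomposition.

The basal-SD cut-off is chosen by scanning a grid of thresholds and
keeping the one that maximizes agreement between the two quantitative
sources (smallest threshold on ties).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .data_io import ANALYSIS_SUBTYPES, GProteinPanel, human_panel
from .qc_filter import apply_sd_cutoff

__all__ = [
    "AgreementResult",
    "coupling_grid",
    "family_grid",
    "pairwise_agreement",
    "threeway_agreement",
    "agreement_by_ligand_match",
    "optimize_sd_cutoff",
    "DEFAULT_CUTOFF_GRID",
]

DEFAULT_CUTOFF_GRID = np.round(np.arange(0.0, 3.0 + 1e-9, 0.1), 10)


@dataclasses.dataclass
class AgreementResult:
    level: str
    per_unit: pd.Series       # unit -> fraction of agreeing cells
    mean_agreement: float     # unweighted mean over units
    n_pairs: int              # total compared cells


def coupling_grid(df: pd.DataFrame, level: str = "subtype",
                  panel: GProteinPanel | None = None,
                  subtypes=ANALYSIS_SUBTYPES) -> pd.DataFrame:
    """Pivot coupler calls into a receptor x unit grid (NaN = untested).

    ``df`` must carry the boolean ``coupler`` column produced by the SD
    cut-off.  At ``level="family"`` a family is a coupler iff any tested
    member subtype is, and untested iff no member was tested.
    """
    panel = panel or human_panel()
    sub = df[df["gprotein"].isin(set(subtypes))]
    grid = sub.pivot_table(index="receptor", columns="gprotein",
                           values="coupler", aggfunc="max")
    grid = grid.reindex(columns=[s for s in subtypes if s in grid.columns])
    grid = grid.astype(float)
    if level == "subtype":
        return grid
    if level != "family":
        raise ValueError(f"level must be 'subtype' or 'family', got {level!r}")
    cols = {}
    for family in panel.families:
        members = [m for m in panel.members(family) if m in grid.columns]
        if members:
            cols[family] = grid[members].max(axis=1, skipna=True)
    return pd.DataFrame(cols, index=grid.index)


def family_grid(subtype_grid: pd.DataFrame,
                panel: GProteinPanel | None = None) -> pd.DataFrame:
    """Aggregate a subtype grid to families by any-coupler-in-family."""
    panel = panel or human_panel()
    subtype_grid = subtype_grid.astype(float)
    cols = {}
    for family in panel.families:
        members = [m for m in panel.members(family) if m in subtype_grid.columns]
        if members:
            cols[family] = subtype_grid[members].max(axis=1, skipna=True)
    return pd.DataFrame(cols, index=subtype_grid.index)


def _aligned(grids):
    receptors = grids[0].index
    units = grids[0].columns
    for g in grids[1:]:
        receptors = receptors.intersection(g.index)
        units = units.intersection(g.columns)
    if len(receptors) == 0 or len(units) == 0:
        raise ValueError("datasets share no tested receptors/units")
    return [g.loc[receptors, units] for g in grids]


def _agreement(aligned, level: str) -> AgreementResult:
    tested = np.ones(aligned[0].shape, dtype=bool)
    for g in aligned:
        tested &= g.notna().values
    base = aligned[0].values
    agree = tested.copy()
    for g in aligned[1:]:
        with np.errstate(invalid="ignore"):
            agree &= (g.values == base)
    per_unit = {}
    for j, unit in enumerate(aligned[0].columns):
        n = tested[:, j].sum()
        if n:
            per_unit[unit] = agree[:, j].sum() / n
    per_unit = pd.Series(per_unit, dtype=float)
    if per_unit.empty:
        raise ValueError("no jointly tested cells")
    return AgreementResult(level=level, per_unit=per_unit,
                           mean_agreement=float(per_unit.mean()),
                           n_pairs=int(tested.sum()))


def pairwise_agreement(a: pd.DataFrame, b: pd.DataFrame,
                       level: str = "subtype") -> AgreementResult:
    """Coupling/noncoupling agreement between two datasets.

    Both coupler and non-coupler matches count; the mean is the
    unweighted average of the per-unit fractions.  Symmetric in its
    arguments.
    """
    return _agreement(_aligned([a, b]), level)


def threeway_agreement(a: pd.DataFrame, b: pd.DataFrame, c: pd.DataFrame,
                       level: str = "family") -> AgreementResult:
    """Agreement over the triple intersection: a cell agrees iff all three match."""
    return _agreement(_aligned([a, b, c]), level)


def agreement_by_ligand_match(a: pd.DataFrame, b: pd.DataFrame,
                              ligand_shared: dict):
    """Mean qualitative agreement for same-agonist vs different-agonist receptors.

    ``ligand_shared`` maps receptor -> True when both sources used the
    same agonist.  Within each stratum the per-receptor agreement
    fraction is averaged; an empty stratum yields NaN.
    """
    aligned = _aligned([a, b])
    av, bv = aligned
    fractions = {}
    for receptor in av.index:
        ra, rb = av.loc[receptor], bv.loc[receptor]
        both = ra.notna() & rb.notna()
        if both.any():
            fractions[receptor] = float((ra[both] == rb[both]).mean())
    same = [v for r, v in fractions.items() if ligand_shared.get(r, False)]
    diff = [v for r, v in fractions.items() if not ligand_shared.get(r, False)]
    frac_same = float(np.mean(same)) if same else float("nan")
    frac_diff = float(np.mean(diff)) if diff else float("nan")
    return frac_same, frac_diff


def optimize_sd_cutoff(a_raw: pd.DataFrame, b_raw: pd.DataFrame,
                       grid=DEFAULT_CUTOFF_GRID, level: str = "subtype",
                       panel: GProteinPanel | None = None,
                       subtypes=ANALYSIS_SUBTYPES):
    """Scan SD multiples and return the threshold maximizing agreement.

    For each candidate k the cut-off is applied to both raw sources and
    the mean agreement over their common tested cells computed; ties are
    broken toward the smallest k.  Returns ``(k_star, curve)`` where
    ``curve`` is a DataFrame with one row per k (mean agreement plus
    per-unit columns).
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("cut-off grid must be nonempty")
    if (grid < 0).any():
        raise ValueError("cut-off grid values must be nonnegative")
    rows = []
    for k in grid:
        ga = coupling_grid(apply_sd_cutoff(a_raw, k), level, panel, subtypes)
        gb = coupling_grid(apply_sd_cutoff(b_raw, k), level, panel, subtypes)
        res = pairwise_agreement(ga, gb, level)
        row = {"k": float(k), "mean_agreement": res.mean_agreement,
               "n_pairs": res.n_pairs}
        row.update({f"agree_{u}": v for u, v in res.per_unit.items()})
        rows.append(row)
    curve = pd.DataFrame(rows)
    best = curve["mean_agreement"].max()
    # smallest k among the maximizers
    k_star = float(curve.loc[curve["mean_agreement"] >= best - 1e-12, "k"].min())
    return k_star, curve
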