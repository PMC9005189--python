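"""Receptor promiscuity and G-protein coverage statistics.

All operations consume the unified map (supported couplings only).
Annotation-only receptors carry family-level presence; they count in
family-level statistics but are excluded from within-family subtype
promiscuity, which needs complete member-level testing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_io import ANALYSIS_SUBTYPES, FAMILIES, GProteinPanel, human_panel

__all__ = [
    "coupled_families",
    "promiscuity_distribution",
    "gprotein_coverage",
    "within_family_promiscuity",
    "venn_intersections",
]


def coupled_families(map_df: pd.DataFrame) -> pd.Series:
    """Receptor -> frozenset of families with at least one supported coupling."""
    if map_df.empty:
        return pd.Series(dtype=object)
    return map_df.groupby("receptor")["family"].agg(frozenset)


def promiscuity_distribution(map_df: pd.DataFrame) -> dict:
    """Distribution of receptors over 1-4 coupled G-protein families.

    Returns counts by family number, the mean number of families per
    receptor, and the universe size (receptors with >= 1 supported
    coupling, including annotation-only receptors).
    """
    fams = coupled_families(map_df)
    n_fam = fams.map(len)
    counts = {k: int((n_fam == k).sum()) for k in (1, 2, 3, 4)}
    return {
        "counts": counts,
        "mean_families": float(n_fam.mean()) if len(n_fam) else float("nan"),
        "universe": int(len(n_fam)),
    }


def gprotein_coverage(map_df: pd.DataFrame,
                      panel: GProteinPanel | None = None,
                      tested_grid: pd.DataFrame | None = None) -> dict:
    """Receptors coupled per family and per subtype.

    ``tested_grid`` (combined receptor x subtype testedness) activates
    the Golf bookkeeping: receptors tested for Gs but not Golf are
    excluded from the Gs-family subtype counts, and Golf couplings count
    only alongside a supported Gs coupling.
    """
    panel = panel or human_panel()
    universe = int(map_df["receptor"].nunique())
    fams = coupled_families(map_df)
    per_family = {}
    for family in FAMILIES:
        count = int(fams.map(lambda s: family in s).sum()) if len(fams) else 0
        per_family[family] = {
            "count": count,
            "pct_of_universe": 100.0 * count / universe if universe else 0.0,
        }

    sub_rows = map_df[map_df["section"] == "quantitative"]
    per_subtype = {s: 0 for s in ANALYSIS_SUBTYPES}
    golf_excluded = []
    if not sub_rows.empty:
        gs_couplers = set(sub_rows.loc[sub_rows["gprotein"] == "Gs", "receptor"])
        if tested_grid is not None and "Gs" in tested_grid.columns:
            tested_gs = tested_grid.index[tested_grid["Gs"].fillna(False).astype(bool)]
            if "Golf" in tested_grid.columns:
                tested_golf = set(
                    tested_grid.index[tested_grid["Golf"].fillna(False).astype(bool)])
            else:
                tested_golf = set()
            golf_excluded = sorted(set(tested_gs) - tested_golf)
        skip_gs = set(golf_excluded)
        for subtype, grp in sub_rows.groupby("gprotein"):
            receptors = set(grp["receptor"])
            if panel.family_of(subtype) == "Gs":
                receptors -= skip_gs
            if subtype == "Golf":
                receptors &= gs_couplers
            per_subtype[subtype] = len(receptors)

    counts = [v["count"] for v in per_family.values()]
    return {
        "per_family": per_family,
        "per_subtype": per_subtype,
        "mean_receptors_per_family": float(np.mean(counts)),
        "universe": universe,
        "golf_excluded": golf_excluded,
    }


def within_family_promiscuity(map_df: pd.DataFrame,
                              tested_grid: pd.DataFrame,
                              panel: GProteinPanel | None = None,
                              subtypes=ANALYSIS_SUBTYPES) -> dict:
    """Fraction of family-coupled receptors that activate every member.

    Only receptors with at least one supported subtype coupling in the
    family *and* all (panel-restricted) members tested qualify for the
    denominator.
    """
    panel = panel or human_panel()
    sub_rows = map_df[map_df["section"] == "quantitative"]
    out = {}
    for family in FAMILIES:
        members = [m for m in panel.members(family) if m in subtypes]
        if not members:
            continue
        coupled = sub_rows[sub_rows["family"] == family]
        by_receptor = coupled.groupby("receptor")["gprotein"].agg(set)
        eligible, full = 0, 0
        for receptor, got in by_receptor.items():
            if receptor not in tested_grid.index:
                continue
            tested = tested_grid.loc[receptor, members].fillna(False).astype(bool)
            if not tested.all():
                continue
            eligible += 1
            if set(members) <= got:
                full += 1
        out[family] = {"fraction_full": full / eligible if eligible else float("nan"),
                       "n_eligible": eligible, "n_full": full}
    return out


def venn_intersections(map_df: pd.DataFrame, level: str = "family",
                       panel: GProteinPanel | None = None) -> dict:
    """Counts of receptors per region of the coupling Venn diagram.

    At ``level="family"`` keys are frozensets of families (15 possible
    regions); at ``level="subtype"`` one Venn per family is returned,
    keyed by family, with regions over its member subtypes.  Region
    counts sum to the number of receptors with >= 1 coupling.
    """
    panel = panel or human_panel()
    if level == "family":
        fams = coupled_families(map_df)
        regions: dict = {}
        for members in fams:
            regions[members] = regions.get(members, 0) + 1
        return regions
    if level != "subtype":
        raise ValueError("level must be 'family' or 'subtype'")
    sub_rows = map_df[map_df["section"] == "quantitative"]
    out = {}
    for family in FAMILIES:
        grp = sub_rows[sub_rows["family"] == family]
        if grp.empty:
            out[family] = {}
            continue
        sets = grp.groupby("receptor")["gprotein"].agg(frozenset)
        regions = {}
        for members in sets:
            regions[members] = regions.get(members, 0) + 1
        out[family] = regions
    return out
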