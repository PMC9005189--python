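"""Evidence classification and assembly of the unified coupling map.

Every (receptor, G protein) cell is described by which sources tested it
and which called a coupling.  The literature annotation is treated as a
single aggregate source that self-supports (its couplings typically rest
on multiple publications), expanded from family level to the subtypes of
the annotated family.  Cells are labeled:

supported
    Coupler in at least two sources (annotation counts as one), or
    annotated with no quantitative test of the cell.
novel
    Coupler in both quantitative sources but not annotated.
proposed
    Coupler in exactly one source with no other source having tested
    the cell.
unique:<source>
    Coupler in one source while at least one other source tested the
    cell and found non-coupling.
missing:<source>
    Non-coupler in a source while at least one other testing source
    couples.

The unified map holds one entry per supported coupling; cells with two
quantitative couplers carry the mean of the two harmonized
log(Emax/EC50) values, cells with one carry that source's value
(never averaged with zero), and annotation-only receptors contribute
family-level entries without a quantitative value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_io import (ANALYSIS_SUBTYPES, GProteinPanel,
                      expand_annotation_to_subtypes, human_panel)

__all__ = [
    "ANNOTATION_SOURCE",
    "classify",
    "evidence_patterns",
    "build_unified_map",
    "find_novel",
    "find_contradicted_annotations",
    "unique_missing_summary",
]

ANNOTATION_SOURCE = "gtp"


def classify(tested_by: frozenset, coupler_in: frozenset,
             quant_sources, annotation_source: str = ANNOTATION_SOURCE) -> frozenset:
    """Label one evidence pattern (see module docstring for the terms)."""
    tested_by = frozenset(tested_by)
    coupler_in = frozenset(coupler_in)
    if not coupler_in <= tested_by:
        raise ValueError("coupler_in must be a subset of tested_by")
    quant = frozenset(quant_sources)
    labels = set()

    quant_tested = tested_by & quant
    annotation_only = coupler_in == {annotation_source} and not quant_tested
    if len(coupler_in) >= 2 or annotation_only:
        labels.add("supported")
    if quant <= coupler_in and len(quant) >= 2 \
            and annotation_source not in coupler_in:
        labels.add("novel")
    if len(coupler_in) == 1 and coupler_in <= quant and tested_by == coupler_in:
        labels.add("proposed")
    if len(coupler_in) == 1 and tested_by - coupler_in:
        labels.add(f"unique:{next(iter(coupler_in))}")
    if coupler_in:
        for source in tested_by - coupler_in:
            labels.add(f"missing:{source}")
    return frozenset(labels)


def evidence_patterns(coupler_grids: dict, annotations: pd.DataFrame | None,
                      panel: GProteinPanel | None = None,
                      subtypes=ANALYSIS_SUBTYPES) -> pd.DataFrame:
    """Tabulate tested-by / coupler-in / labels for every quantitative cell.

    ``coupler_grids`` maps quantitative source id -> receptor x subtype
    grid (1/0/NaN).  Annotated receptors count as tested by the
    annotation source on every cell; a subtype is an annotation coupler
    iff its family is annotated.
    """
    panel = panel or human_panel()
    quant_sources = tuple(coupler_grids)
    receptors = sorted(set().union(*(g.index for g in coupler_grids.values())))
    if annotations is not None and len(annotations):
        ann_universe = set(annotations["receptor"])
        ann_grid = expand_annotation_to_subtypes(
            annotations, panel, receptors=sorted(ann_universe), subtypes=subtypes)
    else:
        ann_universe = set()
        ann_grid = None

    fam_of = {s: panel.family_of(s) for s in subtypes}
    rows = []
    for receptor in receptors:
        for subtype in subtypes:
            tested, couplers = set(), set()
            for source, grid in coupler_grids.items():
                if receptor in grid.index and subtype in grid.columns:
                    cell = grid.loc[receptor, subtype]
                    if pd.notna(cell):
                        tested.add(source)
                        if bool(cell):
                            couplers.add(source)
            if receptor in ann_universe:
                tested.add(ANNOTATION_SOURCE)
                if bool(ann_grid.loc[receptor, subtype]):
                    couplers.add(ANNOTATION_SOURCE)
            if not tested:
                continue
            tested, couplers = frozenset(tested), frozenset(couplers)
            rows.append({
                "receptor": receptor,
                "gprotein": subtype,
                "family": fam_of[subtype],
                "tested_by": tested,
                "coupler_in": couplers,
                "annotated": ANNOTATION_SOURCE in couplers,
                "labels": classify(tested, couplers, quant_sources),
            })
    return pd.DataFrame(rows, columns=["receptor", "gprotein", "family",
                                       "tested_by", "coupler_in", "annotated",
                                       "labels"])


def build_unified_map(coupler_grids: dict, value_grids: dict,
                      annotations: pd.DataFrame | None,
                      panel: GProteinPanel | None = None,
                      subtypes=ANALYSIS_SUBTYPES):
    """Assemble the unified coupling map.

    Parameters
    ----------
    coupler_grids, value_grids :
        Per quantitative source: receptor x subtype coupler grid and the
        matching harmonized log(Emax/EC50) grid.
    annotations :
        Family-level literature annotations (receptor, family, rank).

    Returns
    -------
    (map, patterns) :
        ``map`` has one row per supported coupling -- subtype-level rows
        for receptors with quantitative data (section "quantitative")
        and family-level rows for annotation-only receptors (section
        "annotation_only").  ``patterns`` is the full evidence table.
    """
    panel = panel or human_panel()
    patterns = evidence_patterns(coupler_grids, annotations, panel, subtypes)
    quant_receptors = set(patterns["receptor"])

    entries = []
    for row in patterns.itertuples(index=False):
        if "supported" not in row.labels:
            continue
        vals = []
        for source in row.coupler_in:
            grid = value_grids.get(source)
            if grid is not None and row.receptor in grid.index \
                    and row.gprotein in grid.columns:
                v = grid.loc[row.receptor, row.gprotein]
                if pd.notna(v):
                    vals.append(float(v))
        entries.append({
            "receptor": row.receptor,
            "gprotein": row.gprotein,
            "family": row.family,
            "map_value": float(np.mean(vals)) if vals else np.nan,
            "support_count": len(row.coupler_in),
            "labels": row.labels,
            "section": "quantitative",
        })

    if annotations is not None and len(annotations):
        for rec, grp in annotations.groupby("receptor"):
            if rec in quant_receptors:
                continue
            for family in grp["family"]:
                entries.append({
                    "receptor": rec,
                    "gprotein": None,
                    "family": family,
                    "map_value": np.nan,
                    "support_count": 1,
                    "labels": frozenset({"supported"}),
                    "section": "annotation_only",
                })
    cols = ["receptor", "gprotein", "family", "map_value", "support_count",
            "labels", "section"]
    return pd.DataFrame(entries, columns=cols), patterns


def find_novel(patterns: pd.DataFrame) -> dict:
    """Count novel couplings at subtype level and per receptor/family.

    A family counts in the family tally iff at least one member subtype
    is novel (dual quantitative support for an unannotated family).
    """
    novel = patterns[patterns["labels"].map(lambda ls: "novel" in ls)]
    couplings = list(map(tuple, novel[["receptor", "gprotein"]].values))
    receptors = sorted(novel["receptor"].unique())
    family_pairs = novel[["receptor", "family"]].drop_duplicates()
    tally = family_pairs["family"].value_counts().to_dict()
    return {
        "n_receptors": len(receptors),
        "n_couplings": len(couplings),
        "receptors": receptors,
        "couplings": couplings,
        "family_tally": tally,
        "n_family_pairs": len(family_pairs),
    }


def find_contradicted_annotations(patterns: pd.DataFrame,
                                  annotations: pd.DataFrame,
                                  quant_sources=None) -> list:
    """Annotated family couplings rejected by both quantitative screens.

    An annotated (receptor, family) is contradicted when every
    quantitative source tested at least one member subtype and no tested
    member was a coupler in any quantitative source.
    """
    if annotations is None or not len(annotations):
        return []
    if quant_sources is None:
        quant_sources = sorted(set().union(*patterns["tested_by"])
                               - {ANNOTATION_SOURCE})
    out = []
    for rec, family in annotations[["receptor", "family"]].itertuples(index=False):
        cells = patterns[(patterns["receptor"] == rec)
                         & (patterns["family"] == family)]
        if cells.empty:
            continue
        ok = True
        for source in quant_sources:
            tested = cells["tested_by"].map(lambda t: source in t)
            if not tested.any():
                ok = False
                break
            if cells.loc[tested, "coupler_in"].map(lambda c: source in c).any():
                ok = False
                break
        if ok:
            out.append((rec, family))
    return out


def unique_missing_summary(patterns: pd.DataFrame, common_receptors,
                           sources=None) -> pd.DataFrame:
    """Percent unique (positive) and missing (negative) couplings per source.

    Restricted to ``common_receptors`` (receptors present in all
    sources); the denominator is the full receptor count, so
    non-coupling receptors dilute the percentages as intended.
    """
    common = set(common_receptors)
    n = len(common)
    if n == 0:
        raise ValueError("common receptor set is empty")
    sub = patterns[patterns["receptor"].isin(common)]
    if sources is None:
        sources = sorted(set().union(*sub["tested_by"]))
    rows = []
    for source in sources:
        for subtype, grp in sub.groupby("gprotein"):
            uniq = grp["labels"].map(lambda ls: f"unique:{source}" in ls).sum()
            miss = grp["labels"].map(lambda ls: f"missing:{source}" in ls).sum()
            rows.append({"source": source, "gprotein": subtype,
                         "unique_pct": 100.0 * uniq / n,
                         "missing_pct": -100.0 * miss / n})
    return pd.DataFrame(rows)
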