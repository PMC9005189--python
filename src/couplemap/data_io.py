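"""Readers, writers, and G-protein panel metadata.

All tabular exchange uses a canonical long ("tidy") layout: one assay
measurement per row, one literature annotation per row.  Wide workbook
tabs are converted on ingest so downstream analysis never sees a
source-specific layout.

The panel metadata encodes the 16 human Galpha subtypes, their four
families (Gs, Gi/o, Gq/11, G12/13), which subtypes each source measured,
and the probe equivalence classes of chimera-based assays (distinct
subtypes read out by a physically identical probe share one datapoint).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "PanelError",
    "GProteinPanel",
    "FAMILIES",
    "ANALYSIS_SUBTYPES",
    "MEASUREMENT_COLUMNS",
    "CURVE_STATUSES",
    "human_panel",
    "read_quantitative_table",
    "read_workbook_tab",
    "write_measurements",
    "read_annotation_table",
    "expand_annotation_to_subtypes",
    "read_expression_table",
]


class SchemaError(ValueError):
    """A table is missing required columns or violates a uniqueness contract."""


class PanelError(ValueError):
    """A G-protein token is not part of the panel."""


FAMILIES = ("Gs", "Gi/o", "Gq/11", "G12/13")

# (subtype token, family, gene symbol) -- one row per Galpha subtype,
# with the two GNAO1 splice isoforms (GoA/GoB) listed separately.
_PANEL_ROWS = [
    ("Gs", "Gs", "GNAS"),
    ("Golf", "Gs", "GNAL"),
    ("Gi1", "Gi/o", "GNAI1"),
    ("Gi2", "Gi/o", "GNAI2"),
    ("Gi3", "Gi/o", "GNAI3"),
    ("GoA", "Gi/o", "GNAO1"),
    ("GoB", "Gi/o", "GNAO1"),
    ("Gz", "Gi/o", "GNAZ"),
    ("Gt1", "Gi/o", "GNAT1"),
    ("Gt2", "Gi/o", "GNAT2"),
    ("Ggust", "Gi/o", "GNAT3"),
    ("Gq", "Gq/11", "GNAQ"),
    ("G11", "Gq/11", "GNA11"),
    ("G14", "Gq/11", "GNA14"),
    ("G15", "Gq/11", "GNA15"),
    ("G12", "G12/13", "GNA12"),
    ("G13", "G12/13", "GNA13"),
]

#: The 12 subtypes measured by both quantitative platforms and used for
#: every cross-dataset analysis (Golf, Gi3, transducins and gustducin
#: were not covered by the wild-type-protein biosensor panel).
ANALYSIS_SUBTYPES = (
    "Gs", "Gi1", "Gi2", "GoA", "GoB", "Gz",
    "Gq", "G11", "G14", "G15", "G12", "G13",
)

MEASUREMENT_COLUMNS = [
    "source", "receptor", "gprotein", "ligand", "ligand_type",
    "ligand_shared", "pec50", "emax", "basal_mean", "basal_sd",
    "curve_status", "enzymatic_units", "exclusion",
]

CURVE_STATUSES = ("converged", "unconverged_approximate", "no_activity")

_BOUVIER_SUBTYPES = frozenset(ANALYSIS_SUBTYPES)
_INOUE_SUBTYPES = frozenset(s for s, _, _ in _PANEL_ROWS)

# Chimeric probes in the Gq-backbone platform: subtypes in one class are
# measured by an identical C-terminal hexamer and share a datapoint.  The
# transducin/gustducin hexamer is identical to the Gi1/Gi2 probe.
_INOUE_EQUIVALENCE = (
    frozenset({"Gi1", "Gi2", "Gt1", "Gt2", "Ggust"}),
    frozenset({"GoA", "GoB"}),
    frozenset({"Gq", "G11"}),
)

# Sources reporting a single "Go" value are paired against both GNAO1
# isoforms of sources that resolve them.
ISOFORM_ALIASES = {"Go": ("GoA", "GoB")}


@dataclasses.dataclass(frozen=True)
class GProteinPanel:
    """Static description of the Galpha subtype panel.

    Attributes
    ----------
    frame :
        One row per subtype token: ``subtype``, ``family``, ``gene``.
    tested_by :
        Source id -> frozenset of subtype tokens measured by that source.
    equivalence :
        Source id -> tuple of frozensets; subtypes within a set share a
        physically identical probe (one measured value, duplicated).
    """

    frame: pd.DataFrame
    tested_by: dict
    equivalence: dict

    @property
    def subtypes(self) -> tuple:
        return tuple(self.frame["subtype"])

    @property
    def families(self) -> tuple:
        return FAMILIES

    def family_of(self, subtype: str) -> str:
        row = self.frame.loc[self.frame["subtype"] == subtype, "family"]
        if row.empty:
            raise PanelError(f"unknown G protein token: {subtype!r}")
        return row.iloc[0]

    def members(self, family: str, restrict=None) -> tuple:
        if family not in FAMILIES:
            raise PanelError(f"unknown family: {family!r}")
        out = tuple(self.frame.loc[self.frame["family"] == family, "subtype"])
        if restrict is not None:
            restrict = set(restrict)
            out = tuple(s for s in out if s in restrict)
        return out

    def equivalence_class(self, source: str, subtype: str) -> frozenset:
        for cls in self.equivalence.get(source, ()):
            if subtype in cls:
                return cls
        return frozenset({subtype})

    def validate(self) -> None:
        frame = self.frame
        if frame["subtype"].duplicated().any():
            raise PanelError("duplicated subtype tokens")
        if set(frame["family"]) != set(FAMILIES):
            raise PanelError("panel families do not match the four Galpha families")
        if frame["gene"].nunique() != 16:
            raise PanelError("panel must cover the 16 human Galpha genes")


def human_panel() -> GProteinPanel:
    """The human Galpha panel with per-source coverage and probe classes."""
    frame = pd.DataFrame(_PANEL_ROWS, columns=["subtype", "family", "gene"])
    panel = GProteinPanel(
        frame=frame,
        tested_by={"bouvier": _BOUVIER_SUBTYPES, "inoue": _INOUE_SUBTYPES},
        equivalence={"inoue": _INOUE_EQUIVALENCE},
    )
    panel.validate()
    return panel


# ---------------------------------------------------------------------------
# quantitative measurement tables
# ---------------------------------------------------------------------------

_DEFAULTS = {
    "ligand": "",
    "ligand_type": "endogenous",
    "ligand_shared": True,
    "enzymatic_units": False,
    "exclusion": "none",
}


def _finalize_measurements(df: pd.DataFrame, source_id: str,
                           panel: GProteinPanel | None) -> pd.DataFrame:
    panel = panel or human_panel()
    df = df.copy()
    df["source"] = source_id

    for col, default in _DEFAULTS.items():
        if col not in df.columns:
            df[col] = default
    for col in ("pec50", "emax", "basal_mean", "basal_sd"):
        if col not in df.columns:
            raise SchemaError(f"missing required column(s): {col}")
        df[col] = pd.to_numeric(df[col], errors="coerce")

    # Single "Go" readouts stand for both GNAO1 isoforms.
    expanded = []
    for alias, targets in ISOFORM_ALIASES.items():
        mask = df["gprotein"] == alias
        if mask.any():
            for target in targets:
                sub = df.loc[mask].copy()
                sub["gprotein"] = target
                expanded.append(sub)
            df = df.loc[~mask]
    if expanded:
        df = pd.concat([df, *expanded], ignore_index=True)

    known = set(panel.subtypes)
    bad = sorted(set(df["gprotein"]) - known)
    if bad:
        raise PanelError(f"unknown G protein token(s): {bad}")

    # A row without a measurable response is recorded as no-activity.
    if "curve_status" not in df.columns:
        df["curve_status"] = "converged"
    df["curve_status"] = df["curve_status"].fillna("converged")
    no_data = df["emax"].isna() | df["pec50"].isna()
    df.loc[no_data & (df["curve_status"] != "no_activity"), "curve_status"] = "no_activity"
    bad_status = sorted(set(df["curve_status"]) - set(CURVE_STATUSES))
    if bad_status:
        raise SchemaError(f"invalid curve_status value(s): {bad_status}")

    dup = df.duplicated(subset=["receptor", "gprotein"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["receptor", "gprotein"]].drop_duplicates()
        listing = ", ".join(f"{r}-{g}" for r, g in pairs.itertuples(index=False))
        raise SchemaError(f"duplicated (receptor, gprotein) rows: {listing}")

    df["ligand_shared"] = df["ligand_shared"].astype(bool)
    df["enzymatic_units"] = df["enzymatic_units"].astype(bool)
    df["basal_sd"] = df["basal_sd"].fillna(0.0)
    if (df["basal_sd"] < 0).any():
        raise SchemaError("basal_sd must be nonnegative")
    return df[MEASUREMENT_COLUMNS].reset_index(drop=True)


def read_quantitative_table(path, source_id: str,
                            panel: GProteinPanel | None = None) -> pd.DataFrame:
    """Read a long-format CSV/TSV of coupling measurements.

    Missing pEC50 or Emax cells yield ``curve_status == "no_activity"``.
    Duplicated (receptor, G protein) rows raise :class:`SchemaError`.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    required = {"receptor", "gprotein"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return _finalize_measurements(df, source_id, panel)


def read_workbook_tab(path, sheet: str, source_id: str,
                      panel: GProteinPanel | None = None) -> pd.DataFrame:
    """Read one named workbook tab and convert it to the canonical layout.

    Two layouts are understood: the canonical long layout (same columns
    as the TSV exchange format) and a wide per-receptor layout in which
    each G protein contributes ``<token>_pec50`` / ``<token>_emax`` /
    ``<token>_basal_mean`` / ``<token>_basal_sd`` columns.
    """
    df = pd.read_excel(path, sheet_name=sheet)
    if {"receptor", "gprotein"}.issubset(df.columns):
        return _finalize_measurements(df, source_id, panel)

    if "receptor" not in df.columns:
        raise SchemaError("missing required column(s): receptor")
    tokens = sorted({c.rsplit("_", 1)[0].split("_pec50")[0]
                     for c in df.columns if c.endswith("_pec50")})
    if not tokens:
        raise SchemaError("wide layout requires <gprotein>_pec50 columns")
    long_rows = []
    meta_cols = [c for c in ("ligand", "ligand_type", "ligand_shared",
                             "enzymatic_units", "exclusion") if c in df.columns]
    for _, row in df.iterrows():
        for tok in tokens:
            rec = {"receptor": row["receptor"], "gprotein": tok}
            for field in ("pec50", "emax", "basal_mean", "basal_sd"):
                rec[field] = row.get(f"{tok}_{field}", np.nan)
            status_col = f"{tok}_curve_status"
            if status_col in df.columns and pd.notna(row[status_col]):
                rec["curve_status"] = row[status_col]
            for c in meta_cols:
                rec[c] = row[c]
            long_rows.append(rec)
    return _finalize_measurements(pd.DataFrame(long_rows), source_id, panel)


def write_measurements(df: pd.DataFrame, path) -> None:
    """Write measurements as canonical TSV (lossless round-trip)."""
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# literature annotations
# ---------------------------------------------------------------------------

_RANKS = {"primary", "secondary"}


def read_annotation_table(path) -> pd.DataFrame:
    """Read a receptor -> G-protein-family annotation table.

    Columns: ``receptor``, ``family``, ``rank`` (primary/secondary).
    Receptors absent from the table are "not annotated", which is
    distinct from an annotated noncoupler.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    missing = sorted({"receptor", "family", "rank"} - set(df.columns))
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return validate_annotations(df)


def validate_annotations(df: pd.DataFrame) -> pd.DataFrame:
    bad_rank = sorted(set(df["rank"]) - _RANKS)
    if bad_rank:
        raise ValueError(f"invalid transducer rank(s): {bad_rank}")
    bad_family = sorted(set(df["family"]) - set(FAMILIES))
    if bad_family:
        raise PanelError(f"unknown family token(s): {bad_family}")
    dup = df.duplicated(subset=["receptor", "family"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["receptor", "family"]].drop_duplicates()
        listing = ", ".join(f"{r}-{f}" for r, f in pairs.itertuples(index=False))
        raise ValueError(f"multiple ranks for (receptor, family): {listing}")
    return df.reset_index(drop=True)


def expand_annotation_to_subtypes(annotations: pd.DataFrame,
                                  panel: GProteinPanel | None = None,
                                  receptors=None,
                                  subtypes=ANALYSIS_SUBTYPES) -> pd.DataFrame:
    """Expand family-level annotations to a receptor x subtype grid.

    A subtype is marked annotated-coupling-possible iff its family has a
    known coupling for the receptor.  Returns a boolean DataFrame over
    ``receptors`` (default: annotated receptors) and ``subtypes``.
    """
    panel = panel or human_panel()
    annotations = validate_annotations(annotations)
    if receptors is None:
        receptors = sorted(annotations["receptor"].unique())
    grid = pd.DataFrame(False, index=pd.Index(receptors, name="receptor"),
                        columns=list(subtypes))
    fam_of = {s: panel.family_of(s) for s in subtypes}
    annotated = set(map(tuple, annotations[["receptor", "family"]].values))
    for receptor in grid.index:
        for subtype in subtypes:
            if (receptor, fam_of[subtype]) in annotated:
                grid.loc[receptor, subtype] = True
    return grid


# ---------------------------------------------------------------------------
# tissue expression (Human Protein Atlas consensus dialect)
# ---------------------------------------------------------------------------

def read_expression_table(path, genes=None) -> pd.DataFrame:
    """Read an HPA consensus-tissue TSV (Gene, Gene name, Tissue, nTPM).

    Returns a gene x tissue matrix of nTPM values, optionally restricted
    to ``genes`` (gene symbols, e.g. the 16 Galpha genes).
    """
    df = pd.read_csv(path, sep="\t")
    name_col = "Gene name" if "Gene name" in df.columns else "gene"
    missing = sorted({name_col, "Tissue", "nTPM"} - set(df.columns))
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if genes is not None:
        df = df[df[name_col].isin(set(genes))]
    mat = df.pivot_table(index=name_col, columns="Tissue", values="nTPM",
                         aggfunc="mean")
    mat.index.name = "gene"
    if (mat.values < 0).any():
        raise SchemaError("nTPM values must be nonnegative")
    return mat
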