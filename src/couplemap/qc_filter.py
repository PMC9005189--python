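"""Inclusion/exclusion rules and the basal-SD detection threshold.

Raw biosensor measurements pass four filters, in order:

1. drop responses flagged as equivalent to endogenous-receptor signal;
2. resolve unconverged concentration-response curves (kept only when
   supported, and not contradicted, by independent evidence);
3. shift pEC50 values reported in enzymatic ligand units onto the molar
   scale (a fixed additive offset);
4. call each datapoint coupler / non-coupler with the basal-SD cut-off:
   a coupler must exceed ``basal_mean + k * basal_sd`` (strictly).

Non-coupler values are retained but masked from quantitative analyses.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = [
    "QCConfig",
    "shift_enzymatic_pec50",
    "apply_exclusions",
    "resolve_unconverged",
    "build_cross_support",
    "apply_sd_cutoff",
    "apply_qc",
]

DEFAULT_SD_MULTIPLE = 1.4
DEFAULT_ENZYMATIC_OFFSET = 10.0


@dataclasses.dataclass
class QCConfig:
    """Quality-control parameters.

    sd_multiple_k
        Detection threshold in units of the interday basal SD; a
        datapoint is a coupler iff Emax > basal + k * SD (strict).
    enzymatic_pec50_offset
        Added to pEC50 values measured in enzymatic activity units
        (e.g. thrombin mU/ml) to place them on the common scale.
    cross_support
        Mapping (receptor, gprotein) -> (supported, contradicted)
        used to resolve unconverged curves.  May be None when the
        input contains no unconverged records.
    """

    sd_multiple_k: float = DEFAULT_SD_MULTIPLE
    enzymatic_pec50_offset: float = DEFAULT_ENZYMATIC_OFFSET
    cross_support: dict | None = None

    def __post_init__(self):
        if self.sd_multiple_k < 0:
            raise ValueError("sd_multiple_k must be nonnegative")


def shift_enzymatic_pec50(df: pd.DataFrame,
                          offset: float = DEFAULT_ENZYMATIC_OFFSET) -> pd.DataFrame:
    """Add ``offset`` to the pEC50 of enzymatic-unit records; all else unchanged."""
    out = df.copy()
    mask = out["enzymatic_units"].astype(bool)
    out.loc[mask, "pec50"] = out.loc[mask, "pec50"] + offset
    out.loc[mask, "enzymatic_units"] = False  # now on the common scale
    return out


def apply_exclusions(df: pd.DataFrame):
    """Remove records flagged as endogenous-receptor-equivalent responses.

    Returns ``(kept, dropped_log)``; the log records one row per dropped
    measurement with a reason code.
    """
    flagged = df["exclusion"] == "endogenous_equivalent"
    dropped = df.loc[flagged, ["source", "receptor", "gprotein"]].copy()
    dropped["reason"] = "endogenous_equivalent"
    return df.loc[~flagged].reset_index(drop=True), dropped.reset_index(drop=True)


def build_cross_support(df: pd.DataFrame, other_grid: pd.DataFrame | None,
                        annotation_grid: pd.DataFrame | None) -> dict:
    """Build the support lookup used to adjudicate unconverged curves.

    For every unconverged (receptor, gprotein) pair in ``df``:
    supported iff the other quantitative source called the pair a
    coupler or the literature annotation allows the subtype; contradicted
    iff the other quantitative source tested the pair and found
    non-coupling.  Grids are receptor x subtype with NaN = untested.
    """
    lookup: dict = {}
    pending = df.loc[df["curve_status"] == "unconverged_approximate",
                     ["receptor", "gprotein"]]
    for receptor, gprotein in pending.itertuples(index=False):
        supported = False
        contradicted = False
        if other_grid is not None and receptor in other_grid.index \
                and gprotein in other_grid.columns:
            cell = other_grid.loc[receptor, gprotein]
            if pd.notna(cell):
                if bool(cell):
                    supported = True
                else:
                    contradicted = True
        if annotation_grid is not None and receptor in annotation_grid.index \
                and gprotein in annotation_grid.columns:
            if bool(annotation_grid.loc[receptor, gprotein]):
                supported = True
        lookup[(receptor, gprotein)] = (supported, contradicted)
    return lookup


def resolve_unconverged(df: pd.DataFrame, cross_support: dict | None):
    """Keep unconverged-curve records only when supported and uncontradicted.

    Returns ``(kept, dropped_log)``.  Raises ``KeyError`` if an
    unconverged pair is absent from the lookup (the rule cannot be
    evaluated).
    """
    pending = df["curve_status"] == "unconverged_approximate"
    if not pending.any():
        return df.reset_index(drop=True), _empty_log()
    if cross_support is None:
        raise KeyError("cross_support lookup required to resolve unconverged curves")
    drop_idx = []
    reasons = []
    for idx, row in df.loc[pending].iterrows():
        key = (row["receptor"], row["gprotein"])
        if key not in cross_support:
            raise KeyError(f"no cross-support entry for unconverged pair {key}")
        supported, contradicted = cross_support[key]
        if contradicted:
            drop_idx.append(idx)
            reasons.append("unconverged_contradicted")
        elif not supported:
            drop_idx.append(idx)
            reasons.append("unconverged_unsupported")
    dropped = df.loc[drop_idx, ["source", "receptor", "gprotein"]].copy()
    dropped["reason"] = reasons
    kept = df.drop(index=drop_idx).reset_index(drop=True)
    return kept, dropped.reset_index(drop=True)


def apply_sd_cutoff(df: pd.DataFrame, k: float = DEFAULT_SD_MULTIPLE) -> pd.DataFrame:
    """Call couplers with the basal-SD threshold (strict inequality).

    Adds a boolean ``coupler`` column: True iff the curve produced a
    response and Emax > basal_mean + k * basal_sd.  Values of
    non-couplers are retained (masking happens downstream).
    """
    if k < 0:
        raise ValueError("SD multiple must be nonnegative")
    out = df.copy()
    has_curve = out["curve_status"] != "no_activity"
    threshold = out["basal_mean"] + k * out["basal_sd"]
    with np.errstate(invalid="ignore"):
        above = out["emax"] > threshold
    out["coupler"] = (has_curve & above.fillna(False)).astype(bool)
    return out


def apply_qc(df: pd.DataFrame, cfg: QCConfig):
    """Run the full filter chain in the canonical order.

    Order: exclusions -> unconverged resolution -> enzymatic pEC50
    shift -> SD cut-off.  Returns ``(measurements, dropped_log)``.
    The composition is idempotent: re-running it on its own output
    changes nothing.
    """
    out, log1 = apply_exclusions(df)
    out, log2 = resolve_unconverged(out, cfg.cross_support)
    out = shift_enzymatic_pec50(out, cfg.enzymatic_pec50_offset)
    out = apply_sd_cutoff(out, cfg.sd_multiple_k)
    log = pd.concat([log1, log2], ignore_index=True) if len(log1) or len(log2) \
        else _empty_log()
    return out, log


def _empty_log() -> pd.DataFrame:
    return pd.DataFrame(columns=["source", "receptor", "gprotein", "reason"])
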