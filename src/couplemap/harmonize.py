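"""Normalization of Emax, the combined log(Emax/EC50) activity value,
family aggregation, and evaluation of alternative integration protocols.

The selected protocol, used for the unified map, is:

* Emax minus basal, min-max normalized per G protein across receptors
  (0 = no-agonist signal, 1 = the largest response for that G protein);
* pEC50 used as published (no normalization);
* the two combined as log(Emax/EC50) = log10(emax_frac) + pEC50;
* subtype-to-family aggregation by the maximum subtype value.

Cross-source comparability of a protocol is scored by the mean
"similarity" of paired datapoints -- the symmetric ratio
min(x, y)/max(x, y), bounded in (0, 1] -- and by mean squared Pearson
correlations computed receptor-wise (across G proteins) and
G-protein-wise (across receptors).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import GProteinPanel, human_panel

__all__ = [
    "minmax_normalize_emax",
    "log_emax_ec50",
    "harmonize",
    "aggregate_to_family",
    "similarity",
    "mean_similarity",
    "receptorwise_r2",
    "gproteinwise_r2",
    "evaluate_protocols",
    "PROTOCOL_SCHEMES",
]


def minmax_normalize_emax(df: pd.DataFrame) -> pd.DataFrame:
    """Min-max normalize net Emax per (source, G protein) across receptors.

    The minimum is pinned at 0 (the no-agonist signal); the maximum is
    the largest basal-subtracted response among couplers for that G
    protein, which maps to exactly 1.  Adds ``emax_frac`` (NaN for
    non-couplers).  A G protein whose responses are all nonpositive is
    left NaN and reported via the ``flagged`` attribute-free return: a
    warning column is unnecessary, callers see NaN.
    """
    out = df.copy()
    net = out["emax"] - out["basal_mean"]
    mask = out["coupler"].astype(bool) & (net > 0)
    out["emax_frac"] = np.nan
    for (_, _), idx in out.groupby(["source", "gprotein"]).groups.items():
        sel = out.loc[idx]
        m = mask.loc[idx]
        if not m.any():
            continue
        top = net.loc[idx][m].max()
        out.loc[sel.index[m], "emax_frac"] = net.loc[idx][m] / top
    return out


def log_emax_ec50(emax_frac, pec50):
    """Combined efficacy-potency value: log10(emax_frac) + pEC50.

    Defined for fractional Emax in (0, 1]; equals pEC50 when the
    receptor gives the maximal response for the G protein.
    """
    emax_frac = np.asarray(emax_frac, dtype=float)
    if np.any(emax_frac[~np.isnan(emax_frac)] <= 0):
        raise ValueError("emax_frac must be positive (non-couplers are undefined)")
    return np.log10(emax_frac) + np.asarray(pec50, dtype=float)


def harmonize(df: pd.DataFrame, panel: GProteinPanel | None = None) -> pd.DataFrame:
    """Produce the harmonized long table for one source.

    Input must carry the ``coupler`` flag.  Output adds ``family``,
    ``emax_frac`` and ``log_emax_ec50`` (both NaN for non-couplers).
    """
    panel = panel or human_panel()
    out = minmax_normalize_emax(df)
    out["family"] = out["gprotein"].map({s: panel.family_of(s)
                                         for s in set(out["gprotein"])})
    valid = out["emax_frac"].notna()
    out["log_emax_ec50"] = np.nan
    out.loc[valid, "log_emax_ec50"] = log_emax_ec50(
        out.loc[valid, "emax_frac"], out.loc[valid, "pec50"])
    return out


def aggregate_to_family(harmonized: pd.DataFrame,
                        panel: GProteinPanel | None = None,
                        rule: str = "max") -> pd.DataFrame:
    """Aggregate subtype values onto families.

    With ``rule="max"`` (the selected protocol) the family value is the
    maximum subtype log(Emax/EC50) among couplers, and the reported
    family Emax fraction / pEC50 are those of the argmax subtype.  With
    ``rule="mean"`` (protocol evaluation only) plain means are used.
    A family with no coupler subtype is a non-coupler.
    """
    if rule not in {"max", "mean"}:
        raise ValueError(f"rule must be 'max' or 'mean', got {rule!r}")
    panel = panel or human_panel()
    rows = []
    for (source, receptor, family), grp in harmonized.groupby(
            ["source", "receptor", "family"]):
        couplers = grp[grp["coupler"].astype(bool) & grp["log_emax_ec50"].notna()]
        if couplers.empty:
            rows.append({"source": source, "receptor": receptor,
                         "family": family, "coupler": False,
                         "emax_frac": np.nan, "pec50": np.nan,
                         "log_emax_ec50": np.nan})
            continue
        if rule == "max":
            top = couplers.loc[couplers["log_emax_ec50"].idxmax()]
            rows.append({"source": source, "receptor": receptor,
                         "family": family, "coupler": True,
                         "emax_frac": top["emax_frac"], "pec50": top["pec50"],
                         "log_emax_ec50": top["log_emax_ec50"]})
        else:
            rows.append({"source": source, "receptor": receptor,
                         "family": family, "coupler": True,
                         "emax_frac": couplers["emax_frac"].mean(),
                         "pec50": couplers["pec50"].mean(),
                         "log_emax_ec50": couplers["log_emax_ec50"].mean()})
    return pd.DataFrame(rows)


def similarity(xa, xb):
    """Symmetric ratio min/max in (0, 1]; 1 iff equal; scale-invariant."""
    xa = np.asarray(xa, dtype=float)
    xb = np.asarray(xb, dtype=float)
    lo = np.minimum(xa, xb)
    hi = np.maximum(xa, xb)
    with np.errstate(divide="ignore", invalid="ignore"):
        return lo / hi


def mean_similarity(xa, xb) -> float:
    """Mean min/max ratio over paired datapoints; nonpositive pairs skipped."""
    xa = np.asarray(xa, dtype=float)
    xb = np.asarray(xb, dtype=float)
    ok = (xa > 0) & (xb > 0)
    if not ok.any():
        return float("nan")
    return float(similarity(xa[ok], xb[ok]).mean())


def _mean_groupwise_r2(paired: pd.DataFrame, by: str, min_points: int = 3) -> float:
    vals = []
    for _, grp in paired.groupby(by):
        grp = grp.dropna(subset=["value_a", "value_b"])
        if len(grp) < min_points:
            continue
        if grp["value_a"].nunique() < 2 or grp["value_b"].nunique() < 2:
            continue
        r, _ = stats.pearsonr(grp["value_a"], grp["value_b"])
        vals.append(r * r)
    return float(np.mean(vals)) if vals else float("nan")


def receptorwise_r2(paired: pd.DataFrame, min_points: int = 3) -> float:
    """Mean squared Pearson r of each receptor's profile across units.

    ``paired`` columns: receptor, unit, value_a, value_b -- one row per
    common coupler datapoint.  Receptors with fewer than ``min_points``
    common units are skipped; the mean over qualifying receptors is
    unweighted.
    """
    return _mean_groupwise_r2(paired, "receptor", min_points)


def gproteinwise_r2(paired: pd.DataFrame, min_points: int = 3) -> float:
    """Mean squared Pearson r of each unit's profile across receptors."""
    return _mean_groupwise_r2(paired, "unit", min_points)


PROTOCOL_SCHEMES = (
    "raw_emax", "minmax_emax", "double_norm_emax", "pec50", "log_emax_ec50",
)


def _double_normalize(values: pd.DataFrame) -> pd.DataFrame:
    # second min-max pass across G proteins within each receptor
    top = values.max(axis=1, skipna=True)
    return values.div(top.replace(0, np.nan), axis=0)


def _paired_table(va: pd.DataFrame, vb: pd.DataFrame) -> pd.DataFrame:
    common_r = va.index.intersection(vb.index)
    common_u = va.columns.intersection(vb.columns)
    rows = []
    for r in common_r:
        for u in common_u:
            a, b = va.loc[r, u], vb.loc[r, u]
            if pd.notna(a) and pd.notna(b):
                rows.append({"receptor": r, "unit": u,
                             "value_a": a, "value_b": b})
    return pd.DataFrame(rows, columns=["receptor", "unit", "value_a", "value_b"])


def _value_grid(harm: pd.DataFrame, column: str, unit_col: str) -> pd.DataFrame:
    sub = harm[harm["coupler"].astype(bool)]
    return sub.pivot_table(index="receptor", columns=unit_col,
                           values=column, aggfunc="mean")


def evaluate_protocols(harm_a: pd.DataFrame, harm_b: pd.DataFrame,
                       panel: GProteinPanel | None = None,
                       receptors=None) -> pd.DataFrame:
    """Score every candidate integration protocol on two harmonized sources.

    Inputs are harmonized per-source tables (from :func:`harmonize`);
    ``receptors`` restricts to the comparable subset (same-ligand class A
    receptors in the full-scale analysis).  One output row per scheme at
    the subtype level plus family-aggregated (max and mean) variants of
    the combined value; the selected protocol is flagged.
    """
    panel = panel or human_panel()
    if receptors is not None:
        receptors = set(receptors)
        harm_a = harm_a[harm_a["receptor"].isin(receptors)]
        harm_b = harm_b[harm_b["receptor"].isin(receptors)]

    def net_emax(h):
        grid = _value_grid(h.assign(net=h["emax"] - h["basal_mean"]),
                           "net", "gprotein")
        return grid.where(grid > 0)

    grids = {}
    for scheme in PROTOCOL_SCHEMES:
        if scheme == "raw_emax":
            ga, gb = net_emax(harm_a), net_emax(harm_b)
        elif scheme == "minmax_emax":
            ga = _value_grid(harm_a, "emax_frac", "gprotein")
            gb = _value_grid(harm_b, "emax_frac", "gprotein")
        elif scheme == "double_norm_emax":
            ga = _double_normalize(_value_grid(harm_a, "emax_frac", "gprotein"))
            gb = _double_normalize(_value_grid(harm_b, "emax_frac", "gprotein"))
        elif scheme == "pec50":
            ga = _value_grid(harm_a, "pec50", "gprotein")
            gb = _value_grid(harm_b, "pec50", "gprotein")
        else:
            ga = _value_grid(harm_a, "log_emax_ec50", "gprotein")
            gb = _value_grid(harm_b, "log_emax_ec50", "gprotein")
        grids[(scheme, "subtype")] = (ga, gb)

    for rule in ("max", "mean"):
        fa = aggregate_to_family(harm_a, panel, rule)
        fb = aggregate_to_family(harm_b, panel, rule)
        ga = _value_grid(fa, "log_emax_ec50", "family")
        gb = _value_grid(fb, "log_emax_ec50", "family")
        grids[("log_emax_ec50", f"family_{rule}")] = (ga, gb)

    rows = []
    for (scheme, level), (ga, gb) in grids.items():
        paired = _paired_table(ga, gb)
        rows.append({
            "scheme": scheme,
            "level": level,
            "mean_similarity": mean_similarity(paired["value_a"],
                                               paired["value_b"]),
            "mean_r2_receptorwise": receptorwise_r2(paired),
            "mean_r2_gproteinwise": gproteinwise_r2(paired),
            "n_datapoints": len(paired),
            "selected": scheme == "log_emax_ec50" and level in {"subtype",
                                                                "family_max"},
        })
    return pd.DataFrame(rows)
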