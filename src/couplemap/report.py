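"""End-to-end pipeline driver, coverage summaries, and the run manifest.

``run_pipeline`` executes the whole method in order -- ingest (or
simulate), QC filters, SD cut-off (fixed or optimized), agreement
statistics, harmonization, unified-map assembly, selectivity,
co-coupling, and optionally tissue expression -- and writes a TSV/JSON
bundle plus a manifest that records the configuration hash, chosen
cut-off, universe sizes and seeds, so every reported number traces to a
manifest.  Identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cocoupling import (activation_difference, coupling_vectors,
                         correlation_tree, jaccard_matrix, linkage_to_newick,
                         pearson_matrix)
from .concordance import (DEFAULT_CUTOFF_GRID, agreement_by_ligand_match,
                          coupling_grid, optimize_sd_cutoff,
                          pairwise_agreement, threeway_agreement)
from .coupling_map import (build_unified_map, find_contradicted_annotations,
                           find_novel, unique_missing_summary)
from .data_io import (ANALYSIS_SUBTYPES, expand_annotation_to_subtypes,
                      human_panel, read_annotation_table,
                      read_quantitative_table)
from .harmonize import aggregate_to_family, harmonize
from .qc_filter import (apply_exclusions, apply_sd_cutoff, build_cross_support,
                        resolve_unconverged, shift_enzymatic_pec50)
from .selectivity import (gprotein_coverage, promiscuity_distribution,
                          venn_intersections, within_family_promiscuity)
from .synthetic_data import (recovery_scores, simulate_study,
                             synthetic_expression_matrix)
from .tissue_expression import (coexpression_cluster, display_cap,
                                quartile_threshold, tissues_above_threshold,
                                zscore_per_gene)

__all__ = ["run_pipeline", "summarize_coverage", "config_hash"]


class PipelineError(RuntimeError):
    """Raised with a stage-tagged message when any stage fails."""


def config_hash(config: dict) -> str:
    canon = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # stage-tagged abort
            raise PipelineError(f"[{name}] {exc}") from exc
    return wrap


def _value_grid(harm: pd.DataFrame) -> pd.DataFrame:
    sub = harm[harm["coupler"].astype(bool)]
    return sub.pivot_table(index="receptor", columns="gprotein",
                           values="log_emax_ec50", aggfunc="mean")


def _labels_str(labels) -> str:
    return "|".join(sorted(labels))


def summarize_coverage(family_grids: dict, annotation_grid: pd.DataFrame | None = None) -> dict:
    """Dataset coverage statistics over family-level coupling grids.

    ``family_grids`` maps source id -> receptor x family grid (1/0/NaN);
    include the annotation source as an expanded grid to reproduce the
    three-way coverage summary.
    """
    grids = dict(family_grids)
    if annotation_grid is not None:
        grids["annotation"] = annotation_grid
    out = {"per_source": {}, "n_sources": len(grids)}
    receptor_sets = {s: set(g.index) for s, g in grids.items()}
    for source, grid in grids.items():
        tested = grid.notna()
        couplers = grid.fillna(0).astype(bool) & tested
        n_cells = int(tested.values.sum())
        fam_per_receptor = couplers.sum(axis=1)
        share = couplers.sum(axis=0)
        total = share.sum()
        out["per_source"][source] = {
            "n_receptors": int(len(grid.index)),
            "coupler_cell_fraction": float(couplers.values.sum() / n_cells)
            if n_cells else float("nan"),
            "mean_families_per_receptor": float(fam_per_receptor.mean()),
            "family_share": {f: float(share[f] / total) if total else 0.0
                             for f in grid.columns},
        }
    union = set().union(*receptor_sets.values())
    inter = set.intersection(*receptor_sets.values())
    out["n_receptors_union"] = len(union)
    out["n_receptors_all_sources"] = len(inter)
    return out


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the full analysis described by ``config`` and write the bundle.

    Config keys (YAML-friendly): ``mode`` ("synthetic" or "files"),
    ``seed``, ``n_receptors``, ``low_noise``, ``cutoff`` ("optimize" or a
    number), ``inputs`` (paths for files mode), ``expression``
    ("synthetic", a path, or null).  Returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = human_panel()
    seed = int(config.get("seed", 0))
    manifest = {"config_hash": config_hash(config), "seed": seed,
                "version": __version__, "inputs": {}, "outputs": {},
                "universes": {}}

    # -- ingest ------------------------------------------------------------
    if config.get("mode", "synthetic") == "synthetic":
        truth, meas_a, meas_b, annotations = _stage("ingest")(
            simulate_study, int(config.get("n_receptors", 300)), seed,
            bool(config.get("low_noise", False)),
            config.get("annotation_prob"))
    else:
        truth = None
        inputs = config.get("inputs", {})
        for key in ("source_a", "source_b", "annotations"):
            if key not in inputs:
                raise PipelineError(f"[ingest] missing input path: {key}")
            if not Path(inputs[key]).exists():
                raise PipelineError(f"[ingest] input not readable: {inputs[key]}")
            manifest["inputs"][key] = _digest(Path(inputs[key]))
        meas_a = read_quantitative_table(inputs["source_a"], "source_a", panel)
        meas_b = read_quantitative_table(inputs["source_b"], "source_b", panel)
        annotations = read_annotation_table(inputs["annotations"])

    # -- QC ----------------------------------------------------------------
    def qc(own, other, k_prelim):
        own, log = apply_exclusions(own)
        if (own["curve_status"] == "unconverged_approximate").any():
            other_grid = coupling_grid(
                apply_sd_cutoff(shift_enzymatic_pec50(other), k_prelim),
                "subtype", panel)
            ann_grid = expand_annotation_to_subtypes(annotations, panel) \
                if len(annotations) else None
            support = build_cross_support(own, other_grid, ann_grid)
            own, log2 = resolve_unconverged(own, support)
            log = pd.concat([log, log2], ignore_index=True)
        return shift_enzymatic_pec50(own), log

    k_prelim = float(config.get("prelim_cutoff", 1.4))
    meas_a, log_a = _stage("qc")(qc, meas_a, meas_b, k_prelim)
    meas_b, log_b = _stage("qc")(qc, meas_b, meas_a, k_prelim)
    qc_log = pd.concat([log_a, log_b], ignore_index=True)

    # -- SD cut-off --------------------------------------------------------
    cutoff_cfg = config.get("cutoff", "optimize")
    if cutoff_cfg == "optimize":
        k_star, curve = _stage("cutoff")(optimize_sd_cutoff, meas_a, meas_b,
                                         DEFAULT_CUTOFF_GRID, "subtype", panel)
        curve.to_csv(outdir / "cutoff_curve.tsv", sep="\t", index=False)
    else:
        k_star, curve = float(cutoff_cfg), None
    meas_a = apply_sd_cutoff(meas_a, k_star)
    meas_b = apply_sd_cutoff(meas_b, k_star)
    manifest["sd_cutoff"] = k_star

    # -- agreement ---------------------------------------------------------
    grid_a = coupling_grid(meas_a, "subtype", panel)
    grid_b = coupling_grid(meas_b, "subtype", panel)
    fam_a = coupling_grid(meas_a, "family", panel)
    fam_b = coupling_grid(meas_b, "family", panel)
    agr_sub = pairwise_agreement(grid_a, grid_b, "subtype")
    agr_fam = pairwise_agreement(fam_a, fam_b, "family")
    agreement = {
        "subtype_mean": agr_sub.mean_agreement,
        "subtype_per_unit": agr_sub.per_unit.to_dict(),
        "family_mean": agr_fam.mean_agreement,
        "family_per_unit": agr_fam.per_unit.to_dict(),
        "n_pairs_subtype": agr_sub.n_pairs,
    }
    if len(annotations):
        ann_fam = pd.DataFrame(
            False, index=sorted(set(annotations["receptor"])),
            columns=list(panel.families))
        for r, f in annotations[["receptor", "family"]].itertuples(index=False):
            ann_fam.loc[r, f] = True
        try:
            agr3 = threeway_agreement(fam_a, fam_b, ann_fam.astype(float),
                                      "family")
            agreement["threeway_family_mean"] = agr3.mean_agreement
            agreement["threeway_per_family"] = agr3.per_unit.to_dict()
        except ValueError:
            pass
    shared = dict(meas_a.groupby("receptor")["ligand_shared"].agg("all")
                  & meas_b.groupby("receptor")["ligand_shared"].agg("all"))
    same, diff = agreement_by_ligand_match(grid_a, grid_b, shared)
    agreement["same_ligand"] = same
    agreement["different_ligand"] = diff

    # -- harmonize and build the unified map -------------------------------
    harm_a = _stage("harmonize")(harmonize, meas_a, panel)
    harm_b = _stage("harmonize")(harmonize, meas_b, panel)
    pd.concat([harm_a, harm_b], ignore_index=True).to_csv(
        outdir / "harmonized.tsv", sep="\t", index=False)

    coupler_grids = {"assay_a": grid_a, "assay_b": grid_b}
    value_grids = {"assay_a": _value_grid(harm_a), "assay_b": _value_grid(harm_b)}
    map_df, patterns = _stage("map")(build_unified_map, coupler_grids,
                                     value_grids, annotations, panel)
    novel = find_novel(patterns)
    contradicted = find_contradicted_annotations(patterns, annotations)
    common = set(grid_a.index) & set(grid_b.index)
    if len(annotations):
        common &= set(annotations["receptor"])
    unique_missing = (unique_missing_summary(patterns, common)
                      if common else None)

    # -- selectivity -------------------------------------------------------
    tested = (grid_a.notna().reindex(index=grid_a.index.union(grid_b.index),
                                     columns=ANALYSIS_SUBTYPES, fill_value=False)
              | grid_b.notna().reindex(index=grid_a.index.union(grid_b.index),
                                       columns=ANALYSIS_SUBTYPES,
                                       fill_value=False))
    promiscuity = promiscuity_distribution(map_df)
    coverage = gprotein_coverage(map_df, panel, tested)
    within_family = within_family_promiscuity(map_df, tested, panel)
    venn = venn_intersections(map_df, "family", panel)

    # -- co-coupling -------------------------------------------------------
    vectors_zero = coupling_vectors(map_df, zero_fill=True,
                                    subtypes=ANALYSIS_SUBTYPES)
    vectors_masked = coupling_vectors(map_df, zero_fill=False,
                                      subtypes=ANALYSIS_SUBTYPES)
    cocoupling = {}
    if len(vectors_zero) >= 3:
        r_df, p_df = pearson_matrix(vectors_zero)
        sets = {s: set(vectors_masked.index[vectors_masked[s].notna()])
                for s in vectors_masked.columns}
        jac = jaccard_matrix(sets)
        act = activation_difference(vectors_masked)
        r_df.to_csv(outdir / "cocoupling_pearson_r.tsv", sep="\t")
        p_df.to_csv(outdir / "cocoupling_pearson_p.tsv", sep="\t")
        jac.to_csv(outdir / "cocoupling_jaccard.tsv", sep="\t")
        act.to_csv(outdir / "cocoupling_activation_diff.tsv", sep="\t")
        if not r_df.isna().any().any():
            linkage, leaves = correlation_tree(r_df)
            (outdir / "cocoupling_tree.nwk").write_text(
                linkage_to_newick(linkage, list(r_df.columns)) + "\n")
            cocoupling["leaf_order"] = leaves

    # -- tissue expression (optional) --------------------------------------
    expression = None
    expr_cfg = config.get("expression")
    if expr_cfg:
        if expr_cfg == "synthetic":
            mat = synthetic_expression_matrix(seed)
            expr_source = "synthetic"
        else:
            from .data_io import read_expression_table
            mat = read_expression_table(expr_cfg)
            expr_source = "file (release-sensitive: printed reference values "
            expr_source += "depend on the atlas release)"
        threshold = quartile_threshold(mat)
        counts = tissues_above_threshold(mat, threshold)
        _, flagged = zscore_per_gene(mat)
        _, order, _ = coexpression_cluster(mat)
        expression = {
            "source": expr_source,
            "quartile_threshold_ntpm": threshold,
            "display_cap_ntpm": display_cap(mat),
            "tissues_above_threshold": counts.to_dict(),
            "constant_genes": flagged,
            "cluster_order": order,
        }

    # -- bundle ------------------------------------------------------------
    map_out = map_df.copy()
    map_out["labels"] = map_out["labels"].map(_labels_str)
    map_out.to_csv(outdir / "unified_map.tsv", sep="\t", index=False)
    qc_log.to_csv(outdir / "qc_dropped.tsv", sep="\t", index=False)
    if unique_missing is not None:
        unique_missing.to_csv(outdir / "unique_missing.tsv", sep="\t",
                              index=False)

    results = {
        "agreement": agreement,
        "novel": {k: novel[k] for k in ("n_receptors", "n_couplings",
                                        "family_tally", "n_family_pairs")},
        "contradicted_annotations": [list(t) for t in contradicted],
        "promiscuity": promiscuity,
        "coverage": {
            "per_family": coverage["per_family"],
            "per_subtype": coverage["per_subtype"],
            "mean_receptors_per_family": coverage["mean_receptors_per_family"],
            "universe": coverage["universe"],
        },
        "within_family_promiscuity": within_family,
        "venn_family": {"|".join(sorted(k)): v for k, v in venn.items()},
        "cocoupling": cocoupling,
        "expression": expression,
    }
    if truth is not None:
        results["recovery"] = recovery_scores(map_df, truth)
    (outdir / "results.json").write_text(
        json.dumps(results, indent=2, default=_json_default))

    manifest["universes"] = {
        "map_receptors": int(map_df["receptor"].nunique()),
        "quantitative_receptors": int(
            map_df.loc[map_df["section"] == "quantitative",
                       "receptor"].nunique()),
        "annotation_only_receptors": int(
            map_df.loc[map_df["section"] == "annotation_only",
                       "receptor"].nunique()),
        "common_receptors": len(common),
    }
    for f in sorted(outdir.glob("*")):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _digest(f)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
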