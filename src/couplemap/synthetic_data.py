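"""Ground-truth couplome simulation and synthetic assay/annotation data.

The generator emulates the statistical structure the pipeline assumes:

* a bipartite receptor x G-protein couplome organized in four family
  blocks -- a receptor couples a family with a family-specific
  prevalence, and a coupled family activates each member subtype with a
  common within-family probability (at least one member always);
* two concentration-response screens with per-G-protein assay windows,
  detection sensitivities and interday basal noise, optionally using
  chimeric-probe equivalence classes that duplicate one measured value
  to several subtypes;
* a biased literature-annotation process reporting coupled families
  with per-family probabilities (G12/13 underreported by default).

Family prevalences default to the observed full-scale family coverage
fractions (0.34 / 0.69 / 0.52 / 0.19), so the expected number of
coupled families per receptor is about 1.74.  All generators are
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .data_io import (ANALYSIS_SUBTYPES, FAMILIES, MEASUREMENT_COLUMNS,
                      GProteinPanel, human_panel)

__all__ = [
    "DEFAULT_FAMILY_PREVALENCE",
    "DEFAULT_ANNOTATION_PROB",
    "SyntheticTruth",
    "AssayModel",
    "generate_truth",
    "simulate_assay",
    "simulate_annotation",
    "simulate_threshold_pair",
    "simulate_study",
    "recovery_scores",
    "synthetic_expression_matrix",
    "synthetic_tissue_groups",
    "GPROTEIN_GENES",
]

DEFAULT_FAMILY_PREVALENCE = {
    "Gs": 0.34, "Gi/o": 0.69, "Gq/11": 0.52, "G12/13": 0.19,
}

# literature reporting probabilities: G12/13 couplings underrepresented
DEFAULT_ANNOTATION_PROB = {
    "Gs": 0.8, "Gi/o": 0.8, "Gq/11": 0.8, "G12/13": 0.2,
}

_ANALYSIS_EQUIVALENCE = (
    frozenset({"Gi1", "Gi2"}),
    frozenset({"GoA", "GoB"}),
    frozenset({"Gq", "G11"}),
)


@dataclasses.dataclass
class SyntheticTruth:
    """Ground-truth couplome plus the generative parameters behind it."""

    couplome: pd.DataFrame          # receptor x subtype, boolean
    family_coupled: pd.DataFrame    # receptor x family, boolean
    true_pec50: pd.DataFrame        # NaN where non-coupler
    true_emax_frac: pd.DataFrame    # (0, 1], NaN where non-coupler
    family_prevalence: dict
    within_family_activation_prob: float
    seed: int

    @property
    def receptors(self):
        return list(self.couplome.index)

    @property
    def subtypes(self):
        return list(self.couplome.columns)


def generate_truth(n_receptors: int = 300,
                   family_prevalence: dict | None = None,
                   within_family_activation_prob: float = 0.9,
                   weak_fraction: float = 0.15,
                   pec50_mean: float = 7.0, pec50_sd: float = 1.0,
                   seed: int = 0,
                   panel: GProteinPanel | None = None,
                   subtypes=ANALYSIS_SUBTYPES) -> SyntheticTruth:
    """Draw a ground-truth couplome with family-block structure.

    Couplers receive a true pEC50 ~ Normal(7, 1) and a fractional Emax;
    a ``weak_fraction`` of couplers sit in a low-Emax tail emulating
    weak couplings near the detection limit.
    """
    prevalence = dict(DEFAULT_FAMILY_PREVALENCE if family_prevalence is None
                      else family_prevalence)
    for fam, p in prevalence.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"prevalence for {fam} outside [0, 1]: {p}")
    if not 0.0 <= within_family_activation_prob <= 1.0:
        raise ValueError("within_family_activation_prob outside [0, 1]")
    panel = panel or human_panel()
    rng = np.random.default_rng(seed)

    receptors = [f"R{i:04d}" for i in range(1, n_receptors + 1)]
    members = {fam: [s for s in panel.members(fam) if s in subtypes]
               for fam in FAMILIES}

    couplome = pd.DataFrame(False, index=receptors, columns=list(subtypes))
    family_coupled = pd.DataFrame(False, index=receptors, columns=list(FAMILIES))
    for fam in FAMILIES:
        mem = members[fam]
        if not mem:
            continue
        fam_hit = rng.random(n_receptors) < prevalence.get(fam, 0.0)
        family_coupled[fam] = fam_hit
        hits = rng.random((n_receptors, len(mem))) < within_family_activation_prob
        none = ~hits.any(axis=1)
        forced = rng.integers(0, len(mem), size=n_receptors)
        hits[np.arange(n_receptors)[none], forced[none]] = True
        hits &= fam_hit[:, None]
        couplome.loc[:, mem] = hits

    pec50 = pd.DataFrame(np.nan, index=receptors, columns=list(subtypes))
    emax = pd.DataFrame(np.nan, index=receptors, columns=list(subtypes))
    mask = couplome.values
    n_couplers = int(mask.sum())
    draws_p = rng.normal(pec50_mean, pec50_sd, size=n_couplers)
    weak = rng.random(n_couplers) < weak_fraction
    draws_e = np.where(weak,
                       rng.uniform(0.05, 0.25, size=n_couplers),
                       rng.uniform(0.4, 1.0, size=n_couplers))
    pec50.values[mask] = draws_p
    emax.values[mask] = draws_e
    return SyntheticTruth(couplome=couplome, family_coupled=family_coupled,
                          true_pec50=pec50, true_emax_frac=emax,
                          family_prevalence=prevalence,
                          within_family_activation_prob=within_family_activation_prob,
                          seed=seed)


@dataclasses.dataclass
class AssayModel:
    """Per-source assay statistics.

    window
        Subtype -> raw-unit dynamic range of the biosensor (smaller
        windows emulate low-signal readouts); ``default_window`` is used
        for unlisted subtypes.
    sensitivity
        Subtype -> probability that a true coupling produces a
        measurable curve at all.
    equivalence
        Probe equivalence classes: subtypes in one class are read out by
        the same physical probe and share a single noisy measurement.
    """

    source_id: str
    subtypes: tuple = ANALYSIS_SUBTYPES
    window: dict = dataclasses.field(default_factory=dict)
    default_window: float = 100.0
    sensitivity: dict = dataclasses.field(default_factory=dict)
    default_sensitivity: float = 1.0
    basal_mean: float = 10.0
    basal_sd_scale: float = 2.0
    emax_noise_sd: float = 0.5
    pec50_noise_sd: float = 0.1
    detection_floor: float = 0.0
    equivalence: tuple = ()

    def window_of(self, subtype: str) -> float:
        return float(self.window.get(subtype, self.default_window))

    def sensitivity_of(self, subtype: str) -> float:
        s = float(self.sensitivity.get(subtype, self.default_sensitivity))
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"sensitivity outside [0, 1] for {subtype}")
        return s


def bouvier_like_model(**overrides) -> AssayModel:
    """Wild-type-probe screen with asymmetric windows (small Gs/G12, huge G15)."""
    kw = dict(source_id="bouvier",
              window={"Gs": 40.0, "G12": 70.0, "G15": 1000.0})
    kw.update(overrides)
    return AssayModel(**kw)


def inoue_like_model(**overrides) -> AssayModel:
    """Chimeric-probe screen: Gi1/Gi2, GoA/GoB and Gq/G11 share a probe."""
    kw = dict(source_id="inoue", equivalence=_ANALYSIS_EQUIVALENCE)
    kw.update(overrides)
    return AssayModel(**kw)


def _probe_classes(model: AssayModel):
    seen = set()
    classes = []
    for s in model.subtypes:
        if s in seen:
            continue
        cls = [m for m in sorted(next((c for c in model.equivalence if s in c),
                                      frozenset({s}))) if m in model.subtypes]
        classes.append(cls)
        seen.update(cls)
    return classes


def simulate_assay(truth: SyntheticTruth, model: AssayModel,
                   seed: int = 0) -> pd.DataFrame:
    """Simulate one screen of the truth couplome in canonical long format.

    Raw Emax = basal + window * true_emax + Gaussian noise for detected
    couplers; undetected cells (missed by sensitivity, below the
    detection floor, or true non-couplers) are reported as no-activity.
    Probe equivalence classes receive one measurement, duplicated to
    every member.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for receptor in truth.receptors:
        for cls in _probe_classes(model):
            members_in_truth = [m for m in cls if m in truth.couplome.columns]
            coupled = any(bool(truth.couplome.loc[receptor, m])
                          for m in members_in_truth)
            rep = cls[0]
            basal = model.basal_mean * rng.uniform(0.9, 1.1)
            basal_sd = model.basal_sd_scale * rng.uniform(0.5, 1.5)
            emax_val, pec50_val, status = np.nan, np.nan, "no_activity"
            if coupled:
                best = max(members_in_truth,
                           key=lambda m: (truth.true_emax_frac.loc[receptor, m]
                                          if bool(truth.couplome.loc[receptor, m])
                                          else -1.0))
                signal = model.window_of(rep) * truth.true_emax_frac.loc[receptor, best]
                detected = rng.random() < model.sensitivity_of(rep)
                if detected and signal > model.detection_floor:
                    emax_val = basal + signal + rng.normal(0.0, model.emax_noise_sd)
                    pec50_val = (truth.true_pec50.loc[receptor, best]
                                 + rng.normal(0.0, model.pec50_noise_sd))
                    status = "converged"
            for member in cls:
                rows.append({
                    "source": model.source_id, "receptor": receptor,
                    "gprotein": member, "ligand": f"lig-{receptor}",
                    "ligand_type": "endogenous", "ligand_shared": True,
                    "pec50": pec50_val, "emax": emax_val,
                    "basal_mean": basal, "basal_sd": basal_sd,
                    "curve_status": status, "enzymatic_units": False,
                    "exclusion": "none",
                })
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def simulate_annotation(truth: SyntheticTruth,
                        report_prob: dict | float | None = None,
                        seed: int = 0) -> pd.DataFrame:
    """Simulate biased literature annotation of the truth couplome.

    Each truly coupled family is annotated with a per-family reporting
    probability.  The annotated family with the highest true activity is
    ranked primary, the rest secondary.  Receptors with no annotated
    family are absent from the table (not annotated at all).
    """
    if report_prob is None:
        report_prob = dict(DEFAULT_ANNOTATION_PROB)
    if np.isscalar(report_prob):
        report_prob = {fam: float(report_prob) for fam in FAMILIES}
    rng = np.random.default_rng(seed)
    log_activity = (np.log10(truth.true_emax_frac) + truth.true_pec50)
    rows = []
    for receptor in truth.receptors:
        annotated = []
        for fam in FAMILIES:
            if not bool(truth.family_coupled.loc[receptor, fam]):
                continue
            p = report_prob.get(fam, 0.0)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"report probability outside [0, 1]: {fam}")
            if rng.random() < p:
                members = [s for s in truth.subtypes
                           if bool(truth.couplome.loc[receptor, s])]
                strength = max((log_activity.loc[receptor, s] for s in members
                                if pd.notna(log_activity.loc[receptor, s])),
                               default=-np.inf)
                annotated.append((fam, strength))
        if not annotated:
            continue
        annotated.sort(key=lambda t: -t[1])
        for i, (fam, _) in enumerate(annotated):
            rows.append({"receptor": receptor, "family": fam,
                         "rank": "primary" if i == 0 else "secondary"})
    return pd.DataFrame(rows, columns=["receptor", "family", "rank"])


def simulate_threshold_pair(n_receptors: int = 150, k_true: float = 2.0,
                            weak_fraction: float = 0.35,
                            weak_margin_span: float = 2.0,
                            noise_sd_frac: float = 0.5,
                            seed: int = 0):
    """Two screens whose best-agreement SD cut-off is ``k_true`` by design.

    Construction: strong couplers sit far above basal in both screens;
    weak couplers sit just above ``k_true`` basal-SDs with an
    independent per-screen margin (so any higher cut-off splits them
    inconsistently); non-couplers show converged but near-basal curves
    whose noise tail reaches just below ``k_true`` (it scales with the
    injected threshold) and occasionally crosses low cut-offs in one
    screen only.  Returns ``(measurements_a, measurements_b, truth)``.
    """
    truth = generate_truth(n_receptors, weak_fraction=0.0, seed=seed)
    rng = np.random.default_rng(seed + 1)
    noise_scale = noise_sd_frac * k_true
    # keep the weak-coupler disagreement band wider than the usual
    # 0-3 scan grid so agreement cannot fully recover above k_true
    weak_margin_span = max(weak_margin_span, 3.2 - k_true)
    coupler = truth.couplome.values
    weak = coupler & (rng.random(coupler.shape) < weak_fraction)

    frames = []
    for offset, source in ((10, "assay_a"), (20, "assay_b")):
        rng_s = np.random.default_rng(seed + offset)
        rows = []
        for i, receptor in enumerate(truth.receptors):
            for j, subtype in enumerate(truth.subtypes):
                basal = 10.0 * rng_s.uniform(0.9, 1.1)
                basal_sd = rng_s.uniform(0.8, 1.2)
                if coupler[i, j] and weak[i, j]:
                    margin = k_true + rng_s.uniform(0.02, weak_margin_span)
                    emax = basal + margin * basal_sd
                    pec50 = rng_s.normal(5.5, 0.4)
                elif coupler[i, j]:
                    emax = basal + (k_true + weak_margin_span + 3.0
                                    + rng_s.uniform(0.0, 5.0)) * basal_sd
                    pec50 = float(truth.true_pec50.iloc[i, j])
                else:
                    emax = basal + rng_s.normal(0.0, noise_scale * basal_sd)
                    pec50 = rng_s.normal(5.0, 0.5)
                rows.append({
                    "source": source, "receptor": receptor, "gprotein": subtype,
                    "ligand": f"lig-{receptor}", "ligand_type": "endogenous",
                    "ligand_shared": True, "pec50": pec50, "emax": emax,
                    "basal_mean": basal, "basal_sd": basal_sd,
                    "curve_status": "converged", "enzymatic_units": False,
                    "exclusion": "none",
                })
        frames.append(pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS))
    return frames[0], frames[1], truth


def simulate_study(n_receptors: int = 300, seed: int = 0,
                   low_noise: bool = False,
                   annotation_prob: dict | float | None = None):
    """One complete synthetic study: truth, two screens, annotations.

    With ``low_noise=True`` both screens use uniform wide windows, full
    sensitivity and wild-type probes (no equivalence duplication) -- the
    regime for end-to-end couplome recovery checks.  Otherwise screen A
    has asymmetric windows and screen B chimeric probes, emulating the
    heterogeneity of real platforms.
    """
    truth = generate_truth(n_receptors, seed=seed)
    if low_noise:
        model_a = AssayModel(source_id="assay_a")
        model_b = AssayModel(source_id="assay_b")
    else:
        model_a = bouvier_like_model(source_id="assay_a",
                                     sensitivity={"Gs": 0.85, "G12": 0.9},
                                     emax_noise_sd=1.0)
        model_b = inoue_like_model(source_id="assay_b",
                                   sensitivity={"G15": 0.85},
                                   emax_noise_sd=1.0)
    meas_a = simulate_assay(truth, model_a, seed=seed + 1)
    meas_b = simulate_assay(truth, model_b, seed=seed + 2)
    annotations = simulate_annotation(truth, annotation_prob, seed=seed + 3)
    return truth, meas_a, meas_b, annotations


def recovery_scores(map_df: pd.DataFrame, truth: SyntheticTruth) -> dict:
    """Precision/recall of supported quantitative couplings against truth."""
    found = set(
        map(tuple, map_df.loc[(map_df["section"] == "quantitative")
                              & map_df["gprotein"].notna(),
                              ["receptor", "gprotein"]].values))
    true_cells = {(r, s) for r in truth.receptors for s in truth.subtypes
                  if bool(truth.couplome.loc[r, s])}
    tp = len(found & true_cells)
    precision = tp / len(found) if found else float("nan")
    recall = tp / len(true_cells) if true_cells else float("nan")
    return {"precision": precision, "recall": recall,
            "n_found": len(found), "n_true": len(true_cells)}


# ---------------------------------------------------------------------------
# synthetic tissue expression fixture (HPA-shaped, 16 genes x 50 tissues)
# ---------------------------------------------------------------------------

GPROTEIN_GENES = (
    "GNAS", "GNAL", "GNAI1", "GNAI2", "GNAI3", "GNAO1", "GNAZ",
    "GNAT1", "GNAT2", "GNAT3", "GNAQ", "GNA11", "GNA14", "GNA15",
    "GNA12", "GNA13",
)

_BRAIN_TISSUES = (
    "cerebral cortex", "cerebellum", "hippocampus", "amygdala",
    "basal ganglia", "midbrain", "hypothalamus", "spinal cord",
    "olfactory bulb", "pituitary gland",
)
_TISSUE_GROUPS = {
    "brain": _BRAIN_TISSUES,
    "eye_and_senses": ("retina",),
    "endocrine": ("thyroid gland", "parathyroid gland", "adrenal gland"),
    "respiratory_and_heart": ("lung", "heart muscle", "tongue",
                              "skeletal muscle", "smooth muscle"),
    "gastrointestinal": ("salivary gland", "esophagus", "stomach", "duodenum",
                         "small intestine", "colon", "rectum", "liver",
                         "gallbladder", "pancreas"),
    "urinary_and_reproductive": ("kidney", "urinary bladder", "testis",
                                 "epididymis", "seminal vesicle", "prostate",
                                 "vagina", "ovary", "fallopian tube",
                                 "endometrium", "placenta", "breast"),
    "skin_and_adipose": ("skin", "adipose tissue",),
    "blood_and_immune": ("appendix", "spleen", "lymph node", "tonsil",
                         "bone marrow", "thymus", "blood"),
}
# brain-enriched subtypes span all four families (one or two per family)
_BRAIN_GENES = ("GNAL", "GNAO1", "GNAZ", "GNAQ", "GNA12")


def synthetic_tissue_groups() -> dict:
    """Tissue -> organ-category mapping for the synthetic fixture (50 -> 8)."""
    return {t: g for g, ts in _TISSUE_GROUPS.items() for t in ts}


def synthetic_expression_matrix(seed: int = 0) -> pd.DataFrame:
    """Deterministic HPA-shaped nTPM fixture (16 Galpha genes x 50 tissues).

    Emulates the qualitative features of the real consensus data:
    ubiquitous GNAS/GNAI2, retina-restricted transducins, gut-restricted
    gustducin, and a brain-enriched block spanning all four families.
    Synthetic: values are generated, not measured.
    """
    tissues = [t for ts in _TISSUE_GROUPS.values() for t in ts]
    assert len(tissues) == 50
    rng = np.random.default_rng(seed)
    mat = pd.DataFrame(rng.lognormal(mean=2.6, sigma=0.5,
                                     size=(len(GPROTEIN_GENES), len(tissues))),
                       index=pd.Index(GPROTEIN_GENES, name="gene"),
                       columns=tissues)
    # ubiquitous, high everywhere
    for gene in ("GNAS", "GNAI2"):
        mat.loc[gene] = rng.uniform(120.0, 400.0, size=len(tissues))
    # single-tissue transducers
    for gene in ("GNAT1", "GNAT2"):
        mat.loc[gene] = rng.uniform(0.1, 2.0, size=len(tissues))
        mat.loc[gene, "retina"] = rng.uniform(300.0, 600.0)
    mat.loc["GNAT3"] = rng.uniform(0.1, 2.0, size=len(tissues))
    for t in _TISSUE_GROUPS["gastrointestinal"][:4]:
        mat.loc["GNAT3", t] = rng.uniform(60.0, 110.0)
    # brain-enriched block, co-expressed across the brain tissues
    brain_profile = rng.uniform(80.0, 160.0, size=len(_BRAIN_TISSUES))
    for gene in _BRAIN_GENES:
        mat.loc[gene, list(_BRAIN_TISSUES)] = (
            brain_profile * rng.uniform(0.8, 1.2, size=len(_BRAIN_TISSUES)))
        peripheral = [t for t in tissues if t not in _BRAIN_TISSUES]
        mat.loc[gene, peripheral] = rng.uniform(1.0, 15.0, size=len(peripheral))
    # low-expressed subtypes
    for gene in ("GNAI3", "GNA14"):
        mat.loc[gene] = rng.uniform(0.5, 8.0, size=len(tissues))
    return mat.round(1)
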