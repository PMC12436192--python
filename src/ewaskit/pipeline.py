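"""End-to-end orchestration: simulate -> QC -> filter -> adjust -> associate -> report.

A single :class:`RunConfig` drives every stage; the run directory ends up
holding the simulated inputs, QC report, probe keep-list, adjusted
matrices, one result table per association design, diagnostics and a
machine-readable ``summary.json`` whose content hashes make reruns
comparable. One global seed expands into per-stage seeds through a
documented counter scheme (stage k draws from ``SeedSequence([seed, k])``),
so individual stages are reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import diagnostics as diag
from . import io as eio
from . import preprocess as prep
from . import qc as qcmod
from .data import EffectSpec, MethylationDataset, ProbeManifest, SampleSheet
from .synthdata import PlantedQC, generate_cohort, generate_manifest, generate_reference

STAGE_SIMULATE_MANIFEST = 0
STAGE_SIMULATE_REFERENCE = 1
STAGE_SIMULATE_COHORT = 2

ALL_DESIGNS = ("case_control", "response_binary", "response_continuous",
               "longitudinal", "smoking")


def stage_seed(seed: int, stage: int) -> int:
    """Per-stage seed: first state word of SeedSequence([seed, stage])."""
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0]
               % (2 ** 31))


@dataclass
class RunConfig:
    seed: int = 42
    n_probes: int = 5000
    n_control_probes: int = 300
    n_reference: int = 100
    frac_snp_close: float = 0.02
    frac_cross_reactive: float = 0.05
    n_patients: int = 120
    n_controls: int = 100
    responder_frac: float = 0.5
    reference_separation: float = 1.5
    effects: EffectSpec = field(default_factory=EffectSpec)
    planted_qc: PlantedQC = field(default_factory=PlantedQC)
    qc_thresholds: qcmod.QCThresholds = field(default_factory=qcmod.QCThresholds)
    k_control_pcs: int = 10
    alpha: float = 0.05
    suggestive: float = 1e-5
    designs: tuple = ALL_DESIGNS

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.suggestive < 1:
            raise ValueError("alpha and suggestive must lie in (0, 1)")
        unknown = set(self.designs) - set(ALL_DESIGNS)
        if unknown:
            raise ValueError(f"unknown designs: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effects"]["dirichlet_alpha"] = list(self.effects.dirichlet_alpha)
        d["designs"] = list(self.designs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("effects"), dict):
            eff = dict(d["effects"])
            for k in ("cc_spiked", "pred_spiked", "long_spiked"):
                eff[k] = [tuple(e) for e in eff.get(k, [])]
            if "dirichlet_alpha" in eff:
                eff["dirichlet_alpha"] = tuple(eff["dirichlet_alpha"])
            d["effects"] = EffectSpec(**eff)
        if isinstance(d.get("planted_qc"), dict):
            d["planted_qc"] = PlantedQC(**d["planted_qc"])
        if isinstance(d.get("qc_thresholds"), dict):
            d["qc_thresholds"] = qcmod.QCThresholds(**d["qc_thresholds"])
        if "designs" in d:
            d["designs"] = tuple(d["designs"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# stage functions (pure: in-memory objects in, in-memory objects out)
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig):
    manifest = generate_manifest(
        config.n_probes, config.n_control_probes, config.n_reference,
        config.frac_snp_close, config.frac_cross_reactive,
        seed=stage_seed(config.seed, STAGE_SIMULATE_MANIFEST))
    reference = generate_reference(
        config.n_reference, config.reference_separation,
        seed=stage_seed(config.seed, STAGE_SIMULATE_REFERENCE))
    cohort = generate_cohort(
        manifest, reference, config.n_patients, config.n_controls,
        config.effects, responder_frac=config.responder_frac,
        seed=stage_seed(config.seed, STAGE_SIMULATE_COHORT),
        planted_qc=config.planted_qc)
    return manifest, reference, cohort


def nuisance_covariates(dataset: MethylationDataset,
                        manifest: ProbeManifest,
                        reference,
                        k_pcs: int) -> pd.DataFrame:
    """Control-probe PCs plus estimated cell fractions (granulocytes as
    the reference category, avoiding collinearity with the intercept)."""
    pcs = prep.control_pcs(dataset.control_betas, k=k_pcs)
    ref_ids = [p for p in manifest.reference_ids if p in dataset.betas.columns]
    cells = prep.estimate_cell_fractions(dataset.betas[ref_ids], reference)
    cell_cols = cells.fractions.drop(columns=["Gran"])
    return pcs.scores.join(cell_cols)


def adjust_dataset(dataset: MethylationDataset,
                   manifest: ProbeManifest,
                   reference,
                   kept_probes: list,
                   k_pcs: int):
    """Two-step adjustment: M values residualized on technical covariates."""
    kept = [p for p in kept_probes if p in dataset.betas.columns]
    m = prep.beta_to_m(dataset.betas[kept])
    covs = nuisance_covariates(dataset, manifest, reference, k_pcs)
    adjusted = prep.residualize(m, covs)
    return m, covs, adjusted


def joint_adjust(datasets: dict,
                 manifest: ProbeManifest,
                 reference,
                 kept_probes: list,
                 k_pcs: int):
    """Technical adjustment fit jointly over all arrays (timepoints stacked).

    Control-probe PCs are computed across every array at once and one
    residualization is fit with common coefficients, so the per-probe
    intercept and covariate effects cancel in within-patient differences
    between timepoints. Returns per-timepoint AdjustedMatrix slices plus
    the stacked M matrix and covariates (array ids "sample:timepoint").
    """
    kept = [p for p in kept_probes
            if all(p in ds.betas.columns for ds in datasets.values())]
    frames, ctrls, cells = [], [], []
    for tp in sorted(datasets):
        ds = datasets[tp]
        aid = [f"{s}:{tp}" for s in ds.sample_ids]
        frames.append(ds.betas[kept].set_axis(aid, axis=0))
        ctrls.append(ds.control_betas.set_axis(aid, axis=0))
        ref_ids = [p for p in manifest.reference_ids if p in ds.betas.columns]
        cells.append(prep.estimate_cell_fractions(
            ds.betas[ref_ids].set_axis(aid, axis=0), reference).fractions)
    betas = pd.concat(frames)
    pcs = prep.control_pcs(pd.concat(ctrls), k=k_pcs)
    cellfrac = pd.concat(cells)
    covs = pcs.scores.join(cellfrac.drop(columns=["Gran"]))
    m = prep.beta_to_m(betas)
    stacked = prep.residualize(m, covs)
    adjusted = {}
    for tp, ds in datasets.items():
        aid = [f"{s}:{tp}" for s in ds.sample_ids]
        sl = stacked.residuals.loc[aid].set_axis(list(ds.sample_ids), axis=0)
        adjusted[tp] = prep.AdjustedMatrix(residuals=sl,
                                           covariates_used=stacked.covariates_used)
    return adjusted, m, covs


def clinical_covariates(sheet: SampleSheet, ids,
                        include_hama_baseline: bool = True,
                        include_smoking: bool = True) -> pd.DataFrame:
    tab = sheet.table.loc[list(ids)]
    out = pd.DataFrame(index=tab.index)
    out["age"] = tab["age"].astype(float)
    out["sex_M"] = (tab["sex"] == "M").astype(float)
    if include_smoking:
        out["smoking"] = tab["smoking"].astype("boolean").astype(float)
    out["depression"] = tab["depression"].astype(float)
    if include_hama_baseline:
        out["hama_t0"] = tab["hama_t0"].astype(float)
    return out


def pct_hama_change(sheet: SampleSheet, to_tp: str) -> pd.Series:
    """100 * (baseline - follow-up) / baseline, per patient with both scores."""
    pats = sheet.patient_ids
    h0 = sheet.table.loc[pats, "hama_t0"]
    h1 = sheet.table.loc[pats, f"hama_{to_tp.lower()}"]
    ok = h0.notna() & h1.notna() & (h0 != 0)
    return (100.0 * (h0[ok] - h1[ok]) / h0[ok]).rename("pct_change")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full analysis graph and write all artifacts to ``outdir``.

    Returns the summary dictionary (also written to ``summary.json``).
    Reruns with the same config are bit-identical.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    log_lines = [f"config: {json.dumps(config.to_dict(), sort_keys=True)}"]

    # ---- simulate ------------------------------------------------------
    manifest, reference, cohort = stage_simulate(config)
    eio.write_manifest(manifest, out / "manifest.tsv")
    eio.write_reference(reference, out / "reference.tsv")
    eio.write_sample_sheet(cohort.sheet, out / "sample_sheet.csv")
    for tp, ds in cohort.datasets.items():
        eio.write_dataset(ds, out / f"data_{tp}")

    # ---- sample QC at baseline; exclusion applies to all analyses ------
    report = qcmod.sample_qc(cohort.datasets["T0"], cohort.sheet, manifest,
                             config.qc_thresholds)
    qc_tab = report.table.copy()
    qc_tab["exclusion_reasons"] = qc_tab["exclusion_reasons"].map(";".join)
    qc_tab.to_csv(out / "qc_report.tsv", sep="\t", float_format="%.15g")
    retained = set(report.retained_ids)
    log_lines.append(f"qc: excluded {len(report.excluded_ids)} samples "
                     f"({sorted(report.excluded_ids)})")

    # ---- probe filter --------------------------------------------------
    keep = qcmod.filter_probes(manifest)
    (out / "keep_list.txt").write_text("\n".join(keep.kept_probe_ids) + "\n")
    bonf = qcmod.bonferroni_threshold(keep.n_evaluated, config.alpha)
    log_lines.append(f"filter: kept {keep.n_evaluated} probes "
                     f"(removed {keep.n_removed_snp} SNP-proximal, "
                     f"{keep.n_removed_cross} cross-reactive, "
                     f"{keep.n_removed_control} control)")
    log_lines.append(f"bonferroni threshold: {bonf!r}")

    # ---- technical adjustment, fit jointly over all arrays -------------
    sheet = cohort.sheet
    subs = {}
    for tp, ds in cohort.datasets.items():
        ids = [s for s in ds.sample_ids if s in retained]
        kept_here = [p for p in keep.kept_probe_ids if p in ds.betas.columns]
        subs[tp] = ds.subset_samples(ids).subset_probes(kept_here)
    adjusted, m_stacked, covs_stacked = joint_adjust(
        subs, manifest, reference, keep.kept_probe_ids, config.k_control_pcs)
    for tp, adj in adjusted.items():
        eio.write_matrix(adj.residuals, out / f"adjusted_{tp}.tsv")
    t0_aid = [f"{s}:T0" for s in subs["T0"].sample_ids]
    nuis_t0 = covs_stacked.loc[t0_aid].set_axis(list(subs["T0"].sample_ids),
                                                axis=0)

    summary: dict = {
        "config": config.to_dict(),
        "bonferroni_threshold": bonf,
        "n_evaluated_probes": keep.n_evaluated,
        "n_removed_snp": keep.n_removed_snp,
        "n_removed_cross_reactive": keep.n_removed_cross,
        "qc_excluded": sorted(report.excluded_ids),
        "designs": {},
        "files": {},
    }

    t0_ds = subs["T0"]
    group = (sheet.table["group"] == "patient").reindex(t0_ds.sample_ids)

    def record(name, table, write_tiers=True):
        path = out / f"ewas_{name}.tsv"
        files = diag.annotate_and_write(table, manifest, path,
                                        sig=bonf if write_tiers else None,
                                        suggestive=config.suggestive)
        pvals = table["p_value"].dropna()
        tiers = diag.classify_hits(table, bonf, config.suggestive)["tier"]
        lam = (diag.genomic_inflation(pvals).lambda_
               if len(pvals) >= 10 else float("nan"))
        qq = diag.qq_data(pvals) if len(pvals) else pd.DataFrame()
        qq_path = out / f"qq_{name}.tsv"
        qq.to_csv(qq_path, sep="\t", index=False, float_format="%.15g")
        files["qq"] = str(qq_path)
        summary["designs"][name] = {
            "n_used": int(table["n_used"].max()),
            "n_probes": int(len(table)),
            "lambda": lam,
            "n_significant": int((tiers == "significant").sum()),
            "n_suggestive": int((tiers == "suggestive").sum()),
            "n_flagged": int((tiers == "flagged").sum()),
        }
        for label, f in files.items():
            summary["files"][f"{name}:{label}"] = _sha256(Path(f))
        return tiers

    # ---- case-control design ------------------------------------------
    if "case_control" in config.designs:
        cc = assoc.welch_case_control(adjusted["T0"], group, t0_ds)
        tiers = record("case_control", cc)
        sig_ids = list(tiers.index[tiers == "significant"])
        if sig_ids:
            post = assoc.posthoc_depression_adjust(
                adjusted["T0"], group,
                sheet.table["depression"].reindex(t0_ds.sample_ids),
                sig_ids, sig=bonf, suggestive=config.suggestive)
            post.to_csv(out / "ewas_case_control_posthoc_depression.tsv",
                        sep="\t", float_format="%.15g")
            summary["designs"]["case_control"]["posthoc_remained_significant"] = \
                int((post["status"] == "significant").sum())

    # ---- response prediction (binary + continuous), T0->T1 and T0->T2 --
    for to_tp in ("T1", "T2"):
        labels = qcmod.label_response(sheet, "T0", to_tp)
        usable = labels[labels != "missing"]
        ids = [s for s in t0_ds.sample_ids if s in usable.index]
        if "response_binary" in config.designs:
            # two-step form: the predictor is baseline M already
            # residualized on technical covariates, keeping the logistic
            # model small enough for valid Wald inference
            covs = clinical_covariates(sheet, ids)
            mm = prep.MValueMatrix(adjusted["T0"].residuals.loc[ids],
                                   prep.DEFAULT_OFFSET)
            res = assoc.predict_response_logistic(mm, usable.loc[ids], covs)
            record(f"response_binary_{to_tp}", res)
        if "response_continuous" in config.designs:
            pct = pct_hama_change(sheet, to_tp)
            ids_c = [s for s in t0_ds.sample_ids if s in pct.index]
            covs = nuis_t0.loc[ids_c].join(
                clinical_covariates(sheet, ids_c, include_hama_baseline=False))
            mm = prep.beta_to_m(t0_ds.betas.loc[ids_c])
            res = assoc.response_continuous(mm, pct.loc[ids_c], covs)
            record(f"response_continuous_{to_tp}", res)

    # ---- longitudinal within-patient design ---------------------------
    if "longitudinal" in config.designs:
        # technical coefficients re-fit on within-person variation so
        # between-person variance cannot leak into the paired differences
        arr_person = pd.Series({aid: aid.rsplit(":", 1)[0]
                                for aid in m_stacked.m.index})
        multi = arr_person.map(arr_person.value_counts()) > 1
        pat_arrays = list(arr_person.index[multi])
        m_long = prep.MValueMatrix(m_stacked.m.loc[pat_arrays],
                                   m_stacked.offset_used)
        adj_within = prep.residualize_within(
            m_long, covs_stacked.loc[pat_arrays], arr_person.loc[pat_arrays])
        adjusted_long = {}
        for tp, ds in subs.items():
            aid = [f"{s}:{tp}" for s in ds.sample_ids if f"{s}:{tp}" in adj_within.residuals.index]
            sl = adj_within.residuals.loc[aid]
            sl = sl.set_axis([a.rsplit(":", 1)[0] for a in aid], axis=0)
            adjusted_long[tp] = prep.AdjustedMatrix(sl, adj_within.covariates_used)
        for to_tp in ("T1", "T2"):
            labels = qcmod.label_response(sheet, "T0", to_tp)
            resp = labels[labels != "missing"] == "responder"
            tk_ds = subs[to_tp]
            strata = assoc.longitudinal_delta_test(
                adjusted_long["T0"], adjusted_long[to_tp],
                resp,
                betas_t0=t0_ds.betas, betas_tk=tk_ds.betas)
            for stratum, table in strata.items():
                record(f"longitudinal_{to_tp}_{stratum}", table)

    # ---- smoking EWAS within patients ---------------------------------
    if "smoking" in config.designs:
        smoking = sheet.table["smoking"]
        pat_ids = [s for s in t0_ds.sample_ids
                   if sheet.table.at[s, "group"] == "patient"
                   and pd.notna(smoking.at[s])]
        if len(pat_ids) >= 10 and smoking.loc[pat_ids].nunique() > 1:
            sub = t0_ds.subset_samples(pat_ids)
            covs = nuis_t0.loc[pat_ids].join(clinical_covariates(
                sheet, pat_ids, include_hama_baseline=False,
                include_smoking=False).drop(columns=["depression"]))
            smk = assoc.smoking_ewas_robust(sub, smoking.loc[pat_ids], covs)
            tiers_smk = record("smoking", smk)
            if "case_control" in config.designs:
                smk_hits = set(tiers_smk.index[tiers_smk == "significant"])
                cc_hits = set(sig_ids) if "case_control" in config.designs else set()
                count, pval = assoc.overlap_test(cc_hits, smk_hits,
                                                 keep.n_evaluated)
                summary["smoking_case_control_overlap"] = {
                    "count": count, "hypergeometric_p": pval}
        else:
            log_lines.append("smoking design skipped: no usable contrast")

    # n_used bookkeeping invariant across the shrinking panels
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
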