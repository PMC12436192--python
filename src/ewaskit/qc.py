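"""Sample-level quality control and probe-level filtering.

Samples are excluded when their probe call rate falls below 0.95, when at
least 5% of probes completely lack signal, when methylation-predicted sex
disagrees with the reported sex, or when the per-sample mean of any
control-probe class is a robust outlier (beyond k median absolute
deviations, scaled to SD units, from the cohort median; k = 4 by
default). Probes are dropped when a common SNP sits within 5 bp at
MAF >= 0.01, when they are flagged cross-reactive, or when they are
control probes; the surviving count defines the Bonferroni threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CONTROL_CLASSES, MethylationDataset, ProbeManifest, SampleSheet

_MAD_TO_SD = 1.4826  # consistency factor for Gaussian data


@dataclass
class QCThresholds:
    min_call_rate: float = 0.95
    max_missing_signal_frac: float = 0.05
    control_outlier_sd: float = 4.0
    sex_check: bool = True

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "max_missing_signal_frac"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.control_outlier_sd <= 0:
            raise ValueError("control_outlier_sd must be positive")


@dataclass
class QCReport:
    """Per-sample QC metrics, flags, and the resulting exclusion set."""

    table: pd.DataFrame
    thresholds: QCThresholds

    @property
    def excluded_ids(self) -> list:
        return list(self.table.index[self.table["excluded"]])

    @property
    def retained_ids(self) -> list:
        return list(self.table.index[~self.table["excluded"]])

    def reasons(self, sample_id: str) -> list:
        return list(self.table.loc[sample_id, "exclusion_reasons"])


@dataclass
class ProbeKeepList:
    kept_probe_ids: list
    n_removed_snp: int
    n_removed_cross: int
    n_removed_control: int = 0

    @property
    def n_evaluated(self) -> int:
        return len(self.kept_probe_ids)


def predict_sex(dataset: MethylationDataset, manifest: ProbeManifest) -> pd.Series:
    """Call sample sex from sex-chromosome methylation.

    Males carry detectable chrY probes (detection fraction above 0.5) and
    extreme chrX betas; females lack chrY signal and show intermediate
    chrX betas. Prefers the chrY detection rule, falls back on chrX
    dispersion, and returns "uncallable" when the manifest has no sex
    probes rather than guessing.
    """
    chrom = manifest.table["chrom"].reindex(dataset.probe_ids)
    x_ids = list(chrom.index[chrom == "X"])
    y_ids = list(chrom.index[chrom == "Y"])
    if not x_ids and not y_ids:
        return pd.Series("uncallable", index=dataset.sample_ids, name="predicted_sex")
    if y_ids:
        det = dataset.detection[y_ids].to_numpy(bool).mean(axis=1)
        calls = np.where(det >= 0.5, "M", "F")
    else:
        # X inactivation leaves a sizeable fraction of chrX probes at
        # intermediate beta in females; males stay near 0 or 1
        inter = ((dataset.betas[x_ids] - 0.5).abs() < 0.2).mean(axis=1)
        calls = np.where(inter.to_numpy() < 0.10, "M", "F")
    return pd.Series(calls, index=dataset.sample_ids, name="predicted_sex")


def _control_class_outliers(dataset: MethylationDataset,
                            manifest: ProbeManifest,
                            k_sd: float) -> pd.DataFrame:
    """Robust per-class outlier flags on per-sample control-probe means."""
    cls = manifest.table.loc[dataset.control_betas.columns, "control_class"]
    flags = {}
    for c in CONTROL_CLASSES:
        cols = cls.index[cls == c]
        if len(cols) == 0:
            flags[c] = pd.Series(False, index=dataset.sample_ids)
            continue
        means = dataset.control_betas[cols].mean(axis=1)
        med = means.median()
        mad = (means - med).abs().median()
        scale = _MAD_TO_SD * mad
        if scale == 0:
            flags[c] = pd.Series(False, index=dataset.sample_ids)
        else:
            flags[c] = (means - med).abs() > k_sd * scale
    return pd.DataFrame(flags)


def sample_qc(dataset: MethylationDataset,
              sheet: SampleSheet,
              manifest: ProbeManifest,
              thresholds: QCThresholds | None = None) -> QCReport:
    """Apply all sample-level exclusion rules and report metrics + reasons."""
    thresholds = thresholds or QCThresholds()
    if dataset.betas.shape[0] == 0 or dataset.betas.shape[1] == 0:
        raise ValueError("empty methylation dataset")
    missing = [s for s in dataset.sample_ids if s not in sheet.table.index]
    if missing:
        raise ValueError(f"samples absent from sheet: {missing[:5]}")

    call_rate = dataset.call_rate()
    missing_sig = dataset.missing_signal_frac()
    predicted = predict_sex(dataset, manifest)
    reported = sheet.table.loc[dataset.sample_ids, "reported_sex"]
    mismatch = (predicted != reported) & (predicted != "uncallable")
    ctrl_flags = _control_class_outliers(dataset, manifest,
                                         thresholds.control_outlier_sd)

    rows = []
    for sid in dataset.sample_ids:
        reasons = []
        if call_rate[sid] < thresholds.min_call_rate:
            reasons.append("call_rate")
        if missing_sig[sid] >= thresholds.max_missing_signal_frac:
            reasons.append("missing_signal")
        if thresholds.sex_check and mismatch[sid]:
            reasons.append("sex_mismatch")
        if ctrl_flags.loc[sid].any():
            reasons.append("control_outlier")
        rows.append({
            "sample_id": sid,
            "call_rate": call_rate[sid],
            "missing_signal_frac": missing_sig[sid],
            "predicted_sex": predicted[sid],
            "sex_mismatch": bool(mismatch[sid]),
            **{f"control_outlier_{c}": bool(ctrl_flags.loc[sid, c])
               for c in ctrl_flags.columns},
            "excluded": bool(reasons),
            "exclusion_reasons": reasons,
        })
    table = pd.DataFrame(rows).set_index("sample_id")
    return QCReport(table=table, thresholds=thresholds)


def filter_probes(manifest: ProbeManifest,
                  snp_dist_max: int = 5,
                  snp_maf_min: float = 0.01,
                  drop_cross_reactive: bool = True,
                  drop_controls: bool = True) -> ProbeKeepList:
    """Remove SNP-proximal, cross-reactive, and control probes.

    A probe failing both the SNP and cross-reactive rules is tallied under
    the SNP rule (fixed precedence, so the two counts partition the
    removed set).
    """
    tab = manifest.table
    if len(tab) == 0:
        raise ValueError("empty manifest")
    snp_hit = (tab["snp_dist_bp"].le(snp_dist_max)
               & tab["snp_maf"].ge(snp_maf_min)).fillna(False).to_numpy()
    cross_hit = tab["cross_reactive"].to_numpy(bool) if drop_cross_reactive \
        else np.zeros(len(tab), bool)
    ctrl = tab["is_control"].to_numpy(bool) if drop_controls \
        else np.zeros(len(tab), bool)
    snp_hit = snp_hit & ~ctrl
    cross_hit = cross_hit & ~ctrl
    removed = snp_hit | cross_hit | ctrl
    return ProbeKeepList(
        kept_probe_ids=list(tab.index[~removed]),
        n_removed_snp=int(snp_hit.sum()),
        n_removed_cross=int((cross_hit & ~snp_hit).sum()),
        n_removed_control=int(ctrl.sum()),
    )


def bonferroni_threshold(n_evaluated: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / number of evaluated probes."""
    if n_evaluated < 1:
        raise ValueError("n_evaluated must be at least 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / n_evaluated


def label_response(sheet: SampleSheet,
                   from_tp: str = "T0",
                   to_tp: str = "T1") -> pd.Series:
    """Classify patients as responder / non-responder / missing.

    Response is a >= 50% decrease in HAM-A score between the two
    timepoints; patients missing either score (or with a zero baseline,
    where the fractional change is undefined) are "missing". Controls are
    not labelled.
    """
    order = {"T0": 0, "T1": 1, "T2": 2}
    if order[from_tp] >= order[to_tp]:
        raise ValueError("from_tp must precede to_tp")
    pats = sheet.patient_ids
    h0 = sheet.table.loc[pats, f"hama_{from_tp.lower()}"]
    h1 = sheet.table.loc[pats, f"hama_{to_tp.lower()}"]
    labels = pd.Series("missing", index=pats, name="response")
    zero_base = h0 == 0
    if zero_base.any():
        warnings.warn("zero baseline HAM-A: fractional change undefined, "
                      "labelled missing", stacklevel=2)
    ok = h0.notna() & h1.notna() & ~zero_base
    frac = (h0[ok] - h1[ok]) / h0[ok]
    labels.loc[ok] = np.where(frac >= 0.5, "responder", "non-responder")
    return labels
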