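"""Synthetic EPIC-like methylation cohorts with known ground truth.

The generator emulates the statistical structure an array EWAS pipeline
has to cope with: beta-distributed methylation per probe, a six-cell-type
leukocyte mixture driving the deconvolution reference CpGs, a batch
effect expressed jointly in control probes and a random subset of genomic
probes (so that control-probe principal components can genuinely remove
it), sex-chromosome signal usable by a simple sex predictor, spiked
effects for the three association designs, HAM-A symptom trajectories
with a responder subpopulation, and optionally planted QC violators.

Everything is seeded; a fixed seed reproduces bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .data import (
    CELL_TYPES,
    CONTROL_CLASSES,
    CellReference,
    EffectSpec,
    MethylationDataset,
    ProbeManifest,
    SampleSheet,
)

_LOGIT_EPS = 1e-3


def _safe_logit(b: np.ndarray) -> np.ndarray:
    return logit(np.clip(b, _LOGIT_EPS, 1 - _LOGIT_EPS))


def generate_manifest(
    n_probes: int,
    n_control: int,
    n_reference: int,
    frac_snp_close: float,
    frac_cross_reactive: float,
    seed: int,
    frac_chrx: float = 0.03,
    frac_chry: float = 0.005,
) -> ProbeManifest:
    """Build a probe manifest with genomic probes, control probes and
    cell-reference flags.

    ``frac_snp_close`` of genomic probes receive a SNP within 5 bp at
    MAF >= 0.01 (and are therefore removable by the SNP filter);
    ``frac_cross_reactive`` are flagged cross-reactive. Reference probes
    are autosomal and never carry filter flags, so they survive probe
    filtering. Deterministic for a fixed seed.
    """
    if n_probes <= 0 or n_reference <= 0 or n_control < 0:
        raise ValueError("probe counts must be positive (controls may be zero)")
    if n_reference > n_probes:
        raise ValueError("n_reference cannot exceed n_probes")
    for name, frac in (("frac_snp_close", frac_snp_close),
                       ("frac_cross_reactive", frac_cross_reactive)):
        if not 0 <= frac <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    ids = np.array([f"cg{i:08d}" for i in range(n_probes)])

    # sex-chromosome share yields to the reference-probe count (reference
    # probes must be autosomal)
    n_x = int(round(frac_chrx * n_probes))
    n_y = int(round(frac_chry * n_probes))
    n_x = min(n_x, max(0, n_probes - n_reference - n_y))
    n_y = min(n_y, max(0, n_probes - n_reference - n_x))
    chrom = rng.integers(1, 23, size=n_probes).astype(str)
    sex_idx = rng.choice(n_probes, size=n_x + n_y, replace=False)
    chrom[sex_idx[:n_x]] = "X"
    chrom[sex_idx[n_x:]] = "Y"

    pos = rng.integers(1, 250_000_000, size=n_probes)
    genes = np.array([f"GENE{rng.integers(0, max(n_probes // 2, 1)):06d}"
                      for _ in range(n_probes)])

    autosomal = ~np.isin(chrom, ("X", "Y"))
    ref_idx = rng.choice(np.flatnonzero(autosomal), size=n_reference, replace=False)
    is_ref = np.zeros(n_probes, bool)
    is_ref[ref_idx] = True

    # filter flags are drawn only among non-reference probes
    eligible = np.flatnonzero(~is_ref)
    n_snp = int(round(frac_snp_close * n_probes))
    n_cross = int(round(frac_cross_reactive * n_probes))
    if n_snp + n_cross > eligible.size:
        raise ValueError("filter fractions leave no unflagged probes")
    flagged = rng.choice(eligible, size=n_snp + n_cross, replace=False)
    snp_idx, cross_idx = flagged[:n_snp], flagged[n_snp:]

    snp_dist = np.full(n_probes, np.nan)
    snp_maf = np.full(n_probes, np.nan)
    snp_dist[snp_idx] = rng.integers(0, 6, size=n_snp)
    snp_maf[snp_idx] = rng.uniform(0.01, 0.5, size=n_snp)
    cross = np.zeros(n_probes, bool)
    cross[cross_idx] = True

    genomic = pd.DataFrame({
        "probe_id": ids,
        "chrom": chrom,
        "pos": pos,
        "nearest_gene": genes,
        "snp_dist_bp": snp_dist,
        "snp_maf": snp_maf,
        "cross_reactive": cross,
        "is_control": False,
        "control_class": "none",
        "is_cell_reference": is_ref,
    })

    if n_control > 0:
        cls = np.array([CONTROL_CLASSES[i % len(CONTROL_CLASSES)]
                        for i in range(n_control)])
        ctrl = pd.DataFrame({
            "probe_id": [f"ctrl{i:05d}" for i in range(n_control)],
            "chrom": "control",
            "pos": 0,
            "nearest_gene": "none",
            "snp_dist_bp": np.nan,
            "snp_maf": np.nan,
            "cross_reactive": False,
            "is_control": True,
            "control_class": cls,
            "is_cell_reference": False,
        })
        genomic = pd.concat([genomic, ctrl], ignore_index=True)

    return ProbeManifest(genomic.set_index("probe_id"))


def generate_reference(n_reference: int, separation: float, seed: int) -> CellReference:
    """Reference beta signatures for the six leukocyte types.

    Each reference CpG gets a probe-level baseline on the logit scale plus
    an independent per-cell-type offset with SD ``separation``; larger
    separation makes the columns closer to orthogonal and the
    deconvolution better conditioned.
    """
    if n_reference < 6:
        raise ValueError("need at least 6 reference probes")
    if separation <= 0:
        raise ValueError("separation must be positive")
    rng = np.random.default_rng(seed)
    base = rng.uniform(-1.5, 1.5, size=(n_reference, 1))
    offsets = rng.normal(0.0, separation, size=(n_reference, len(CELL_TYPES)))
    betas = expit(base + offsets)
    frame = pd.DataFrame(
        betas,
        index=[f"ref{i:04d}" for i in range(n_reference)],
        columns=list(CELL_TYPES),
    )
    return CellReference(frame)


def spikeable_probes(manifest: ProbeManifest, n: int) -> list:
    """First ``n`` autosomal genomic probes that survive every probe filter
    (no SNP flag, not cross-reactive, not control, not cell-reference) —
    safe targets for spiked effects."""
    tab = manifest.table
    ok = (~tab["is_control"]
          & ~tab["cross_reactive"]
          & ~tab["is_cell_reference"]
          & ~tab["chrom"].isin(["X", "Y"])
          & ~(tab["snp_dist_bp"].le(5) & tab["snp_maf"].ge(0.01)).fillna(False))
    ids = list(tab.index[ok][:n])
    if len(ids) < n:
        raise ValueError(f"only {len(ids)} spikeable probes available")
    return ids


@dataclass
class PlantedQC:
    """Counts of samples deliberately violating each QC rule.

    low_call: 6% of detected probes set to missing beta (call rate 0.94).
    boundary_call: exactly 5% missing (call rate 0.95, must be retained).
    missing_signal: 6% of probes with no signal at all.
    sex_swap: reported sex flipped relative to the methylation-borne sex.
    control_outlier: one control-probe class shifted far out for the sample.
    """

    low_call: int = 0
    boundary_call: int = 0
    missing_signal: int = 0
    sex_swap: int = 0
    control_outlier: int = 0

    @property
    def total(self) -> int:
        return (self.low_call + self.boundary_call + self.missing_signal
                + self.sex_swap + self.control_outlier)


@dataclass
class CohortTruth:
    """Ground truth recorded by the generator for test oracles."""

    cell_fractions: pd.DataFrame
    responder: pd.Series
    true_sex: pd.Series
    batch_shift: pd.Series
    batch_loading: pd.Series
    planted_reasons: dict = field(default_factory=dict)
    expected_excluded: set = field(default_factory=set)
    retained_boundary: set = field(default_factory=set)


@dataclass
class Cohort:
    """Bundle of everything one simulated study produces."""

    sheet: SampleSheet
    datasets: dict  # timepoint -> MethylationDataset
    truth: CohortTruth
    effects: EffectSpec

    @property
    def t0(self) -> MethylationDataset:
        return self.datasets["T0"]


def _truncated_normal(rng, mean, sd, low, high, size):
    a, b = (low - mean) / sd, (high - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                         random_state=rng)


def generate_cohort(
    manifest: ProbeManifest,
    reference: CellReference,
    n_patients: int,
    n_controls: int,
    effects: EffectSpec,
    responder_frac: float = 0.5,
    seed: int = 0,
    planted_qc: PlantedQC | None = None,
    n_batches: int = 2,
    female_frac: float = 0.57,
    hama_dropout: tuple = (0.11, 0.19),
    meth_dropout: tuple = (0.21, 0.26),
    depression_frac: float = 0.32,
    smoking_frac: float = 0.26,
) -> Cohort:
    """Simulate a longitudinal case-control methylation cohort.

    Patients are measured at T0 (baseline), T1 (post-treatment) and T2
    (6-month follow-up), controls at T0 only. Treatment response
    (>= 50% HAM-A decrease from baseline) is driven by a latent Bernoulli
    whose log-odds are shifted by baseline M values at ``pred_spiked``
    probes; case-control and responder-only longitudinal effects are
    spiked on the beta scale per ``effects``. Dropout at T1/T2 follows
    ``hama_dropout`` (clinical score missing) plus ``meth_dropout``
    (methylation sample additionally missing among those with scores), so
    the per-design sample sizes shrink the way a real longitudinal study's
    do.
    """
    if not 0 <= responder_frac <= 1:
        raise ValueError("responder_frac must lie in [0, 1]")
    if n_patients <= 0 or n_controls < 0:
        raise ValueError("cohort sizes must be positive")
    effects.validate_against(manifest)
    ref_ids = list(manifest.reference_ids)
    if list(reference.betas.index) != ref_ids and len(reference.betas) != len(ref_ids):
        raise ValueError("reference rows do not match manifest is_cell_reference flags")
    planted_qc = planted_qc or PlantedQC()

    rng = np.random.default_rng(seed)
    pat_ids = [f"P{i:04d}" for i in range(n_patients)]
    con_ids = [f"C{i:04d}" for i in range(n_controls)]
    all_ids = pat_ids + con_ids
    n_total = len(all_ids)

    # ---- clinical sheet ------------------------------------------------
    # controls are frequency-matched to the patients' realized sex split,
    # as in a matched case-control design
    sex = np.where(rng.random(n_total) < female_frac, "F", "M")
    if n_controls > 0 and n_patients > 0:
        pat_f = (sex[:n_patients] == "F").mean()
        n_f = int(round(n_controls * pat_f))
        con_sex = np.array(["F"] * n_f + ["M"] * (n_controls - n_f))
        sex[n_patients:] = con_sex[rng.permutation(n_controls)]
    age = np.clip(rng.normal(33.3, 11.3, n_total), 18, 70).round(1)
    smoking = pd.array([bool(x) for x in rng.random(n_total) < smoking_frac],
                       dtype="boolean")
    smoking[n_patients:] = pd.NA  # not ascertained for controls
    depression = np.zeros(n_total, bool)
    depression[:n_patients] = rng.random(n_patients) < depression_frac
    medication = np.zeros(n_total, bool)
    medication[:n_patients] = rng.random(n_patients) < 0.2
    batch = rng.integers(0, n_batches, n_total)

    # ---- cell mixtures and probe-level means ---------------------------
    alpha = np.asarray(effects.dirichlet_alpha, float)
    w = rng.dirichlet(alpha, size=n_total)  # samples x 6
    cellfrac = pd.DataFrame(w, index=all_ids, columns=list(CELL_TYPES))

    gen_ids = list(manifest.genomic_ids)
    n_probes = len(gen_ids)
    gen_tab = manifest.table.loc[gen_ids]
    is_ref = gen_tab["is_cell_reference"].to_numpy()
    chrom = gen_tab["chrom"].to_numpy()
    is_x = chrom == "X"
    is_y = chrom == "Y"

    # bimodal autosomal means, typical of array methylomes
    comp = rng.random(n_probes)
    mu = np.where(comp < 0.3, rng.beta(2, 18, n_probes),
                  np.where(comp < 0.6, rng.beta(18, 2, n_probes),
                           rng.beta(5, 5, n_probes)))

    # per-sample mean matrix on the beta scale
    mean_beta = np.tile(mu, (n_total, 1))
    ref_cols = np.flatnonzero(is_ref)
    r = reference.betas.to_numpy(float)  # ref probes x 6
    mean_beta[:, ref_cols] = w @ r.T

    # sex-chromosome structure
    female = sex == "F"
    x_cols = np.flatnonzero(is_x)
    if x_cols.size:
        male_x = np.where(rng.random(x_cols.size) < 0.5,
                          rng.uniform(0.03, 0.10, x_cols.size),
                          rng.uniform(0.90, 0.97, x_cols.size))
        # ~a quarter of chrX probes show X-inactivation-driven intermediate
        # methylation in females; the rest behave the same in both sexes
        inter = rng.random(x_cols.size) < 0.25
        fem_x = np.where(inter, rng.uniform(0.40, 0.60, x_cols.size), male_x)
        mean_beta[np.ix_(~female, x_cols)] = male_x
        mean_beta[np.ix_(female, x_cols)] = fem_x
    y_cols = np.flatnonzero(is_y)
    if y_cols.size:
        mean_beta[:, y_cols] = rng.uniform(0.6, 0.9, y_cols.size)

    # spiked probes get mid-range baselines so the requested effects fit
    # inside (0, 1); an out-of-range delta is still an error
    col_of = {p: i for i, p in enumerate(gen_ids)}
    spiked_all = ([p for p, _ in effects.cc_spiked]
                  + [p for p, _ in effects.pred_spiked]
                  + [p for p, _ in effects.long_spiked])
    for pid in spiked_all:
        j = col_of[pid]
        mean_beta[:, j] = rng.uniform(0.35, 0.55)

    # case-control spikes: patients' mean beta shifted by delta
    for pid, delta in effects.cc_spiked:
        j = col_of[pid]
        shifted = mean_beta[:n_patients, j] + delta
        if (shifted <= 0).any() or (shifted >= 1).any():
            raise ValueError(f"cc_spiked delta at {pid} pushes means outside (0, 1)")
        mean_beta[:n_patients, j] = shifted

    # ---- batch effect, shared by control probes and a probe subset -----
    shift_levels = effects.batch_sd * (np.arange(n_batches)
                                       - (n_batches - 1) / 2.0)
    sample_shift = shift_levels[batch]
    # sign-symmetric loadings: batch pushes individual probes both ways,
    # so per-class control means stay unimodal while the batch direction
    # remains fully recoverable from a control-probe PCA
    loading = np.zeros(n_probes)
    affected = rng.random(n_probes) < 0.2
    loading[affected] = rng.normal(0.0, 1.0, affected.sum())

    # person-level biological variation, shared across timepoints.
    # Methylomes are variance-heterogeneous: most probes are tight, a
    # minority highly variable. bio_sd scales the most variable class.
    bio_scale = effects.bio_sd * rng.choice(
        [0.25, 0.6, 1.0], size=n_probes, p=[0.6, 0.3, 0.1])
    bio_scale[is_ref] = min(effects.bio_sd, 0.1)
    # spiked probes sit in the variance class where their planted effect
    # is identifiable: group/longitudinal anchors are tight, response
    # predictors need between-person spread to carry information
    for pid, _ in effects.cc_spiked + effects.long_spiked:
        bio_scale[col_of[pid]] = 0.25 * effects.bio_sd
    for pid, _ in effects.pred_spiked:
        bio_scale[col_of[pid]] = effects.bio_sd
    bio = rng.normal(0.0, 1.0, size=(n_total, n_probes)) * bio_scale

    # per-array technical factor (scan/chip effects), expressed in a
    # subset of genomic probes and in the control probes below
    tech_loading = np.zeros(n_probes)
    tech_affected = rng.random(n_probes) < 0.3
    tech_loading[tech_affected] = rng.normal(0.0, 1.0, tech_affected.sum())

    def draw_betas(mean_b, shift, rows, tech):
        z = _safe_logit(mean_b) + bio[rows]
        z = z + np.outer(shift, loading) + np.outer(tech, tech_loading)
        z = z + rng.normal(0.0, effects.noise_sd, size=mean_b.shape)
        return expit(z)

    tech_t0 = rng.normal(0.0, effects.tech_sd, n_total)
    betas_t0 = draw_betas(mean_beta, sample_shift, np.arange(n_total), tech_t0)

    # ---- HAM-A trajectories and treatment response ---------------------
    hama_t0 = np.full(n_total, np.nan)
    hama_t0[:n_patients] = np.round(
        _truncated_normal(rng, 24.5, 5.3, 19, 56, n_patients))

    # response log-odds shifted by baseline M at pred_spiked probes
    logit_p = np.full(n_patients, logit(np.clip(responder_frac, 1e-6, 1 - 1e-6)))
    for pid, slope in effects.pred_spiked:
        j = col_of[pid]
        # slope is log-odds per unit M value (log2 of the methylation odds)
        m = _safe_logit(betas_t0[:n_patients, j]) / np.log(2)
        logit_p = logit_p + slope * (m - m.mean())
    responder = rng.random(n_patients) < expit(logit_p)
    if responder_frac == 0:
        responder[:] = False
    elif responder_frac == 1:
        responder[:] = True

    # improvement fractions with a margin around the 50% boundary so that
    # integer rounding of scores cannot flip the planted status
    imp1 = np.where(
        responder,
        _truncated_normal(rng, 0.68, 0.12, 0.53, 0.97, n_patients),
        _truncated_normal(rng, 0.25, 0.15, -0.30, 0.45, n_patients),
    )
    gain = rng.normal(0.05, 0.05, n_patients)
    imp2 = np.where(responder,
                    np.clip(imp1 + gain, 0.53, 0.97),
                    np.clip(imp1 + gain, -0.30, 0.45))
    hama_t1 = np.full(n_total, np.nan)
    hama_t2 = np.full(n_total, np.nan)
    hama_t1[:n_patients] = np.round(hama_t0[:n_patients] * (1 - imp1))
    hama_t2[:n_patients] = np.round(hama_t0[:n_patients] * (1 - imp2))

    # dropout: clinical score missing at T1/T2; methylation additionally
    # missing for some patients who do have scores
    have_hama1 = rng.random(n_patients) >= hama_dropout[0]
    have_hama2 = rng.random(n_patients) >= hama_dropout[1]
    hama_t1[:n_patients] = np.where(have_hama1, hama_t1[:n_patients], np.nan)
    hama_t2[:n_patients] = np.where(have_hama2, hama_t2[:n_patients], np.nan)
    have_meth1 = have_hama1 & (rng.random(n_patients) >= meth_dropout[0])
    have_meth2 = have_hama2 & (rng.random(n_patients) >= meth_dropout[1])

    # ---- planted QC violators (controls first, never spiked patients) --
    reasons: dict[str, list[str]] = {}
    true_sex = sex.copy()
    reported_sex = sex.copy()
    victims = iter(con_ids + pat_ids[::-1])

    def next_victim(reason_list):
        sid = next(victims)
        reasons.setdefault(sid, []).extend(reason_list)
        return sid

    swap_ids = [next_victim(["sex_mismatch"]) for _ in range(planted_qc.sex_swap)]
    for sid in swap_ids:
        i = all_ids.index(sid)
        reported_sex[i] = "M" if true_sex[i] == "F" else "F"

    lowcall_ids = [next_victim(["call_rate"]) for _ in range(planted_qc.low_call)]
    boundary_ids = [next(victims) for _ in range(planted_qc.boundary_call)]
    # no signal at all implies the probe also fails the call-rate rule
    nosig_ids = [next_victim(["call_rate", "missing_signal"])
                 for _ in range(planted_qc.missing_signal)]
    outlier_ids = [next_victim(["control_outlier"])
                   for _ in range(planted_qc.control_outlier)]

    # ---- assemble T0 dataset -------------------------------------------
    detection = np.ones((n_total, n_probes), bool)
    if y_cols.size:
        detection[np.ix_(female, y_cols)] = False
    betas_t0 = np.where(detection, betas_t0, np.nan)

    def set_call_rate(sid, target, kill_signal):
        # knock out exactly enough probes that the realized call rate /
        # undetected fraction hits the target, whatever is already missing
        # (e.g. undetected chrY probes in females)
        i = all_ids.index(sid)
        ok = detection[i] & ~np.isnan(betas_t0[i])
        k = int(ok.sum()) - int(round(target * n_probes))
        if k > 0:
            hit = rng.choice(np.flatnonzero(ok), size=k, replace=False)
            betas_t0[i, hit] = np.nan
            if kill_signal:
                detection[i, hit] = False

    for sid in lowcall_ids:
        set_call_rate(sid, 0.94, kill_signal=False)
    for sid in nosig_ids:
        set_call_rate(sid, 0.94, kill_signal=True)
    for sid in boundary_ids:
        set_call_rate(sid, 0.95, kill_signal=False)

    ctrl_ids = list(manifest.control_ids)
    ctrl_cls = manifest.table.loc[ctrl_ids, "control_class"].to_numpy()
    ctrl_mu = rng.uniform(0.2, 0.8, len(ctrl_ids))
    ctrl_loading = rng.normal(0.0, 1.0, len(ctrl_ids))
    ctrl_tech_loading = rng.normal(0.0, 1.0, len(ctrl_ids))
    ctrl_z = (_safe_logit(np.tile(ctrl_mu, (n_total, 1)))
              + np.outer(sample_shift, ctrl_loading)
              + np.outer(tech_t0, ctrl_tech_loading)
              + rng.normal(0.0, 0.1, size=(n_total, len(ctrl_ids))))
    for sid in outlier_ids:
        i = all_ids.index(sid)
        # blow out one bisulfite-conversion class far beyond 4 robust SDs
        hit = ctrl_cls == "BS-II"
        ctrl_z[i, hit] += 4.0
    control_betas = expit(ctrl_z)

    sheet = SampleSheet(pd.DataFrame({
        "sample_id": all_ids,
        "group": ["patient"] * n_patients + ["control"] * n_controls,
        "age": age,
        "sex": true_sex,
        "reported_sex": reported_sex,
        "smoking": smoking,
        "depression": depression,
        "medication": medication,
        "hama_t0": hama_t0,
        "hama_t1": hama_t1,
        "hama_t2": hama_t2,
        "batch": batch,
    }).set_index("sample_id"))

    def as_dataset(b, det, cb, ids, tp):
        return MethylationDataset(
            betas=pd.DataFrame(b, index=ids, columns=gen_ids),
            detection=pd.DataFrame(det, index=ids, columns=gen_ids),
            control_betas=pd.DataFrame(cb, index=ids, columns=ctrl_ids),
            timepoint=tp,
        )

    datasets = {"T0": as_dataset(betas_t0, detection, control_betas,
                                 all_ids, "T0")}

    # ---- follow-up timepoints (patients only) --------------------------
    for tp, have, drifts_idx in (("T1", have_meth1, 0), ("T2", have_meth2, 1)):
        keep = np.flatnonzero(have)
        ids_tp = [pat_ids[i] for i in keep]
        mean_tp = mean_beta[keep].copy()
        for pid, drift in effects.long_spiked:
            d = drift[drifts_idx] if isinstance(drift, (tuple, list)) else drift
            j = col_of[pid]
            resp_rows = responder[keep]
            mean_tp[resp_rows, j] = np.clip(mean_tp[resp_rows, j] + d,
                                            _LOGIT_EPS, 1 - _LOGIT_EPS)
        tech_tp = rng.normal(0.0, effects.tech_sd, keep.size)
        b_tp = draw_betas(np.clip(mean_tp, _LOGIT_EPS, 1 - _LOGIT_EPS),
                          sample_shift[keep], keep, tech_tp)
        det_tp = np.ones_like(b_tp, bool)
        fem_keep = female[:n_patients][keep]
        if y_cols.size:
            det_tp[np.ix_(fem_keep, y_cols)] = False
        b_tp = np.where(det_tp, b_tp, np.nan)
        cb_tp = expit(_safe_logit(np.tile(ctrl_mu, (keep.size, 1)))
                      + np.outer(sample_shift[keep], ctrl_loading)
                      + np.outer(tech_tp, ctrl_tech_loading)
                      + rng.normal(0.0, 0.1, size=(keep.size, len(ctrl_ids))))
        datasets[tp] = as_dataset(b_tp, det_tp, cb_tp, ids_tp, tp)

    truth = CohortTruth(
        cell_fractions=cellfrac,
        responder=pd.Series(responder, index=pat_ids, name="responder"),
        true_sex=pd.Series(true_sex, index=all_ids, name="sex"),
        batch_shift=pd.Series(sample_shift, index=all_ids, name="batch_shift"),
        batch_loading=pd.Series(loading, index=gen_ids, name="batch_loading"),
        planted_reasons={k: sorted(set(v)) for k, v in reasons.items()},
        expected_excluded=set(reasons),
        retained_boundary=set(boundary_ids),
    )
    return Cohort(sheet=sheet, datasets=datasets, truth=truth, effects=effects)
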