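"""Core data containers shared across the pipeline.

All tabular payloads are pandas objects keyed by probe and sample
identifiers; the dataclasses here add validation and a stable vocabulary
(cell types, control-probe classes, timepoints) on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Leukocyte cell types resolved by the reference-based deconvolution,
#: in fixed column order.
CELL_TYPES = ("CD8T", "CD4T", "NK", "B", "Mono", "Gran")

#: Control-probe classes monitored for per-sample technical outliers.
CONTROL_CLASSES = (
    "BS-I-C",
    "BS-II",
    "Specificity-I",
    "Specificity-II",
    "Staining-Red",
    "Staining-Green",
)

TIMEPOINTS = ("T0", "T1", "T2")

MANIFEST_COLUMNS = (
    "probe_id",
    "chrom",
    "pos",
    "nearest_gene",
    "snp_dist_bp",
    "snp_maf",
    "cross_reactive",
    "is_control",
    "control_class",
    "is_cell_reference",
)


@dataclass
class ProbeManifest:
    """Per-probe annotation: genomic location, filter flags, control class.

    ``table`` is indexed by ``probe_id`` and carries the columns of
    :data:`MANIFEST_COLUMNS` (minus the index). Control probes have no
    meaningful genomic coordinates; their ``chrom`` is ``"control"``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.name != "probe_id":
            if "probe_id" in self.table.columns:
                self.table = self.table.set_index("probe_id")
            else:
                raise ValueError("manifest table must be keyed by probe_id")
        if not self.table.index.is_unique:
            dups = self.table.index[self.table.index.duplicated()].unique()
            raise ValueError(f"duplicate probe ids in manifest: {list(dups[:5])}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    @property
    def genomic_ids(self) -> pd.Index:
        return self.table.index[~self.table["is_control"]]

    @property
    def control_ids(self) -> pd.Index:
        return self.table.index[self.table["is_control"]]

    @property
    def reference_ids(self) -> pd.Index:
        return self.table.index[self.table["is_cell_reference"]]

    def subset(self, probe_ids) -> "ProbeManifest":
        return ProbeManifest(self.table.loc[list(probe_ids)].copy())


@dataclass
class CellReference:
    """Reference methylation signatures for the six leukocyte types.

    ``betas`` has one row per cell-discriminating reference CpG and one
    column per cell type (ordered as :data:`CELL_TYPES`).
    """

    betas: pd.DataFrame

    def __post_init__(self) -> None:
        if tuple(self.betas.columns) != CELL_TYPES:
            raise ValueError(f"reference columns must be {CELL_TYPES}")
        vals = self.betas.to_numpy(float)
        if np.isnan(vals).any() or (vals < 0).any() or (vals > 1).any():
            raise ValueError("reference betas must lie in [0, 1]")

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.betas.to_numpy(float)))


@dataclass
class SampleSheet:
    """Clinical covariates and anxiety-severity scores per sample.

    ``table`` is indexed by ``sample_id`` with columns: group
    (patient/control), age, sex, reported_sex, smoking (nullable; the
    control group has no smoking information), depression, medication,
    hama_t0/hama_t1/hama_t2 (Hamilton Anxiety Rating Scale scores, NaN
    when not assessed) and batch.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.name != "sample_id":
            if "sample_id" in self.table.columns:
                self.table = self.table.set_index("sample_id")
            else:
                raise ValueError("sample sheet must be keyed by sample_id")
        bad_age = self.table["age"] <= 0
        if bad_age.any():
            raise ValueError("ages must be positive")
        controls = self.table["group"] == "control"
        for col in ("hama_t0", "hama_t1", "hama_t2"):
            if col in self.table.columns and self.table.loc[controls, col].notna().any():
                raise ValueError("controls must not carry HAM-A scores")
        patients = self.table["group"] == "patient"
        if patients.any() and self.table.loc[patients, "hama_t0"].isna().any():
            raise ValueError("patients must have a baseline HAM-A score")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def patient_ids(self) -> pd.Index:
        return self.table.index[self.table["group"] == "patient"]

    @property
    def control_ids(self) -> pd.Index:
        return self.table.index[self.table["group"] == "control"]

    def subset(self, sample_ids) -> "SampleSheet":
        return SampleSheet(self.table.loc[list(sample_ids)].copy())


@dataclass
class MethylationDataset:
    """Beta-value matrix for one timepoint plus detection information.

    ``betas``: samples x genomic probes, values in [0, 1], NaN for
    missing calls. ``detection``: boolean, True where the probe produced
    signal. ``control_betas``: samples x control probes, used for
    technical-variance diagnostics and adjustment.
    """

    betas: pd.DataFrame
    detection: pd.DataFrame
    control_betas: pd.DataFrame
    timepoint: str = "T0"

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}")
        if self.betas.shape != self.detection.shape:
            raise ValueError("betas and detection mask must be congruent")
        if not self.betas.index.equals(self.control_betas.index):
            raise ValueError("betas and control_betas must share sample index")
        vals = self.betas.to_numpy(float)
        if vals.size and np.isfinite(vals).any():
            with np.errstate(invalid="ignore"):
                if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
                    raise ValueError("beta values must lie in [0, 1]")

    @property
    def sample_ids(self) -> pd.Index:
        return self.betas.index

    @property
    def probe_ids(self) -> pd.Index:
        return self.betas.columns

    def call_rate(self) -> pd.Series:
        """Fraction of genomic probes that are detected with a non-missing beta."""
        ok = self.detection.to_numpy(bool) & ~self.betas.isna().to_numpy()
        return pd.Series(ok.mean(axis=1), index=self.betas.index, name="call_rate")

    def missing_signal_frac(self) -> pd.Series:
        """Fraction of genomic probes completely lacking signal."""
        frac = 1.0 - self.detection.to_numpy(bool).mean(axis=1)
        return pd.Series(frac, index=self.betas.index, name="missing_signal_frac")

    def subset_samples(self, sample_ids) -> "MethylationDataset":
        ids = list(sample_ids)
        return MethylationDataset(
            betas=self.betas.loc[ids].copy(),
            detection=self.detection.loc[ids].copy(),
            control_betas=self.control_betas.loc[ids].copy(),
            timepoint=self.timepoint,
        )

    def subset_probes(self, probe_ids) -> "MethylationDataset":
        ids = list(probe_ids)
        return MethylationDataset(
            betas=self.betas[ids].copy(),
            detection=self.detection[ids].copy(),
            control_betas=self.control_betas.copy(),
            timepoint=self.timepoint,
        )


@dataclass
class EffectSpec:
    """Planted effect structure for the synthetic cohort generator.

    cc_spiked: (probe_id, target patient-minus-control mean beta difference).
    pred_spiked: (probe_id, log-odds of treatment response per unit M value
    at baseline). long_spiked: (probe_id, (beta drift at T1, beta drift at
    T2)) applied in responders only. noise_sd is the logit-scale
    measurement SD per array; bio_sd the logit-scale between-person
    biological SD, shared across a person's timepoints (damped at
    cell-reference probes, whose variance is composition-driven);
    tech_sd the magnitude of a per-array technical factor expressed in
    the control probes and a subset of genomic probes (what control-probe
    PCs are meant to remove); dirichlet_alpha parameterises the
    cell-mixture draw; batch_sd the logit-scale batch shift magnitude.
    """

    cc_spiked: list = field(default_factory=list)
    pred_spiked: list = field(default_factory=list)
    long_spiked: list = field(default_factory=list)
    noise_sd: float = 0.10
    bio_sd: float = 0.60
    tech_sd: float = 0.20
    dirichlet_alpha: tuple = (2.4, 4.5, 1.5, 1.5, 2.1, 18.0)
    batch_sd: float = 0.30

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.bio_sd < 0:
            raise ValueError("bio_sd must be non-negative")
        if self.batch_sd < 0:
            raise ValueError("batch_sd must be non-negative")
        alpha = np.asarray(self.dirichlet_alpha, float)
        if alpha.shape != (6,) or (alpha <= 0).any():
            raise ValueError("dirichlet_alpha must be a positive 6-vector")
        for pid, delta in self.cc_spiked:
            if abs(delta) >= 1:
                raise ValueError(f"cc_spiked delta for {pid} leaves (0, 1)")

    def validate_against(self, manifest: ProbeManifest) -> None:
        """Check spiked probes exist, are genomic, and keep means inside (0, 1)."""
        genomic = set(manifest.genomic_ids)
        for name, entries in (
            ("cc_spiked", self.cc_spiked),
            ("pred_spiked", self.pred_spiked),
            ("long_spiked", self.long_spiked),
        ):
            for entry in entries:
                pid = entry[0]
                if pid not in genomic:
                    raise ValueError(f"{name} probe {pid!r} is not a genomic probe")


def null_effects(**overrides) -> EffectSpec:
    """An EffectSpec with no spiked probes (null generator)."""
    return EffectSpec(**overrides)
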