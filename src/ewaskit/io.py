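"""Plain-text readers and writers for pipeline artifacts.

Formats: probe manifest and beta matrices as TSV (samples as rows, probe
ids as columns, missing entries as NA), sample sheet as CSV, cell
reference as TSV. A methylation dataset occupies one directory per
timepoint with betas.tsv, detection.tsv (0/1) and control_betas.tsv.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .data import CellReference, MethylationDataset, ProbeManifest, SampleSheet

FLOAT_FMT = "%.15g"


def write_manifest(manifest: ProbeManifest, path) -> None:
    manifest.table.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_manifest(path) -> ProbeManifest:
    tab = pd.read_csv(path, sep="\t", index_col="probe_id",
                      dtype={"chrom": str, "nearest_gene": str,
                             "control_class": str})
    for col in ("cross_reactive", "is_control", "is_cell_reference"):
        tab[col] = tab[col].astype(bool)
    return ProbeManifest(tab)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, float_format=FLOAT_FMT)


def read_sample_sheet(path) -> SampleSheet:
    tab = pd.read_csv(path, index_col="sample_id")
    tab["smoking"] = tab["smoking"].map(
        {True: True, False: False, "True": True, "False": False}).astype("boolean")
    for col in ("depression", "medication"):
        tab[col] = tab[col].astype(bool)
    return SampleSheet(tab)


def write_reference(reference: CellReference, path) -> None:
    reference.betas.to_csv(path, sep="\t", index_label="probe_id",
                           float_format=FLOAT_FMT)


def read_reference(path) -> CellReference:
    return CellReference(pd.read_csv(path, sep="\t", index_col="probe_id"))


def write_dataset(dataset: MethylationDataset, dirpath) -> None:
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    dataset.betas.to_csv(d / "betas.tsv", sep="\t", na_rep="NA",
                         index_label="sample_id", float_format=FLOAT_FMT)
    dataset.detection.astype(int).to_csv(d / "detection.tsv", sep="\t",
                                         index_label="sample_id")
    dataset.control_betas.to_csv(d / "control_betas.tsv", sep="\t",
                                 index_label="sample_id",
                                 float_format=FLOAT_FMT)
    (d / "timepoint.txt").write_text(dataset.timepoint + "\n")


def read_dataset(dirpath) -> MethylationDataset:
    d = Path(dirpath)
    betas = pd.read_csv(d / "betas.tsv", sep="\t", index_col="sample_id",
                        na_values="NA")
    detection = pd.read_csv(d / "detection.tsv", sep="\t",
                            index_col="sample_id").astype(bool)
    control = pd.read_csv(d / "control_betas.tsv", sep="\t",
                          index_col="sample_id")
    tp = (d / "timepoint.txt").read_text().strip()
    return MethylationDataset(betas=betas, detection=detection,
                              control_betas=control, timepoint=tp)


def write_matrix(frame: pd.DataFrame, path, index_label="sample_id") -> None:
    frame.to_csv(path, sep="\t", na_rep="NA", index_label=index_label,
                 float_format=FLOAT_FMT)


def read_matrix(path, index_col="sample_id") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values="NA")
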