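"""Multiple-testing classification, inflation diagnostics and serialization.

The genomic inflation factor lambda is the ratio of the median observed
association chi-square (one degree of freedom, obtained from two-sided
p-values) to the theoretical chi-square median; lambda near 1 indicates
a well-calibrated genome-wide null. Hits are tiered as significant
(p <= Bonferroni threshold) or suggestive (threshold < p < 1e-5, strict
upper bound). Result tables and Manhattan-plot data are written as
plain tab-separated text with a deterministic (p, probe_id) ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

SUGGESTIVE_DEFAULT = 1e-5


@dataclass
class InflationStat:
    lambda_: float
    n_pvalues: int


def genomic_inflation(p_values) -> InflationStat:
    """Lambda = median observed chi2(1) / theoretical chi2(1) median.

    The theoretical median is evaluated from the inverse CDF at runtime
    (~0.4549), not hard-coded. Input p-values must lie in (0, 1]; flagged
    rows (NaN) should be dropped by the caller.
    """
    p = np.asarray(pd.Series(p_values).dropna(), float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
    return InflationStat(lambda_=lam, n_pvalues=int(p.size))


def qq_data(p_values) -> pd.DataFrame:
    """Expected vs observed -log10 p for a QQ plot (no rendering)."""
    p = np.asarray(pd.Series(p_values).dropna(), float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    obs = np.sort(p)
    n = p.size
    expected = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame({
        "expected_neglog10": -np.log10(expected),
        "observed_neglog10": -np.log10(obs),
    })


def classify_hits(results: pd.DataFrame,
                  sig: float,
                  suggestive: float = SUGGESTIVE_DEFAULT) -> pd.DataFrame:
    """Tier probes: significant (p <= sig), suggestive (sig < p < suggestive).

    The significant boundary is inclusive and the suggestive boundary
    strict; flagged rows (no p-value) get tier "flagged".
    """
    if not 0 < sig < 1 or not 0 < suggestive < 1:
        raise ValueError("thresholds must lie in (0, 1)")
    # on small probe sets the family-wise threshold can exceed the
    # suggestive one; the suggestive band is then empty by construction
    p = results["p_value"]
    tier = np.where(p.isna(), "flagged",
                    np.where(p <= sig, "significant",
                             np.where(p < suggestive, "suggestive", "none")))
    out = pd.DataFrame({"tier": tier}, index=results.index)
    out["sig_threshold"] = sig
    out["suggestive_threshold"] = suggestive
    return out


def annotate_results(results: pd.DataFrame, manifest) -> pd.DataFrame:
    """Attach nearest-gene, chromosome and position from the manifest."""
    unknown = [p for p in results.index if p not in manifest.table.index]
    if unknown:
        raise ValueError(f"probes missing from manifest: {unknown[:5]}")
    ann = manifest.table.loc[results.index, ["chrom", "pos", "nearest_gene"]]
    out = results.join(ann)
    return out.sort_values(["p_value", "probe_id"], na_position="last")


def annotate_and_write(results: pd.DataFrame,
                       manifest,
                       out_path,
                       sig: float | None = None,
                       suggestive: float = SUGGESTIVE_DEFAULT) -> dict:
    """Write the annotated result table and Manhattan-plot data.

    Result TSV is sorted by (p, probe_id); the Manhattan file is BED-like
    (chrom, pos-1, pos, -log10 p, tier) with 0-based half-open intervals.
    Returns the paths written.
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    annotated = annotate_results(results, manifest)
    if sig is not None:
        annotated = annotated.join(classify_hits(annotated, sig, suggestive)["tier"])
    annotated.to_csv(out_path, sep="\t", float_format="%.15g")

    manhattan_path = out_path.with_name(out_path.stem + ".manhattan.bed")
    ok = annotated["p_value"].notna()
    man = pd.DataFrame({
        "chrom": annotated.loc[ok, "chrom"],
        "start": annotated.loc[ok, "pos"].astype(int) - 1,
        "end": annotated.loc[ok, "pos"].astype(int),
        "neglog10_p": -np.log10(annotated.loc[ok, "p_value"]),
    })
    if sig is not None:
        man["tier"] = annotated.loc[ok, "tier"]
    man.to_csv(manhattan_path, sep="\t", index=False, float_format="%.15g")
    return {"results": str(out_path), "manhattan": str(manhattan_path)}


def read_results(path) -> pd.DataFrame:
    """Round-trip reader for tables written by :func:`annotate_and_write`."""
    return pd.read_csv(path, sep="\t", index_col="probe_id")
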