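"""Bland-Altman agreement between volume estimators and the reference method.

Relative differences (percent of the mean of the two methods) are summarized
per muscle by their mean (bias), sample standard deviation, and the limits of
agreement bias +/- 1.96 SD.  A positive difference means the estimator
underestimates the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "relative_difference",
    "bland_altman",
    "BlandAltman",
    "AgreementSummary",
    "agreement_summary",
    "cohort_summary",
]


def relative_difference(
    mv_ref_mm3, mv_est_mm3, denominator: str = "mean"
):
    """Relative difference in percent between reference and estimated volume.

    ``100 * (ref - est) / ((ref + est)/2)`` by default (classical
    Bland-Altman denominator for ratio-scale data); ``denominator='reference'``
    divides by the reference instead.  Positive values mean the estimator
    underestimates.  Accepts scalars or arrays.
    """
    ref = np.asarray(mv_ref_mm3, dtype=float)
    est = np.asarray(mv_est_mm3, dtype=float)
    if np.any(ref <= 0) or np.any(est <= 0):
        raise ValueError("volumes must be positive")
    if denominator == "mean":
        denom = (ref + est) / 2.0
    elif denominator == "reference":
        denom = ref
    else:
        raise ValueError("denominator must be 'mean' or 'reference'")
    out = 100.0 * (ref - est) / denom
    return out if np.ndim(mv_ref_mm3) or np.ndim(mv_est_mm3) else float(out)


@dataclass(frozen=True)
class BlandAltman:
    """Bias and limits of agreement of a set of paired percent differences."""

    bias_pct: float
    sd_pct: float
    lloa_pct: float
    uloa_pct: float
    n: int


def bland_altman(differences_pct) -> BlandAltman:
    """Bias (mean), sample SD and the +/- 1.96 SD limits of agreement."""
    d = np.asarray(differences_pct, dtype=float)
    if d.size < 2:
        raise ValueError("at least 2 paired differences are required")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias, sd, bias - 1.96 * sd, bias + 1.96 * sd, int(d.size))


@dataclass
class AgreementSummary:
    """Per-muscle/method agreement against the slice-by-slice reference.

    ``table`` has one row per (muscle, method) with bias, SD and limits;
    ``per_subject`` is the long-format table (mean of methods in mm^3,
    percent difference) from which Bland-Altman plots are drawn.
    """

    table: pd.DataFrame
    per_subject: pd.DataFrame


def agreement_summary(
    results: pd.DataFrame,
    method_columns: dict[str, str],
    ref_column: str = "mv_ref_mm3",
    muscle_column: str = "muscle",
    denominator: str = "mean",
) -> AgreementSummary:
    """Bland-Altman summary per muscle for each estimator column.

    Parameters
    ----------
    results:
        Per-subject table with the reference volume, one column per
        estimator, and a muscle identifier.
    method_columns:
        Mapping from method name to the column holding its estimates.
    """
    rows, per_subject = [], []
    for muscle, grp in results.groupby(muscle_column, sort=True):
        for method, col in method_columns.items():
            diffs = relative_difference(
                grp[ref_column].to_numpy(), grp[col].to_numpy(), denominator
            )
            ba = bland_altman(diffs)
            rows.append(
                {
                    "muscle": muscle,
                    "method": method,
                    "bias_pct": ba.bias_pct,
                    "sd_pct": ba.sd_pct,
                    "lloa_pct": ba.lloa_pct,
                    "uloa_pct": ba.uloa_pct,
                    "n": ba.n,
                }
            )
            means = (grp[ref_column].to_numpy() + grp[col].to_numpy()) / 2.0
            for sid, m, dpct in zip(grp["subject_id"], means, diffs):
                per_subject.append(
                    {
                        "muscle": muscle,
                        "method": method,
                        "subject_id": sid,
                        "mean_mm3": m,
                        "diff_pct": dpct,
                    }
                )
    return AgreementSummary(pd.DataFrame(rows), pd.DataFrame(per_subject))


def cohort_summary(results: pd.DataFrame, muscle_column: str = "muscle") -> pd.DataFrame:
    """Mean +/- SD per muscle of volume, length, ACSA_max, its location, and p.

    Locations are reported in percent of muscle length (0 = distal).
    """
    cols = {
        "mv_ref_mm3": "mv_ref_mm3",
        "length_mm": "length_mm",
        "acsa_max_mm2": "acsa_max_mm2",
        "acsa_max_location_pct": "acsa_max_location_pct",
        "p": "p",
    }
    rows = []
    for muscle, grp in results.groupby(muscle_column, sort=True):
        row = {"muscle": muscle, "n": len(grp)}
        for name, col in cols.items():
            vals = grp[col].to_numpy(dtype=float)
            row[f"{name}_mean"] = float(vals.mean())
            row[f"{name}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
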