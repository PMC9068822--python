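"""Descriptive expression-response transforms and qPCR relative expression.

Two small, exact computations:

* the baseline-vs-response representation of a treatment experiment —
  per gene, ``baseline = ln(E_ctrl / E_ctrl,avg)`` (how high the gene sat
  in control, relative to the grand mean over all genes and control
  replicates) against ``response = ln(E_trt / E_ctrl)`` (how it moved) —
  and its Spearman trend statistic;

* the qPCR log2 relative expression ``log2RE = -(Ct_X - Ct_ref)``,
  i.e. log2 of 2^-dCt against a reference gene such as GAPDH.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ResponseProfile",
    "response_vs_baseline",
    "trend_statistic",
    "log2_relative_expression",
]


@dataclass
class ResponseProfile:
    table: pd.DataFrame  # index: gene ids, columns: baseline, response
    pseudocount: float

    @property
    def baseline(self) -> pd.Series:
        return self.table["baseline"]

    @property
    def response(self) -> pd.Series:
        return self.table["response"]


def response_vs_baseline(
    matrix: pd.DataFrame,
    labels: pd.Series | dict,
    ctrl_label: str,
    trt_label: str,
    pseudocount: float = 0.5,
    min_tpm: float = 0.0,
) -> ResponseProfile:
    """Baseline and response coordinates per gene.

    *matrix* is genes x samples of non-negative abundances (TPM); *labels*
    maps sample name to condition.  E_ctrl / E_trt are per-gene replicate
    means plus a pseudocount; E_ctrl,avg is the grand mean over all genes
    and control replicates (plus the same pseudocount).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("expression matrix contains negative entries")
    labels = pd.Series(labels)
    ctrl_cols = labels.index[labels == ctrl_label]
    trt_cols = labels.index[labels == trt_label]
    if len(ctrl_cols) == 0 or len(trt_cols) == 0:
        raise KeyError(f"no samples labeled {ctrl_label!r} or {trt_label!r}")
    sub = matrix
    if min_tpm > 0:
        sub = matrix.loc[matrix[ctrl_cols].mean(axis=1) >= min_tpm]
    e_ctrl = sub[ctrl_cols].mean(axis=1) + pseudocount
    e_trt = sub[trt_cols].mean(axis=1) + pseudocount
    e_ctrl_avg = float(sub[ctrl_cols].to_numpy().mean()) + pseudocount
    table = pd.DataFrame(
        {
            "baseline": np.log(e_ctrl / e_ctrl_avg),
            "response": np.log(e_trt / e_ctrl),
        }
    )
    return ResponseProfile(table=table, pseudocount=pseudocount)


def trend_statistic(profile: ResponseProfile) -> dict:
    """Spearman rank correlation between baseline and response.

    A negative rho is the mean-reversion signature: initially lowly
    expressed genes move up, initially highly expressed genes move down.
    """
    n = len(profile.table)
    if n < 3:
        raise ValueError("need at least 3 genes")
    b = profile.baseline.to_numpy()
    r = profile.response.to_numpy()
    if np.ptp(b) == 0 or np.ptp(r) == 0:
        return {"rho": float("nan"), "n": n, "defined": False}
    rho, _ = stats.spearmanr(b, r)
    return {"rho": float(rho), "n": n, "defined": True}


def log2_relative_expression(
    ct: pd.DataFrame, reference_gene: str = "GAPDH"
) -> pd.DataFrame:
    """log2RE = -(Ct_X - Ct_ref) per sample and gene.

    *ct* has columns sample, gene, Ct.  Every sample must carry a Ct for
    the reference gene; lower Ct than the reference means positive log2RE.
    """
    required = {"sample", "gene", "Ct"}
    if missing := required - set(ct.columns):
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    ref = ct.loc[ct["gene"] == reference_gene].set_index("sample")["Ct"]
    out_rows = []
    for sample, grp in ct.groupby("sample"):
        if sample not in ref.index:
            raise KeyError(f"sample {sample!r} lacks reference gene {reference_gene!r}")
        for _, row in grp.iterrows():
            if row["gene"] == reference_gene:
                continue
            out_rows.append(
                {
                    "sample": sample,
                    "gene": row["gene"],
                    "log2RE": -(row["Ct"] - ref.loc[sample]),
                }
            )
    return pd.DataFrame(out_rows)
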