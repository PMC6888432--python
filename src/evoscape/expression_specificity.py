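"""Tissue-specificity calls on protein x tissue TPM tables.

For each protein with expression x_1..x_n over n tissues, the mean
mu = (1/n) sum x_i and the population standard deviation
s = sqrt((1/n) sum (x_i - mu)^2) define the specificity threshold
mu + 1.65 s; a tissue is a specific-expression call when its TPM strictly
exceeds that threshold. 1.65 is the one-sided 90%-confidence normal factor,
so under a no-specificity null roughly the upper ~5% tail of tissues is
flagged. The divisor-n (population) SD and the strict inequality are part of
the statistic's definition and are asserted in tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CONFIDENCE_FACTOR",
    "SpecificityCall",
    "read_expression",
    "specificity_calls",
    "summarize_by_tissue",
    "write_calls",
]

CONFIDENCE_FACTOR = 1.65


@dataclass(frozen=True)
class SpecificityCall:
    protein: str
    tissue: str
    tpm: float
    mu: float
    s: float
    threshold: float  # mu + 1.65 * s
    flag: int         # 1 iff tpm > threshold (strict)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Protein x tissue TPM table; first column is the protein id.

    Missing cells become explicit zeros with a warning, negative values are
    an error.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.isna().any().any():
        import warnings

        warnings.warn("missing TPM cells set to 0", stacklevel=2)
        df = df.fillna(0.0)
    if (df.to_numpy() < 0).any():
        raise ValueError("negative TPM values in expression table")
    return df


def specificity_calls(table: pd.DataFrame,
                      factor: float = CONFIDENCE_FACTOR,
                      log_transform: bool = False) -> list[SpecificityCall]:
    """All (protein, tissue) specificity calls for an expression table.

    ``log_transform`` applies log1p to TPM before computing mu/s/threshold
    (off by default; the statistic is defined on raw TPM).
    """
    if table.shape[1] < 2:
        raise ValueError("need at least two tissues per protein")
    X = table.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("negative TPM values")
    W = np.log1p(X) if log_transform else X
    mu = W.mean(axis=1)
    s = W.std(axis=1)  # population SD (divisor n)
    thr = mu + factor * s
    calls = []
    for i, protein in enumerate(table.index):
        for j, tissue in enumerate(table.columns):
            calls.append(SpecificityCall(
                protein=str(protein), tissue=str(tissue), tpm=float(X[i, j]),
                mu=float(mu[i]), s=float(s[i]), threshold=float(thr[i]),
                flag=int(W[i, j] > thr[i])))
    return calls


def summarize_by_tissue(calls: list[SpecificityCall], tissue: str
                        ) -> pd.DataFrame:
    """Proteins specifically expressed in one tissue, sorted by name."""
    tissues = {c.tissue for c in calls}
    if tissue not in tissues:
        raise KeyError(f"tissue {tissue!r} not present in the calls")
    rows = [(c.protein, c.tpm, c.threshold) for c in calls
            if c.tissue == tissue and c.flag]
    rows.sort()
    return pd.DataFrame(rows, columns=["protein", "tpm", "threshold"])


def write_calls(calls: list[SpecificityCall], path: str | Path,
                flagged_only: bool = True) -> None:
    from .formats_io import _comment_header

    with open(path, "w") as fh:
        fh.write(_comment_header(factor=CONFIDENCE_FACTOR) + "\n")
        fh.write("protein\ttissue\ttpm\tmu\ts\tthreshold\tflag\n")
        for c in calls:
            if flagged_only and not c.flag:
                continue
            fh.write(f"{c.protein}\t{c.tissue}\t{c.tpm:.6g}\t{c.mu:.6g}\t"
                     f"{c.s:.6g}\t{c.threshold:.6g}\t{c.flag}\n")
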