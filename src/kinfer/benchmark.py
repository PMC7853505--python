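"""Scoring inferred against truth relationships.

The confusion matrix is oriented inferred-by-truth: rows are inferred
labels, columns are truth labels.  Pairs present in only one of the two
maps count as "unrelated" on the missing side; truly-unrelated pairs
absent from both maps are not enumerated (their count is quadratic in
the cohort), so the unrelated/unrelated cell only reflects pairs that
appeared somewhere.

Per degree i with TP_i correct calls, P_i truth pairs and FP_i false
calls:  recall = TP_i/P_i,  precision = TP_i/(TP_i+FP_i),
F1 = 2*recall*precision/(recall+precision); degrees with no truth pairs
report NaN rather than 0.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

LABELS = ["MZ", "PO", "FS", "2nd", "3rd", "4th", "unrelated"]


def confusion(
    truth: Mapping[tuple, str], inferred: Mapping[tuple, str]
) -> pd.DataFrame:
    """Inferred-by-truth label counts over the union of scored pairs."""
    index = {lab: i for i, lab in enumerate(LABELS)}
    mat = np.zeros((len(LABELS), len(LABELS)), dtype=np.int64)
    for pair in set(truth) | set(inferred):
        t = truth.get(pair, "unrelated")
        f = inferred.get(pair, "unrelated")
        if t not in index or f not in index:
            raise ValueError(f"unknown degree label for pair {pair}: {t!r}/{f!r}")
        mat[index[f], index[t]] += 1
    return pd.DataFrame(mat, index=pd.Index(LABELS, name="inferred"),
                        columns=pd.Index(LABELS, name="truth"))


def precision_recall_f1(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-degree TP/P/FP, precision, recall and F1 from a confusion
    matrix (rows = inferred, columns = truth)."""
    mat = matrix.to_numpy()
    tp = np.diag(mat).astype(float)
    p = mat.sum(axis=0).astype(float)  # truth totals per column
    called = mat.sum(axis=1).astype(float)
    fp = called - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        recall = np.where(p > 0, tp / p, np.nan)
        precision = np.where(tp + fp > 0, tp / (tp + fp), np.nan)
        denom = recall + precision
        f1 = np.where(
            np.isnan(recall) | np.isnan(precision),
            np.nan,
            np.where(denom > 0, 2 * recall * precision / np.where(denom > 0, denom, 1), 0.0),
        )
    return pd.DataFrame(
        {
            "TP": tp.astype(np.int64),
            "P": p.astype(np.int64),
            "FP": fp.astype(np.int64),
            "recall": recall,
            "precision": precision,
            "F1": f1,
        },
        index=matrix.index.rename("degree"),
    )
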