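"""External clustering validation via normalized mutual information.

The predicted clustering and the ground truth are viewed as two discrete
random variables over the items; agreement is quantified by

    NMI = 2 I(X; Y) / (H(X) + H(Y))

with natural logarithms, computed from the contingency table. NMI is 1 for
identical partitions (up to label renaming), 0 for independent ones, and
symmetric in its arguments.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .io import MpickDataError
from .modularity import Partition

__all__ = ["contingency_table", "nmi", "otu_count_summary"]


def _as_label_map(x) -> dict[str, object]:
    if isinstance(x, Partition):
        return dict(x.assignment)
    return dict(x)


def contingency_table(pred, truth) -> pd.DataFrame:
    """Counts n_kl of items in predicted cluster k and truth class l."""
    pred = _as_label_map(pred)
    truth = _as_label_map(truth)
    missing = sorted(set(truth) - set(pred))
    extra = sorted(set(pred) - set(truth))
    if missing or extra:
        raise MpickDataError(
            "id sets differ between prediction and truth; "
            f"missing from prediction: {missing[:5]}; unexpected: {extra[:5]}"
        )
    ids = list(pred)
    return pd.crosstab(
        pd.Series([pred[i] for i in ids], name="pred"),
        pd.Series([truth[i] for i in ids], name="truth"),
    )


def nmi(pred, truth) -> float:
    """Normalized mutual information in [0, 1] between two labelings.

    Degenerate conventions: two single-cluster partitions (which then
    necessarily coincide) score 1; if exactly one side has zero entropy the
    score is 0.
    """
    table = contingency_table(pred, truth).to_numpy(dtype=float)
    n = table.sum()
    if n < 1:
        raise MpickDataError("empty labelings")
    pk = table.sum(axis=1) / n
    pl = table.sum(axis=0) / n
    hx = -sum(p * math.log(p) for p in pk if p > 0)
    hy = -sum(p * math.log(p) for p in pl if p > 0)
    if hx == 0 and hy == 0:
        return 1.0
    if hx == 0 or hy == 0:
        return 0.0
    info = 0.0
    nk = table.sum(axis=1)
    nl = table.sum(axis=0)
    for k in range(table.shape[0]):
        for l in range(table.shape[1]):
            if table[k, l] > 0:
                info += (table[k, l] / n) * math.log(
                    n * table[k, l] / (nk[k] * nl[l])
                )
    value = 2.0 * info / (hx + hy)
    # clip floating-point excursions just outside [0, 1]
    return float(min(1.0, max(0.0, value)))


def otu_count_summary(counts_or_partitions) -> tuple[float, float]:
    """Mean and sample standard deviation (n-1) of OTU counts.

    Accepts raw counts or Partition objects. A single replicate reports a
    standard deviation of 0 with a warning.
    """
    counts = [
        c.n_clusters if isinstance(c, Partition) else int(c)
        for c in counts_or_partitions
    ]
    if not counts:
        raise MpickDataError("no replicates")
    if len(counts) == 1:
        warnings.warn("single replicate: standard deviation reported as 0")
        return float(counts[0]), 0.0
    arr = np.asarray(counts, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1))
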