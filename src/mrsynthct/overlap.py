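"""Segmentation overlap metrics: Dice and its false-negative / false-positive
decomposition, all in percent.

With segmentation ``A`` and ground truth ``G``:

    DSC = 200·|A∩G| / (|A|+|G|)
    FND = 200·|A̅∩G| / (|A|+|G|)      (under-segmentation)
    FPD = 200·|A∩G̅| / (|A|+|G|)      (over-segmentation)

The three are linked by the identity ``FND + FPD = 200 − 2·DSC``. FND and
FPD may exceed 100 by these definitions (e.g. an empty segmentation of a
nonempty truth gives FND = 200); no clamping is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError
from .volio import CLASS_NAMES, BinaryMask, LabelMap, check_same_grid

__all__ = ["OverlapScores", "overlap_scores", "cohort_overlap_table"]


@dataclass(frozen=True)
class OverlapScores:
    dsc: float
    fnd: float
    fpd: float
    n_segmented: int
    n_truth: int
    n_intersection: int


def overlap_scores(A: BinaryMask, G: BinaryMask) -> OverlapScores:
    """Dice-type overlap of a segmentation ``A`` against ground truth ``G``."""
    check_same_grid(A, G)
    a, g = A.mask, G.mask
    na = int(a.sum())
    ng = int(g.sum())
    if na + ng == 0:
        raise UndefinedMetricError("both masks empty: overlap undefined")
    n_int = int((a & g).sum())
    denom = na + ng
    return OverlapScores(
        dsc=200.0 * n_int / denom,
        fnd=200.0 * int((~a & g).sum()) / denom,
        fpd=200.0 * int((a & ~g).sum()) / denom,
        n_segmented=na,
        n_truth=ng,
        n_intersection=n_int,
    )


def per_class_scores(predicted: LabelMap, truth: LabelMap) -> dict[int, OverlapScores]:
    """Overlap scores for each of the eight classes of a label-map pair."""
    check_same_grid(predicted, truth)
    out = {}
    for code in CLASS_NAMES:
        A = BinaryMask(predicted.labels == code, predicted.spacing, predicted.origin)
        G = BinaryMask(truth.labels == code, truth.spacing, truth.origin)
        out[code] = overlap_scores(A, G)
    return out


def cohort_overlap_table(cases) -> pd.DataFrame:
    """Per-class mean and sample SD (n−1) of DSC/FND/FPD across a cohort.

    ``cases`` is a sequence of ``(predicted LabelMap, truth LabelMap)``
    pairs. With a single case the SD is undefined; it is reported as 0 and
    the ``degenerate_sd`` column is set.
    """
    cases = list(cases)
    if not cases:
        raise ValueError("empty cohort")
    records: dict[int, dict[str, list[float]]] = {
        code: {"dsc": [], "fnd": [], "fpd": []} for code in CLASS_NAMES
    }
    for predicted, truth in cases:
        for code, sc in per_class_scores(predicted, truth).items():
            records[code]["dsc"].append(sc.dsc)
            records[code]["fnd"].append(sc.fnd)
            records[code]["fpd"].append(sc.fpd)

    degenerate = len(cases) < 2
    rows = []
    for code in CLASS_NAMES:
        row: dict[str, object] = {"class": CLASS_NAMES[code]}
        for metric in ("dsc", "fnd", "fpd"):
            vals = np.asarray(records[code][metric])
            row[f"{metric}_mean"] = float(vals.mean())
            row[f"{metric}_sd"] = 0.0 if degenerate else float(vals.std(ddof=1))
        row["degenerate_sd"] = degenerate
        rows.append(row)
    return pd.DataFrame(rows).set_index("class")
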