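"""Edge/flat region classification and scute-shape frequency tables.

Scutes are split into carapace-edge and flat-region scutes by their
size-normalized Gaussian curvature (normalized CGS ≥ 5 → edge), and
polygon-shape frequencies (proportion of scutes with k neighbors) are
computed per specimen excluding opening scutes, whose neighbor count is
not comparable because at least one edge has no neighbor.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .morphometrics import MISSING_FLAG

CGS_EDGE_THRESHOLD = 5.0

#: neighbor-count display classes: 3..8 and ">=9" pooled
SHAPE_CLASSES = [3, 4, 5, 6, 7, 8, "9+"]


def classify_region(normalized_cgs, threshold: float = CGS_EDGE_THRESHOLD):
    """'edge' where normalized CGS ≥ threshold (inclusive), else 'flat'.

    Accepts a scalar or an array; NaN curvature yields the empty string
    with a warning (record excluded from region analyses).
    """
    arr = np.asarray(normalized_cgs, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    out = np.where(arr >= threshold, "edge", "flat").astype(object)
    bad = ~np.isfinite(arr)
    if np.any(bad):
        warnings.warn(f"{int(bad.sum())} scutes lack curvature and are "
                      "excluded from region classification", stacklevel=2)
        out[bad] = ""
    return out[0] if scalar else out


def shape_frequencies(records: pd.DataFrame,
                      exclude_zero_area: bool = False) -> pd.DataFrame:
    """Per-specimen proportions of scutes with k neighbors (k = 3…8, ≥9).

    Opening scutes (plane-based area flagged −1000) are excluded from
    the denominator; ``exclude_zero_area`` additionally drops scutes
    whose computed area is zero.  Returns one row per specimen with
    ``prop_k`` and ``count_k`` columns plus ``n_included`` and
    ``n_excluded_opening``.
    """
    req = {"specimen", "n_neighbors", "area"}
    if not req.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(req)}")
    rows = []
    for spec_id, grp in records.groupby("specimen", sort=True):
        opening = grp["area"] == MISSING_FLAG
        included = ~opening
        if exclude_zero_area:
            included &= grp["area"] != 0
        sub = grp[included]
        if len(sub) == 0:
            raise ValueError(f"specimen {spec_id}: no scutes left after "
                             "excluding opening scutes")
        row = {"specimen": spec_id, "n_included": len(sub),
               "n_excluded_opening": int(opening.sum())}
        k = sub["n_neighbors"].to_numpy()
        k = np.clip(k, 3, None)  # degenerate counts pooled into class 3
        for cls in SHAPE_CLASSES:
            if cls == "9+":
                c = int((k >= 9).sum())
            else:
                c = int((k == cls).sum())
            row[f"count_{cls}"] = c
            row[f"prop_{cls}"] = c / len(sub)
        rows.append(row)
    out = pd.DataFrame(rows)
    prop_cols = [f"prop_{c}" for c in SHAPE_CLASSES]
    assert np.allclose(out[prop_cols].sum(axis=1), 1.0, atol=1e-9)
    return out
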