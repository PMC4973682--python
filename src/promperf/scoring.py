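"""Oxford Hip Score (OHS) scoring and the ordinal threshold map.

The OHS is a 12-item instrument; each item is answered on a five-point
ordinal scale scored 0 (most severe symptoms) to 4 (no symptoms) and the
total is the unweighted sum, 0 (worst) to 48 (best).

Each item is modelled as the discretisation of a latent standard-normal
variable cut at ordered thresholds: category 0 iff Z <= alpha_1, category
m iff alpha_m < Z <= alpha_{m+1}, top category iff Z > alpha_{M-1}.  A
latent value exactly equal to a cut-point belongs to the lower category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_ITEMS = 12
N_CATEGORIES = 5
MAX_TOTAL = N_ITEMS * (N_CATEGORIES - 1)  # 48


@dataclass(frozen=True)
class ItemThresholds:
    """Strictly increasing cut-points on the latent scale for one item.

    For an M-category item there are M-1 cut-points.
    """

    alpha: np.ndarray

    def __post_init__(self) -> None:
        alpha = np.asarray(self.alpha, dtype=float)
        if alpha.ndim != 1 or alpha.size < 1:
            raise ValueError("thresholds must be a 1-d vector with >= 1 cut-point")
        if not np.all(np.isfinite(alpha)):
            raise ValueError("thresholds must be finite")
        if alpha.size > 1 and not np.all(np.diff(alpha) > 0):
            raise ValueError("thresholds must be strictly increasing")
        object.__setattr__(self, "alpha", alpha)

    @property
    def n_categories(self) -> int:
        return self.alpha.size + 1


def categorize_latent(z, thresholds: ItemThresholds):
    """Map latent values to ordinal categories through the threshold model.

    Category m is the number of cut-points strictly below z, so z equal to
    a cut-point falls in the lower category.  Accepts scalars or arrays.
    """
    alpha = thresholds.alpha if isinstance(thresholds, ItemThresholds) else np.asarray(thresholds, float)
    z = np.asarray(z, dtype=float)
    cat = np.searchsorted(alpha, z, side="left")
    return cat if cat.ndim else int(cat)


def score_total(items):
    """Total OHS from 12 item scores; NaN if any item is missing.

    Item non-response is treated as missing data to be imputed at item
    level, not pro-rated, so a total is only defined when all 12 items are
    observed.  Missing items are encoded as NaN (or None).
    """
    arr = np.asarray([np.nan if v is None else v for v in items], dtype=float)
    if arr.shape != (N_ITEMS,):
        raise ValueError(f"expected {N_ITEMS} items, got shape {arr.shape}")
    observed = ~np.isnan(arr)
    vals = arr[observed]
    if vals.size and (np.any(vals < 0) | np.any(vals > 4) | np.any(vals != np.round(vals))):
        raise ValueError("item scores must be integers in 0..4 or missing")
    if not observed.all():
        return float("nan")
    return float(arr.sum())


def score_totals_frame(items_matrix) -> np.ndarray:
    """Vectorised totals for an (n, 12) matrix with NaN for missing items."""
    arr = np.asarray(items_matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != N_ITEMS:
        raise ValueError(f"expected an (n, {N_ITEMS}) matrix")
    totals = arr.sum(axis=1)
    totals[np.isnan(arr).any(axis=1)] = np.nan
    return totals
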