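"""Cross-validation of RI signatures against fluorescence.

Three complementary checks of whether an RI pattern is specific to a
fluorescently identified structure:

* :func:`ks_bootstrap` — does the RI distribution under a fluorescence mask
  differ from the whole-cell RI distribution, beyond what a random
  size-matched mask would show?  Assessed across a range of mask
  stringencies (fluorescence threshold quantiles).
* :func:`pearson_coloc` — pixelwise Pearson correlation of the two signals
  inside the cell.
* :func:`overlap_fraction` — object-level overlap of two binary labelings
  (e.g. thresholded fluorescence vs RI segmentation, or algorithm vs human
  expert).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

__all__ = [
    "MaskStringencyCurve",
    "OverlapResult",
    "ks_bootstrap",
    "pearson_coloc",
    "overlap_fraction",
]

DEFAULT_QUANTILES = tuple(np.round(np.arange(0.50, 1.00, 0.05), 2))


@dataclass
class MaskStringencyCurve:
    """Bootstrapped KS p-values as a function of mask stringency.

    ``table`` columns: quantile, n_mask_px, ks_statistic, p_value (NaN for
    quantiles whose mask is empty, flagged in ``empty``).
    """

    table: pd.DataFrame
    n_bootstrap: int
    seed: int

    @property
    def quantiles(self) -> np.ndarray:
        return self.table["quantile"].to_numpy()

    @property
    def p_values(self) -> np.ndarray:
        return self.table["p_value"].to_numpy()


def ks_bootstrap(
    ri_map: np.ndarray,
    fluo_img: np.ndarray,
    cell_mask: np.ndarray,
    quantiles=DEFAULT_QUANTILES,
    n_bootstrap: int = 500,
    seed: int = 0,
) -> MaskStringencyCurve:
    """Mask-conditioned two-sample KS test with a random-mask bootstrap null.

    For each fluorescence threshold quantile q the mask is
    ``fluo >= quantile_q(fluo within cell)`` intersected with the cell.
    The observed statistic is the two-sample KS distance between RI values
    under the mask and under the whole cell.  Its p-value is the fraction
    of ``n_bootstrap`` random size-matched masks (uniform pixel draws
    within the cell — the 'random object' null) whose statistic is at
    least as large, with the usual +1 correction so the null p-value is
    uniform on a (B+1)-point grid.
    """
    if ri_map.shape != fluo_img.shape or ri_map.shape != cell_mask.shape:
        raise ValueError("ri_map, fluo_img and cell_mask must share one grid")
    if n_bootstrap < 100:
        raise ValueError("n_bootstrap must be >= 100 for a usable p-value grid")
    quantiles = np.asarray(sorted(quantiles), dtype=float)
    if np.any(np.diff(quantiles) <= 0):
        raise ValueError("quantiles must be strictly increasing")
    cell_mask = cell_mask.astype(bool)
    ri_cell = ri_map[cell_mask].astype(float)
    fluo_cell = fluo_img[cell_mask].astype(float)
    rng = np.random.default_rng(seed)
    rows = []
    for q in quantiles:
        thr = np.quantile(fluo_cell, q)
        sel = fluo_cell >= thr
        m = int(sel.sum())
        if m == 0 or m == len(ri_cell):
            rows.append({"quantile": q, "n_mask_px": m,
                         "ks_statistic": np.nan, "p_value": np.nan})
            continue
        obs = ks_2samp(ri_cell[sel], ri_cell).statistic
        boot = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            pick = rng.choice(len(ri_cell), size=m, replace=False)
            boot[b] = ks_2samp(ri_cell[pick], ri_cell).statistic
        p = (1 + int(np.sum(boot >= obs))) / (n_bootstrap + 1)
        rows.append({"quantile": q, "n_mask_px": m, "ks_statistic": obs,
                     "p_value": p})
    return MaskStringencyCurve(pd.DataFrame(rows), n_bootstrap, seed)


def pearson_coloc(
    ri_map: np.ndarray, fluo_img: np.ndarray, cell_mask: np.ndarray
) -> float:
    """Pearson correlation of the two pixel vectors inside the cell mask.

    Returns NaN (undefined) when either signal is constant under the mask.
    """
    cell_mask = cell_mask.astype(bool)
    if not cell_mask.any():
        raise ValueError("cell mask is empty")
    a = ri_map[cell_mask].astype(float)
    b = fluo_img[cell_mask].astype(float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass(frozen=True)
class OverlapResult:
    """Pixel overlap of two labelings: the fraction of a covered by b,
    of b covered by a, and their Jaccard index."""

    fraction_a_in_b: float
    fraction_b_in_a: float
    jaccard: float


def overlap_fraction(labels_a: np.ndarray, labels_b: np.ndarray) -> OverlapResult:
    """Overlap |a AND b| / |a| of two masks or label images, plus the
    symmetric variants.  Empty ``labels_a`` flags every field NaN."""
    if labels_a.shape != labels_b.shape:
        raise ValueError("labelings must share one grid")
    a = np.asarray(labels_a) > 0
    b = np.asarray(labels_b) > 0
    na, nb = int(a.sum()), int(b.sum())
    inter = int((a & b).sum())
    union = na + nb - inter
    if na == 0:
        return OverlapResult(float("nan"), float("nan"),
                             float("nan") if union == 0 else inter / union)
    return OverlapResult(
        fraction_a_in_b=inter / na,
        fraction_b_in_a=inter / nb if nb else float("nan"),
        jaccard=inter / union if union else float("nan"),
    )
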