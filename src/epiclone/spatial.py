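"""Multivariate spatial autocorrelation correlograms.

The statistic is the multiallelic autocorrelation coefficient r of Smouse &
Peakall: pairwise squared Euclidean distances between marker vectors are
Gower-centred into a covariance-like matrix C, and within each geographic
distance class

    r = sum_{pairs (x,y) in class} c_xy / sum_{pairs} 0.5 * (c_xx + c_yy).

Significance per class comes from random permutation of sample locations
against marker rows; uncertainty of r itself from bootstrap resampling of
pairs within the class.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io_core import SsrTable, SubepilocusMatrix


def ssr_allele_counts(ssr: SsrTable) -> pd.DataFrame:
    """Encode diploid genotypes as per-allele counts in {0, 1, 2} per locus."""
    cols = {}
    for locus in ssr.loci:
        a = ssr.df[f"{locus}.1"]
        b = ssr.df[f"{locus}.2"]
        alleles = sorted(
            set(a.dropna().astype(int)) | set(b.dropna().astype(int))
        )
        for al in alleles:
            cols[f"{locus}:{al}"] = (
                (a == al).astype(float) + (b == al).astype(float)
            )
    return pd.DataFrame(cols, index=ssr.df.index)


def epigenotype_matrix(matrices: dict[str, SubepilocusMatrix]) -> pd.DataFrame:
    """Concatenate the binary subepilocus scores into one marker matrix."""
    parts = []
    for klass in ("n", "m", "h"):
        df = matrices[klass].df.copy()
        df.columns = [f"{c}:{klass}" for c in df.columns]
        parts.append(df)
    return pd.concat(parts, axis=1)


def squared_marker_distance(markers: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Pairwise squared Euclidean distances (symmetric, zero diagonal)."""
    X = np.asarray(markers, dtype=float)
    if X.ndim != 2:
        raise ValueError("marker matrix must be 2-D")
    return squareform(pdist(X, metric="sqeuclidean"))


def gower_center(D: np.ndarray) -> np.ndarray:
    """Double-centre a squared-distance matrix: c_xy = -0.5 (d_xy - ri - rj + g)."""
    D = np.asarray(D, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    row = D.mean(axis=1, keepdims=True)
    grand = D.mean()
    return -0.5 * (D - row - row.T + grand)


def _pair_class_masks(coords: np.ndarray, edges: np.ndarray) -> list[np.ndarray]:
    """Boolean (n, n) upper-triangle masks, one per half-open class [lo, hi)."""
    geo = squareform(pdist(np.asarray(coords, dtype=float)))
    iu = np.triu(np.ones_like(geo, dtype=bool), k=1)
    masks = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        masks.append(iu & (geo >= lo) & (geo < hi))
    return masks


def autocorrelation_r(C: np.ndarray, mask: np.ndarray) -> float:
    """r for the pairs selected by a boolean upper-triangle mask.

    Returns NaN (flagged undefined) when the class has no pairs or the
    denominator vanishes (all samples identical).
    """
    if not mask.any():
        return float("nan")
    i, j = np.nonzero(mask)
    num = C[i, j].sum()
    den = 0.5 * (C[i, i] + C[j, j]).sum()
    if den == 0:
        return float("nan")
    return float(num / den)


@dataclasses.dataclass
class Correlogram:
    """Per-distance-class r with permutation envelope and bootstrap CI."""

    table: pd.DataFrame
    # columns: lo, hi, n_pairs, r, perm_p, perm_lo, perm_hi, boot_lo, boot_hi
    n_perm: int
    n_boot: int
    seed: int


def _r_all_classes(C: np.ndarray, masks: list[np.ndarray]) -> np.ndarray:
    return np.array([autocorrelation_r(C, m) for m in masks])


def correlogram(
    markers,
    coords,
    class_width: float = 1.0,
    max_dist: float = 20.0,
    n_perm: int = 9999,
    n_boot: int = 9999,
    seed: int = 0,
    equal_pairs: bool = False,
    n_classes: int | None = None,
) -> Correlogram:
    """Full correlogram with permutation test and bootstrap CIs per class.

    By default distance classes are fixed-width bins [0, w), [w, 2w), ... up
    to ``max_dist``.  With ``equal_pairs=True`` the class edges are instead
    chosen so each class holds (close to) the same number of pairs
    (``n_classes`` bins, default max_dist / class_width).

    The permutation scheme shuffles sample locations jointly against marker
    rows while holding C fixed; the two-sided p-value uses the add-one
    estimator p = (1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1).  Bootstrap CIs
    resample pairs within each class with replacement.
    """
    X = np.asarray(markers, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if len(X) != len(coords):
        raise ValueError("markers and coordinates differ in sample count")
    n = len(X)
    if n < 3:
        raise ValueError("need at least three samples")
    rng = np.random.default_rng(seed)
    C = gower_center(squared_marker_distance(X))

    if equal_pairs:
        k = n_classes or max(1, int(round(max_dist / class_width)))
        geo = pdist(coords)
        qs = np.quantile(geo, np.linspace(0, 1, k + 1))
        edges = np.unique(qs)
        edges[-1] = edges[-1] + 1e-9  # close the top bin
    else:
        edges = np.arange(0.0, max_dist + class_width, class_width)
    masks = _pair_class_masks(coords, edges)

    r_obs = _r_all_classes(C, masks)

    # permutation null: permute rows/cols of C (== shuffling locations)
    perm_r = np.full((n_perm, len(masks)), np.nan)
    for p in range(n_perm):
        perm = rng.permutation(n)
        Cp = C[np.ix_(perm, perm)]
        perm_r[p] = _r_all_classes(Cp, masks)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN empty classes
        exceed = np.abs(perm_r) >= np.abs(r_obs)[None, :]
        perm_p = (1 + np.nansum(exceed, axis=0)) / (n_perm + 1)
        perm_lo = np.nanpercentile(perm_r, 2.5, axis=0)
        perm_hi = np.nanpercentile(perm_r, 97.5, axis=0)

    # bootstrap over pairs within class
    boot_lo = np.full(len(masks), np.nan)
    boot_hi = np.full(len(masks), np.nan)
    diag = np.diag(C)
    for ci, mask in enumerate(masks):
        i, j = np.nonzero(mask)
        if len(i) == 0 or np.isnan(r_obs[ci]):
            continue
        num_terms = C[i, j]
        den_terms = 0.5 * (diag[i] + diag[j])
        idx = rng.integers(0, len(i), size=(n_boot, len(i)))
        num = num_terms[idx].sum(axis=1)
        den = den_terms[idx].sum(axis=1)
        ok = den != 0
        if ok.any():
            rb = num[ok] / den[ok]
            boot_lo[ci], boot_hi[ci] = np.percentile(rb, [2.5, 97.5])

    table = pd.DataFrame(
        {
            "lo": edges[:-1],
            "hi": edges[1:],
            "n_pairs": [int(m.sum()) for m in masks],
            "r": r_obs,
            "perm_p": np.where(np.isnan(r_obs), np.nan, perm_p),
            "perm_lo": perm_lo,
            "perm_hi": perm_hi,
            "boot_lo": boot_lo,
            "boot_hi": boot_hi,
        }
    )
    return Correlogram(table=table, n_perm=n_perm, n_boot=n_boot, seed=seed)


def autocorrelation_extent(corr: Correlogram) -> float:
    """Distance (class upper edge) up to which aggregation is significant.

    The extent is the upper edge of the last class in the initial run of
    classes with positive r outside the permutation envelope (r > perm_hi).
    Classes with no pairs carry no evidence and are skipped.  Returns 0 when
    the first populated class is already non-significant.
    """
    extent = 0.0
    for row in corr.table.itertuples():
        if row.n_pairs == 0:
            continue
        if np.isnan(row.r) or not (row.r > row.perm_hi):
            break
        extent = row.hi
    return float(extent)
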