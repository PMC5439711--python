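"""MS-AFLP condition classification, mixed scoring, and quality statistics.

HpaII and MspI are isoschizomers cutting 5'-CCGG-3' with different
methylation sensitivities, so the presence/absence pattern of a fragment
across the two digests encodes the methylation state of the site:

====================  =========  ==========================================
(HpaII, MspI) bands   condition  interpretation
====================  =========  ==========================================
(1, 1)                I          non-methylated
(0, 1)                II         internal (CG) cytosine methylation
(1, 0)                III        external cytosine hemi-methylation (CHG)
(0, 0)                IV         full methylation or site loss by mutation
====================  =========  ==========================================

Mixed scoring expands each polymorphic site into three binary subepiloci:
n (condition I), m (condition II) and h (condition III); condition IV scores
0 at all three, so the three class matrices are one-hot-or-empty.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io_core import BandMatrix, SubepilocusMatrix, pair_band_matrices

CONDITIONS = ("I", "II", "III", "IV")

#: (hpa, msp) band pair -> condition
_CONDITION_OF = {(1, 1): "I", (0, 1): "II", (1, 0): "III", (0, 0): "IV"}

#: condition -> (n, m, h) subepilocus bits
_MIXED_SCORE = {
    "I": (1, 0, 0),
    "II": (0, 1, 0),
    "III": (0, 0, 1),
    "IV": (0, 0, 0),
}

#: condition -> (hpa, msp) band pair (inverse of classification; used by the
#: simulator and by round-trip tests)
BANDS_OF_CONDITION = {v: k for k, v in _CONDITION_OF.items()}


def classify_condition(hpa, msp):
    """Condition call for one (HpaII, MspI) band pair; missing propagates."""
    if pd.isna(hpa) or pd.isna(msp):
        return None
    return _CONDITION_OF[(int(hpa), int(msp))]


def mixed_score(condition):
    """(n, m, h) bits for a condition call; missing in, missing out."""
    if condition is None or (isinstance(condition, float) and np.isnan(condition)):
        return (None, None, None)
    return _MIXED_SCORE[condition]


def condition_matrix(hpa: BandMatrix, msp: BandMatrix) -> pd.DataFrame:
    """Samples x fragments matrix of condition calls (object dtype, None=missing)."""
    pair_band_matrices(hpa, msp)
    h = hpa.df.to_numpy(dtype=float)
    m = msp.df.to_numpy(dtype=float)
    out = np.full(h.shape, None, dtype=object)
    valid = ~(np.isnan(h) | np.isnan(m))
    codes = (h * 2 + m)  # 3->I, 1->II, 2->III, 0->IV
    lut = {3.0: "I", 1.0: "II", 2.0: "III", 0.0: "IV"}
    for code, cond in lut.items():
        out[valid & (codes == code)] = cond
    return pd.DataFrame(out, index=hpa.df.index, columns=hpa.df.columns)


def find_polymorphic(conditions: pd.DataFrame) -> list[str]:
    """Fragments showing >=2 distinct non-missing conditions across samples.

    Order of the input columns is preserved.  All-missing fragments are
    dropped (they carry no condition call at all).
    """
    if len(conditions) < 2:
        raise ValueError("need at least two samples to assess polymorphism")
    retained = []
    for col in conditions.columns:
        seen = {c for c in conditions[col] if c is not None}
        if len(seen) >= 2:
            retained.append(col)
    return retained


def subepilocus_matrices(
    conditions: pd.DataFrame, loci: list[str] | None = None
) -> dict[str, SubepilocusMatrix]:
    """Mixed-score a condition matrix into the three subepilocus matrices."""
    if loci is None:
        loci = list(conditions.columns)
    sub = conditions[loci]
    out = {}
    for ci, klass in enumerate(("n", "m", "h")):
        vals = sub.map(
            lambda c, ci=ci: np.nan if c is None else float(_MIXED_SCORE[c][ci])
        ).astype(float)
        out[klass] = SubepilocusMatrix(klass=klass, df=vals)
    return out


def scoring_error_rate(original: BandMatrix, replicate: BandMatrix) -> float:
    """Percent mismatch between paired non-missing band calls.

    Returns NaN when no jointly non-missing pairs exist.  Symmetric in its
    arguments.
    """
    if list(original.df.index) != list(replicate.df.index) or list(
        original.df.columns
    ) != list(replicate.df.columns):
        raise ValueError("original and replicate matrices are not aligned")
    a = original.df.to_numpy(dtype=float)
    b = replicate.df.to_numpy(dtype=float)
    paired = ~(np.isnan(a) | np.isnan(b))
    n = int(paired.sum())
    if n == 0:
        return float("nan")
    mism = int((a[paired] != b[paired]).sum())
    return 100.0 * mism / n


def scoring_error_report(
    pairs: list[tuple[BandMatrix, BandMatrix]]
) -> pd.DataFrame:
    """Per (enzyme, primer pair) error rates plus pooled rows.

    ``pairs`` is a list of (original, replicate) band matrices.
    """
    rows = []
    pooled: dict[str, list[int]] = {}
    for orig, rep in pairs:
        a = orig.df.to_numpy(dtype=float)
        b = rep.df.to_numpy(dtype=float)
        paired = ~(np.isnan(a) | np.isnan(b))
        mism = int((a[paired] != b[paired]).sum())
        n = int(paired.sum())
        rows.append(
            {
                "enzyme": orig.enzyme,
                "primer_pair": orig.primer_pair,
                "error_rate_pct": 100.0 * mism / n if n else np.nan,
                "n_paired_calls": n,
            }
        )
        acc = pooled.setdefault(orig.enzyme, [0, 0])
        acc[0] += mism
        acc[1] += n
    for enzyme, (mism, n) in sorted(pooled.items()):
        rows.append(
            {
                "enzyme": enzyme,
                "primer_pair": "(pooled)",
                "error_rate_pct": 100.0 * mism / n if n else np.nan,
                "n_paired_calls": n,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stability of epigenetic variation

@dataclasses.dataclass
class StabilityReport:
    """Per locus x site-class concordance percentages, plus the overall mean.

    Site classes follow the standard MSAP reading: the CG column compares the
    HpaII-channel call (whose loss marks internal-CG methylation), the CHG
    column the MspI-channel call (whose loss marks external hemi-methylation).
    """

    df: pd.DataFrame  # index: locus; columns: CG, CHG; values in [0, 100]

    def __post_init__(self) -> None:
        vals = self.df.to_numpy(dtype=float)
        ok = np.isnan(vals) | ((vals >= 0) & (vals <= 100))
        if not ok.all():
            raise ValueError("concordance percentage outside [0, 100]")

    @property
    def overall_mean(self) -> float:
        return float(np.nanmean(self.df.to_numpy(dtype=float)))


_CHANNELS = {"CG": "hpa", "CHG": "msp"}


def positional_stability(leaves: pd.DataFrame) -> StabilityReport:
    """Leaf-position concordance with the top leaf, averaged over ramets.

    ``leaves`` is long-format with columns ``ramet``, ``leaf_rank`` (0 = top
    leaf, increasing downward), ``locus``, ``hpa``, ``msp`` (band calls).
    For each ramet and locus the fraction of leaves (top leaf included)
    matching the top leaf's call is computed per channel, then averaged
    across ramets.  A one-leaf ramet contributes 100% (degenerate but legal).
    """
    loci = list(dict.fromkeys(leaves["locus"]))
    out = pd.DataFrame(index=pd.Index(loci, name="locus"), columns=["CG", "CHG"],
                       dtype=float)
    for site, chan in _CHANNELS.items():
        for locus in loci:
            sub = leaves[leaves["locus"] == locus]
            per_ramet = []
            for _, grp in sub.groupby("ramet", sort=False):
                grp = grp.sort_values("leaf_rank")
                top = grp[chan].iloc[0]
                match = (grp[chan] == top).mean()
                per_ramet.append(100.0 * match)
            out.loc[locus, site] = float(np.mean(per_ramet)) if per_ramet else np.nan
    return StabilityReport(out)


def seasonal_stability(june: pd.DataFrame, september: pd.DataFrame) -> StabilityReport:
    """Between-date concordance over paired ramets.

    Inputs are long-format with columns ``ramet``, ``locus``, ``hpa``,
    ``msp``; ramets are paired by id.  Per locus and channel the percentage
    of pairs with identical calls is reported; loci with no pairs are NaN.
    """
    merged = june.merge(september, on=["ramet", "locus"], suffixes=("_jun", "_sep"))
    loci = list(dict.fromkeys(june["locus"]))
    out = pd.DataFrame(index=pd.Index(loci, name="locus"), columns=["CG", "CHG"],
                       dtype=float)
    for site, chan in _CHANNELS.items():
        for locus in loci:
            sub = merged[merged["locus"] == locus]
            if len(sub) == 0:
                out.loc[locus, site] = np.nan
                continue
            match = (sub[f"{chan}_jun"] == sub[f"{chan}_sep"]).mean()
            out.loc[locus, site] = 100.0 * match
    return StabilityReport(out)
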