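"""Data model and tabular I/O shared by every pipeline stage.

All on-disk formats are UTF-8 TSV with a header row and ``NA`` for missing
values.  Coordinates are 0-based integer metres at grid-line crossings;
vegetation-cover quadrats are unit squares named by their lower-left corner,
so a ``plot_size``-metre plot has ``(plot_size + 2)**2`` quadrats once the
one-quadrat surrounding ring is included (484 for a 20 m plot).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

NA = "NA"

#: midpoint shading fraction of the five ordinal cover categories
#: (no shade; <=30%; <=60%; <=90%; <=100%)
COVER_MIDPOINTS = np.array([0.0, 0.15, 0.45, 0.75, 0.95])

ENZYMES = ("HpaII", "MspI")
SUBEPILOCUS_CLASSES = ("n", "m", "h")
STAGES = ("flowering", "vegetative")


class ValidationError(ValueError):
    """Raised when an input table violates a schema invariant."""


@dataclasses.dataclass
class SampleFrame:
    """Per-ramet records: id, integer grid coordinates, growth stage.

    ``genet_id`` and ``cover_x`` are filled in by later stages and may be
    missing (pd.NA / NaN) on input.
    """

    df: pd.DataFrame  # columns: sample_id, x, y, stage, genet_id, cover_x
    plot_size: int = 20

    def __post_init__(self) -> None:
        df = self.df
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample_id {dup!r}")
        for c in ("x", "y"):
            bad = (df[c] < 0) | (df[c] > self.plot_size)
            if bad.any():
                row = df.index[bad][0]
                raise ValidationError(
                    f"coordinate out of range at row {row}, column {c!r}: "
                    f"{df.loc[row, c]}"
                )
        if df.duplicated(subset=["x", "y"]).any():
            raise ValidationError("more than one sample at a grid point")
        bad_stage = ~df["stage"].isin(STAGES)
        if bad_stage.any():
            raise ValidationError(
                f"unknown growth stage {df.loc[df.index[bad_stage][0], 'stage']!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    def coords(self) -> np.ndarray:
        """(n, 2) integer array of grid coordinates, in row order."""
        return self.df[["x", "y"]].to_numpy(dtype=int)

    def __eq__(self, other) -> bool:
        return isinstance(other, SampleFrame) and _frames_equal(self.df, other.df)


@dataclasses.dataclass
class CoverGrid:
    """Ordinal vegetation-cover categories on unit quadrats.

    Categories 0..4 mean: no shade, <=30%, <=60%, <=90%, <=100% cover.
    The grid must cover the focal plot plus the one-quadrat surrounding ring
    (lower-left corners from -1 to plot_size).
    """

    df: pd.DataFrame  # columns: qx, qy, category
    plot_size: int = 20

    def __post_init__(self) -> None:
        df = self.df
        bad = ~df["category"].isin(range(5))
        if bad.any():
            row = df.index[bad][0]
            raise ValidationError(
                f"category out of range at row {row}: {df.loc[row, 'category']}"
            )
        if df.duplicated(subset=["qx", "qy"]).any():
            raise ValidationError("duplicate quadrat")
        need = {
            (qx, qy)
            for qx in range(-1, self.plot_size + 1)
            for qy in range(-1, self.plot_size + 1)
        }
        have = set(zip(df["qx"], df["qy"]))
        if not need <= have:
            missing = sorted(need - have)[0]
            raise ValidationError(
                f"cover grid does not cover plot + ring; missing quadrat {missing}"
            )

    def category_at(self) -> Mapping[tuple[int, int], int]:
        return {
            (int(r.qx), int(r.qy)): int(r.category) for r in self.df.itertuples()
        }

    def __eq__(self, other) -> bool:
        return isinstance(other, CoverGrid) and _frames_equal(self.df, other.df)


@dataclasses.dataclass
class BandMatrix:
    """Presence/absence calls for one primer pair under one enzyme digest.

    Values are 0, 1 or missing (NaN); rows are samples, columns fragments.
    """

    enzyme: str
    primer_pair: str
    df: pd.DataFrame  # index: sample_id, columns: fragment names, float 0/1/NaN

    def __post_init__(self) -> None:
        if self.enzyme not in ENZYMES:
            raise ValidationError(f"unknown enzyme {self.enzyme!r}")
        vals = self.df.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0) | (vals == 1)
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValidationError(
                f"malformed band call at row {self.df.index[i]!r}, "
                f"column {self.df.columns[j]!r}: {vals[i, j]}"
            )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BandMatrix)
            and self.enzyme == other.enzyme
            and self.primer_pair == other.primer_pair
            and _frames_equal(self.df, other.df)
        )


def pair_band_matrices(hpa: BandMatrix, msp: BandMatrix) -> None:
    """Validate that the two digests of one primer pair are comparable."""
    if hpa.primer_pair != msp.primer_pair:
        raise ValidationError("band matrices are from different primer pairs")
    if list(hpa.df.index) != list(msp.df.index):
        only = set(hpa.df.index) ^ set(msp.df.index)
        raise ValidationError(
            f"sample sets differ between HpaII and MspI matrices: {sorted(only)}"
        )
    if list(hpa.df.columns) != list(msp.df.columns):
        raise ValidationError("fragment sets differ between the two digests")


@dataclasses.dataclass
class SsrTable:
    """Diploid genotypes at named SSR loci; allele pairs stored smaller-first."""

    df: pd.DataFrame  # index: sample_id; two columns per locus: <locus>.1, <locus>.2

    def __post_init__(self) -> None:
        for locus in self.loci:
            a = self.df[f"{locus}.1"].to_numpy(dtype=float)
            b = self.df[f"{locus}.2"].to_numpy(dtype=float)
            both = ~(np.isnan(a) | np.isnan(b))
            if np.isnan(a[~np.isnan(b)]).any() or np.isnan(b[~np.isnan(a)]).any():
                raise ValidationError(
                    f"half-missing genotype at locus {locus!r}"
                )
            if (a[both] > b[both]).any():
                raise ValidationError(
                    f"allele pair not in canonical order at locus {locus!r}"
                )

    @property
    def loci(self) -> list[str]:
        return sorted({c.rsplit(".", 1)[0] for c in self.df.columns})

    def complete_cases(self) -> "SsrTable":
        """Drop samples with any missing locus (exclusion is logged upstream)."""
        keep = ~self.df.isna().any(axis=1)
        return SsrTable(self.df.loc[keep].copy())

    def genotype_strings(self) -> pd.Series:
        """Canonical multilocus-genotype string per sample."""
        parts = []
        for locus in self.loci:
            a, b = self.df[f"{locus}.1"], self.df[f"{locus}.2"]
            parts.append(
                a.map(lambda v: NA if pd.isna(v) else str(int(v)))
                + "/"
                + b.map(lambda v: NA if pd.isna(v) else str(int(v)))
            )
        out = parts[0]
        for p in parts[1:]:
            out = out + ";" + p
        return out

    def __eq__(self, other) -> bool:
        return isinstance(other, SsrTable) and _frames_equal(self.df, other.df)


@dataclasses.dataclass
class SubepilocusMatrix:
    """Binary scores y_ijk for one subepilocus class (n, m or h)."""

    klass: str
    df: pd.DataFrame  # index: sample_id, columns: locus names, float 0/1/NaN

    def __post_init__(self) -> None:
        if self.klass not in SUBEPILOCUS_CLASSES:
            raise ValidationError(f"unknown subepilocus class {self.klass!r}")
        vals = self.df.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0) | (vals == 1)
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValidationError(
                f"malformed score at row {self.df.index[i]!r}, "
                f"column {self.df.columns[j]!r}"
            )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SubepilocusMatrix)
            and self.klass == other.klass
            and _frames_equal(self.df, other.df)
        )


def check_one_hot(matrices: Mapping[str, SubepilocusMatrix]) -> None:
    """At most one of the n/m/h matrices may score 1 at any (sample, locus)."""
    total = sum(
        np.nan_to_num(matrices[k].df.to_numpy(dtype=float)) for k in SUBEPILOCUS_CLASSES
    )
    if (total > 1).any():
        raise ValidationError("subepilocus classes are not mutually exclusive")


def _frames_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    try:
        pd.testing.assert_frame_equal(a.reset_index(drop=a.index.name is None),
                                      b.reset_index(drop=b.index.name is None),
                                      check_dtype=False)
        return True
    except AssertionError:
        return False


# ---------------------------------------------------------------------------
# readers / writers

SCHEMAS = ("samples", "cover", "ssr", "bands", "subepiloci")


def read_table(path, schema: str, **kw):
    """Read one of the five table types; dispatches on ``schema``."""
    readers = {
        "samples": read_samples,
        "cover": read_cover,
        "ssr": read_ssr,
        "bands": read_bands,
        "subepiloci": read_subepiloci,
    }
    if schema not in readers:
        raise ValueError(f"unknown schema {schema!r}; expected one of {SCHEMAS}")
    return readers[schema](path, **kw)


def write_table(obj, path) -> None:
    """Write any of the five table types; inverse of :func:`read_table`."""
    if isinstance(obj, SampleFrame):
        df = obj.df.copy()
        df.to_csv(path, sep="\t", index=False, na_rep=NA)
    elif isinstance(obj, CoverGrid):
        obj.df.to_csv(path, sep="\t", index=False, na_rep=NA)
    elif isinstance(obj, BandMatrix):
        out = obj.df.map(lambda v: NA if pd.isna(v) else str(int(v)))
        out.insert(0, "enzyme", obj.enzyme)
        out.insert(1, "primer_pair", obj.primer_pair)
        out.to_csv(path, sep="\t", index=True, index_label="sample_id")
    elif isinstance(obj, SsrTable):
        out = obj.df.map(lambda v: NA if pd.isna(v) else str(int(v)))
        out.to_csv(path, sep="\t", index=True, index_label="sample_id")
    elif isinstance(obj, SubepilocusMatrix):
        out = obj.df.map(lambda v: NA if pd.isna(v) else str(int(v)))
        out.insert(0, "class", obj.klass)
        out.to_csv(path, sep="\t", index=True, index_label="sample_id")
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")


def _read_tsv(path, **kw) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False, **kw)


def read_samples(path, plot_size: int = 20) -> SampleFrame:
    df = _read_tsv(path, dtype={"sample_id": str, "stage": str})
    need = {"sample_id", "x", "y", "stage"}
    if not need <= set(df.columns):
        raise ValidationError(f"samples table missing columns {need - set(df.columns)}")
    for c in ("x", "y"):
        if not np.allclose(df[c] % 1, 0):
            raise ValidationError(f"non-integer coordinate in column {c!r}")
        df[c] = df[c].astype(int)
    if "genet_id" not in df.columns:
        df["genet_id"] = pd.NA
    if "cover_x" not in df.columns:
        df["cover_x"] = np.nan
    df["genet_id"] = df["genet_id"].astype("Int64")
    df["cover_x"] = df["cover_x"].astype(float)
    return SampleFrame(df, plot_size=plot_size)


def read_cover(path, plot_size: int = 20) -> CoverGrid:
    df = _read_tsv(path)
    need = {"qx", "qy", "category"}
    if not need <= set(df.columns):
        raise ValidationError(f"cover table missing columns {need - set(df.columns)}")
    if df["category"].isna().any():
        raise ValidationError("missing cover category")
    df = df.astype({"qx": int, "qy": int, "category": int})
    return CoverGrid(df, plot_size=plot_size)


def read_ssr(path) -> SsrTable:
    df = _read_tsv(path, index_col="sample_id")
    df.index = df.index.astype(str)
    return SsrTable(df.astype(float))


def read_bands(path) -> BandMatrix:
    df = _read_tsv(path, index_col="sample_id")
    df.index = df.index.astype(str)
    enzyme = "HpaII"
    primer = ""
    if "enzyme" in df.columns:
        col = df.pop("enzyme")
        enzyme = col.iloc[0] if len(col) else "HpaII"
    if "primer_pair" in df.columns:
        col = df.pop("primer_pair")
        primer = col.iloc[0] if len(col) else ""
    return BandMatrix(enzyme=enzyme, primer_pair=primer, df=df.astype(float))


def read_subepiloci(path) -> SubepilocusMatrix:
    df = _read_tsv(path, index_col="sample_id")
    df.index = df.index.astype(str)
    klass = "n"
    if "class" in df.columns:
        col = df.pop("class")
        klass = col.iloc[0] if len(col) else "n"
    return SubepilocusMatrix(klass=klass, df=df.astype(float))


# ---------------------------------------------------------------------------
# spatial helpers

def grid_adjacency(samples: SampleFrame) -> dict[str, set[str]]:
    """Rook neighbourhood restricted to sampled points.

    Two samples are adjacent iff their grid points are exactly 1 m apart.
    The map is symmetric and irreflexive; isolated samples get an empty set.
    """
    by_coord = {
        (int(r.x), int(r.y)): r.sample_id for r in samples.df.itertuples()
    }
    adj: dict[str, set[str]] = {sid: set() for sid in samples.sample_ids}
    for (x, y), sid in by_coord.items():
        for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            other = by_coord.get((x + dx, y + dy))
            if other is not None:
                adj[sid].add(other)
    return adj


def cover_covariate(
    samples: SampleFrame, cover: CoverGrid, standardize: bool = True
) -> pd.Series:
    """Vegetation-cover covariate x_j for each sample.

    A grid point inherits the mean of the midpoint shading fractions of the
    (up to four) quadrats incident to it; with the surrounding ring present
    all four always exist.  By default the values are centred to mean 0 and
    scaled to unit SD over the sample set, which is the scale the model fits
    on (recorded in run metadata).
    """
    cat = cover.category_at()
    vals = []
    for r in samples.df.itertuples():
        x, y = int(r.x), int(r.y)
        quads = [(x - 1, y - 1), (x - 1, y), (x, y - 1), (x, y)]
        frac = [COVER_MIDPOINTS[cat[q]] for q in quads if q in cat]
        vals.append(float(np.mean(frac)))
    out = pd.Series(vals, index=samples.df["sample_id"].to_numpy(), name="cover_x")
    if standardize:
        sd = out.std(ddof=0)
        out = (out - out.mean()) / (sd if sd > 0 else 1.0)
    return out
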