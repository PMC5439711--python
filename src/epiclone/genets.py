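"""Genet assignment from multilocus SSR genotypes, and the P_gen screen.

Ramets sharing an identical multilocus genotype across all scored SSR loci
are assumed to belong to one genet (one clonal lineage).  The screen against
falsely merging distinct sexual recruits is P_gen: the Hardy-Weinberg
probability of drawing the multilocus genotype independently, which must be
small (the conventional threshold is < 0.001) for the exact-match rule to be
safe.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io_core import SsrTable


@dataclasses.dataclass
class GenetAssignment:
    """Partition of samples into genets, ranked by ramet count.

    Genets are numbered 1..G in decreasing order of the number of ramets;
    ties are broken by first-encountered sample order, which makes the
    numbering deterministic for a fixed row order.
    """

    membership: pd.Series  # sample_id -> genet_id (int)
    genets: pd.DataFrame  # index: genet_id; columns: ramet_count, genotype

    @property
    def n_genets(self) -> int:
        return len(self.genets)

    def members(self, genet_id: int) -> list[str]:
        return list(self.membership.index[self.membership == genet_id])


def assign_genets(ssr: SsrTable) -> GenetAssignment:
    """Group samples by exact multilocus-genotype identity and rank genets."""
    if len(ssr.df) == 0:
        return GenetAssignment(
            membership=pd.Series(dtype=int),
            genets=pd.DataFrame(columns=["ramet_count", "genotype"]),
        )
    if ssr.df.isna().any().any():
        raise ValueError(
            "missing genotypes present; filter with SsrTable.complete_cases first"
        )
    geno = ssr.genotype_strings()
    # group keys in first-encountered order
    order = list(dict.fromkeys(geno))
    counts = geno.value_counts()
    ranked = sorted(order, key=lambda g: (-counts[g], order.index(g)))
    genet_of = {g: i + 1 for i, g in enumerate(ranked)}
    membership = geno.map(genet_of).astype(int)
    membership.index = ssr.df.index
    genets = pd.DataFrame(
        {
            "ramet_count": [int(counts[g]) for g in ranked],
            "genotype": ranked,
        },
        index=pd.Index(range(1, len(ranked) + 1), name="genet_id"),
    )
    return GenetAssignment(membership=membership, genets=genets)


def genet_size_summary(assignment: GenetAssignment) -> dict:
    """Counts of large (>=10 ramets), smaller multi-ramet (2-9) and unique genets."""
    sizes = assignment.genets["ramet_count"]
    hist = sizes.value_counts().sort_index()
    return {
        "large": int((sizes >= 10).sum()),
        "smaller": int(((sizes >= 2) & (sizes < 10)).sum()),
        "singletons": int((sizes == 1).sum()),
        "histogram": {int(k): int(v) for k, v in hist.items()},
    }


def allele_frequencies(ssr: SsrTable, level: str = "ramet") -> dict[str, dict[int, float]]:
    """Relative allele frequencies per locus.

    ``level='ramet'`` counts every sample (the default screening convention);
    ``level='genet'`` counts each distinct multilocus genotype once.
    """
    if level == "genet":
        geno = ssr.genotype_strings()
        keep = ~geno.duplicated()
        table = SsrTable(ssr.df.loc[keep].copy())
    elif level == "ramet":
        table = ssr
    else:
        raise ValueError(f"unknown level {level!r}")
    freqs: dict[str, dict[int, float]] = {}
    for locus in table.loci:
        alleles = np.concatenate(
            [
                table.df[f"{locus}.1"].dropna().to_numpy(dtype=float),
                table.df[f"{locus}.2"].dropna().to_numpy(dtype=float),
            ]
        )
        vals, counts = np.unique(alleles, return_counts=True)
        total = counts.sum()
        freqs[locus] = {int(v): c / total for v, c in zip(vals, counts)}
    return freqs


def p_gen(
    genotype: dict[str, tuple[int, int]], freqs: dict[str, dict[int, float]]
) -> float:
    """Hardy-Weinberg probability of one multilocus genotype.

    Per locus: p**2 for a homozygote, 2*p*q for a heterozygote; the product
    over loci equals (product of allele frequencies) * 2**h with h the number
    of heterozygous loci.  Every allele must be present in ``freqs`` (estimate
    frequencies from the full sample first).
    """
    prob = 1.0
    for locus, (a, b) in genotype.items():
        locus_freqs = freqs[locus]
        if a not in locus_freqs or b not in locus_freqs:
            raise KeyError(
                f"allele not in frequency table at locus {locus!r}: {(a, b)}"
            )
        p, q = locus_freqs[a], locus_freqs[b]
        prob *= p * q if a == b else 2.0 * p * q
    return prob


def p_gen_report(ssr: SsrTable, level: str = "ramet") -> pd.DataFrame:
    """P_gen for every distinct multilocus genotype in the table."""
    freqs = allele_frequencies(ssr, level=level)
    geno = ssr.genotype_strings()
    rows = []
    seen = set()
    for sid in ssr.df.index:
        g = geno.loc[sid]
        if g in seen:
            continue
        seen.add(g)
        gt = {
            locus: (
                int(ssr.df.loc[sid, f"{locus}.1"]),
                int(ssr.df.loc[sid, f"{locus}.2"]),
            )
            for locus in ssr.loci
        }
        rows.append({"genotype": g, "p_gen": p_gen(gt, freqs)})
    return pd.DataFrame(rows)
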