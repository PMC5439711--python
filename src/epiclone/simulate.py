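"""Seeded synthetic datasets with the statistical structure the analysis assumes.

The generator emulates a 20 m x 20 m sampling lattice (441 grid points) in a
clonal herb population: genet founders arrive by a homogeneous Poisson
process, each genet spreads by a random walk of stolon-scale clonal steps,
one ramet per grid point is retained (the ramet nearest the point), a planar
vegetation-cover cline with ordinal noise covers the plot plus its ring, SSR
genotypes are drawn once per genet under Hardy-Weinberg equilibrium, and
methylation conditions arise from class-specific linear predictors — shared
intercepts, per-locus and per-genet-per-locus deviations, a cover slope and
ICAR-structured spatial noise — renormalised into a four-way categorical
draw (n / m / h / condition IV) so the three subepilocus classes are
mutually exclusive.  Band calls are then flipped independently at the two
enzyme channels' scoring-error rates.

Every observable file passes io_core validation, and the emitted ground
truth (genet labels, generative parameters, pre-error conditions) suffices
to score a full pipeline run without re-reading the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io_core, msap
from .io_core import (
    BandMatrix,
    CoverGrid,
    SampleFrame,
    SsrTable,
    grid_adjacency,
)

_DEF_CLASS_INTERCEPTS = {"n": -0.27, "m": 1.40, "h": -3.19}


def structure_config(seed: int = 0) -> "SimulationConfig":
    """Scenario with purely genet-driven methylation on the default geometry.

    Cover slopes and the spatial random field are switched off, so epigenetic
    aggregation can only arise from clonal patch structure plus independent
    scoring noise.  The h (hemi-methylation) class is placed in the regime
    the field survey reports for it: rare overall and with essentially no
    genet structure (the survey's deviating-genet counts for h were all
    zero), hence a small genet-effect scale.
    """
    cfg = SimulationConfig()
    return dataclasses.replace(
        cfg,
        seed=seed,
        class_params={
            "n": ClassParams(g0=-0.27, sigma_g=2.0, sigma_gk=1.5,
                             e0=0.0, sigma_e=0.0, sigma_s=0.0),
            "m": ClassParams(g0=1.40, sigma_g=2.0, sigma_gk=1.5,
                             e0=0.0, sigma_e=0.0, sigma_s=0.0),
            "h": ClassParams(g0=-5.0, sigma_g=1.0, sigma_gk=0.5,
                             e0=0.0, sigma_e=0.0, sigma_s=0.0),
        },
    )


def recovery_config(seed: int = 0) -> "SimulationConfig":
    """Geometry for parameter-recovery benchmarks: ~300 ramets in ~50 genets.

    Fewer founders spreading further than the population default, so most
    genets carry several ramets and genet-level effects are estimable; effect
    scales are unchanged.
    """
    return dataclasses.replace(
        SimulationConfig(),
        founder_density=0.11,
        mean_steps=30.0,
        step_dispersion=0.9,
        seed=seed,
    )


@dataclasses.dataclass
class ClassParams:
    """Generative effect scales for one subepilocus class's predictor."""

    g0: float
    sigma_g: float = 2.0
    sigma_gk: float = 1.5
    e0: float = 0.0
    sigma_e: float = 0.3
    sigma_s: float = 0.5


@dataclasses.dataclass
class SimulationConfig:
    """Study-condition parameters of the generator.

    Defaults emulate the field regime: a 20 m plot sampled at every grid
    crossing, founder density and clonal spread tuned so roughly 300-400
    ramets are sampled and singleton genets are the modal class, stolon
    steps of mean ~0.5 m (stolons exceed 30 cm), enzyme scoring-error rates
    of 3.9% (EcoRI-HpaII) and 7.4% (EcoRI-MspI), and class intercepts chosen
    so the m class is common, n uncommon and h rare (global rates near
    69% / 13% / 0.7%).
    """

    plot_size: int = 20
    founder_density: float = 0.42  # founders per square metre
    mean_steps: float = 3.0  # median clonal steps per genet (lognormal-Poisson)
    step_dispersion: float = 1.8  # sdlog of the per-genet step-count intensity
    step_length: float = 0.5  # mean stolon step length, metres (exponential)
    capture_radius: float = 0.5  # max ramet-to-grid-point distance sampled
    flowering_fraction: float = 0.53  # 176 of 335 sampled ramets flowering
    cover_direction: tuple[float, float] = (0.35, -1.0)  # densening axis (to S/SE)
    cover_slope: float = 1.6  # latent-trend units across the plot
    cover_noise: float = 0.8  # SD of latent ordinal noise
    n_ssr_loci: int = 8
    n_alleles: tuple[int, ...] = (7, 9, 6, 8, 10, 7, 8, 9)
    n_msap_loci: int = 24
    primer_pairs: tuple[str, ...] = ("P1", "P2", "P3", "P4")
    class_params: dict = dataclasses.field(
        default_factory=lambda: {
            k: ClassParams(g0=v) for k, v in _DEF_CLASS_INTERCEPTS.items()
        }
    )
    error_rate_hpa: float = 0.039
    error_rate_msp: float = 0.074
    seed: int = 20100616

    def subseed(self, label: str) -> np.random.Generator:
        """Deterministic per-component generator derived from the master seed."""
        h = hashlib.sha256(f"{self.seed}:{label}".encode()).digest()
        return np.random.default_rng(int.from_bytes(h[:4], "big"))


# ---------------------------------------------------------------------------
# cover

def simulate_cover(config: SimulationConfig, seed=None) -> CoverGrid:
    """Ordinal cover categories from a planar latent trend plus noise."""
    rng = config.subseed("cover") if seed is None else np.random.default_rng(seed)
    P = config.plot_size
    qx, qy = np.meshgrid(np.arange(-1, P + 1), np.arange(-1, P + 1), indexing="ij")
    dx, dy = config.cover_direction
    norm = np.hypot(dx, dy) or 1.0
    axis = (qx * dx + qy * dy) / (norm * P)  # roughly -1..1 across the plot
    latent = config.cover_slope * axis + config.cover_noise * rng.normal(
        size=qx.shape
    )
    # map latent z-scores to the five ordinal categories by equal quantile cuts
    if latent.std() > 0:
        z = (latent - latent.mean()) / latent.std()
    else:
        z = np.zeros_like(latent)
    cuts = np.quantile(z, [0.2, 0.4, 0.6, 0.8]) if latent.std() > 0 else None
    cat = (
        np.digitize(z, cuts) if cuts is not None else np.zeros_like(z, dtype=int)
    )
    df = pd.DataFrame(
        {"qx": qx.ravel(), "qy": qy.ravel(), "category": cat.ravel().astype(int)}
    )
    return CoverGrid(df, plot_size=P)


# ---------------------------------------------------------------------------
# genets and ramets

def simulate_genets(
    config: SimulationConfig, seed=None, allow_empty: bool = False
):
    """Founder placement + clonal random walks, thinned to one ramet per point.

    Returns a SampleFrame (one row per sampled grid point) and the true genet
    label per sample.  Genet labels are arbitrary positive integers at this
    stage; ranked ids come from genet assignment.
    """
    rng = config.subseed("genets") if seed is None else np.random.default_rng(seed)
    P = config.plot_size
    margin = 2.0  # founders just outside the plot can spread in
    area = (P + 2 * margin) ** 2
    n_founders = rng.poisson(config.founder_density * area)
    if n_founders == 0:
        if allow_empty:
            empty = SampleFrame(
                pd.DataFrame(
                    columns=["sample_id", "x", "y", "stage", "genet_id", "cover_x"]
                ).astype({"x": int, "y": int}),
                plot_size=P,
            )
            return empty, pd.Series(dtype=int)
        raise RuntimeError("no founders drawn; re-seed or lower plot margin")
    ramets = []  # (x, y, genet)
    for g in range(1, n_founders + 1):
        x = rng.uniform(-margin, P + margin)
        y = rng.uniform(-margin, P + margin)
        ramets.append((x, y, g))
        # lognormal-Poisson step count: right-skewed genet sizes with
        # singletons modal and a few genets spreading over tens of points
        lam = rng.lognormal(np.log(config.mean_steps), config.step_dispersion)
        n_steps = rng.poisson(lam)
        cx, cy = x, y
        for _ in range(n_steps):
            ang = rng.uniform(0, 2 * np.pi)
            step = rng.exponential(config.step_length)
            cx, cy = cx + step * np.cos(ang), cy + step * np.sin(ang)
            ramets.append((cx, cy, g))

    # nearest ramet within capture_radius of each grid point
    taken: dict[tuple[int, int], tuple[float, int]] = {}
    for x, y, g in ramets:
        gx, gy = round(x), round(y)
        if not (0 <= gx <= P and 0 <= gy <= P):
            continue
        d = float(np.hypot(x - gx, y - gy))
        if d > config.capture_radius:
            continue
        if (gx, gy) not in taken or d < taken[(gx, gy)][0]:
            taken[(gx, gy)] = (d, g)

    rows = []
    labels = []
    for i, ((gx, gy), (_, g)) in enumerate(sorted(taken.items())):
        stage = (
            "flowering" if rng.uniform() < config.flowering_fraction else "vegetative"
        )
        rows.append(
            {
                "sample_id": f"s{i + 1:03d}",
                "x": gx,
                "y": gy,
                "stage": stage,
                "genet_id": pd.NA,
                "cover_x": np.nan,
            }
        )
        labels.append(g)
    df = pd.DataFrame(rows)
    samples = SampleFrame(df, plot_size=P)
    truth = pd.Series(labels, index=df["sample_id"].to_numpy(), name="true_genet")
    return samples, truth


# ---------------------------------------------------------------------------
# SSR genotypes

def simulate_ssr(
    true_genets: pd.Series, config: SimulationConfig, seed=None,
    max_redraws: int = 1000,
) -> SsrTable:
    """One Hardy-Weinberg multilocus genotype per genet, shared by its ramets."""
    rng = config.subseed("ssr") if seed is None else np.random.default_rng(seed)
    loci = [f"SSR{i + 1}" for i in range(config.n_ssr_loci)]
    spectra = {}
    for locus, k in zip(loci, config.n_alleles):
        if k < 1:
            raise ValueError("allele spectrum must have at least one allele")
        sizes = 100 + 2 * np.arange(k) + 10 * loci.index(locus)
        freqs = rng.dirichlet(np.full(k, 2.0))
        spectra[locus] = (sizes, freqs)

    max_distinct = int(np.prod([k * (k + 1) // 2 for k in config.n_alleles]))
    genet_ids = sorted(set(true_genets))
    if max_distinct < len(genet_ids):
        raise RuntimeError(
            "allele spectra too small to give every genet a distinct genotype"
        )

    def draw_genotype():
        gt = {}
        for locus in loci:
            sizes, freqs = spectra[locus]
            a, b = rng.choice(sizes, size=2, p=freqs)
            gt[locus] = (min(a, b), max(a, b))
        return tuple(sorted(gt.items()))

    genotypes: dict[int, tuple] = {}
    seen = set()
    for g in genet_ids:
        for attempt in range(max_redraws):
            gt = draw_genotype()
            if gt not in seen:
                break
        else:
            raise RuntimeError(
                f"could not draw a collision-free genotype after {max_redraws} tries"
            )
        seen.add(gt)
        genotypes[g] = gt

    data = {}
    for locus in loci:
        data[f"{locus}.1"] = [
            float(dict(genotypes[true_genets[s]])[locus][0]) for s in true_genets.index
        ]
        data[f"{locus}.2"] = [
            float(dict(genotypes[true_genets[s]])[locus][1]) for s in true_genets.index
        ]
    df = pd.DataFrame(data, index=pd.Index(true_genets.index, name="sample_id"))
    return SsrTable(df)


# ---------------------------------------------------------------------------
# methylation

def _icar_draw(
    rng: np.random.Generator, adjacency: dict[str, set[str]],
    sample_ids: list[str], sigma: float,
) -> np.ndarray:
    """Centred ICAR sample on the adjacency graph; isolated nodes ~ N(0, sigma).

    Drawn through the eigendecomposition of the graph Laplacian: independent
    N(0, sigma / sqrt(lambda_r)) weights on the non-null eigenvectors of each
    connected component, which realises the pairwise-difference density and
    is already component-centred.
    """
    S = len(sample_ids)
    if sigma == 0:
        return np.zeros(S)
    pos = {s: i for i, s in enumerate(sample_ids)}
    G = nx.Graph()
    G.add_nodes_from(range(S))
    for a, nbrs in adjacency.items():
        for b in nbrs:
            G.add_edge(pos[a], pos[b])
    s = np.zeros(S)
    for comp in nx.connected_components(G):
        comp = sorted(comp)
        if len(comp) == 1:
            s[comp[0]] = rng.normal(0, sigma)
            continue
        Lap = nx.laplacian_matrix(G.subgraph(comp), nodelist=comp).toarray()
        w, V = np.linalg.eigh(Lap)
        keep = w > 1e-10
        z = rng.normal(size=keep.sum())
        s[comp] = V[:, keep] @ (z * sigma / np.sqrt(w[keep]))
    return s


@dataclasses.dataclass
class GroundTruth:
    """Everything needed to score a pipeline run against the generator."""

    genet_labels: pd.Series  # sample_id -> true genet label
    conditions: pd.DataFrame  # samples x loci, condition I-IV before scoring error
    params: dict  # class -> dict of generative effect arrays
    locus_names: list[str]


def simulate_methylation(
    samples: SampleFrame,
    true_genets: pd.Series,
    cover: CoverGrid,
    config: SimulationConfig,
    seed=None,
):
    """True conditions, error-free and error-bearing band matrices, ground truth."""
    rng = config.subseed("methylation") if seed is None else np.random.default_rng(seed)
    sample_ids = samples.sample_ids
    S = len(sample_ids)
    L = config.n_msap_loci
    genet_ids = sorted(set(true_genets))
    gidx = {g: i for i, g in enumerate(genet_ids)}
    kj = np.array([gidx[true_genets[s]] for s in sample_ids])
    x = io_core.cover_covariate(samples, cover).to_numpy() if S else np.zeros(0)
    adjacency = grid_adjacency(samples)

    per_primer = int(np.ceil(L / len(config.primer_pairs))) if L else 1
    locus_names = [
        f"Lo{p + 1}-{100 + 11 * i:03d}"
        for p in range(len(config.primer_pairs))
        for i in range(per_primer)
    ][:L]

    eta = {}
    params = {}
    for klass, cp in config.class_params.items():
        g_i = rng.normal(0, cp.sigma_g, L)
        g_ik = rng.normal(0, cp.sigma_gk, (L, len(genet_ids)))
        e_i = rng.normal(0, cp.sigma_e, L)
        s_j = _icar_draw(rng, adjacency, sample_ids, cp.sigma_s)
        eta[klass] = (
            cp.g0
            + g_i[:, None]
            + g_ik[:, kj]
            + (cp.e0 + e_i[:, None]) * x[None, :]
            + s_j[None, :]
        )
        params[klass] = {
            "g0": cp.g0, "g_i": g_i, "g_ik": g_ik, "e0": cp.e0,
            "e_i": e_i, "s_j": s_j, "genet_ids": genet_ids,
        }

    # four-way categorical: P(class c) = exp(eta_c) / (1 + sum exp(eta)),
    # residual mass -> condition IV
    exp_eta = np.stack([np.exp(eta[k]) for k in ("n", "m", "h")])  # (3, L, S)
    denom = 1.0 + exp_eta.sum(axis=0)
    probs = np.concatenate([exp_eta / denom, (1.0 / denom)[None]], axis=0)
    u = rng.uniform(size=(L, S))
    cum = np.cumsum(probs, axis=0)
    cat = (u[None, :, :] > cum).sum(axis=0)  # 0=n, 1=m, 2=h, 3=IV
    cond = np.array(["I", "II", "III", "IV"], dtype=object)[cat]
    conditions = pd.DataFrame(cond.T, index=sample_ids, columns=locus_names)

    # conditions -> band calls, split across primer pairs
    hpa_true = np.zeros((S, L))
    msp_true = np.zeros((S, L))
    for c, (hb, mb) in msap.BANDS_OF_CONDITION.items():
        sel = conditions.to_numpy() == c
        hpa_true[sel] = hb
        msp_true[sel] = mb
    flip_h = rng.uniform(size=(S, L)) < config.error_rate_hpa
    flip_m = rng.uniform(size=(S, L)) < config.error_rate_msp
    hpa_obs = np.where(flip_h, 1 - hpa_true, hpa_true)
    msp_obs = np.where(flip_m, 1 - msp_true, msp_true)

    def split(matrix):
        out = {}
        per = int(np.ceil(L / len(config.primer_pairs)))
        for p, primer in enumerate(config.primer_pairs):
            cols = locus_names[p * per:(p + 1) * per]
            if not cols:
                continue
            idx = [locus_names.index(c) for c in cols]
            out[primer] = pd.DataFrame(
                matrix[:, idx], index=pd.Index(sample_ids, name="sample_id"),
                columns=cols,
            )
        return out

    bands = {}
    for primer, df_h in split(hpa_obs).items():
        bands[(primer, "HpaII")] = BandMatrix("HpaII", primer, df_h)
    for primer, df_m in split(msp_obs).items():
        bands[(primer, "MspI")] = BandMatrix("MspI", primer, df_m)
    bands_true = {}
    for primer, df_h in split(hpa_true).items():
        bands_true[(primer, "HpaII")] = BandMatrix("HpaII", primer, df_h)
    for primer, df_m in split(msp_true).items():
        bands_true[(primer, "MspI")] = BandMatrix("MspI", primer, df_m)

    truth = GroundTruth(
        genet_labels=true_genets,
        conditions=conditions,
        params=params,
        locus_names=locus_names,
    )
    return conditions, bands, bands_true, truth


def simulate_bernoulli_class(
    samples: SampleFrame,
    true_genets: pd.Series,
    cover: CoverGrid,
    cp: ClassParams,
    n_loci: int,
    seed: int,
):
    """Binary outcomes drawn directly from the fitted model's own generative
    form (marginal Bernoulli with hierarchical effects and an ICAR field),
    for parameter-recovery benchmarks.

    Returns ``(y, params)`` where ``y`` is a samples x loci DataFrame and
    ``params`` holds the drawn effects, including the (loci x genets) matrix
    of genet deviations keyed by sorted genet label order.
    """
    rng = np.random.default_rng(seed)
    sample_ids = samples.sample_ids
    genet_ids = sorted(set(true_genets))
    gidx = {g: i for i, g in enumerate(genet_ids)}
    kj = np.array([gidx[true_genets[s]] for s in sample_ids])
    x = io_core.cover_covariate(samples, cover).to_numpy()
    adjacency = grid_adjacency(samples)
    g_i = rng.normal(0, cp.sigma_g, n_loci)
    g_ik = rng.normal(0, cp.sigma_gk, (n_loci, len(genet_ids)))
    e_i = rng.normal(0, cp.sigma_e, n_loci)
    s_j = _icar_draw(rng, adjacency, sample_ids, cp.sigma_s)
    eta = (
        cp.g0
        + g_i[:, None]
        + g_ik[:, kj]
        + (cp.e0 + e_i[:, None]) * x[None, :]
        + s_j[None, :]
    )
    q = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.uniform(size=eta.shape) < q).astype(float)
    df = pd.DataFrame(
        y.T, index=pd.Index(sample_ids, name="sample_id"),
        columns=[f"L{i + 1:02d}" for i in range(n_loci)],
    )
    params = {
        "g0": cp.g0, "g_i": g_i, "g_ik": g_ik, "e0": cp.e0, "e_i": e_i,
        "s_j": s_j, "genet_ids": genet_ids,
    }
    return df, params


# ---------------------------------------------------------------------------
# full dataset

def simulate_dataset(config: SimulationConfig, out_dir) -> Path:
    """Write a complete, reproducible run directory and return its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cover = simulate_cover(config)
    samples, true_genets = simulate_genets(config)
    ssr = simulate_ssr(true_genets, config)
    conditions, bands, _, truth = simulate_methylation(
        samples, true_genets, cover, config
    )

    files = []

    def emit(obj, name):
        io_core.write_table(obj, out / name)
        files.append(name)

    emit(samples, "samples.tsv")
    emit(cover, "cover.tsv")
    emit(ssr, "ssr.tsv")
    for (primer, enzyme), bm in sorted(bands.items()):
        emit(bm, f"bands_{primer}_{enzyme}.tsv")

    conditions.to_csv(out / "true_conditions.tsv", sep="\t", index_label="sample_id")
    files.append("true_conditions.tsv")
    true_genets.rename("true_genet").to_csv(
        out / "true_genets.tsv", sep="\t", index_label="sample_id"
    )
    files.append("true_genets.tsv")
    truth_params = {
        klass: {
            "g0": p["g0"],
            "e0": p["e0"],
            "g_i": np.asarray(p["g_i"]).tolist(),
            "e_i": np.asarray(p["e_i"]).tolist(),
            "g_ik": np.asarray(p["g_ik"]).tolist(),
            "s_j": np.asarray(p["s_j"]).tolist(),
            "genet_ids": [int(g) for g in p["genet_ids"]],
        }
        for klass, p in truth.params.items()
    }
    (out / "true_params.json").write_text(
        json.dumps(
            {"locus_names": truth.locus_names, "classes": truth_params}, indent=1
        )
    )
    files.append("true_params.json")

    manifest = {
        "seed": config.seed,
        "plot_size": config.plot_size,
        "n_samples": len(samples.df),
        "n_true_genets": int(true_genets.nunique()) if len(true_genets) else 0,
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
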