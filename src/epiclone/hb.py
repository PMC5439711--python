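"""Hierarchical Bayesian Bernoulli model for subepilocus states.

For subepilocus score y_ijk of locus i in sample j belonging to genet k,

    y_ijk ~ Bernoulli(q_ijk),
    logit(q_ijk) = g0 + g_i + g_ik + (e0 + e_i) * x_j + s_j,

with g0 the intercept, g_i a per-locus deviation, g_ik a per-locus-per-genet
deviation, (e0 + e_i) the vegetation-cover slope, and s_j a spatial random
effect on the sampling lattice.  Priors: vague Gaussians (variance 1e3) on
g0 and e0; zero-mean Gaussian hierarchies N(0, sigma^2) on g_i, g_ik, e_i;
an intrinsic CAR prior on {s_j} over the 1-m rook adjacency (each s_j
conditionally Gaussian around the mean of its neighbours, isolated samples
getting a proper N(0, sigma_s) prior); Uniform(0, 100) on every dispersion
parameter.

The sampler is a blocked random-walk Metropolis-within-Gibbs with
per-block adaptive step sizes frozen after burn-in, so the post-burn-in
chain satisfies detailed balance.  Spatial effects are updated by graph
colour classes (no two updated nodes adjacent, so parallel accept/reject
within a class is exact), and the ICAR level constraint is resolved by
subtracting the global mean of {s_j} each sweep and absorbing it into g0 —
an exact reparameterisation that leaves the likelihood unchanged.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io_core import SubepilocusMatrix

VAGUE_SD = np.sqrt(1000.0)  # prior SD of g0 and e0
SIGMA_MAX = 100.0  # upper bound of the uniform dispersion priors


def inv_logit(eta):
    """Numerically stable inverse logit."""
    eta = np.asarray(eta, dtype=float)
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    ex = np.exp(eta[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def _softplus(eta):
    return np.logaddexp(0.0, eta)


# ---------------------------------------------------------------------------
# data container

@dataclasses.dataclass
class ModelData:
    """One subepilocus class's outcomes plus the design information.

    ``y`` is loci x samples with NaN for missing calls; ``genet_idx`` maps
    each sample to a 0-based genet index; ``x`` is the standardized cover
    covariate (None disables the covariate term); ``edges`` are index pairs
    of 1-m-adjacent samples (None disables the spatial term).
    """

    y: np.ndarray  # (L, S) float, NaN = missing
    genet_idx: np.ndarray  # (S,) int
    locus_names: list[str]
    genet_ids: list[int]
    sample_ids: list[str]
    x: np.ndarray | None = None  # (S,) float
    edges: np.ndarray | None = None  # (E, 2) int

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.genet_idx = np.asarray(self.genet_idx, dtype=int)
        L, S = self.y.shape
        if len(self.genet_idx) != S:
            raise ValueError("genet index length does not match sample count")
        if self.x is not None:
            self.x = np.asarray(self.x, dtype=float)
            if len(self.x) != S:
                raise ValueError("covariate length does not match sample count")
        if self.edges is not None:
            self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.mask = ~np.isnan(self.y)  # valid cells
        self.y0 = np.nan_to_num(self.y)  # y with 0 at missing cells
        flat = (self.y[self.mask] if self.mask.any() else np.array([]))
        # loci with zero observed variance are retained; the prior regularizes
        self.constant_loci = [
            self.locus_names[i]
            for i in range(L)
            if self.mask[i].any() and np.nanstd(self.y[i]) == 0
        ]

    @property
    def n_loci(self) -> int:
        return self.y.shape[0]

    @property
    def n_samples(self) -> int:
        return self.y.shape[1]

    @property
    def n_genets(self) -> int:
        return len(self.genet_ids)

    @property
    def has_covariate(self) -> bool:
        return self.x is not None

    @property
    def has_spatial(self) -> bool:
        return self.edges is not None


def build_model_data(
    subepiloci: SubepilocusMatrix,
    membership: pd.Series,
    x: pd.Series | None = None,
    adjacency: Mapping[str, set[str]] | None = None,
) -> ModelData:
    """Assemble ModelData from pipeline objects, aligning on sample ids.

    Only samples present in both the score matrix and the genet membership
    are used.  Every retained sample must have a genet.
    """
    sample_ids = [s for s in subepiloci.df.index if s in membership.index]
    y = subepiloci.df.loc[sample_ids].to_numpy(dtype=float).T  # (L, S)
    genet_ids = sorted(set(int(membership.loc[s]) for s in sample_ids))
    gpos = {g: i for i, g in enumerate(genet_ids)}
    genet_idx = np.array([gpos[int(membership.loc[s])] for s in sample_ids])
    xv = None
    if x is not None:
        xv = x.loc[sample_ids].to_numpy(dtype=float)
    edges = None
    if adjacency is not None:
        pos = {s: i for i, s in enumerate(sample_ids)}
        eset = set()
        for a, nbrs in adjacency.items():
            for b in nbrs:
                if a in pos and b in pos:
                    eset.add((min(pos[a], pos[b]), max(pos[a], pos[b])))
        edges = np.array(sorted(eset), dtype=int).reshape(-1, 2)
    return ModelData(
        y=y,
        genet_idx=genet_idx,
        locus_names=list(subepiloci.df.columns),
        genet_ids=genet_ids,
        sample_ids=sample_ids,
        x=xv,
        edges=edges,
    )


# ---------------------------------------------------------------------------
# parameters and log joint

@dataclasses.dataclass
class ModelParams:
    g0: float
    e0: float
    g: np.ndarray  # (L,)
    e: np.ndarray  # (L,)
    gik: np.ndarray  # (L, G)
    s: np.ndarray  # (S,)
    sig_g: float
    sig_gk: float
    sig_e: float
    sig_s: float

    def copy(self) -> "ModelParams":
        return ModelParams(
            self.g0, self.e0, self.g.copy(), self.e.copy(), self.gik.copy(),
            self.s.copy(), self.sig_g, self.sig_gk, self.sig_e, self.sig_s,
        )


def linear_predictor(params: ModelParams, data: ModelData) -> np.ndarray:
    """The (L, S) logit-scale matrix g0 + g_i + g_ik + (e0 + e_i) x_j + s_j."""
    eta = params.g0 + params.g[:, None] + params.gik[:, data.genet_idx]
    if data.has_covariate:
        eta = eta + (params.e0 + params.e[:, None]) * data.x[None, :]
    if data.has_spatial:
        eta = eta + params.s[None, :]
    return eta


def _car_structure(data: ModelData):
    """Isolated-node mask, ICAR rank, and colour classes of the adjacency."""
    S = data.n_samples
    G = nx.Graph()
    G.add_nodes_from(range(S))
    if data.edges is not None and len(data.edges):
        G.add_edges_from(map(tuple, data.edges))
    isolated = np.array([G.degree[j] == 0 for j in range(S)])
    comps = [c for c in nx.connected_components(G) if len(c) > 1]
    rank = sum(len(c) - 1 for c in comps)
    coloring = nx.greedy_color(G, strategy="largest_first")
    n_colors = 1 + max(coloring.values(), default=0)
    classes = [
        np.array([j for j in range(S) if coloring[j] == c and not isolated[j]])
        for c in range(n_colors)
    ]
    classes = [c for c in classes if len(c)]
    if isolated.any():
        classes.append(np.nonzero(isolated)[0])
    # neighbour lists in CSR-ish form for vectorised conditional updates
    nbr_idx = [np.array(sorted(G.neighbors(j)), dtype=int) for j in range(S)]
    return isolated, rank, classes, nbr_idx


def log_car_prior(
    s: np.ndarray, edges: np.ndarray | None, isolated: np.ndarray,
    rank: int, sigma: float,
) -> float:
    """Improper ICAR log density (pairwise-difference form) + proper isolated terms.

    log p = -(rank + n_iso) log sigma - [sum_edges (s_a - s_b)^2
            + sum_iso s_j^2] / (2 sigma^2) + const.
    """
    q = 0.0
    if edges is not None and len(edges):
        d = s[edges[:, 0]] - s[edges[:, 1]]
        q += float(d @ d)
    q += float(s[isolated] @ s[isolated])
    n_iso = int(isolated.sum())
    return -(rank + n_iso) * np.log(sigma) - q / (2.0 * sigma**2)


def log_joint(params: ModelParams, data: ModelData) -> float:
    """Unnormalised log posterior density; -inf outside prior support."""
    for sig in (params.sig_g, params.sig_gk, params.sig_e, params.sig_s):
        if not (0.0 < sig < SIGMA_MAX):
            return -np.inf
    eta = linear_predictor(params, data)
    ll = float(
        np.sum(data.mask * (data.y0 * eta - _softplus(eta)))
    )
    lp = -(params.g0**2) / (2 * VAGUE_SD**2)
    lp += -np.log(params.sig_g) * data.n_loci - float(
        params.g @ params.g
    ) / (2 * params.sig_g**2)
    lp += -np.log(params.sig_gk) * params.gik.size - float(
        np.sum(params.gik**2)
    ) / (2 * params.sig_gk**2)
    if data.has_covariate:
        lp += -(params.e0**2) / (2 * VAGUE_SD**2)
        lp += -np.log(params.sig_e) * data.n_loci - float(
            params.e @ params.e
        ) / (2 * params.sig_e**2)
    if data.has_spatial:
        isolated, rank, _, _ = _car_structure(data)
        lp += log_car_prior(params.s, data.edges, isolated, rank, params.sig_s)
    return ll + lp


# ---------------------------------------------------------------------------
# sampler

@dataclasses.dataclass
class McmcSettings:
    chains: int = 3
    burn_in: int = 1000
    thin: int = 50
    keep: int = 1000


@dataclasses.dataclass
class PosteriorDraws:
    """Retained MCMC draws, chains x draws (x parameter dimensions)."""

    params: dict[str, np.ndarray]
    locus_names: list[str]
    genet_ids: list[int]
    sample_ids: list[str]
    settings: McmcSettings
    seed: int

    @property
    def n_chains(self) -> int:
        return self.params["g0"].shape[0]

    def pooled(self, name: str) -> np.ndarray:
        """All chains concatenated along the draw axis."""
        a = self.params[name]
        return a.reshape(-1, *a.shape[2:])


class _AdaptiveScale:
    """Multiplicative step-size adaptation toward a target acceptance rate."""

    def __init__(self, shape, target=0.44, rate=0.05, init=0.5):
        self.step = np.full(shape, init, dtype=float)
        self.target = target
        self.rate = rate
        self.frozen = False

    def adapt(self, accepted):
        if self.frozen:
            return
        self.step *= np.exp(self.rate * (np.asarray(accepted, dtype=float) - self.target))
        np.clip(self.step, 1e-4, 50.0, out=self.step)


def _delta_ll_rows(data, eta, d_eta):
    """Per-locus log-likelihood change for a row-wise shift d_eta (L, S)."""
    new = eta + d_eta
    return np.sum(
        data.mask * (data.y0 * d_eta - (_softplus(new) - _softplus(eta))), axis=1
    )


def _run_chain(data: ModelData, settings: McmcSettings, rng: np.random.Generator):
    L, S, G = data.n_loci, data.n_samples, data.n_genets
    # genet group bookkeeping for vectorised g_ik updates
    order = np.argsort(data.genet_idx, kind="stable")
    bounds = np.searchsorted(data.genet_idx[order], np.arange(G + 1))
    groups_present = np.diff(bounds) > 0

    if data.has_spatial:
        isolated, rank, color_classes, nbr_idx = _car_structure(data)
        deg = np.array([len(nb) for nb in nbr_idx])
        # padded neighbour table for vectorised conditional sums; index S is a
        # dummy slot whose value is pinned at 0
        max_deg = int(deg.max()) if S else 0
        nbr_pad = np.full((S, max(max_deg, 1)), S, dtype=int)
        for j, nb in enumerate(nbr_idx):
            nbr_pad[j, : len(nb)] = nb
    else:
        isolated = rank = color_classes = deg = nbr_pad = None

    p = ModelParams(
        g0=float(rng.normal(0, 0.5)),
        e0=float(rng.normal(0, 0.5)) if data.has_covariate else 0.0,
        g=rng.normal(0, 0.5, L),
        e=rng.normal(0, 0.5, L) if data.has_covariate else np.zeros(L),
        gik=rng.normal(0, 0.5, (L, G)),
        s=rng.normal(0, 0.1, S) if data.has_spatial else np.zeros(S),
        sig_g=1.0, sig_gk=1.0, sig_e=1.0, sig_s=1.0,
    )
    if data.has_spatial:
        p.s -= p.s.mean()
    eta = linear_predictor(p, data)
    if not np.isfinite(log_joint(p, data)):
        raise RuntimeError(f"non-finite log joint at initialisation: {p}")

    sc_g0 = _AdaptiveScale(())
    sc_e0 = _AdaptiveScale(())
    sc_g = _AdaptiveScale(L)
    sc_e = _AdaptiveScale(L)
    sc_gik = _AdaptiveScale((L, G))
    sc_s = _AdaptiveScale(S, init=0.3)
    sc_sig = {k: _AdaptiveScale((), init=0.3) for k in ("g", "gk", "e", "s")}
    sc_swap0 = _AdaptiveScale(())
    sc_swap_g = _AdaptiveScale(L)
    sc_swap_e = _AdaptiveScale(())
    scales = [sc_g0, sc_e0, sc_g, sc_e, sc_gik, sc_s, sc_swap0, sc_swap_g,
              sc_swap_e, *sc_sig.values()]

    n_iter = settings.burn_in + settings.thin * settings.keep
    out = {
        "g0": np.empty(settings.keep),
        "e0": np.empty(settings.keep),
        "g": np.empty((settings.keep, L)),
        "e": np.empty((settings.keep, L)),
        "gik": np.empty((settings.keep, L, G)),
        "s": np.empty((settings.keep, S)),
        "sig_g": np.empty(settings.keep),
        "sig_gk": np.empty(settings.keep),
        "sig_e": np.empty(settings.keep),
        "sig_s": np.empty(settings.keep),
    }
    kept = 0

    def sig_update(name, value, count, ssq, scale):
        prop = value * np.exp(scale.step * rng.normal())
        if not (0.0 < prop < SIGMA_MAX):
            scale.adapt(0.0)
            return value
        # conditional density sigma^-count exp(-ssq / (2 sigma^2)); log-scale
        # proposal contributes the Jacobian log(prop/value)
        logr = (
            -count * (np.log(prop) - np.log(value))
            - ssq / 2.0 * (1.0 / prop**2 - 1.0 / value**2)
            + (np.log(prop) - np.log(value))
        )
        acc = np.log(rng.uniform()) < logr
        scale.adapt(acc)
        return prop if acc else value

    for it in range(n_iter):
        if it == settings.burn_in:
            for sc in scales:
                sc.frozen = True

        # g0 (scalar)
        d = sc_g0.step * rng.normal()
        dll = float(np.sum(_delta_ll_rows(data, eta, np.full((1, 1), d))))
        # full-matrix shift: compute directly for efficiency
        dlp = -((p.g0 + d) ** 2 - p.g0**2) / (2 * VAGUE_SD**2)
        acc = np.log(rng.uniform()) < dll + dlp
        sc_g0.adapt(acc)
        if acc:
            p.g0 += d
            eta += d

        # g_i (row block, independent rows)
        d = sc_g.step * rng.normal(size=L)
        dll = _delta_ll_rows(data, eta, d[:, None])
        dlp = -((p.g + d) ** 2 - p.g**2) / (2 * p.sig_g**2)
        acc = np.log(rng.uniform(size=L)) < dll + dlp
        sc_g.adapt(acc)
        if acc.any():
            p.g[acc] += d[acc]
            eta[acc] += d[acc, None]

        if data.has_covariate:
            # e0 (scalar)
            d = sc_e0.step * rng.normal()
            d_eta = d * data.x[None, :]
            dll = float(np.sum(_delta_ll_rows(data, eta, d_eta)))
            dlp = -((p.e0 + d) ** 2 - p.e0**2) / (2 * VAGUE_SD**2)
            acc = np.log(rng.uniform()) < dll + dlp
            sc_e0.adapt(acc)
            if acc:
                p.e0 += d
                eta += d_eta

            # e_i (row block)
            d = sc_e.step * rng.normal(size=L)
            d_eta = d[:, None] * data.x[None, :]
            dll = _delta_ll_rows(data, eta, d_eta)
            dlp = -((p.e + d) ** 2 - p.e**2) / (2 * p.sig_e**2)
            acc = np.log(rng.uniform(size=L)) < dll + dlp
            sc_e.adapt(acc)
            if acc.any():
                p.e[acc] += d[acc]
                eta[acc] += d_eta[acc]

        # g_ik (cell blocks; disjoint likelihood support per (i, k))
        d = sc_gik.step * rng.normal(size=(L, G))
        d_eta = d[:, data.genet_idx]
        new = eta + d_eta
        cell = data.mask * (data.y0 * d_eta - (_softplus(new) - _softplus(eta)))
        # sum cells per genet group (columns pre-sorted by genet)
        dll = np.add.reduceat(cell[:, order], bounds[:-1], axis=1)
        dll[:, ~groups_present] = 0.0
        dlp = -((p.gik + d) ** 2 - p.gik**2) / (2 * p.sig_gk**2)
        acc = np.log(rng.uniform(size=(L, G))) < dll + dlp
        sc_gik.adapt(acc)
        if acc.any():
            da = np.where(acc, d, 0.0)
            p.gik += da
            eta += da[:, data.genet_idx]

        # ridge-swap moves: shift mass along likelihood-invariant directions
        # (the predictor only identifies sums such as g0 + g_i + g_ik), so the
        # acceptance ratio involves priors only.  These decorrelate the
        # hierarchy levels without touching eta.
        d = sc_swap0.step * rng.normal()
        dlp = (
            -((p.g0 + d) ** 2 - p.g0**2) / (2 * VAGUE_SD**2)
            - (np.sum((p.g - d) ** 2) - np.sum(p.g**2)) / (2 * p.sig_g**2)
        )
        acc = np.log(rng.uniform()) < dlp
        sc_swap0.adapt(acc)
        if acc:
            p.g0 += d
            p.g -= d

        d = sc_swap_g.step * rng.normal(size=L)
        dlp = (
            -((p.g + d) ** 2 - p.g**2) / (2 * p.sig_g**2)
            - (
                np.sum((p.gik - d[:, None]) ** 2, axis=1) - np.sum(p.gik**2, axis=1)
            ) / (2 * p.sig_gk**2)
        )
        acc = np.log(rng.uniform(size=L)) < dlp
        sc_swap_g.adapt(acc)
        if acc.any():
            p.g[acc] += d[acc]
            p.gik[acc] -= d[acc, None]

        if data.has_covariate:
            d = sc_swap_e.step * rng.normal()
            dlp = (
                -((p.e0 + d) ** 2 - p.e0**2) / (2 * VAGUE_SD**2)
                - (np.sum((p.e - d) ** 2) - np.sum(p.e**2)) / (2 * p.sig_e**2)
            )
            acc = np.log(rng.uniform()) < dlp
            sc_swap_e.adapt(acc)
            if acc:
                p.e0 += d
                p.e -= d

        if data.has_spatial:
            # s_j by colour class (no two updated nodes adjacent)
            for cls in color_classes:
                d = sc_s.step[cls] * rng.normal(size=len(cls))
                new_cols = eta[:, cls] + d[None, :]
                dll = np.sum(
                    data.mask[:, cls]
                    * (
                        data.y0[:, cls] * d[None, :]
                        - (_softplus(new_cols) - _softplus(eta[:, cls]))
                    ),
                    axis=0,
                )
                s_old = p.s[cls]
                s_new = s_old + d
                s_ext = np.append(p.s, 0.0)
                nb_sum = s_ext[nbr_pad[cls]].sum(axis=1)
                k = deg[cls]
                # joint-exponent change with neighbours fixed:
                # sum_j' (s_j - s_j')^2 = k s_j^2 - 2 s_j nb_sum + const
                dq = k * (s_new**2 - s_old**2) - 2 * (s_new - s_old) * nb_sum
                dq = dq + np.where(isolated[cls], s_new**2 - s_old**2, 0.0)
                dlp = -dq / (2 * p.sig_s**2)
                acc = np.log(rng.uniform(size=len(cls))) < dll + dlp
                step_view = sc_s.step[cls]
                if not sc_s.frozen:
                    step_view *= np.exp(sc_s.rate * (acc.astype(float) - sc_s.target))
                    sc_s.step[cls] = np.clip(step_view, 1e-4, 50.0)
                if acc.any():
                    upd = cls[acc]
                    p.s[upd] += d[acc]
                    eta[:, upd] += d[acc][None, :]

            # global recentering absorbed into the intercept (exact)
            m = p.s.mean()
            p.s -= m
            p.g0 += m

            q_edges = 0.0
            if data.edges is not None and len(data.edges):
                de = p.s[data.edges[:, 0]] - p.s[data.edges[:, 1]]
                q_edges = float(de @ de)
            q_iso = float(p.s[isolated] @ p.s[isolated])
            p.sig_s = sig_update(
                "s", p.sig_s, rank + int(isolated.sum()), q_edges + q_iso,
                sc_sig["s"],
            )

        p.sig_g = sig_update("g", p.sig_g, L, float(p.g @ p.g), sc_sig["g"])
        p.sig_gk = sig_update(
            "gk", p.sig_gk, p.gik.size, float(np.sum(p.gik**2)), sc_sig["gk"]
        )
        if data.has_covariate:
            p.sig_e = sig_update("e", p.sig_e, L, float(p.e @ p.e), sc_sig["e"])

        post = it - settings.burn_in
        if post >= 0 and (post + 1) % settings.thin == 0:
            out["g0"][kept] = p.g0
            out["e0"][kept] = p.e0
            out["g"][kept] = p.g
            out["e"][kept] = p.e
            out["gik"][kept] = p.gik
            out["s"][kept] = p.s
            out["sig_g"][kept] = p.sig_g
            out["sig_gk"][kept] = p.sig_gk
            out["sig_e"][kept] = p.sig_e
            out["sig_s"][kept] = p.sig_s
            kept += 1
            if kept == settings.keep:
                break
    return out


def run_mcmc(
    data: ModelData, settings: McmcSettings | None = None, seed: int = 0
) -> PosteriorDraws:
    """Sample the posterior with independent chains; reproducible given seed."""
    settings = settings or McmcSettings()
    ss = np.random.SeedSequence(seed)
    chains = []
    for child in ss.spawn(settings.chains):
        rng = np.random.default_rng(child)
        chains.append(_run_chain(data, settings, rng))
    params = {
        k: np.stack([c[k] for c in chains]) for k in chains[0]
    }
    return PosteriorDraws(
        params=params,
        locus_names=data.locus_names,
        genet_ids=data.genet_ids,
        sample_ids=data.sample_ids,
        settings=settings,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# convergence

def gelman_rubin(chains: np.ndarray) -> float:
    """Classic potential scale reduction factor for one scalar parameter.

    ``chains`` is (n_chains, n_draws).  Compares within-chain and
    among-chain variance; values near 1 indicate convergence.
    """
    chains = np.asarray(chains, dtype=float)
    m, n = chains.shape
    if m < 2:
        raise ValueError("need at least two chains")
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0 if B == 0 else np.inf
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


def convergence(
    draws: PosteriorDraws, n_gik_monitor: int = 50, threshold: float = 1.1,
    seed: int = 0,
) -> pd.DataFrame:
    """PSRF per monitored parameter; a run fails if any exceeds ``threshold``.

    Monitored: g0, e0, all dispersions, every g_i, and a seeded random
    subsample of up to ``n_gik_monitor`` genet-by-locus deviations.
    """
    rows = []
    for name in ("g0", "e0", "sig_g", "sig_gk", "sig_e", "sig_s"):
        rows.append((name, gelman_rubin(draws.params[name])))
    g = draws.params["g"]
    for i, locus in enumerate(draws.locus_names):
        rows.append((f"g[{locus}]", gelman_rubin(g[:, :, i])))
    gik = draws.params["gik"]
    L, G = gik.shape[2], gik.shape[3]
    rng = np.random.default_rng(seed)
    cells = [(i, k) for i in range(L) for k in range(G)]
    if len(cells) > n_gik_monitor:
        pick = rng.choice(len(cells), size=n_gik_monitor, replace=False)
        cells = [cells[int(c)] for c in pick]
    for i, k in cells:
        rows.append(
            (
                f"gik[{draws.locus_names[i]},{draws.genet_ids[k]}]",
                gelman_rubin(gik[:, :, i, k]),
            )
        )
    df = pd.DataFrame(rows, columns=["parameter", "psrf"])
    df["converged"] = df["psrf"] <= threshold
    return df


# ---------------------------------------------------------------------------
# probability summaries and deviation calling

@dataclasses.dataclass
class ProbSummary:
    median: float
    lo: float
    hi: float

    def as_tuple(self):
        return (self.median, self.lo, self.hi)


def _summary(draws_1d: np.ndarray) -> ProbSummary:
    med, lo, hi = np.percentile(draws_1d, [50, 2.5, 97.5])
    return ProbSummary(float(med), float(lo), float(hi))


def global_probability(draws: PosteriorDraws, locus: str) -> ProbSummary:
    """Posterior of inverse-logit(g0 + g_i) at covariate mean, zero spatial effect."""
    i = draws.locus_names.index(locus)
    eta = draws.pooled("g0") + draws.pooled("g")[:, i]
    return _summary(inv_logit(eta))


def genet_probability(draws: PosteriorDraws, locus: str, genet_id: int) -> ProbSummary:
    """Posterior of inverse-logit(g0 + g_i + g_ik), same evaluation point."""
    i = draws.locus_names.index(locus)
    if genet_id not in draws.genet_ids:
        raise KeyError(f"unknown genet {genet_id}")
    k = draws.genet_ids.index(genet_id)
    eta = draws.pooled("g0") + draws.pooled("g")[:, i] + draws.pooled("gik")[:, i, k]
    return _summary(inv_logit(eta))


def classify_deviation(genet: ProbSummary, glob: ProbSummary) -> int:
    """+1 / -1 when the genet's 95% BCI excludes the global median; else 0."""
    if genet.lo > glob.median:
        return 1
    if genet.hi < glob.median:
        return -1
    return 0


def probability_summary(
    draws: PosteriorDraws,
    data: ModelData,
    min_ramets: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-locus global summaries and per-(locus, genet) summaries with flags.

    Singleton genets (fewer than ``min_ramets`` ramets in the fitted data)
    are estimated by the model but suppressed from the genet-level report.
    The per-locus table also carries the raw empirical score rate for
    comparison with the model-derived probability.
    """
    counts = np.bincount(data.genet_idx, minlength=data.n_genets)
    glob_rows, genet_rows = [], []
    for i, locus in enumerate(draws.locus_names):
        gl = global_probability(draws, locus)
        valid = data.mask[i]
        emp = float(data.y0[i, valid].mean()) if valid.any() else np.nan
        glob_rows.append(
            {
                "locus": locus,
                "median": gl.median,
                "lo": gl.lo,
                "hi": gl.hi,
                "empirical_rate": emp,
            }
        )
        for k, gid in enumerate(draws.genet_ids):
            if counts[k] < min_ramets:
                continue
            gp = genet_probability(draws, locus, gid)
            genet_rows.append(
                {
                    "locus": locus,
                    "genet_id": gid,
                    "ramet_count": int(counts[k]),
                    "median": gp.median,
                    "lo": gp.lo,
                    "hi": gp.hi,
                    "flag": classify_deviation(gp, gl),
                }
            )
    return pd.DataFrame(glob_rows), pd.DataFrame(genet_rows)


def deviation_table(genet_summaries: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Counts of low/high deviating genets per locus for each subepilocus class.

    ``genet_summaries`` maps class label (n, m, h) to the per-genet summary
    frame from :func:`probability_summary`.
    """
    loci: list[str] = []
    for df in genet_summaries.values():
        for locus in df["locus"]:
            if locus not in loci:
                loci.append(locus)
    out = pd.DataFrame(index=pd.Index(loci, name="locus"))
    for klass, df in genet_summaries.items():
        low = df[df["flag"] == -1].groupby("locus").size()
        high = df[df["flag"] == 1].groupby("locus").size()
        out[f"{klass}_low"] = [int(low.get(l, 0)) for l in loci]
        out[f"{klass}_high"] = [int(high.get(l, 0)) for l in loci]
    return out
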