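"""Pipeline orchestration, caching, and figure/table rendering.

A run directory holds every stage's inputs and outputs plus a manifest
(``run_manifest.json``) recording, per stage, the SHA-256 hashes of the
inputs it consumed and the outputs it produced.  A stage is skipped on
re-run when its recorded input hashes still match, so reports are pure
functions of run-directory contents.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import genets as genets_mod
from . import hb, io_core, msap, spatial

log = logging.getLogger("epiclone")


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def plot_size_of(run_dir: Path) -> int:
    """Plot size recorded in the dataset manifest, or inferred from the cover
    grid's extent (its ring reaches one quadrat beyond the plot)."""
    run_dir = Path(run_dir)
    mf = run_dir / "manifest.json"
    if mf.exists():
        data = json.loads(mf.read_text())
        if "plot_size" in data:
            return int(data["plot_size"])
    cov = pd.read_csv(run_dir / "cover.tsv", sep="\t")
    return int(cov["qx"].max())


class RunManifest:
    def __init__(self, run_dir: Path):
        self.path = Path(run_dir) / "run_manifest.json"
        self.data = (
            json.loads(self.path.read_text()) if self.path.exists() else {"stages": {}}
        )

    def stage_fresh(self, name: str, inputs: list[Path], outputs: list[Path]) -> bool:
        rec = self.data["stages"].get(name)
        if rec is None:
            return False
        if not all(Path(o).exists() for o in rec["outputs"]):
            return False
        current = {str(p): _sha(Path(p)) for p in inputs if Path(p).exists()}
        if current != rec["input_hashes"]:
            return False
        out_hashes = {str(p): _sha(Path(p)) for p in rec["outputs"]}
        return out_hashes == rec["output_hashes"]

    def record(self, name: str, inputs: list[Path], outputs: list[Path]) -> None:
        self.data["stages"][name] = {
            "input_hashes": {str(p): _sha(Path(p)) for p in inputs},
            "outputs": [str(p) for p in outputs],
            "output_hashes": {str(p): _sha(Path(p)) for p in outputs},
        }
        self.path.write_text(json.dumps(self.data, indent=1))


# ---------------------------------------------------------------------------
# stages

def score_stage(run_dir: Path) -> None:
    """Band matrices -> conditions, polymorphic loci, subepilocus matrices."""
    run_dir = Path(run_dir)
    band_files = sorted(run_dir.glob("bands_*_HpaII.tsv"))
    cond_parts = []
    for hf in band_files:
        primer = hf.name.split("_")[1]
        hpa = io_core.read_bands(hf)
        msp = io_core.read_bands(run_dir / f"bands_{primer}_MspI.tsv")
        cond_parts.append(msap.condition_matrix(hpa, msp))
    conditions = pd.concat(cond_parts, axis=1)
    retained = msap.find_polymorphic(conditions)
    log.info("retained %d of %d fragments as polymorphic", len(retained),
             conditions.shape[1])
    out = conditions.map(lambda c: "NA" if c is None else c)
    out.to_csv(run_dir / "conditions.tsv", sep="\t", index_label="sample_id")
    mats = msap.subepilocus_matrices(conditions, retained)
    for klass, mat in mats.items():
        io_core.write_table(mat, run_dir / f"subepiloci_{klass}.tsv")
    pd.Series(retained, name="locus").to_csv(
        run_dir / "polymorphic_loci.tsv", sep="\t", index=False
    )


def genets_stage(run_dir: Path) -> None:
    """SSR table -> genet assignment + P_gen report."""
    run_dir = Path(run_dir)
    ssr = io_core.read_ssr(run_dir / "ssr.tsv")
    complete = ssr.complete_cases()
    dropped = len(ssr.df) - len(complete.df)
    if dropped:
        log.info("excluded %d samples with missing SSR genotypes", dropped)
    assignment = genets_mod.assign_genets(complete)
    out = assignment.membership.rename("genet_id").to_frame()
    out["ramet_count"] = assignment.genets.loc[out["genet_id"], "ramet_count"].to_numpy()
    out.to_csv(run_dir / "genets.tsv", sep="\t", index_label="sample_id")
    genets_mod.p_gen_report(complete).to_csv(
        run_dir / "pgen.tsv", sep="\t", index=False
    )


def correlogram_stage(
    run_dir: Path, markers: str, n_perm: int = 999, n_boot: int = 999,
    seed: int = 0, class_width: float = 1.0, max_dist: float | None = None,
) -> None:
    run_dir = Path(run_dir)
    samples = io_core.read_samples(run_dir / "samples.tsv",
                                   plot_size=plot_size_of(run_dir))
    if max_dist is None:
        max_dist = float(samples.plot_size)
    if markers == "ssr":
        ssr = io_core.read_ssr(run_dir / "ssr.tsv").complete_cases()
        X = spatial.ssr_allele_counts(ssr)
    elif markers == "subepiloci":
        mats = {
            k: io_core.read_subepiloci(run_dir / f"subepiloci_{k}.tsv")
            for k in ("n", "m", "h")
        }
        X = spatial.epigenotype_matrix(mats).dropna(axis=0)
    else:
        raise ValueError(f"unknown marker set {markers!r}")
    keep = [s for s in samples.sample_ids if s in X.index]
    coords = samples.df.set_index("sample_id").loc[keep, ["x", "y"]].to_numpy()
    corr = spatial.correlogram(
        X.loc[keep], coords, class_width=class_width, max_dist=max_dist,
        n_perm=n_perm, n_boot=n_boot, seed=seed,
    )
    corr.table.to_csv(run_dir / f"correlogram_{markers}.tsv", sep="\t", index=False)


def fit_stage(
    run_dir: Path, klass: str, settings: hb.McmcSettings | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit one subepilocus class; writes summaries, draws and convergence."""
    run_dir = Path(run_dir)
    samples = io_core.read_samples(run_dir / "samples.tsv",
                                   plot_size=plot_size_of(run_dir))
    cover = io_core.read_cover(run_dir / "cover.tsv", plot_size=samples.plot_size)
    sub = io_core.read_subepiloci(run_dir / f"subepiloci_{klass}.tsv")
    membership = pd.read_csv(
        run_dir / "genets.tsv", sep="\t", index_col="sample_id"
    )["genet_id"]
    membership.index = membership.index.astype(str)
    x = io_core.cover_covariate(samples, cover)
    adjacency = io_core.grid_adjacency(samples)
    data = hb.build_model_data(sub, membership, x=x, adjacency=adjacency)
    draws = hb.run_mcmc(data, settings, seed=seed)
    conv = hb.convergence(draws)
    fit_dir = run_dir / f"fit_{klass}"
    fit_dir.mkdir(exist_ok=True)
    conv.to_csv(fit_dir / "convergence.tsv", sep="\t", index=False)
    if not conv["converged"].all():
        worst = conv.loc[conv["psrf"].idxmax()]
        log.warning(
            "fit_%s not converged: %s psrf=%.3f", klass, worst["parameter"],
            worst["psrf"],
        )
    glob, genet = hb.probability_summary(draws, data)
    glob.to_csv(fit_dir / "posterior_summary.tsv", sep="\t", index=False)
    genet.to_csv(fit_dir / "genet_summary.tsv", sep="\t", index=False)
    # columnar per-chain scalar draws
    scalars = {
        k: draws.params[k] for k in ("g0", "e0", "sig_g", "sig_gk", "sig_e", "sig_s")
    }
    rows = []
    for chain in range(draws.n_chains):
        df = pd.DataFrame({k: v[chain] for k, v in scalars.items()})
        df.insert(0, "chain", chain)
        rows.append(df)
    pd.concat(rows).to_csv(fit_dir / "draws_scalars.tsv", sep="\t", index=False)
    return genet


def deviation_stage(run_dir: Path) -> pd.DataFrame:
    run_dir = Path(run_dir)
    summaries = {}
    for klass in ("n", "m", "h"):
        f = run_dir / f"fit_{klass}" / "genet_summary.tsv"
        summaries[klass] = pd.read_csv(f, sep="\t")
    table = hb.deviation_table(summaries)
    table.to_csv(run_dir / "deviations.tsv", sep="\t")
    return table


# ---------------------------------------------------------------------------
# full pipeline

def run_pipeline(
    run_dir, seed: int = 0, n_perm: int = 999, n_boot: int = 999,
    settings: hb.McmcSettings | None = None,
) -> Path:
    """Execute score -> genets -> correlograms -> fits -> deviations with caching."""
    run_dir = Path(run_dir)
    manifest = RunManifest(run_dir)
    band_inputs = sorted(run_dir.glob("bands_*.tsv"))

    stages = [
        (
            "score",
            band_inputs,
            [run_dir / "conditions.tsv", run_dir / "polymorphic_loci.tsv"]
            + [run_dir / f"subepiloci_{k}.tsv" for k in ("n", "m", "h")],
            lambda: score_stage(run_dir),
        ),
        (
            "genets",
            [run_dir / "ssr.tsv"],
            [run_dir / "genets.tsv", run_dir / "pgen.tsv"],
            lambda: genets_stage(run_dir),
        ),
        (
            "correlogram_ssr",
            [run_dir / "ssr.tsv", run_dir / "samples.tsv"],
            [run_dir / "correlogram_ssr.tsv"],
            lambda: correlogram_stage(
                run_dir, "ssr", n_perm=n_perm, n_boot=n_boot, seed=seed
            ),
        ),
        (
            "correlogram_subepiloci",
            [run_dir / f"subepiloci_{k}.tsv" for k in ("n", "m", "h")]
            + [run_dir / "samples.tsv"],
            [run_dir / "correlogram_subepiloci.tsv"],
            lambda: correlogram_stage(
                run_dir, "subepiloci", n_perm=n_perm, n_boot=n_boot, seed=seed
            ),
        ),
    ]
    for klass in ("n", "m", "h"):
        stages.append(
            (
                f"fit_{klass}",
                [
                    run_dir / f"subepiloci_{klass}.tsv",
                    run_dir / "genets.tsv",
                    run_dir / "samples.tsv",
                    run_dir / "cover.tsv",
                ],
                [
                    run_dir / f"fit_{klass}" / "posterior_summary.tsv",
                    run_dir / f"fit_{klass}" / "genet_summary.tsv",
                    run_dir / f"fit_{klass}" / "convergence.tsv",
                ],
                lambda klass=klass: fit_stage(
                    run_dir, klass, settings=settings, seed=seed
                ),
            )
        )
    stages.append(
        (
            "deviations",
            [run_dir / f"fit_{k}" / "genet_summary.tsv" for k in ("n", "m", "h")],
            [run_dir / "deviations.tsv"],
            lambda: deviation_stage(run_dir),
        )
    )

    for name, inputs, outputs, fn in stages:
        if manifest.stage_fresh(name, inputs, outputs):
            log.info("stage %s: cache hit, skipping", name)
            continue
        log.info("stage %s: running", name)
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - annotate failing stage
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest.record(name, inputs, outputs)
    return run_dir


# ---------------------------------------------------------------------------
# figures

def render_reports(run_dir) -> list[Path]:
    """Deviation diagrams, flagged-genet maps and correlogram plots."""
    run_dir = Path(run_dir)
    fig_dir = run_dir / "figures"
    fig_dir.mkdir(exist_ok=True)
    written = []

    samples = io_core.read_samples(run_dir / "samples.tsv")
    membership = pd.read_csv(run_dir / "genets.tsv", sep="\t", index_col="sample_id")

    for klass in ("n", "m", "h"):
        genet_file = run_dir / f"fit_{klass}" / "genet_summary.tsv"
        if not genet_file.exists():
            continue
        genet = pd.read_csv(genet_file, sep="\t")
        glob = pd.read_csv(
            run_dir / f"fit_{klass}" / "posterior_summary.tsv", sep="\t"
        ).set_index("locus")
        for locus, sub in genet.groupby("locus"):
            # genets in descending ramet-count order, ties by genet id
            sub = sub.sort_values(["ramet_count", "genet_id"],
                                  ascending=[False, True]).reset_index()
            fig, (ax1, ax2) = plt.subplots(
                1, 2, figsize=(9, 3.2), width_ratios=[2, 1]
            )
            colors = np.where(
                sub["flag"] == 1, "red", np.where(sub["flag"] == -1, "blue", "0.3")
            )
            xs = np.arange(len(sub))
            ax1.vlines(xs, sub["lo"], sub["hi"], colors=colors, lw=1)
            ax1.hlines(sub["median"], xs - 0.35, xs + 0.35, colors=colors, lw=2)
            ax1.axhline(glob.loc[locus, "median"], ls=":", color="k", lw=1)
            ax1.set_ylim(0, 1)
            ax1.set_xlabel("genet (descending ramet count)")
            ax1.set_ylabel("probability")
            ax1.set_title(f"{locus} ({klass}-subepilocus)")

            flagged = sub[sub["flag"] != 0].set_index("genet_id")["flag"]
            pts = samples.df.drop(columns=["genet_id"]).merge(
                membership, left_on="sample_id", right_index=True
            )
            cmap = pts["genet_id"].map(
                lambda g: "red" if flagged.get(g, 0) == 1
                else ("blue" if flagged.get(g, 0) == -1 else "0.7")
            )
            ax2.scatter(pts["x"], pts["y"], c=cmap, s=8)
            ax2.set_aspect("equal")
            ax2.set_title("flagged genets")
            fig.tight_layout()
            out = fig_dir / f"deviation_{klass}_{locus}.png"
            fig.savefig(out, dpi=110)
            plt.close(fig)
            written.append(out)

    for markers in ("ssr", "subepiloci"):
        f = run_dir / f"correlogram_{markers}.tsv"
        if not f.exists():
            continue
        tab = pd.read_csv(f, sep="\t")
        mid = (tab["lo"] + tab["hi"]) / 2
        fig, ax = plt.subplots(figsize=(6, 3.2))
        ax.plot(mid, tab["r"], "-o", ms=3, label="r")
        ax.fill_between(mid, tab["perm_lo"], tab["perm_hi"], alpha=0.2,
                        label="permutation envelope")
        ax.plot(mid, tab["boot_lo"], "--", lw=0.8, color="C1")
        ax.plot(mid, tab["boot_hi"], "--", lw=0.8, color="C1",
                label="bootstrap 95% CI")
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xlabel("distance class midpoint (m)")
        ax.set_ylabel("autocorrelation r")
        ax.legend(fontsize=7)
        ax.set_title(f"{markers} correlogram")
        fig.tight_layout()
        out = fig_dir / f"correlogram_{markers}.png"
        fig.savefig(out, dpi=110)
        plt.close(fig)
        written.append(out)
    return written
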