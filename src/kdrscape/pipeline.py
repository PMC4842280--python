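"""Config-driven orchestration of the full analysis flow.

Two analysis tracks mirror the study design: a functional-locus track
(resistance-codon fragment: diversity, neutrality, expansion, codon
frequencies, haplotype network and origin counting) and a neutral-marker
track (structure, spatial analyses). Outputs are plain TSV/JSON/Newick files
plus a manifest recording every parameter and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diversity import diversity_stats, mismatch_distribution
from .expansion import analyse_expansion
from .kdrnet import (
    allele_frequencies,
    build_network,
    classify_kdr_codon,
    count_origin_events,
    network_edge_table,
    network_states,
)
from .neutrality import compute_neutrality, fdr_adjust, neutrality_pvalues
from .seqdata import (
    Alignment,
    FragmentLayout,
    PopulationSet,
    read_alignment,
    read_popmap,
    write_alignment,
    write_popmap,
)
from .spatial import geographic_distances, ibd_inputs, landscape_surface, mantel, samova
from .structure import amova, nei_distance, pairwise_differentiation, upgma
from .synth import SimConfig, config_to_json, simulate_dataset


@dataclass
class PipelineConfig:
    """Inputs, toggles and statistical parameters of one pipeline run."""

    alignment: str | None = None
    popmap: str | None = None
    layout: str | None = None
    sim: SimConfig | None = None
    out_dir: str = "kdrscape_out"
    overwrite: bool = False
    seed: int = 0
    # stage toggles
    run_diversity: bool = True
    run_neutrality: bool = True
    run_expansion: bool = True
    run_structure: bool = True
    run_spatial: bool = True
    run_kdrnet: bool = True
    # statistical parameters
    perms: int = 1000
    neutrality_reps: int = 1000
    bootstrap_reps: int = 200
    maf: float = 0.10
    connection_limit: int = 2
    k_range: tuple[int, int] = (2, 4)
    samova_runs: int = 10
    samova_iters: int = 2000
    grid: tuple[int, int] = (80, 80)
    alpha: float = 1.0
    mu_locus: float | None = None
    expansion_method: str = "moments"
    region_grouping: bool = True


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _load_inputs(cfg: PipelineConfig):
    if cfg.sim is not None:
        return simulate_dataset(cfg.sim)
    if cfg.alignment is None or cfg.popmap is None:
        raise ValueError("either sim config or alignment+popmap required")
    aln = read_alignment(cfg.alignment)
    pops = read_popmap(cfg.popmap)
    if cfg.layout is None:
        raise ValueError("layout JSON required for file inputs")
    layout = FragmentLayout.from_json(cfg.layout)
    return aln, pops, layout


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dictionary."""
    out = Path(cfg.out_dir)
    if out.exists() and not cfg.overwrite and any(out.iterdir()):
        raise FileExistsError(f"{out} is not empty (pass overwrite)")
    out.mkdir(parents=True, exist_ok=True)
    aln, pops, layout = _load_inputs(cfg)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "n_sequences": aln.n,
        "alignment_length": aln.length,
        "populations": pops.populations,
        "parameters": {
            k: v
            for k, v in dataclasses.asdict(cfg).items()
            if k not in ("sim",)
        },
        "outputs": [],
    }
    if cfg.sim is not None:
        manifest["sim_config"] = config_to_json(cfg.sim)
        write_alignment(aln, out / "simulated.fasta")
        write_popmap(pops, out / "simulated_popmap.tsv")
        layout.to_json(out / "simulated_layout.json")

    def _emit(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        manifest["outputs"].append(name)

    pop_alns = {
        p: aln.subset([s for s in aln.ids if pops.sample_to_pop[s] == p])
        for p in pops.populations
    }

    try:
        if cfg.run_diversity or cfg.run_neutrality or cfg.run_expansion:
            rows = []
            for pi, (p, sub) in enumerate(pop_alns.items()):
                row: dict = {"population": p}
                st = diversity_stats(sub)
                row.update(
                    n=st.n, S=st.S, K=st.K, Pi=st.Pi, h=st.h, Hd=st.Hd,
                    eta=st.eta, eta_s=st.eta_s, L=st.L,
                )
                if cfg.run_neutrality and st.n >= 4 and st.S >= 1:
                    ns = compute_neutrality(sub)
                    ns = neutrality_pvalues(
                        ns, st.n, st.S, reps=cfg.neutrality_reps,
                        seed=cfg.seed * 1009 + pi,
                    )
                    row.update(
                        D=ns.D, Dstar=ns.Dstar, Fstar=ns.Fstar, Fs=ns.Fs,
                        R2=ns.R2,
                        **{f"p_{k}": v for k, v in ns.pvals.items()},
                    )
                if cfg.run_expansion and st.n >= 5 and st.S >= 1:
                    mm = mismatch_distribution(sub)
                    fit = analyse_expansion(
                        mm, st.n, method=cfg.expansion_method,
                        reps=cfg.bootstrap_reps, seed=cfg.seed * 2003 + pi,
                        mu_locus=cfg.mu_locus,
                    )
                    row.update(
                        tau=fit.tau, theta0=fit.theta0, theta1=fit.theta1,
                        SSD=fit.SSD, p_SSD=fit.p_SSD, r=fit.r, p_r=fit.p_r,
                        time_years=fit.time_years,
                    )
                rows.append(row)
            table = pd.DataFrame(rows)
            for col in [c for c in table.columns if c.startswith("p_")]:
                finite = table[col].notna()
                q = pd.Series(np.nan, index=table.index)
                if finite.any():
                    q[finite] = fdr_adjust(list(table.loc[finite, col]))
                table[f"q_{col[2:]}"] = q
            _emit("per_population.tsv", table)
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError("per-population", exc)

    grouping = None
    if cfg.region_grouping and len(set(pops.pop_region.values())) >= 2:
        grouping = dict(pops.pop_region)

    try:
        if cfg.run_structure:
            res = amova(
                aln, pops, grouping=grouping, mode="phist",
                perms=cfg.perms, seed=cfg.seed + 11,
            )
            (out / "amova.json").write_text(
                json.dumps(
                    {
                        "variance_components": res.variance_components,
                        "percentages": res.percentages,
                        "phi": res.phi,
                        "pvals": res.pvals,
                        "df": res.df,
                        "two_level": res.two_level,
                    },
                    indent=1,
                )
            )
            manifest["outputs"].append("amova.json")
            fst_dm, pmat = pairwise_differentiation(
                aln, pops, mode="fst_freq", perms=cfg.perms, seed=cfg.seed + 13
            )
            fst_dm.to_frame().to_csv(out / "pairwise_fst.tsv", sep="\t")
            pd.DataFrame(pmat, index=fst_dm.labels, columns=fst_dm.labels).to_csv(
                out / "pairwise_fst_pvalues.tsv", sep="\t"
            )
            manifest["outputs"] += ["pairwise_fst.tsv", "pairwise_fst_pvalues.tsv"]
            from .seqdata import collapse_haplotypes

            table = collapse_haplotypes(aln, pops)
            if (table.pop_sizes() >= 2).all():
                nei = nei_distance(table)
                (out / "upgma.nwk").write_text(upgma(nei) + "\n")
                nei.to_frame().to_csv(out / "nei_distance.tsv", sep="\t")
                manifest["outputs"] += ["upgma.nwk", "nei_distance.tsv"]
    except Exception as exc:
        raise StageError("structure", exc)

    try:
        if cfg.run_spatial and pops.pop_coords:
            geo, gen = ibd_inputs(aln, pops, mode="phist", seed=cfg.seed + 17)
            mr = mantel(geo, gen, perms=max(cfg.perms, 100), seed=cfg.seed + 19)
            (out / "mantel.json").write_text(
                json.dumps(
                    {"r": mr.r, "R2": mr.R2, "p": mr.p, "n_pairs": mr.n_pairs}
                )
            )
            manifest["outputs"].append("mantel.json")
            kmin, kmax = cfg.k_range
            kmax = min(kmax, len(pops.populations) - 1)
            if kmax >= kmin:
                sres = samova(
                    aln, pops, K_range=range(kmin, kmax + 1),
                    runs=cfg.samova_runs, iters=cfg.samova_iters,
                    seed=cfg.seed + 23,
                )
                rows = [
                    {
                        "K": r.K, "F_CT": r.fct, "F_SC": r.fsc, "F_ST": r.fst,
                        "grouping": json.dumps(r.best_grouping),
                    }
                    for r in sres
                ]
                _emit("samova.tsv", pd.DataFrame(rows))
            surf = landscape_surface(pops, gen, grid=cfg.grid, alpha=cfg.alpha)
            np.savetxt(out / "landscape_grid.tsv", surf.grid, delimiter="\t")
            manifest["outputs"].append("landscape_grid.tsv")
    except Exception as exc:
        raise StageError("spatial", exc)

    try:
        if cfg.run_kdrnet:
            alleles = classify_kdr_codon(aln, layout)
            freqs = allele_frequencies(alleles, aln.ids, pops)
            freqs.to_csv(out / "allele_frequencies.tsv", sep="\t")
            manifest["outputs"].append("allele_frequencies.tsv")
            states, sites, codon_idx = network_states(aln, pops, layout, cfg.maf)
            net = build_network(
                states, connection_limit=cfg.connection_limit,
                codon_site_idx=codon_idx, sites=sites,
            )
            _emit("network_edges.tsv", network_edge_table(net))
            origins = count_origin_events(net, layout)
            (out / "origins.json").write_text(
                json.dumps(
                    {
                        "n_events": origins.n_events,
                        "n_backgrounds": origins.n_backgrounds,
                        "n_resistant_haplotypes": origins.n_resistant_haplotypes,
                        "lower_bound": origins.lower_bound,
                        "events": [
                            dataclasses.asdict(e) for e in origins.events
                        ],
                        "sites": sites,
                    },
                    indent=1,
                )
            )
            manifest["outputs"].append("origins.json")
    except Exception as exc:
        raise StageError("kdrnet", exc)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
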