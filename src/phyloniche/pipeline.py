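"""End-to-end orchestration of the phyloclimatic analysis.

``run_all`` drives the full chain — occurrence thinning and layer pruning,
partial-ROC evaluation, pairwise niche overlap and the age-range correlation,
PNO profiles and weighted-mean traits, phylogenetic signal, trait-model
selection, disparity through time with MDI, phylogenetic PCA, and ancestral
tolerances — writing one TSV per report plus a machine-readable manifest.
Every stochastic stage draws its own sub-seed from the run seed, so stages
are independently reproducible.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .disparity import dtt_with_null, mdi_by_clade
from .evomodels import model_table
from .grids import (GridLayer, OccurrenceSet, partial_roc, prune_correlated_layers,
                    read_grid, read_occurrences, thin_occurrences)
from .overlap import age_range_correlation, overlap_matrix, suitability_dist
from .pno import ancestral_tolerance, compute_pno, pno_weighted_mean
from .ppca import ordinary_pca, phylo_pca
from .signal import signal_table
from .trees import Phylo, read_newick_file

log = logging.getLogger("phyloniche")

__all__ = ["RunConfig", "run_all", "stage_seed"]


@dataclass
class RunConfig:
    """Paths, thresholds and the master seed of one pipeline run.

    Threshold defaults follow common phyloclimatic practice: collinearity cut
    at |r| < 0.75, occurrence thinning at 0.5 km, partial-ROC omission error
    5% with 50% resampling over 1000 bootstraps, 1000 ARC and ancestral-
    tolerance iterations, 50 PNO bins, 1000 DTT simulations at 95% CI, 80%
    central density for tolerances.
    """

    tree: str = ""
    layers_dir: str = ""
    suitability_dir: str = ""
    occurrences: str = ""
    out_dir: str = "results"
    r_max: float = 0.75
    thin_km: float = 0.5
    roc_E: float = 0.05
    roc_boot_frac: float = 0.5
    n_boot: int = 1000
    arc_iter: int = 1000
    pno_bins: int = 50
    dtt_sims: int = 1000
    ci: float = 0.95
    anctol_iter: int = 1000
    tol_level: float = 0.8
    n_perm: int = 1000
    n_pcs: int = 3
    clades: dict = field(default_factory=dict)   # name -> tip labels, for MDI
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not 0 < self.r_max < 1:
            raise ValueError("r_max must be in (0, 1)")
        if not 0 < self.roc_E < 0.5:
            raise ValueError("roc_E must be in (0, 0.5)")
        if not 0 < self.ci < 1 or not 0 < self.tol_level < 1:
            raise ValueError("ci and tol_level must be in (0, 1)")
        if self.thin_km < 0:
            raise ValueError("thin_km must be >= 0")


def stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """Deterministic per-stage sub-seed (stage-name hashed)."""
    return np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])


def _write(df: pd.DataFrame, path: Path, index=False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def run_all(config: RunConfig,
            tree: Phylo | None = None,
            climate: dict[str, GridLayer] | None = None,
            suitability: dict[str, GridLayer] | None = None,
            occurrences: dict[str, OccurrenceSet] | None = None) -> dict:
    """Run the full analysis; inputs may be passed in memory or loaded from paths.

    ``suitability`` maps species to their (single, combined) suitability
    surface.  Returns a dict of the in-memory result tables; all reports are
    also written under ``config.out_dir``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if tree is None:
        tree = read_newick_file(config.tree)
    if climate is None:
        climate = {p.stem: read_grid(p) for p in sorted(Path(config.layers_dir).glob("*.asc"))}
    if suitability is None:
        suitability = {p.stem: read_grid(p)
                       for p in sorted(Path(config.suitability_dir).glob("*.asc"))}
    if occurrences is None:
        occurrences = read_occurrences(config.occurrences)
    species = tree.tip_labels
    results: dict = {}
    ref = next(iter(climate.values()))

    # -- prep: thinning + layer pruning -------------------------------------
    log.info("prep: thinning occurrences and pruning correlated layers")
    ss = stage_seed(config.seed, "prep").spawn(len(occurrences))
    thinned = {sp: thin_occurrences(o, config.thin_km, grid=ref, seed=s)
               for (sp, o), s in zip(sorted(occurrences.items()), ss)}
    kept = prune_correlated_layers(climate, r_max=config.r_max)
    climate = {k: climate[k] for k in kept}
    results["layers_kept"] = kept
    pd.DataFrame({"layer": kept}).pipe(_write, out / "layers_kept.tsv")

    # -- partial ROC ---------------------------------------------------------
    log.info("proc: partial-ROC evaluation")
    rows = []
    ss = stage_seed(config.seed, "proc").spawn(len(species))
    for sp, s in zip(species, ss):
        r = partial_roc(suitability[sp], thinned[sp], E=config.roc_E,
                        boot_frac=config.roc_boot_frac, n_boot=config.n_boot, seed=s)
        rows.append({"species": sp, "mean_AUC_ratio": r.mean_ratio,
                     "p": r.p_value, "p_boot": r.p_boot, "degenerate": r.degenerate})
    results["partial_roc"] = pd.DataFrame(rows)
    _write(results["partial_roc"], out / "partial_roc.tsv")

    # -- niche overlap + ARC -------------------------------------------------
    log.info("overlap: D/I matrix and age-range correlation")
    shared = None
    for sp in species:
        m = suitability[sp].valid_mask()
        shared = m if shared is None else (shared & m)
    dists = [suitability_dist(suitability[sp], sp, mask=shared) for sp in species]
    M = overlap_matrix(dists)
    results["overlap"] = M
    _write(M.to_frame(), out / "overlap.tsv", index=True)
    arc = age_range_correlation(tree, M, stat="I", n_iter=config.arc_iter,
                                seed=stage_seed(config.seed, "arc"))
    results["arc"] = arc
    _write(pd.DataFrame([{"slope": arc.slope, "intercept": arc.intercept,
                          "p_slope": arc.p_slope, "p_intercept": arc.p_intercept,
                          "n_iter": arc.n_iter}]), out / "arc.tsv")
    _write(arc.nodes, out / "arc_nodes.tsv")

    # -- PNO profiles and traits ----------------------------------------------
    log.info("pno: profiles and weighted means")
    profiles: dict[str, dict] = {}
    trait_cols = {}
    pno_rows = []
    for var, layer in climate.items():
        vals = layer.valid_values()
        vmin, vmax = float(vals.min()), float(vals.max())
        profiles[var] = {}
        means = {}
        for sp in species:
            prof = compute_pno(layer, suitability[sp], n_bins=config.pno_bins,
                               vmin=vmin, vmax=vmax, variable=var, species=sp)
            profiles[var][sp] = prof
            means[sp] = pno_weighted_mean(prof)
            pno_rows.extend({"variable": var, "species": sp,
                             "bin_center": c, "mass": m}
                            for c, m in zip(prof.centers, prof.mass))
        trait_cols[var] = means
    traits = pd.DataFrame(trait_cols).loc[species]
    results["traits"] = traits
    traits.rename_axis("species").to_csv(out / "traits.csv")
    _write(pd.DataFrame(pno_rows), out / "pno_profiles.tsv")

    # -- signal (Table 1 analogue) -------------------------------------------
    log.info("signal: Blomberg K and Pagel lambda")
    t1 = signal_table(tree, traits, n_perm=config.n_perm,
                      seed=stage_seed(config.seed, "signal"))
    results["table1"] = t1
    _write(t1, out / "table1.tsv")

    # -- model fitting (Table 2 analogue) -------------------------------------
    log.info("fitmodels: BM/OU/EB/delta with AICc ranking")
    t2 = model_table(tree, traits)
    results["table2"] = t2
    _write(t2, out / "table2.tsv")

    # -- DTT / MDI (Table 3 analogue) ------------------------------------------
    log.info("dtt: disparity through time and MDI")
    t3_rows = []
    dtt_seeds = stage_seed(config.seed, "dtt").spawn(len(traits.columns))
    for var, s in zip(traits.columns, dtt_seeds):
        if config.clades:
            tab = mdi_by_clade(tree, traits[var], config.clades,
                               n_sim=config.dtt_sims, ci=config.ci, seed=s)
            for _, row in tab.iterrows():
                t3_rows.append({"layer": var, "clade": row["clade"], "MDI": row["MDI"]})
            res = dtt_with_null(tree, traits[var], n_sim=config.dtt_sims,
                                ci=config.ci, seed=s)
        else:
            res = dtt_with_null(tree, traits[var], n_sim=config.dtt_sims,
                                ci=config.ci, seed=s)
            t3_rows.append({"layer": var, "clade": "total", "MDI": res.mdi})
        _write(res.to_frame(), out / "dtt" / f"{var}.tsv")
    results["table3"] = pd.DataFrame(t3_rows)
    _write(results["table3"], out / "table3.tsv")

    # -- pPCA ------------------------------------------------------------------
    log.info("ppca: phylogenetic and ordinary PCA")
    pp = phylo_pca(tree, traits)
    results["ppca"] = pp
    _write(pp.loadings.rename_axis("variable"), out / "ppca" / "loadings.tsv", index=True)
    _write(pp.scores.rename_axis("species"), out / "ppca" / "scores.tsv", index=True)
    if traits.shape[1] >= 2:
        op = ordinary_pca(traits, standardize=True)
        _write(op.scores.rename_axis("species"), out / "ppca" / "pca_scores.tsv", index=True)
        npc = min(config.n_pcs, op.scores.shape[1])
        pc_traits = op.scores.iloc[:, :npc]
        t1pc = signal_table(tree, pc_traits, n_perm=config.n_perm,
                            seed=stage_seed(config.seed, "signal-pc"))
        t2pc = model_table(tree, pc_traits)
        results["table1_pc"] = t1pc
        results["table2_pc"] = t2pc
        _write(t1pc, out / "table1_pc.tsv")
        _write(t2pc, out / "table2_pc.tsv")

    # -- ancestral tolerances ---------------------------------------------------
    log.info("anctol: ancestral tolerance reconstruction")
    anct_seeds = stage_seed(config.seed, "anctol").spawn(len(profiles))
    for (var, profs), s in zip(profiles.items(), anct_seeds):
        tol = ancestral_tolerance(tree, profs, n_iter=config.anctol_iter,
                                  seed=s, level=config.tol_level)
        _write(tol.to_frame(), out / "anctol" / f"{var}.tsv")
        _write(tol.tip_summary, out / "anctol" / f"{var}_tips.tsv")
    results["anctol_vars"] = list(profiles)

    manifest = {"config": asdict(config), "version": __version__,
                "n_species": len(species), "layers_kept": kept}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log.info("run complete: outputs in %s", out)
    return results
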