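"""End-to-end workflow: merge -> QC -> {ROH, inbreeding, islands},
{distance, MDS, NJ}, {admixture CV}, {LD decay}, and pedigree analytics.

A :class:`RunConfig` holds every stage parameter (defaulting to the
standard study values: MAF 0.05, call-rate 0.05, HWE 1e-6, array ROH
preset, top-1% islands, admixture k 2..12 with 5-fold CV, LD to 2000 kb);
:func:`run_pipeline` executes the stages, writes plain-text outputs (TSV,
BED, Newick) into an output directory, and returns a manifest recording
parameters, seeds, and per-stage row counts so any output can be
reproduced.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import admixture as admix
from . import genotypes as geno
from . import islands as isl
from . import ld as ldmod
from . import pedigree as pedmod
from . import roh as rohmod
from . import structure as struct

log = logging.getLogger("breedpop")


@dataclass
class RunConfig:
    ped_map_paths: list[tuple[str, str]] = field(default_factory=list)
    pedigree_csv: str | None = None
    out_dir: str = "breedpop_out"
    seed: int = 0
    # QC
    maf_min: float = 0.05
    marker_missing_max: float = 0.05
    sample_missing_max: float = 0.05
    hwe_p_min: float = 1e-6
    # ROH / islands
    roh_preset: str = "array"
    island_top_fraction: float = 0.01
    autosome_length_mb: float = rohmod.DOG_AUTOSOME_MB
    gene_bed: str | None = None
    # structure
    mds_k: int = 2
    # admixture
    admix_k_min: int = 2
    admix_k_max: int = 12
    admix_folds: int = 5
    admix_restarts: int = 3
    # LD
    ld_max_dist_kb: float = 2000.0
    ld_bin1_bp: int = 100
    ld_bin2_bp: int = 3000
    ld_break_bp: int = 2000
    ld_subsample: int | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


def run_pipeline(cfg: RunConfig, gm: geno.GenotypeMatrix | None = None) -> dict:
    """Run every applicable stage; returns (and writes) the manifest.

    A pre-built genotype matrix may be passed directly (e.g. from the
    simulators); otherwise the PED/MAP panels in the config are read and
    merged.  Stages that lack inputs (no pedigree, too few samples for LD)
    are skipped and noted in the manifest.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": json.loads(cfg.to_json()), "stages": {}, "outputs": {}}
    t_all = time.time()

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                info = fn() or {}
            except Exception as exc:
                log.error("stage %s failed: %s", name, exc)
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            info["seconds"] = round(time.time() - t0, 3)
            manifest["stages"][name] = info
            log.info("stage %s done in %.2fs", name, info["seconds"])
            return info
        return deco

    # -- input ----------------------------------------------------------
    if gm is None:
        panels = [geno.read_plink_text(p, m) for p, m in cfg.ped_map_paths]
        if len(panels) == 1:
            gm = panels[0]
            manifest["stages"]["merge"] = {"skipped": "single panel"}
        else:
            gm, rep = geno.merge_panels(panels)
            manifest["stages"]["merge"] = {
                "n_common_markers": rep.n_common_markers,
                "n_palindromic_dropped": rep.n_palindromic_dropped,
                "n_incompatible_dropped": rep.n_incompatible_dropped,
            }

    @stage("qc")
    def _qc():
        nonlocal gm
        params = geno.QCParams(cfg.maf_min, cfg.marker_missing_max,
                               cfg.sample_missing_max, cfg.hwe_p_min)
        gm, rep = geno.qc_filter(gm, params)
        return {"n_samples": gm.n_samples, "n_markers": gm.n_markers,
                "removed_samples": len(rep.removed_samples),
                "removed_markers": len(rep.removed_markers_missing)
                + len(rep.removed_markers_maf) + len(rep.removed_markers_hwe)}

    @stage("roh")
    def _roh():
        params = rohmod.PRESETS[cfg.roh_preset]
        segs = rohmod.detect_roh(gm, params)
        df = rohmod.segments_to_frame(segs)
        df.to_csv(out / "roh_segments.tsv", sep="\t", index=False)
        manifest["outputs"]["roh_segments"] = str(out / "roh_segments.tsv")
        froh = rohmod.f_roh_per_sample(segs, gm.sample_ids, cfg.autosome_length_mb)
        fhom = rohmod.f_hom(gm)
        pd.DataFrame({"f_roh": froh, "f_hom": fhom}).to_csv(
            out / "inbreeding.tsv", sep="\t")
        manifest["outputs"]["inbreeding"] = str(out / "inbreeding.tsv")
        manifest["roh_segments"] = segs
        return {"n_segments": len(segs), "mean_f_roh": float(froh.mean())}

    @stage("islands")
    def _islands():
        segs = manifest.pop("roh_segments")
        freqs = isl.snp_roh_frequency(segs, gm.markers, gm.sample_ids)
        freqs.to_frame().to_csv(out / "snp_roh_frequency.tsv", sep="\t", index=False)
        islands = isl.call_islands(freqs, cfg.island_top_fraction)
        isl.islands_to_bed(islands, out / "islands.bed")
        manifest["outputs"]["islands"] = str(out / "islands.bed")
        info = {"n_islands": len(islands)}
        if cfg.gene_bed:
            genes = isl.read_gene_bed(cfg.gene_bed)
            rows = [{"chrom": i.chrom, "start_bp": i.start_bp, "end_bp": i.end_bp,
                     "genes": ";".join(isl.genes_in_interval(genes, i))}
                    for i in islands]
            pd.DataFrame(rows).to_csv(out / "island_genes.tsv", sep="\t", index=False)
            info["gene_bed"] = cfg.gene_bed
        return info

    @stage("structure")
    def _structure():
        D = struct.ibs_distance(gm)
        struct.write_distance_tsv(D, out / "distance.tsv")
        coords, evals = struct.classical_mds(D, cfg.mds_k)
        pd.DataFrame(coords, index=D.ids,
                     columns=[f"C{i + 1}" for i in range(cfg.mds_k)]).to_csv(
            out / "mds.tsv", sep="\t")
        tree = struct.neighbor_joining(D)
        (out / "tree.nwk").write_text(struct.write_newick(tree) + "\n")
        manifest["outputs"]["tree"] = str(out / "tree.nwk")
        return {"n_clamped_branches": tree.n_clamped,
                "top_eigenvalues": [float(v) for v in evals[:cfg.mds_k]]}

    @stage("admixture")
    def _admixture():
        ks = list(range(cfg.admix_k_min, min(cfg.admix_k_max, gm.n_samples) + 1))
        if not ks:
            return {"skipped": "too few samples for requested k range"}
        best_k, results = admix.choose_k(gm, ks, folds=cfg.admix_folds, seed=cfg.seed)
        pd.DataFrame([{"k": r.k, "cv_error": r.mean_cv_error} for r in results]).to_csv(
            out / "admixture_cv.tsv", sep="\t", index=False)
        fit = admix.fit_admixture(gm, best_k, seed=cfg.seed,
                                  n_restarts=cfg.admix_restarts)
        np.savetxt(out / f"admixture_Q_k{best_k}.txt", fit.Q, fmt="%.6f")
        np.savetxt(out / f"admixture_P_k{best_k}.txt", fit.P.T, fmt="%.6f")
        return {"best_k": best_k, "loglik": fit.loglik, "converged": fit.converged}

    @stage("ld")
    def _ld():
        g = gm
        if g.n_samples <= 3:
            return {"skipped": "3 or fewer samples"}
        if cfg.ld_subsample is not None and cfg.ld_subsample < g.n_samples:
            g = ldmod.subsample_individuals(g, cfg.ld_subsample, seed=cfg.seed)
        pairs = ldmod.pairwise_r2(g, cfg.ld_max_dist_kb)
        curve = ldmod.decay_curve(pairs, cfg.ld_bin1_bp, cfg.ld_bin2_bp, cfg.ld_break_bp)
        curve.to_frame().to_csv(out / "ld_decay.tsv", sep="\t", index=False)
        return {"n_pairs": len(pairs)}

    if cfg.pedigree_csv:
        @stage("pedigree")
        def _pedigree():
            recs = pedmod.read_pedigree_csv(cfg.pedigree_csv)
            ped, rep = pedmod.clean_pedigree(recs)
            sires = pedmod.popular_sires(ped)
            sizes, mean_litter = pedmod.litter_sizes(ped)
            try:
                gi = pedmod.generation_interval(ped)
            except ValueError:
                gi = float("nan")
            rows = [{"id": r.id, "f_ped": ped.inbreeding(r.id),
                     "cge": ped.complete_generation_equivalent(r.id)}
                    for r in ped if not r.phantom]
            pd.DataFrame(rows).to_csv(out / "pedigree_inbreeding.tsv",
                                      sep="\t", index=False)
            return {"n_records": len(ped), "n_popular_sires": len(sires),
                    "mean_litter_size": mean_litter, "generation_interval": gi,
                    "n_cleaning_year_resets": rep.n_year_reset}
    else:
        manifest["stages"]["pedigree"] = {"skipped": "no pedigree supplied"}

    manifest["seconds_total"] = round(time.time() - t_all, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
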