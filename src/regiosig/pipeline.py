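"""End-to-end orchestration: simulate -> DE -> overlap -> clones -> chromatin.

One global seed is expanded into per-stage child seeds through
``numpy.random.SeedSequence(seed).generate_state(...)`` (fixed stage order,
values reduced mod 2**31), so any stage can be re-run in isolation with a
stable seed. Every intermediate is written to disk, every effective
parameter is echoed into the report, and the report carries sha256
checksums of all written files: identical config + seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import ConfigError, GeneSet, NUCLEI
from . import chromatin as chrom
from . import clones as clon
from . import diffexpr as de
from . import io as rio
from . import overlap as ovl
from . import synthdata as synth

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "StageError"]

_STAGES = ("simulate", "de", "overlap", "clones", "chromatin")

# Default ChIP panel: (gene, region) -> true (K4me3 %, K27me3 %). Thalamic
# identity genes are active in thalamic astrocytes and poised/repressed in
# cortical ones; cortical genes mirror that; reprogramming-responsive genes
# sit near the equality line (poised) in both.
_DEFAULT_CHIP_PANEL = {
    "Th": {
        "Gbx2": (4.0, 0.5), "Rora": (3.0, 0.8), "Lef1": (2.5, 0.8),
        "Slc17a6": (1.2, 1.0), "Pou2f2": (1.0, 1.1),
        "Tbr1": (0.9, 1.0), "Ctip2": (0.8, 1.1), "Fezf2": (0.4, 2.0),
    },
    "Ctx": {
        "Gbx2": (0.4, 3.0), "Rora": (0.6, 1.8), "Lef1": (0.7, 1.6),
        "Slc17a6": (1.0, 1.2), "Pou2f2": (1.1, 1.0),
        "Tbr1": (3.0, 0.7), "Ctip2": (2.5, 0.8), "Fezf2": (2.0, 0.5),
    },
}
_DEFAULT_EXPR_DCT = {
    "Th": {"Gbx2": 5.0, "Rora": 6.0, "Lef1": 6.5, "Slc17a6": 8.0,
           "Pou2f2": 9.0, "Tbr1": 12.0, "Ctip2": 12.5, "Fezf2": 11.0},
    "Ctx": {"Gbx2": 12.0, "Rora": 9.0, "Lef1": 10.0, "Slc17a6": 11.0,
            "Pou2f2": 10.5, "Tbr1": 6.0, "Ctip2": 6.5, "Fezf2": 7.0},
}


@dataclass
class PipelineConfig:
    """All stage parameters; defaults echo the printed study thresholds
    (alpha 0.1, fold-change cutoffs 0 and 0.322, top-400, QC 600 UMIs / 5%
    mitochondrial, clone filters 3 cells / 2 reporters, poised band 0.5)."""

    seed: int = 0
    stages: tuple = _STAGES
    # expression simulation
    n_genes: int = 4000
    samples_per_group: int = 4
    frac_region_genes: float = 0.15
    frac_celltype_genes: float = 0.10
    region_lfc: float = 1.5
    astro_attenuation: float = 0.5
    celltype_lfc: float = 2.0
    dispersion: float = 0.05
    lib_size_range: tuple = (5e5, 1.5e6)
    # DE thresholds
    alpha: float = 0.1
    min_lfc: float = 0.0
    min_lfc_restrictive: float = 0.322
    top_n: int = 400
    # single cell
    n_cells_per_group: int = 150
    min_umi: int = 600
    max_mito: float = 0.05
    sc_logfc_threshold: float = 0.1
    sc_min_pct: float = 0.0
    sc_target_sum: float = 1e4
    # clones
    n_progenitors: int = 120
    n_animals: int = 4
    p_integrate: float = 0.5
    dispersion_eps: float = 0.15
    frac_pure_clones: float = 0.39
    p_neuron: float = 0.5
    home_nucleus_probs: tuple = (0.18, 0.56, 0.26)
    clone_nuclei: tuple = NUCLEI
    clone_min_size: int = 3
    clone_min_reporters: int = 2
    # chromatin
    input_dilution: float = 0.01
    poised_band: float = 0.5
    ct_noise_sd: float = 0.25
    chip_replicates: int = 12

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("stages", "lib_size_range", "home_nucleus_probs", "clone_nuclei"):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(**d)


def validate_config(cfg: PipelineConfig) -> list:
    """Return every violation found (empty list means valid)."""
    findings = []

    def check(cond: bool, msg: str) -> None:
        if not cond:
            findings.append(msg)

    check(set(cfg.stages) <= set(_STAGES),
          f"stages: unknown entries {sorted(set(cfg.stages) - set(_STAGES))}")
    check(cfg.n_genes >= 1, "n_genes: must be >= 1")
    check(cfg.samples_per_group >= 2, "samples_per_group: must be >= 2")
    check(0.0 < cfg.alpha <= 1.0, "alpha: must lie in (0, 1]")
    check(cfg.min_lfc >= 0.0, "min_lfc: must be >= 0")
    check(cfg.min_lfc_restrictive >= 0.0, "min_lfc_restrictive: must be >= 0")
    check(1 <= cfg.top_n <= cfg.n_genes, "top_n: must lie in [1, n_genes]")
    check(0.0 <= cfg.frac_region_genes <= 1.0, "frac_region_genes: must lie in [0, 1]")
    check(0.0 < cfg.astro_attenuation <= 1.0, "astro_attenuation: must lie in (0, 1]")
    check(cfg.dispersion >= 0.0, "dispersion: must be >= 0")
    check(cfg.min_umi >= 0, "min_umi: must be >= 0")
    check(0.0 < cfg.max_mito <= 1.0, "max_mito: must lie in (0, 1]")
    check(cfg.sc_min_pct >= 0.0, "sc_min_pct: must be >= 0")
    check(cfg.n_progenitors >= 1, "n_progenitors: must be >= 1")
    check(0.0 < cfg.p_integrate <= 1.0, "p_integrate: must lie in (0, 1]")
    check(cfg.clone_min_size >= 1, "clone_min_size: must be >= 1")
    check(cfg.clone_min_reporters >= 1, "clone_min_reporters: must be >= 1")
    for label in cfg.clone_nuclei:
        check(label in NUCLEI,
              f"clone_nuclei: unknown nucleus label {label!r}; vocabulary is {NUCLEI}")
    check(abs(sum(cfg.home_nucleus_probs) - 1.0) <= 1e-12,
          "home_nucleus_probs: must sum to 1")
    check(0.0 < cfg.input_dilution <= 1.0, "input_dilution: must lie in (0, 1]")
    check(cfg.poised_band >= 0.0, "poised_band: must be >= 0")
    check(cfg.ct_noise_sd >= 0.0, "ct_noise_sd: must be >= 0")
    return findings


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def stage_seeds(seed: int) -> dict:
    """Deterministic per-stage child seeds (documented expansion scheme)."""
    state = np.random.SeedSequence(seed).generate_state(8) % (2**31)
    names = ("bulk_region", "bulk_nuclei", "sc", "clones",
             "ct_th", "ct_ctx", "spare_a", "spare_b")
    return {n: int(s) for n, s in zip(names, state)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _samples_of(m, **filters) -> list:
    mask = np.ones(len(m.samples), dtype=bool)
    for col, val in filters.items():
        mask &= (m.samples[col] == val).to_numpy()
    return list(m.samples.index[mask])


def _float(x) -> float:
    # round to 10 significant digits so reports stay byte-stable without
    # collapsing small p-values to zero
    x = float(x)
    return float(f"{x:.10g}")


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Execute the configured stages in dependency order and write a report.

    Returns the report dict (also written to ``report.json`` together with
    a human-readable ``summary.txt``). Failures raise :class:`StageError`
    naming the stage; nothing past a failed stage is written.
    """
    findings = validate_config(cfg)
    if findings:
        raise ConfigError("invalid config: " + "; ".join(findings))
    outdir = Path(outdir)
    datadir = outdir / "data"
    datadir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(cfg.seed)
    written: list = []
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "stage_seeds": seeds,
        "parameters": yaml.safe_load(yaml.safe_dump(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in asdict(cfg).items()})),
        "stages": {},
    }

    def emit(path: Path) -> None:
        written.append(path)

    state: dict = {}

    def run_stage(name, fn):
        if name not in cfg.stages:
            return
        try:
            report["stages"][name] = fn()
        except Exception as exc:  # fail fast, naming the stage
            raise StageError(name, exc) from exc

    # ---------------------------------------------------------------- simulate
    def do_simulate():
        bulk_cfg = synth.ExpressionSimConfig(
            n_genes=cfg.n_genes, n_regions=2, n_celltypes=2,
            samples_per_group=cfg.samples_per_group,
            frac_region_genes=cfg.frac_region_genes,
            frac_celltype_genes=cfg.frac_celltype_genes,
            region_lfc=cfg.region_lfc, astro_attenuation=cfg.astro_attenuation,
            celltype_lfc=cfg.celltype_lfc, dispersion=cfg.dispersion,
            lib_size_range=cfg.lib_size_range, seed=seeds["bulk_region"],
        )
        bulk, bulk_truth = synth.simulate_bulk_counts(bulk_cfg)
        nuc_cfg = synth.ExpressionSimConfig(
            n_genes=cfg.n_genes, n_regions=3, n_celltypes=2,
            samples_per_group=cfg.samples_per_group,
            frac_region_genes=cfg.frac_region_genes,
            frac_celltype_genes=cfg.frac_celltype_genes,
            region_lfc=cfg.region_lfc, astro_attenuation=cfg.astro_attenuation,
            celltype_lfc=cfg.celltype_lfc, dispersion=cfg.dispersion,
            lib_size_range=cfg.lib_size_range, seed=seeds["bulk_nuclei"],
        )
        nuc, nuc_truth = synth.simulate_bulk_counts(nuc_cfg)
        sc_cfg = synth.ExpressionSimConfig(
            n_genes=cfg.n_genes, n_regions=2, n_celltypes=2,
            samples_per_group=cfg.samples_per_group,
            frac_region_genes=cfg.frac_region_genes,
            frac_celltype_genes=cfg.frac_celltype_genes,
            region_lfc=cfg.region_lfc, astro_attenuation=cfg.astro_attenuation,
            celltype_lfc=cfg.celltype_lfc, dispersion=cfg.dispersion,
            lib_size_range=cfg.lib_size_range, seed=seeds["sc"],
        )
        sc, sc_truth = synth.simulate_sc_counts(sc_cfg, cfg.n_cells_per_group)
        clone_cfg = synth.CloneSimConfig(
            n_progenitors=cfg.n_progenitors, p_integrate=cfg.p_integrate,
            n_animals=cfg.n_animals, dispersion_eps=cfg.dispersion_eps,
            frac_pure_clones=cfg.frac_pure_clones, p_neuron=cfg.p_neuron,
            home_nucleus_probs=cfg.home_nucleus_probs, seed=seeds["clones"],
        )
        cells = synth.simulate_clones(clone_cfg)

        chip_tables, rt_tables = [], []
        for region, seed_key in (("Th", "ct_th"), ("Ctx", "ct_ctx")):
            ct_cfg = synth.CtSimConfig(
                true_percent_input=_DEFAULT_CHIP_PANEL[region],
                expression_dct=_DEFAULT_EXPR_DCT[region],
                input_dilution=cfg.input_dilution,
                ct_noise_sd=cfg.ct_noise_sd,
                n_replicates=cfg.chip_replicates,
                gene_regions={g: region for g in _DEFAULT_CHIP_PANEL[region]},
                seed=seeds[seed_key],
            )
            chip, rt = synth.simulate_ct_tables(ct_cfg)
            rt["region"] = region
            chip_tables.append(chip)
            rt_tables.append(rt)
        chip = pd.concat(chip_tables, ignore_index=True)
        rt = pd.concat(rt_tables, ignore_index=True)

        rio.write_counts_tsv(bulk, datadir / "bulk_region_counts.tsv",
                             datadir / "bulk_region_meta.tsv")
        rio.write_counts_tsv(nuc, datadir / "bulk_nuclei_counts.tsv",
                             datadir / "bulk_nuclei_meta.tsv")
        rio.write_mtx_dir(sc, datadir / "sc")
        cells.to_csv(datadir / "clone_cells.tsv", sep="\t", index=False)
        chip.to_csv(datadir / "chip_ct.tsv", sep="\t", index=False)
        rt.to_csv(datadir / "rt_ct.tsv", sep="\t", index=False)
        rio.write_json(bulk_truth.to_jsonable(), datadir / "bulk_region_truth.json")
        rio.write_json(nuc_truth.to_jsonable(), datadir / "bulk_nuclei_truth.json")
        for p in [datadir / "bulk_region_counts.tsv", datadir / "bulk_region_meta.tsv",
                  datadir / "bulk_nuclei_counts.tsv", datadir / "bulk_nuclei_meta.tsv",
                  datadir / "sc" / "matrix.mtx", datadir / "sc" / "features.tsv",
                  datadir / "sc" / "barcodes.tsv", datadir / "sc" / "metadata.tsv",
                  datadir / "clone_cells.tsv", datadir / "chip_ct.tsv",
                  datadir / "rt_ct.tsv", datadir / "bulk_region_truth.json",
                  datadir / "bulk_nuclei_truth.json"]:
            emit(p)

        state.update(bulk=bulk, bulk_truth=bulk_truth, nuc=nuc,
                     nuc_truth=nuc_truth, sc=sc, sc_truth=sc_truth,
                     cells=cells, chip=chip, rt=rt)
        return {
            "bulk_shape": list(bulk.counts.shape),
            "nuclei_shape": list(nuc.counts.shape),
            "sc_shape": list(sc.counts.shape),
            "n_barcoded_cells": int(len(cells)),
        }

    # --------------------------------------------------------------------- de
    def do_de():
        bulk, nuc, sc = state["bulk"], state["nuc"], state["sc"]
        sets: dict = {}
        de_counts: dict = {}
        for ct in ("astrocyte", "neuron"):
            ctx = _samples_of(bulk, region="Ctx", cell_type=ct)
            th = _samples_of(bulk, region="Th", cell_type=ct)
            res = de.nb_wald_test(bulk, ctx, th)  # log2fc > 0 = Th-enriched
            res.table.to_csv(outdir / f"de_bulk_{ct}.tsv", sep="\t")
            emit(outdir / f"de_bulk_{ct}.tsv")
            up, down = de.deg_filter(res, cfg.alpha, cfg.min_lfc)
            sets[f"As-Th" if ct == "astrocyte" else "Ns-Th"] = GeneSet(
                "As-Th" if ct == "astrocyte" else "Ns-Th", up.genes, up.provenance)
            sets[f"As-Ctx" if ct == "astrocyte" else "Ns-Ctx"] = GeneSet(
                "As-Ctx" if ct == "astrocyte" else "Ns-Ctx", down.genes, down.provenance)
            de_counts[f"{ct}_th_enriched"] = len(up)
            de_counts[f"{ct}_ctx_enriched"] = len(down)

        # top-N most differentially enriched genes between neurons
        ns_th = bulk.subset_samples(_samples_of(bulk, region="Th", cell_type="neuron"))
        ns_ctx = bulk.subset_samples(_samples_of(bulk, region="Ctx", cell_type="neuron"))
        top_th, top_ctx = de.top_n_enriched(ns_th, ns_ctx, n=cfg.top_n)
        sets["Ns-Th-top"] = GeneSet("Ns-Th-top", top_th.genes, top_th.provenance)
        sets["Ns-Ctx-top"] = GeneSet("Ns-Ctx-top", top_ctx.genes, top_ctx.provenance)

        # per-nucleus one-vs-rest DE within each cell type
        for ct, tag in (("astrocyte", "As"), ("neuron", "Ns")):
            for nucleus in NUCLEI:
                own = _samples_of(nuc, region=nucleus, cell_type=ct)
                rest = [s for s in _samples_of(nuc, cell_type=ct) if s not in own]
                res = de.nb_wald_test(nuc, rest, own)  # log2fc > 0 = nucleus-enriched
                up, _ = de.deg_filter(res, cfg.alpha, cfg.min_lfc)
                sets[f"{tag}-{nucleus}"] = GeneSet(f"{tag}-{nucleus}", up.genes,
                                                   up.provenance)
                de_counts[f"{tag}_{nucleus}"] = len(up)

        # single cell: QC then rank-sum DE per cell type
        n_before = sc.n_samples
        sc_f = de.sc_qc_filter(sc, cfg.min_umi, cfg.max_mito)
        sc_counts = {"cells_before_qc": int(n_before),
                     "cells_after_qc": int(sc_f.n_samples)}
        for ct, tag in (("astrocyte", "As"), ("neuron", "Ns")):
            th = _samples_of(sc_f, region="Th", cell_type=ct)
            ctx = _samples_of(sc_f, region="Ctx", cell_type=ct)
            res = de.wilcoxon_de(sc_f, th, ctx, cfg.sc_logfc_threshold,
                                 cfg.sc_min_pct, cfg.sc_target_sum)
            res.table.to_csv(outdir / f"de_sc_{ct}.tsv", sep="\t")
            emit(outdir / f"de_sc_{ct}.tsv")
            up, down = de.deg_filter(res, cfg.alpha, cfg.sc_logfc_threshold)
            sets[f"sc-{tag}-Th"] = GeneSet(f"sc-{tag}-Th", up.genes, up.provenance)
            sets[f"sc-{tag}-Ctx"] = GeneSet(f"sc-{tag}-Ctx", down.genes, down.provenance)
            sc_counts[f"sc_{ct}_th_degs"] = len(up)
            sc_counts[f"sc_{ct}_ctx_degs"] = len(down)

        rio.write_gmt(sets.values(), outdir / "gene_sets.gmt")
        emit(outdir / "gene_sets.gmt")
        state["sets"] = sets
        return {"deg_counts": de_counts, "single_cell": sc_counts}

    # ---------------------------------------------------------------- overlap
    def do_overlap():
        sets = state["sets"]
        bulk = state["bulk"]
        universe = GeneSet("bulk_universe", list(bulk.gene_ids))
        pct = {
            "ns_th_top_in_as_th": ovl.percent_shared(sets["Ns-Th-top"], sets["As-Th"]),
            "ns_th_top_in_as_ctx": ovl.percent_shared(sets["Ns-Th-top"], sets["As-Ctx"]),
            "ns_ctx_top_in_as_ctx": ovl.percent_shared(sets["Ns-Ctx-top"], sets["As-Ctx"]),
            "ns_ctx_top_in_as_th": ovl.percent_shared(sets["Ns-Ctx-top"], sets["As-Th"]),
        }
        region_grid = ovl.comparison_matrix(
            [sets["As-Th"], sets["As-Ctx"]],
            [sets["Ns-Th-top"], sets["Ns-Ctx-top"]],
            universe,
        )
        nuc_universe = GeneSet("nuclei_universe", list(state["nuc"].gene_ids))
        nuc_grid = ovl.comparison_matrix(
            [sets[f"As-{n}"] for n in NUCLEI],
            [sets[f"Ns-{n}"] for n in NUCLEI],
            nuc_universe,
        )
        region_grid.to_long_frame().to_csv(outdir / "overlap_region.tsv",
                                           sep="\t", index=False)
        nuc_grid.to_long_frame().to_csv(outdir / "overlap_nuclei.tsv",
                                        sep="\t", index=False)
        emit(outdir / "overlap_region.tsv")
        emit(outdir / "overlap_nuclei.tsv")
        state["nuc_grid"] = nuc_grid
        p = nuc_grid.p_values().to_numpy()
        diag = np.diag(p)
        off = p[~np.eye(3, dtype=bool)]
        return {
            "percent_shared": {k: _float(v) for k, v in pct.items()},
            "region_grid_p": {
                f"{r.name_a}|{r.name_b}": _float(r.p_one_sided)
                for row in region_grid.results for r in row
            },
            "nuclei_on_diagonal_max_p": _float(diag.max()),
            "nuclei_off_diagonal_min_p": _float(off.min()),
            "nuclei_diagonal_separated": bool(diag.max() < off.min()),
        }

    # ----------------------------------------------------------------- clones
    def do_clones():
        cells = state["cells"]
        coded = clon.call_codes(cells)
        clones, discarded = clon.group_clones(
            coded, cfg.clone_min_size, cfg.clone_min_reporters
        )
        summary = clon.clone_summary(clones)
        truth = coded.set_index("cell_id")["progenitor_id"]
        ari = clon.partition_recovery_score(clones, truth)
        collision = synth.analytic_code_collision_prob(cfg.p_integrate)

        per_home = {}
        for nucleus in NUCLEI:
            members = [c for c in clones if c.home_nucleus == nucleus]
            if len(members) >= 2:
                groups = {n: [float(c.dispersion[n]) for c in members]
                          for n in NUCLEI}
                kd = clon.kruskal_dunn(groups)
                per_home[nucleus] = {
                    "n_clones": len(members),
                    "h": _float(kd.h_statistic),
                    "p_omnibus": _float(kd.p_omnibus),
                }

        rows = [
            {
                "animal_id": c.animal_id, "code": c.code, "size": c.size,
                "composition": c.composition, "home_nucleus": c.home_nucleus,
                **{f"pct_{n}": _float(c.dispersion[n]) for n in NUCLEI},
            }
            for c in clones
        ]
        pd.DataFrame(rows).to_csv(outdir / "clones.tsv", sep="\t", index=False)
        emit(outdir / "clones.tsv")
        out = {
            "n_clones": summary["n_clones"],
            "frac_pure": _float(summary["frac_pure"]),
            "composition_counts": summary["composition_counts"],
            "discarded": discarded,
            "ari_vs_truth": _float(ari),
            "analytic_collision_prob": _float(collision),
            "dispersion_tests": per_home,
            "home_nucleus_dispersion": summary["home_nucleus_dispersion"],
        }
        rio.write_json(out, outdir / "clones_summary.json")
        emit(outdir / "clones_summary.json")
        return out

    # -------------------------------------------------------------- chromatin
    def do_chromatin():
        chip, rt = state["chip"], state["rt"]
        rep, summary = chrom.chip_table_analysis(
            chip, cfg.input_dilution, cfg.poised_band
        )
        rep.to_csv(outdir / "chip_replicates.tsv", sep="\t", index=False)
        summary.to_csv(outdir / "chip_summary.tsv", sep="\t", index=False)
        emit(outdir / "chip_replicates.tsv")
        emit(outdir / "chip_summary.tsv")

        tests = {}
        for gene, grp in rep.groupby("gene", sort=True):
            th = grp.loc[grp["region"] == "Th", "ratio"].to_numpy()
            ctx = grp.loc[grp["region"] == "Ctx", "ratio"].to_numpy()
            if len(th) >= 2 and len(ctx) >= 2:
                res = chrom.compare_ratios(th, ctx)
                tests[gene] = {"t": _float(res["t"]), "p": _float(res["p"]),
                               "df": res["df"]}

        expr_rows = []
        for region, grp in rt.groupby("region", sort=True):
            ex = chrom.rt_table_analysis(grp)
            ex.insert(0, "region", region)
            expr_rows.append(ex)
        expr = pd.concat(expr_rows, ignore_index=True)
        expr.to_csv(outdir / "expression_summary.tsv", sep="\t", index=False)
        emit(outdir / "expression_summary.tsv")

        states = {
            f"{row.gene}|{row.region}": row.state
            for row in summary.itertuples()
        }
        return {"state_calls": states, "th_vs_ctx_ratio_tests": tests}

    run_stage("simulate", do_simulate)
    run_stage("de", do_de)
    run_stage("overlap", do_overlap)
    run_stage("clones", do_clones)
    run_stage("chromatin", do_chromatin)

    report["checksums"] = {
        str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(written))
    }
    rio.write_json(report, outdir / "report.json")

    lines = [f"regiosig {__version__} pipeline report (seed {cfg.seed})"]
    for stage, payload in report["stages"].items():
        lines.append(f"[{stage}]")
        lines.append(yaml.safe_dump(payload, sort_keys=True).rstrip())
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    return report
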