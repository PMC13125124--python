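"""Pipeline orchestration, publication-style outputs and track plots.

``run_pipeline`` chains filter -> BLUPs -> bulks -> scan for each
population and trait, cross-validates regions between two populations,
and writes the full set of plain-text artifacts (tracks, windows, region
table, BED, BLUPs, bulks, variance components, manifest) under an output
directory.  The pipeline contains no randomness: re-running on the same
inputs reproduces byte-identical tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bsa import CandidateRegion, bulk_frequency, region_pve, scan_chromosome, validate_across_populations
from .bulks import composite_ranking, select_bulks
from .genofilter import GenotypeMatrix, filter_variants, informative_loci
from .io import (
    read_pheno,
    read_vcf,
    regions_to_frame,
    write_regions_bed,
    write_regions_tsv,
)
from .pheno import BlupTable, compute_blups, heritability, trait_correlations, variance_components

logger = logging.getLogger("bsaqtl")

__all__ = ["PopulationInput", "PipelineConfig", "PipelineResult", "run_pipeline", "plot_tracks"]


@dataclass
class PopulationInput:
    name: str
    vcf: str
    pheno: str
    parents: tuple[str, str]
    reference_parent: str

    def __post_init__(self) -> None:
        if self.reference_parent not in self.parents:
            raise ValueError("reference_parent must be one of the two parents")


@dataclass
class PipelineConfig:
    populations: list[PopulationInput]
    out_dir: str
    traits: list[str] | None = None
    bulk_size: int = 20
    ranking: str = "mean_rank"
    max_missing: float = 0.10
    max_het: float = 0.10
    min_maf: float = 0.05
    min_calls: int = 15
    min_freq: float = 0.3
    width_bp: int = 2_000_000
    step_bp: int = 10_000
    confidence: float = 0.999
    min_run_snps: int = 10
    min_beyond_fraction: float = 0.8
    max_gap_snps: int = 10
    make_plots: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        pops = [
            PopulationInput(
                name=p["name"],
                vcf=p["vcf"],
                pheno=p["pheno"],
                parents=tuple(p["parents"]),
                reference_parent=p["reference_parent"],
            )
            for p in raw.pop("populations")
        ]
        return cls(populations=pops, **raw)


@dataclass
class PipelineResult:
    regions: list[CandidateRegion]
    manifest: dict
    out_dir: Path
    blups: dict[str, BlupTable] = field(default_factory=dict)


def _scan_population(
    pop: PopulationInput, cfg: PipelineConfig, out: Path, manifest: dict
) -> tuple[list[CandidateRegion], BlupTable, pd.DataFrame]:
    logger.info("population %s: reading inputs", pop.name)
    G = read_vcf(pop.vcf)
    pheno = read_pheno(pop.pheno)
    traits = cfg.traits or list(dict.fromkeys(pheno["trait"]))
    rils = [s for s in G.samples if s not in pop.parents]
    if cfg.bulk_size * 2 > len(rils):
        raise RuntimeError(
            f"bulks stage: bulk_size {cfg.bulk_size} needs >= {2 * cfg.bulk_size} RILs, "
            f"population {pop.name} has {len(rils)}"
        )

    G_f, report = filter_variants(
        G, cfg.max_missing, cfg.max_het, cfg.min_maf, parents=pop.parents
    )
    info = informative_loci(G_f, *pop.parents)
    report.removed_noninformative = int((~info).sum())
    G_i = G_f.subset_loci(info)
    logger.info(
        "population %s: %d loci in, %d after QC, %d informative",
        pop.name, G.n_loci, G_f.n_loci, G_i.n_loci,
    )
    report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)

    blups = compute_blups(pheno, traits)
    blups.to_csv(out / "blups.csv")

    vc_rows = []
    for trait in traits:
        vc = variance_components(pheno, trait)
        vc_rows.append(
            {
                "trait": trait,
                "var_G": vc.var_G,
                "var_E": vc.var_E,
                "var_GEI": vc.var_GEI,
                "var_block": vc.var_block,
                "var_error": vc.var_error,
                "H2": heritability(vc),
                **{f"p_{k}": v for k, v in vc.lrt_pvalues.items()},
            }
        )
    pd.DataFrame(vc_rows).to_csv(out / "variance_components.tsv", sep="\t", index=False)

    rmat, pmat = trait_correlations(blups)
    rmat.to_csv(out / "trait_correlations.tsv", sep="\t")
    pmat.to_csv(out / "trait_correlation_pvalues.tsv", sep="\t")

    chrom_lengths = G_i.loci.groupby("chrom", sort=False)["pos"].max().to_dict()
    bulk_rows, track_rows, window_rows, regions = [], [], [], []
    for trait in traits:
        scores = composite_ranking(blups, trait, ranking=cfg.ranking)
        scores = scores[scores.index.isin(rils)]
        pair = select_bulks(scores, cfg.bulk_size, trait=trait)
        bulk_rows.append(pair.to_frame())
        low_tracks = bulk_frequency(G_i, pair.low, pop.reference_parent, cfg.min_calls, "low")
        high_tracks = bulk_frequency(G_i, pair.high, pop.reference_parent, cfg.min_calls, "high")
        gei = blups.gei_blups(trait)
        deltas_t, windows_t, thr_t = {}, {}, {}
        for chrom in G_i.chromosomes():
            delta, windows, thr, regs = scan_chromosome(
                high_tracks[chrom], low_tracks[chrom],
                min_freq=cfg.min_freq, width_bp=cfg.width_bp, step_bp=cfg.step_bp,
                confidence=cfg.confidence, min_run_snps=cfg.min_run_snps,
                min_beyond_fraction=cfg.min_beyond_fraction,
                max_gap_snps=cfg.max_gap_snps,
                chrom_length=int(chrom_lengths[chrom]),
                population=pop.name, trait=trait,
            )
            track_rows.append(
                pd.DataFrame(
                    {
                        "trait": trait, "chrom": chrom, "pos": delta.pos,
                        "freq_low": low_tracks[chrom].freq,
                        "freq_high": high_tracks[chrom].freq,
                        "delta": delta.delta,
                    }
                )
            )
            window_rows.append(
                pd.DataFrame(
                    {
                        "trait": trait, "chrom": chrom, "start": windows.start,
                        "end": windows.end, "mean_delta": windows.mean,
                        "n_snps": windows.count,
                    }
                )
            )
            for reg in regs:
                reg.pve = region_pve(reg, delta, G_i, gei, pop.reference_parent, rils)
            regions.extend(regs)
            deltas_t[chrom], windows_t[chrom] = delta, windows
            if thr is not None:
                thr_t[chrom] = thr
        if cfg.make_plots:
            plots_dir = out / "plots"
            plots_dir.mkdir(exist_ok=True)
            plot_tracks(
                deltas_t, windows_t, thr_t,
                [r for r in regions if r.trait == trait],
                plots_dir / f"{trait}.png",
                title=f"{pop.name} {trait}",
            )
        logger.info("population %s trait %s: %d regions", pop.name, trait, len([r for r in regions if r.trait == trait]))

    pd.concat(bulk_rows, ignore_index=True).to_csv(out / "bulks.tsv", sep="\t", index=False)
    pd.concat(track_rows, ignore_index=True).to_csv(out / "tracks.tsv", sep="\t", index=False)
    pd.concat(window_rows, ignore_index=True).to_csv(out / "windows.tsv", sep="\t", index=False)

    manifest["populations"][pop.name] = {
        "n_samples": len(G.samples),
        "n_rils": len(rils),
        "loci_input": G.n_loci,
        "loci_after_qc": G_f.n_loci,
        "loci_informative": G_i.n_loci,
        "traits": traits,
        "n_regions": len(regions),
        "scans_completed": len(traits),
    }
    return regions, blups, pheno


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full analysis for every configured population and write
    all artifacts under ``cfg.out_dir``."""
    out_root = Path(cfg.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "bsaqtl",
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            k: getattr(cfg, k)
            for k in (
                "bulk_size", "ranking", "max_missing", "max_het", "min_maf",
                "min_calls", "min_freq", "width_bp", "step_bp", "confidence",
                "min_run_snps", "min_beyond_fraction", "max_gap_snps",
            )
        },
        "populations": {},
        "complete": False,
    }
    all_regions: list[list[CandidateRegion]] = []
    blup_tables: dict[str, BlupTable] = {}
    try:
        for pop in cfg.populations:
            pop_dir = out_root / pop.name
            pop_dir.mkdir(parents=True, exist_ok=True)
            regions, blups, _ = _scan_population(pop, cfg, pop_dir, manifest)
            all_regions.append(regions)
            blup_tables[pop.name] = blups
    except Exception:
        manifest["complete"] = False
        with open(out_root / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise

    if len(all_regions) == 2:
        regions = validate_across_populations(all_regions[0], all_regions[1])
    else:
        regions = [r for rs in all_regions for r in rs]
    regions = sorted(regions, key=lambda r: (r.population, r.trait, str(r.chrom), r.start_bp))

    write_regions_tsv(regions, out_root / "regions.tsv")
    write_regions_bed(regions, out_root / "regions.bed")
    manifest["n_regions_total"] = len(regions)
    manifest["n_validated"] = sum(r.validated for r in regions)
    manifest["complete"] = True
    with open(out_root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(regions=regions, manifest=manifest, out_dir=out_root, blups=blup_tables)


def plot_tracks(
    deltas: dict,
    windows: dict,
    thresholds: dict,
    regions: list[CandidateRegion],
    out_path: str,
    title: str = "",
) -> None:
    """One panel per chromosome: delta points vs Mbp, sliding-window mean
    line, symmetric dashed threshold lines and shaded called regions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(deltas)
    n = max(len(chroms), 1)
    ncol = min(5, n)
    nrow = (n + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.2 * nrow), squeeze=False)
    for ax in axes.ravel()[n:]:
        ax.axis("off")
    for ax, chrom in zip(axes.ravel(), chroms):
        d = deltas[chrom]
        ok = ~d.mask
        if not ok.any():
            ax.annotate("no data", (0.5, 0.5), xycoords="axes fraction", ha="center")
        else:
            ax.plot(d.pos[ok] / 1e6, d.delta[ok], ".", ms=1.5, color="0.6", rasterized=True)
            w = windows.get(chrom)
            if w is not None and w.start.size:
                mid = (w.start + w.end) / 2e6
                ax.plot(mid, w.mean, color="tab:blue", lw=1.0)
            thr = thresholds.get(chrom)
            if thr is not None:
                ax.axhline(thr.upper, color="tab:red", ls="--", lw=0.8)
                ax.axhline(-thr.upper, color="tab:red", ls="--", lw=0.8)
        for reg in regions:
            if reg.chrom == chrom:
                ax.axvspan(reg.start_bp / 1e6, reg.end_bp / 1e6, color="gold", alpha=0.3)
        ax.set_ylim(-1, 1)
        ax.set_title(str(chrom), fontsize=8)
    fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
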