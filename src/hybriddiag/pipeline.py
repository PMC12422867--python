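"""End-to-end orchestration: simulate -> mask -> blocks -> triangle -> window -> niche.

A single :class:`RunConfig` carries every seed, simulator parameter and
analysis threshold; the defaults are the thresholds of the underlying
protocol (base/mapping quality 20/20, >= 10 variants and >= 100 bp per
phase block, >= 97% alignment identity, AIM delta = 1.0, 10-km thinning
cells, 2-year / 50%-detection locality retention).  ``run_pipeline``
returns a machine-readable report and is deterministic given the seeds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import blocks as blk
from . import consensus, niche, simulate, triangle, windowhet
from .simulate import genotypes_at

__all__ = ["RunConfig", "run_pipeline", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run (defaults = protocol values)."""

    seed: int = 1
    # simulator
    L: int = 60_000
    divergence: float = 0.03
    polymorphism: float = 0.002
    pedigree_class: str = "F1"
    recomb_rate: float = 1.0
    mean_depth: float = 8.0
    error_rate: float = 0.0
    block_length_mean: float = 340.0
    block_length_sd: float = 120.0
    switch_error_rate: float = 0.0
    mito_length: int = 2000
    # analysis thresholds
    bq_min: int = 20
    mq_min: int = 20
    min_variants: int = 10
    min_length: int = 100
    min_identity: float = 0.97
    delta: float = 1.0
    genotype_error_rate: float = 0.0
    # window heterozygosity
    window_start: int = 0
    window_length: int = 4850
    # checklists / niche
    n_localities: int = 120
    n_years: int = 5
    detection_rate: float = 0.4
    cooccurrence_rate: float = 0.05
    vagrancy_rate: float = 0.05
    cell_km: float = 10.0
    min_years: int = 2
    min_rate: float = 0.5
    retention_window: tuple[str, str] = ("2019-01-01", "2023-05-31")
    absence_years: tuple[int, ...] = (2019, 2020, 2021, 2022, 2023)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    names = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "retention_window" in data:
        data["retention_window"] = tuple(data["retention_window"])
    if "absence_years" in data:
        data["absence_years"] = tuple(data["absence_years"])
    return RunConfig(**data)


def save_config(path, config: RunConfig) -> None:
    data = asdict(config)
    data["retention_window"] = list(data["retention_window"])
    data["absence_years"] = list(data["absence_years"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def _seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Run every stage on one simulated scenario; returns the JSON-able report.

    Stages: species-pair simulation, cross, mitochondrial pileup + masked
    consensus, phase-block simulation + filtering + parental assignment,
    AIM discovery + triangle statistics, window heterozygosity with a
    synthetic-hybrid contrast, and checklist filtering + niche overlap.
    Any stage failure aborts with the stage name and cause.
    """
    report: dict = {"config": asdict(config)}
    report["config"]["retention_window"] = list(config.retention_window)
    report["config"]["absence_years"] = list(config.absence_years)
    seeds = _seeds(config.seed, 8)
    stage = "simulate"
    try:
        panel = simulate.simulate_species_pair(
            L=config.L,
            divergence=config.divergence,
            polymorphism=config.polymorphism,
            seed=seeds[0],
            mito_length=config.mito_length,
        )
        ind = simulate.simulate_cross(
            panel, config.pedigree_class, recomb_rate=config.recomb_rate, seed=seeds[1]
        )
        p1 = simulate.simulate_cross(panel, "P1", seed=seeds[2], sample_id="P1_ref")
        p2 = simulate.simulate_cross(panel, "P2", seed=seeds[3], sample_id="P2_ref")
        report["simulate"] = {
            "L": panel.L,
            "n_fixed_sites": int(len(panel.fixed_sites)),
            "pedigree_class": ind.pedigree_class,
            "mito_source": ind.mito_source,
        }

        stage = "mask"
        mito_ind = simulate.DiploidIndividual(
            sample_id=ind.sample_id + "_mt",
            pedigree_class=ind.pedigree_class,
            hap1=ind.mito_seq,
            hap2=ind.mito_seq,
            truth_tracts=([(0, len(ind.mito_seq), ind.mito_source)],) * 2,
            mito_source=ind.mito_source,
        )
        mito_pileup = simulate.simulate_pileup(
            mito_ind,
            mean_depth=config.mean_depth,
            error_rate=config.error_rate,
            seed=seeds[4],
        )
        masked = consensus.masked_consensus(
            mito_pileup, bq_min=config.bq_min, mq_min=config.mq_min
        )
        report["mask"] = {
            "coverage_fraction": consensus.coverage_fraction(masked),
            "length": len(masked),
        }

        stage = "blocks"
        raw_blocks = simulate.simulate_phase_blocks(
            ind,
            block_length_dist=(config.block_length_mean, config.block_length_sd),
            switch_error_rate=config.switch_error_rate,
            seed=seeds[5],
        )
        kept = blk.filter_blocks(
            raw_blocks, min_variants=config.min_variants, min_length=config.min_length
        )
        blocks_report: dict = {"n_raw": len(raw_blocks), "n_filtered": len(kept)}
        if len(kept) >= 2:
            n, mv, sv, ml, sl = blk.block_summary(kept)
            blocks_report["summary"] = {
                "n": n,
                "mean_variants": mv,
                "sd_variants": sv,
                "mean_length": ml,
                "sd_length": sl,
            }
            panel_seqs = blk.CandidatePanel(
                {panel.label_a: panel.seq_a, panel.label_b: panel.seq_b}
            )
            tally = blk.tally_top_hits(kept, panel_seqs, min_identity=config.min_identity)
            prop, pval = blk.f1_balance_test(tally, panel.label_a, panel.label_b)
            blocks_report["tally"] = {
                str(k): v for k, v in sorted(tally.counts.items(), key=lambda kv: str(kv[0]))
            }
            blocks_report["n_queries"] = tally.n_queries
            blocks_report["parent1_share"] = prop
            blocks_report["balance_p"] = pval
        report["blocks"] = blocks_report

        stage = "triangle"
        positions = panel.fixed_sites
        aims = triangle.discover_aims(
            [genotypes_at(p1, positions)], [genotypes_at(p2, positions)], delta=config.delta
        )
        sample_gts = genotypes_at(ind, aims.positions())
        if config.genotype_error_rate > 0:
            # per-allele substitution error applied to the called genotypes
            rng = np.random.default_rng(seeds[7] + 1)
            bases = "ACGT"
            for pos, (a1, a2) in list(sample_gts.items()):
                gt = [a1, a2]
                for k in range(2):
                    if rng.random() < config.genotype_error_rate:
                        gt[k] = bases[int(rng.integers(0, 4))]
                sample_gts[pos] = (gt[0], gt[1])
        stats = triangle.triangle_stats_for_sample(ind.sample_id, sample_gts, aims)
        report["triangle"] = {
            "n_aims": len(aims),
            "hybrid_index": stats.hybrid_index,
            "interclass_het": stats.interclass_het,
            "n_aims_used": stats.n_aims_used,
            "in_triangle": stats.in_triangle,
        }

        stage = "windowhet"
        wstart = config.window_start
        wend = min(wstart + config.window_length, config.L)
        natural = windowhet.window_from_individual(ind, wstart, wend)
        synthetic = windowhet.make_synthetic_hybrid(
            panel.seq_a[wstart:wend], panel.seq_b[wstart:wend]
        )
        within = windowhet.window_from_individual(p1, wstart, wend)
        report["windowhet"] = {
            "natural_het": windowhet.per_site_heterozygosity(natural),
            "synthetic_het": windowhet.per_site_heterozygosity(synthetic),
            "within_lineage_het": windowhet.per_site_heterozygosity(within),
        }

        stage = "niche"
        table = simulate.simulate_checklists(
            n_localities=config.n_localities,
            n_years=config.n_years,
            detection_rate=config.detection_rate,
            cooccurrence_rate=config.cooccurrence_rate,
            vagrancy_rate=config.vagrancy_rate,
            seed=seeds[6],
        )
        sp_a, sp_b = "species_a", "species_b"
        co = niche.find_cooccurrences(table, sp_a, sp_b)
        fa = niche.filter_localities(
            table, sp_a, window=config.retention_window,
            min_years=config.min_years, min_rate=config.min_rate,
        )
        fb = niche.filter_localities(
            table, sp_b, window=config.retention_window,
            min_years=config.min_years, min_rate=config.min_rate,
        )
        rng_seeds = _seeds(seeds[7], 2)
        pts_a = niche.thin_grid(
            fa.retained[["lon", "lat"]].drop_duplicates(), cell_km=config.cell_km,
            seed=rng_seeds[0],
        )
        pts_b = niche.thin_grid(
            fb.retained[["lon", "lat"]].drop_duplicates(), cell_km=config.cell_km,
            seed=rng_seeds[1],
        )
        niche_report: dict = {
            "cooccurrence": {
                "n_checklists": co.n_checklists,
                "n_localities": co.n_localities,
            },
            "n_presences_a": len(pts_a),
            "n_presences_b": len(pts_b),
            "n_absence_localities_a": len(niche.build_absence_set(table, sp_a, config.absence_years)),
            "n_absence_localities_b": len(niche.build_absence_set(table, sp_b, config.absence_years)),
        }
        if len(pts_a) >= 3 and len(pts_b) >= 3:
            surf = niche.SuitabilitySurface.empty()
            sa = niche.fit_gaussian_envelope(pts_a, surf)
            sb = niche.fit_gaussian_envelope(pts_b, surf)
            abs_a = niche.build_absence_set(table, sp_a, config.absence_years)
            abs_b = niche.build_absence_set(table, sp_b, config.absence_years)
            if len(abs_a) and len(abs_b):
                thr_a = niche.youden_threshold(
                    np.concatenate([sa.sample(pts_a["lon"], pts_a["lat"]),
                                    sa.sample(abs_a["lon"], abs_a["lat"])]),
                    np.concatenate([np.ones(len(pts_a), bool), np.zeros(len(abs_a), bool)]),
                )
                thr_b = niche.youden_threshold(
                    np.concatenate([sb.sample(pts_b["lon"], pts_b["lat"]),
                                    sb.sample(abs_b["lon"], abs_b["lat"])]),
                    np.concatenate([np.ones(len(pts_b), bool), np.zeros(len(abs_b), bool)]),
                )
                overlap = niche.binarize_and_overlap(sa, sb, thr_a, thr_b)
                niche_report["threshold_a"] = thr_a
                niche_report["threshold_b"] = thr_b
                niche_report["overlap_area_km2"] = overlap.area_km2
                niche_report["overlap_centroid"] = (
                    list(overlap.centroid) if overlap.centroid else None
                )
        report["niche"] = niche_report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        save_config(outdir / "config_resolved.yaml", config)
        report["files"] = ["report.json", "config_resolved.yaml"]
    return report
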