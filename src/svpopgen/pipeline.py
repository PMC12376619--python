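"""End-to-end pipeline: simulate/load -> catalog -> scans -> report.

`run_pipeline` executes the toggled stages in dependency order over either a
synthetic cohort or user-supplied files and writes per-stage TSVs plus a
machine-readable summary whose fields mirror the catalog's headline numbers:
per-type counts, sharing classes, control-absent counts, TE fraction, di-SV
count, hotspot count and span, enrichment Z/p and introgression call counts.
Every summary number is an aggregation of a stage table the run also wrote;
given the same inputs, config and seed the whole run is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import catalog as catalog_ops
from . import hotspots as hotspot_scan
from . import introgression as intro_scan
from .io import GenotypeMatrix, PopulationManifest, SVCatalog, write_sv_vcf
from .popgen import allele_freq, carrier_freq, di_scan, wc_fst, windowed_fst
from .simulate import Cohort, SimulationConfig, simulate_cohort

ALL_STAGES = (
    "catalog", "popgen", "hotspots", "enrichment", "introgression",
)

_STAGE_DEPS = {"enrichment": "hotspots"}


def percent(numerator: float, denominator: float, decimals: int = 2) -> float:
    """100*a/b rounded half-even to ``decimals`` places (errors on b == 0)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    q = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_EVEN))


def summarize_counts(counts: Mapping[str, int], total: int | None = None) -> dict[str, Any]:
    """Augment labeled counts with totals and half-even percentages."""
    total = total if total is not None else sum(counts.values())
    out: dict[str, Any] = {"total": total}
    for name, value in counts.items():
        out[name] = int(value)
        out[f"{name}_pct"] = percent(value, total) if total else None
    return out


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    merge_policy: catalog_ops.MergePolicy = field(default_factory=catalog_ops.MergePolicy)
    introgression_policy: intro_scan.IntrogressionPolicy = field(
        default_factory=intro_scan.IntrogressionPolicy
    )
    di_alpha: float = 0.001
    di_mode: str = "pooled"
    hotspot_bandwidth: float = 500_000
    hotspot_grid_step: int = 10_000
    hotspot_n_perm: int = 200
    hotspot_alpha: float = 0.05
    enrichment_draws: int = 1000
    fst_window: int = 50_000
    fst_step: int = 25_000

    def __post_init__(self) -> None:
        for s in self.stages:
            if s not in ALL_STAGES:
                raise ValueError(f"unknown stage {s!r}")
            dep = _STAGE_DEPS.get(s)
            if dep and dep not in self.stages:
                raise ValueError(f"stage {s!r} requires stage {dep!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulate" in raw:
            raw["simulate"] = SimulationConfig(**raw["simulate"])
        if "merge_policy" in raw:
            raw["merge_policy"] = catalog_ops.MergePolicy(**raw["merge_policy"])
        if "introgression_policy" in raw:
            raw["introgression_policy"] = intro_scan.IntrogressionPolicy(
                **raw["introgression_policy"]
            )
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def run_pipeline(
    config: RunConfig,
    cohort: Cohort | None = None,
) -> dict[str, Any]:
    """Execute the toggled stages and write per-stage TSVs plus summary JSON.

    A pre-built cohort may be passed to reuse an existing simulation;
    otherwise one is generated from ``config.simulate`` and ``config.seed``.
    Returns the summary dict (also written to ``out_dir/summary.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    if cohort is None:
        cohort = simulate_cohort(config.simulate, seed=config.seed)
    catalog, matrix, manifest = cohort.catalog, cohort.matrix, cohort.manifest
    chrom_lengths = cohort.config.chromosomes
    summary: dict[str, Any] = {"seed": config.seed, "n_samples": len(matrix.sample_ids)}
    log: list[str] = []

    def _log(stage: str, msg: str) -> None:
        log.append(f"{stage}\t{msg}")

    # --- catalog stage ----------------------------------------------------
    annotated = pd.DataFrame(index=catalog.ids)
    annotated.index.name = "sv_id"
    for rec in catalog:
        pass
    annotated["chrom"] = [r.chrom for r in catalog]
    annotated["start"] = [r.start for r in catalog]
    annotated["end"] = [r.end for r in catalog]
    annotated["svtype"] = [r.svtype for r in catalog]
    annotated["svlen"] = [r.svlen for r in catalog]
    te_series = None
    if "catalog" in config.stages:
        type_counts = catalog.type_counts()
        summary["sv_type_counts"] = summarize_counts(type_counts, total=len(catalog))
        sharing, sharing_counts = catalog_ops.classify_sharing(matrix)
        annotated["sharing_class"] = sharing
        summary["sharing_counts"] = summarize_counts(
            sharing_counts, total=sum(sharing_counts.values())
        )
        ctrl_ids, ctrl_types = catalog_ops.control_absent(matrix, manifest, catalog)
        summary["control_absent"] = {
            "n": len(ctrl_ids),
            "pct_of_catalog": percent(len(ctrl_ids), len(catalog)),
            "by_type": ctrl_types,
        }
        annotated["control_absent"] = [sv in set(ctrl_ids) for sv in catalog.ids]
        annotated["region"] = catalog_ops.annotate_regions(
            catalog, cohort.genes, cohort.exons
        )
        te_series = catalog_ops.tag_te(
            catalog, cohort.repeats, ins_labels=cohort.ins_te_labels
        )
        annotated["te_label"] = te_series
        n_te = int(te_series.notna().sum())
        summary["te"] = {"n": n_te, "pct_of_catalog": percent(n_te, len(catalog))}
        growth = catalog_ops.cumulative_growth(matrix, manifest.merge_order())
        pd.DataFrame(
            {"sample": manifest.merge_order(), "cumulative_svs": growth}
        ).to_csv(out / "growth_curve.tsv", sep="\t", index=False)
        _log("catalog", f"{len(catalog)} SVs, {n_te} TE-derived, "
                        f"{len(ctrl_ids)} control-absent")

    # --- popgen stage -----------------------------------------------------
    if "popgen" in config.stages:
        target = manifest.samples_with_role("target")
        control = manifest.samples_with_role("control")
        annotated["target_af"] = allele_freq(matrix, target)
        annotated["control_af"] = allele_freq(matrix, control)
        annotated["target_carrier"] = carrier_freq(matrix, target)
        comps = wc_fst(matrix, {"target": target, "control": control})
        annotated["fst"] = comps.theta
        win = windowed_fst(
            [r.start for r in catalog], comps,
            window=config.fst_window, step=config.fst_step,
            chroms=[r.chrom for r in catalog],
        )
        win.to_csv(out / "windowed_fst.tsv", sep="\t", index=False)
        di_table = di_scan(matrix, manifest, mode=config.di_mode, alpha=config.di_alpha)
        di_table.to_csv(out / "di_scan.tsv", sep="\t")
        outlier_cols = [c for c in di_table.columns if c.endswith("outlier")]
        n_di = int(di_table[outlier_cols].any(axis=1).sum())
        annotated = annotated.join(di_table)
        summary["di"] = {
            "n_outliers": n_di,
            "pct_of_catalog": percent(n_di, len(catalog)),
            "alpha": config.di_alpha,
            "mean_fst_target_vs_control": float(np.nanmean(comps.theta)),
            "ratio_of_sums_fst": comps.ratio_of_sums(),
        }
        _log("popgen", f"{n_di} di outliers at alpha={config.di_alpha}")

    # --- hotspot stage ----------------------------------------------------
    hotspots = None
    if "hotspots" in config.stages:
        mids = hotspot_scan.sv_midpoints(catalog)
        hotspots = hotspot_scan.call_hotspots(
            mids, chrom_lengths,
            bandwidth=config.hotspot_bandwidth, grid_step=config.hotspot_grid_step,
            n_perm=config.hotspot_n_perm, alpha=config.hotspot_alpha,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        hotspots.table.to_csv(out / "hotspots.tsv", sep="\t", index=False)
        summary["hotspots"] = {
            "n": len(hotspots),
            "total_bp": hotspots.total_bp,
            "n_sv_inside": int(hotspots.table["n_sv"].sum()) if len(hotspots) else 0,
        }
        _log("hotspots", f"{len(hotspots)} hotspots spanning {hotspots.total_bp} bp")

    # --- enrichment stage -------------------------------------------------
    if "enrichment" in config.stages:
        if hotspots is None or len(hotspots) == 0:
            raise RuntimeError("enrichment requires a nonempty hotspot set")
        if te_series is None:
            te_series = catalog_ops.tag_te(
                catalog, cohort.repeats, ins_labels=cohort.ins_te_labels
            )
        te_points: dict[str, list[int]] = {}
        for rec in catalog:
            if te_series[rec.id] is not None:
                te_points.setdefault(rec.chrom, []).append(rec.midpoint)
        te_points_arr = {c: np.array(v) for c, v in te_points.items()}
        enr_rows = []
        # TE-derived SVs are a subset of the catalog: the subset null asks a
        # composition question, free of the density signal hotspots select on
        res_te = hotspot_scan.enrichment_z(
            hotspots, te_points_arr, chrom_lengths,
            n_draws=config.enrichment_draws, seed=int(rng.integers(0, 2**31 - 1)),
            null="subset", all_points=hotspot_scan.sv_midpoints(catalog),
        )
        enr_rows.append(("te_sv_midpoints", res_te))
        cons_points: dict[str, list[int]] = {}
        for chrom, start, end, _ in cohort.conserved:
            cons_points.setdefault(chrom, []).append((start + end) // 2)
        res_cons = hotspot_scan.enrichment_z(
            hotspots, {c: np.array(v) for c, v in cons_points.items()}, chrom_lengths,
            n_draws=config.enrichment_draws, seed=int(rng.integers(0, 2**31 - 1)),
        )
        enr_rows.append(("conserved_elements", res_cons))
        enr_df = pd.DataFrame(
            [
                (name, r.observed, r.null_mean, r.null_sd, r.z, r.p, r.n_draws)
                for name, r in enr_rows
            ],
            columns=["annotation", "observed", "null_mean", "null_sd", "z", "p", "n_draws"],
        )
        enr_df.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        summary["enrichment"] = {
            name: {"observed": r.observed, "z": r.z, "p": r.p} for name, r in enr_rows
        }
        _log("enrichment", f"TE Z={res_te.z:.2f}, conserved Z={res_cons.z:.2f}")

    # --- introgression stage ----------------------------------------------
    if "introgression" in config.stages:
        calls = intro_scan.candidate_introgressed(
            matrix, manifest, config.introgression_policy
        )
        cand_ids = calls.index[calls["candidate"]].tolist()
        val = intro_scan.validate_candidates_with_snps(
            cand_ids, matrix, manifest, cohort.snp_windows
        )
        calls["status"] = "rejected"
        calls.loc[calls["candidate"], "status"] = val["status"].reindex(cand_ids).values
        freqs = intro_scan.introgression_frequencies(cand_ids, matrix, manifest)
        calls.to_csv(out / "introgression_calls.tsv", sep="\t")
        freqs.to_csv(out / "introgression_frequencies.tsv", sep="\t")
        n_validated = int((val["status"] == "validated").sum())
        summary["introgression"] = {
            "n_candidates": len(cand_ids),
            "n_validated": n_validated,
            "n_no_snps": int((val["status"] == "no_snps").sum()),
        }
        _log("introgression", f"{len(cand_ids)} candidates, {n_validated} validated")

    annotated.to_csv(out / "catalog_annotated.tsv", sep="\t")
    write_sv_vcf(catalog, matrix, out / "catalog.vcf", chrom_lengths=chrom_lengths)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(log) + "\n")
    return summary
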