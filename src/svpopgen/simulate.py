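"""Synthetic multi-population SV cohorts with planted truth.

The generator emulates the statistical structure the pipeline's stages
assume, on a compact default genome (3 chromosomes x 50 Mb):

* SV positions: uniform background plus Gaussian position clusters (the
  planted hotspots); SV types drawn from the empirical type mix of a
  long-read cattle catalog (DEL 0.403, INS 0.539, DUP 0.029, INV 0.012,
  BND 0.017).
* Genotypes: the Balding-Nichols model — ancestral ALT frequency
  p ~ Uniform(0.05, 0.95), each population's frequency
  ~ Beta(p(1-F)/F, (1-p)(1-F)/F), individual genotypes ~ Binomial(2, p_pop).
  F is the drift/differentiation parameter; the Weir-Cockerham estimator
  should recover it.
* Selection: a chosen set of SVs gets the target-population ancestral
  frequency shifted by +delta (capped at 1) before the Balding-Nichols
  draw, planting elevated differentiation for the di scan.
* Introgression: a chosen set of SVs is fixed ALT in the donor, absent in
  controls, and segregates at a configured carrier frequency in targets;
  each such SV also gets a flanking-SNP window in which carriers hold one
  donor-derived haplotype.
* Annotations: TE labels with a higher tag probability inside planted
  clusters than outside; matching repeat/gene/conserved-element tracks.

Genotype error and missingness are applied last.  Everything derives from a
single integer seed; identical seeds give identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GenotypeMatrix,
    IntervalSet,
    ManifestEntry,
    PopulationManifest,
    SVCatalog,
    SVRecord,
    write_bed,
    write_manifest,
    write_snp_vcf,
    write_sv_vcf,
)

#: empirical SV type mix of a 222k-SV long-read cattle catalog
DEFAULT_SVTYPE_PROPS = {
    "DEL": 0.403, "INS": 0.539, "DUP": 0.029, "INV": 0.012, "BND": 0.017,
}

#: repeat-class mix among TE-derived SVs (LINE-dominated, as in ruminants)
TE_CLASS_PROPS = {"LINE": 0.81, "SINE": 0.107, "LTR": 0.072, "DNA": 0.011}


@dataclass
class PopulationSpec:
    name: str
    role: str
    n: int


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator with cohort-realistic defaults."""

    chromosomes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 50_000_000, "chr2": 50_000_000, "chr3": 50_000_000}
    )
    n_sv_background: int = 5000
    n_clusters: int = 5
    svs_per_cluster: int = 300
    cluster_sd: float = 100_000.0
    cluster_centers: list[tuple[str, int]] | None = None
    svtype_props: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SVTYPE_PROPS)
    )
    # default cohort mirrors a plateau-cattle scan design: five high-altitude
    # target populations (36 samples), four low-altitude controls (23), and
    # a 12-sample donor species
    populations: list[PopulationSpec] = field(
        default_factory=lambda: [
            PopulationSpec("Yushu", "target", 10),
            PopulationSpec("Langkazi", "target", 7),
            PopulationSpec("Diqing", "target", 10),
            PopulationSpec("Dingjie", "target", 6),
            PopulationSpec("Bailang", "target", 3),
            PopulationSpec("Fuzhou", "control", 10),
            PopulationSpec("Yanbian", "control", 5),
            PopulationSpec("Luxi", "control", 7),
            PopulationSpec("Simmental", "control", 1),
            PopulationSpec("Yak", "donor", 12),
        ]
    )
    fst: float = 0.1
    n_differentiated: int = 50
    delta: float = 0.6
    n_introgressed: int = 50
    introgressed_carrier_freq: float = 0.3
    te_prob_hotspot: float = 0.6
    te_prob_background: float = 0.2
    n_conserved: int = 2000
    conserved_hotspot_weight: float = 0.3
    n_genes: int = 300
    snp_flank: int = 50_000
    snp_density: float = 0.001
    donor_divergence: float = 0.2
    hap_noise: float = 0.02
    missing_rate: float = 0.0
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.svtype_props.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"svtype proportions sum to {total}, expected 1")
        if not (0 < self.fst < 1):
            raise ValueError("fst must be in (0, 1)")
        if not (0 < self.donor_divergence < 1):
            raise ValueError("donor_divergence must be in (0, 1)")
        for name in (
            "n_sv_background", "n_clusters", "svs_per_cluster",
            "n_differentiated", "n_introgressed", "n_conserved", "n_genes",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        n_special = self.n_differentiated + self.n_introgressed
        if n_special > self.total_svs:
            raise ValueError("more planted SVs than SVs simulated")
        if self.n_differentiated > 0 and not any(
            p.role == "target" for p in self.populations
        ):
            raise ValueError("differentiated SVs require a target population")
        if self.n_introgressed > 0:
            roles = {p.role for p in self.populations}
            if not {"target", "control", "donor"} <= roles:
                raise ValueError("introgressed SVs require target, control and donor pops")

    @property
    def total_svs(self) -> int:
        return self.n_sv_background + self.n_clusters * self.svs_per_cluster

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "populations" in raw:
            raw["populations"] = [PopulationSpec(**p) for p in raw["populations"]]
        if "cluster_centers" in raw and raw["cluster_centers"] is not None:
            raw["cluster_centers"] = [tuple(c) for c in raw["cluster_centers"]]
        return cls(**raw)


@dataclass
class Cohort:
    catalog: SVCatalog
    matrix: GenotypeMatrix
    manifest: PopulationManifest
    truth: pd.DataFrame
    config: SimulationConfig
    cluster_centers: list[tuple[str, int]]
    repeats: IntervalSet
    genes: IntervalSet
    exons: IntervalSet
    conserved: IntervalSet
    ins_te_labels: dict[str, str]
    snp_windows: dict[str, tuple[list[str], np.ndarray]]


def _draw_lengths(rng: np.random.Generator, n: int) -> np.ndarray:
    """SV lengths >= 50 bp, lognormal with a few-hundred-bp mode, capped at 100 kb."""
    lens = np.exp(rng.normal(5.7, 1.0, size=n)).astype(np.int64)
    return np.clip(lens, 50, 100_000)


def _balding_nichols_freq(
    rng: np.random.Generator, p: np.ndarray, F: float
) -> np.ndarray:
    scale = (1.0 - F) / F
    return rng.beta(np.clip(p * scale, 1e-9, None), np.clip((1 - p) * scale, 1e-9, None))


def simulate_cohort(config: SimulationConfig, seed: int) -> Cohort:
    """Generate (catalog, genotype matrix, manifest, truth) for one seed."""
    rng = np.random.default_rng(seed)
    chroms = list(config.chromosomes)
    lengths = np.array([config.chromosomes[c] for c in chroms], dtype=np.int64)
    weights = lengths / lengths.sum()

    # --- positions -------------------------------------------------------
    centers = list(config.cluster_centers or [])
    while len(centers) < config.n_clusters:
        ci = rng.choice(len(chroms), p=weights)
        margin = min(5_000_000, lengths[ci] // 10)
        centers.append((chroms[ci], int(rng.integers(margin, lengths[ci] - margin))))
    centers = centers[: config.n_clusters]

    pos_chrom: list[str] = []
    pos: list[int] = []
    cluster_of: list[int] = []
    for k, (chrom, center) in enumerate(centers):
        L = config.chromosomes[chrom]
        draws = rng.normal(center, config.cluster_sd, size=config.svs_per_cluster)
        draws = np.clip(np.round(draws), 1, L).astype(np.int64)
        pos_chrom.extend([chrom] * config.svs_per_cluster)
        pos.extend(draws.tolist())
        cluster_of.extend([k] * config.svs_per_cluster)
    bg_ci = rng.choice(len(chroms), size=config.n_sv_background, p=weights)
    for ci in bg_ci:
        pos_chrom.append(chroms[ci])
        pos.append(int(rng.integers(1, lengths[ci] + 1)))
        cluster_of.append(-1)

    n_sv = len(pos)
    types = rng.choice(
        list(config.svtype_props), size=n_sv, p=list(config.svtype_props.values())
    )
    svlens = _draw_lengths(rng, n_sv)

    order = np.lexsort((np.asarray(pos), np.asarray(pos_chrom)))
    records: list[SVRecord] = []
    truth_rows = []
    width = max(5, len(str(n_sv)))
    for rank, i in enumerate(order):
        chrom, start, svtype, svlen = pos_chrom[i], int(pos[i]), str(types[i]), int(svlens[i])
        L = config.chromosomes[chrom]
        sv_id = f"SV{rank + 1:0{width}d}"
        if svtype in ("INS", "BND"):
            end = start
        else:
            # anchor convention: END = POS + svlen; shift off the telomere
            start = max(1, min(start, L - svlen))
            svlen = min(svlen, L - start)
            end = start + svlen
        mate_chrom = mate_pos = None
        if svtype == "BND":
            mi = rng.choice(len(chroms), p=weights)
            mate_chrom = chroms[mi]
            mate_pos = int(rng.integers(1, lengths[mi] + 1))
            svlen = 0
        records.append(
            SVRecord(
                id=sv_id, chrom=chrom, start=start, end=end, svtype=svtype,
                svlen=svlen, mate_chrom=mate_chrom, mate_pos=mate_pos,
            )
        )
        truth_rows.append({"sv_id": sv_id, "cluster": cluster_of[i]})
    catalog = SVCatalog(records)
    truth = pd.DataFrame(truth_rows).set_index("sv_id")
    truth["hotspot_member"] = truth["cluster"] >= 0

    # --- planted differentiated / introgressed sets ----------------------
    special = rng.choice(
        n_sv, size=config.n_differentiated + config.n_introgressed, replace=False
    )
    diff_idx = set(special[: config.n_differentiated].tolist())
    intro_idx = set(special[config.n_differentiated :].tolist())
    truth["differentiated"] = [i in diff_idx for i in range(n_sv)]
    truth["introgressed"] = [i in intro_idx for i in range(n_sv)]

    # --- manifest ---------------------------------------------------------
    entries = []
    sample_pops: list[tuple[str, PopulationSpec]] = []
    idx = 0
    for spec in config.populations:
        for j in range(spec.n):
            sid = f"{spec.name}_{j + 1:02d}"
            entries.append(ManifestEntry(sid, spec.name, spec.role, idx))
            sample_pops.append((sid, spec))
            idx += 1
    manifest = PopulationManifest(entries)
    sample_ids = [s for s, _ in sample_pops]

    # --- genotypes --------------------------------------------------------
    p_anc = rng.uniform(0.05, 0.95, size=n_sv)
    truth["ancestral_p"] = p_anc
    gt = np.zeros((n_sv, len(sample_ids)), dtype=np.int8)
    is_diff = truth["differentiated"].to_numpy()
    p_target = np.minimum(1.0, p_anc + np.where(is_diff, config.delta, 0.0))
    col = 0
    for spec in config.populations:
        base = p_target if spec.role == "target" else p_anc
        pop_freq = _balding_nichols_freq(rng, base, config.fst)
        draws = rng.binomial(2, pop_freq[:, None], size=(n_sv, spec.n))
        gt[:, col : col + spec.n] = draws.astype(np.int8)
        col += spec.n

    # monomorphic redraw (capped): keep the cohort polymorphic at most SVs
    roles = np.array([spec.role for _, spec in sample_pops])
    for _ in range(20):
        mono = ~(gt > 0).any(axis=1)
        mono &= ~truth["introgressed"].to_numpy()
        if not mono.any():
            break
        idxs = np.flatnonzero(mono)
        p_anc[idxs] = rng.uniform(0.05, 0.95, size=len(idxs))
        col = 0
        for spec in config.populations:
            base = p_anc[idxs].copy()
            if spec.role == "target":
                base = np.minimum(1.0, base + np.where(is_diff[idxs], config.delta, 0.0))
            pop_freq = _balding_nichols_freq(rng, base, config.fst)
            gt[np.ix_(idxs, np.arange(col, col + spec.n))] = rng.binomial(
                2, pop_freq[:, None], size=(len(idxs), spec.n)
            ).astype(np.int8)
            col += spec.n
        truth["ancestral_p"] = p_anc

    # introgressed overwrite: donor fixed, control absent, target segregating
    donor_cols = np.flatnonzero(roles == "donor")
    control_cols = np.flatnonzero(roles == "control")
    target_cols = np.flatnonzero(roles == "target")
    q_intro = 1.0 - math.sqrt(1.0 - config.introgressed_carrier_freq)
    for i in sorted(intro_idx):
        gt[i, donor_cols] = HOM_ALT
        gt[i, control_cols] = HOM_REF
        for _ in range(100):
            draws = rng.binomial(2, q_intro, size=len(target_cols)).astype(np.int8)
            if (draws > 0).any():
                break
        gt[i, target_cols] = draws

    # --- noise ------------------------------------------------------------
    truth["gt_error"] = 0
    if config.error_rate > 0:
        flip = rng.random(gt.shape) < config.error_rate
        shift = rng.integers(1, 3, size=gt.shape)
        gt = np.where(flip, (gt + shift) % 3, gt).astype(np.int8)
        truth["gt_error"] = flip.sum(axis=1)
    if config.missing_rate > 0:
        gt = np.where(rng.random(gt.shape) < config.missing_rate, MISSING, gt).astype(np.int8)
    matrix = GenotypeMatrix(catalog.ids, sample_ids, gt)

    # --- TE labels and repeat track ---------------------------------------
    te_classes = list(TE_CLASS_PROPS)
    te_p = list(TE_CLASS_PROPS.values())
    te_labels: list[str | None] = []
    repeat_rows = []
    ins_te_labels: dict[str, str] = {}
    for rec, in_hot in zip(catalog, truth["hotspot_member"].to_numpy()):
        prob = config.te_prob_hotspot if in_hot else config.te_prob_background
        label = None
        if rec.svtype in ("DEL", "DUP", "INS") and rng.random() < prob:
            label = str(rng.choice(te_classes, p=te_p))
            if rec.svtype == "INS":
                ins_te_labels[rec.id] = label
            else:
                # repeat interval reciprocally overlapping the SV span (>= 90%)
                pad = max(0, int(0.05 * (rec.end - rec.start + 1)))
                repeat_rows.append((rec.chrom, max(1, rec.start + pad), rec.end - pad, label))
        te_labels.append(label)
    truth["te_label"] = te_labels
    # background repeats unrelated to any SV
    for _ in range(500):
        ci = rng.choice(len(chroms), p=weights)
        start = int(rng.integers(1, lengths[ci] - 10_000))
        repeat_rows.append((chroms[ci], start, start + int(rng.integers(100, 8000)),
                            str(rng.choice(te_classes, p=te_p))))
    repeats = IntervalSet(repeat_rows)

    # --- gene / conserved tracks -----------------------------------------
    gene_rows, exon_rows = [], []
    for g in range(config.n_genes):
        ci = rng.choice(len(chroms), p=weights)
        g_len = int(rng.integers(5_000, 80_000))
        g_start = int(rng.integers(1, max(2, lengths[ci] - g_len)))
        g_end = g_start + g_len - 1
        gene_rows.append((chroms[ci], g_start, g_end, f"gene{g + 1}"))
        n_ex = int(rng.integers(2, 8))
        ex_starts = np.sort(rng.integers(g_start, g_end - 200, size=n_ex))
        for es in ex_starts:
            exon_rows.append((chroms[ci], int(es), min(g_end, int(es) + int(rng.integers(80, 300))),
                              f"gene{g + 1}"))
    genes, exons = IntervalSet(gene_rows), IntervalSet(exon_rows)

    cons_rows = []
    hot_spans = [
        (chrom, center - 2 * config.cluster_sd, center + 2 * config.cluster_sd)
        for chrom, center in centers
    ]
    while len(cons_rows) < config.n_conserved:
        ci = rng.choice(len(chroms), p=weights)
        start = int(rng.integers(1, lengths[ci] - 200))
        in_hot = any(
            c == chroms[ci] and lo <= start <= hi for c, lo, hi in hot_spans
        )
        if in_hot and rng.random() > config.conserved_hotspot_weight:
            continue
        cons_rows.append((chroms[ci], start, start + int(rng.integers(20, 200))))
    conserved = IntervalSet(cons_rows)

    # --- flanking SNP windows for introgressed SVs ------------------------
    snp_windows: dict[str, tuple[list[str], np.ndarray]] = {}
    intro_ids = truth.index[truth["introgressed"]].tolist()
    for sv_id in intro_ids:
        row = matrix.sv_row(sv_id)
        carriers = [
            s for s in sample_ids
            if manifest[s].role == "target" and row[matrix.sample_indices([s])[0]] in (HET, HOM_ALT)
        ]
        child_seed = int(rng.integers(0, 2**31 - 1))
        snp_windows[sv_id] = simulate_flanking_snps(
            config, manifest, carriers, introgressed=True, seed=child_seed
        )
    return Cohort(
        catalog=catalog, matrix=matrix, manifest=manifest, truth=truth,
        config=config, cluster_centers=centers, repeats=repeats, genes=genes,
        exons=exons, conserved=conserved, ins_te_labels=ins_te_labels,
        snp_windows=snp_windows,
    )


def simulate_flanking_snps(
    config: SimulationConfig,
    manifest: PopulationManifest,
    carriers: Sequence[str],
    introgressed: bool,
    seed: int,
) -> tuple[list[str], np.ndarray]:
    """Simulate SNP genotypes in an SV's flanking window.

    Two haplotype pools diverge at each site with probability
    ``donor_divergence``; every drawn haplotype additionally mutates per
    site with probability ``hap_noise``.  Donor-role samples draw two donor
    haplotypes; for an introgressed SV each carrier draws one donor and one
    cattle haplotype; everyone else draws two cattle haplotypes.  Returns
    (sample_ids, samples x sites dosages).
    """
    rng = np.random.default_rng(seed)
    n_sites = max(1, int(round(2 * config.snp_flank * config.snp_density)))
    cattle_hap = np.zeros(n_sites, dtype=np.int8)
    donor_hap = (rng.random(n_sites) < config.donor_divergence).astype(np.int8)
    carriers = set(carriers)
    sample_ids = manifest.sample_ids
    geno = np.zeros((len(sample_ids), n_sites), dtype=np.int8)

    def draw(base: np.ndarray) -> np.ndarray:
        noise = rng.random(n_sites) < config.hap_noise
        return np.where(noise, 1 - base, base).astype(np.int8)

    for i, s in enumerate(sample_ids):
        role = manifest[s].role
        if role == "donor":
            hap1, hap2 = draw(donor_hap), draw(donor_hap)
        elif introgressed and s in carriers:
            hap1, hap2 = draw(donor_hap), draw(cattle_hap)
        else:
            hap1, hap2 = draw(cattle_hap), draw(cattle_hap)
        geno[i] = hap1 + hap2
    return list(sample_ids), geno


def write_fixtures(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort as standard files, all re-readable by the io module.

    Emits the multi-sample SV VCF, manifest TSV, repeat/gene/exon/conserved
    BEDs, INS TE-label sidecar TSV, truth TSV and one SNP VCF per
    introgressed SV's flanking window.  Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["sv_vcf"] = out / "cohort.sv.vcf"
    write_sv_vcf(cohort.catalog, cohort.matrix, paths["sv_vcf"],
                 chrom_lengths=cohort.config.chromosomes)
    paths["manifest"] = out / "manifest.tsv"
    write_manifest(cohort.manifest, paths["manifest"])
    for name, ivs in (
        ("repeats", cohort.repeats), ("genes", cohort.genes),
        ("exons", cohort.exons), ("conserved", cohort.conserved),
    ):
        paths[name] = out / f"{name}.bed"
        write_bed(ivs, paths[name])
    paths["ins_te"] = out / "ins_te_labels.tsv"
    with open(paths["ins_te"], "w") as fh:
        fh.write("sv_id\tte_label\n")
        for sv_id, label in cohort.ins_te_labels.items():
            fh.write(f"{sv_id}\t{label}\n")
    paths["truth"] = out / "truth.tsv"
    cohort.truth.to_csv(paths["truth"], sep="\t")
    snp_dir = out / "snp_windows"
    snp_dir.mkdir(exist_ok=True)
    for sv_id, (sample_ids, geno) in cohort.snp_windows.items():
        rec = cohort.catalog[sv_id]
        lo = max(1, rec.start - cohort.config.snp_flank)
        positions = np.linspace(lo, rec.end + cohort.config.snp_flank, geno.shape[1])
        positions = np.unique(positions.astype(np.int64))
        if len(positions) < geno.shape[1]:  # degenerate tiny windows
            positions = np.arange(lo, lo + geno.shape[1])
        p = snp_dir / f"{sv_id}.snps.vcf"
        write_snp_vcf(sample_ids, rec.chrom, positions, geno, p)
        paths[f"snps_{sv_id}"] = p
    return paths
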