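#!/usr/bin/env python
"""Rebuild the nonredundant cohort catalog from per-sample call sets.

Emulates the discovery stage: each sample's call set is its carried SVs
with caller-style breakpoint jitter; a three-caller consensus is shown for
one sample, then all samples are merged back into a nonredundant catalog
whose size should match the original cohort catalog.  The catalog is then
classified (sharing classes, cumulative growth) and annotated (genic
region, TE tag by 80% reciprocal overlap, control-absence filter).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from svpopgen.catalog import (
    MergePolicy,
    annotate_regions,
    classify_sharing,
    consensus_filter,
    control_absent,
    cumulative_growth,
    merge_samples,
    tag_te,
)
from svpopgen.io import SVCatalog, SVRecord, read_bed, read_manifest, read_sv_vcf

COHORT = Path("results/cohort")
OUT = Path("results/catalog")


def jittered(rec: SVRecord, rng, new_id: str, max_jitter: int = 100) -> SVRecord:
    shift = int(rng.integers(-max_jitter, max_jitter + 1))
    start = max(1, rec.start + shift)
    end = start + rec.svlen if rec.svtype in ("DEL", "DUP", "INV") else start
    return SVRecord(id=new_id, chrom=rec.chrom, start=start, end=end,
                    svtype=rec.svtype, svlen=rec.svlen,
                    mate_chrom=rec.mate_chrom, mate_pos=rec.mate_pos)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    catalog, matrix = read_sv_vcf(COHORT / "cohort.sv.vcf")
    manifest = read_manifest(COHORT / "manifest.tsv")
    rng = np.random.default_rng(2024)
    presence = matrix.presence()

    # --- three-caller consensus for the first sample -----------------------
    first = matrix.sample_ids[0]
    carried = [rec for i, rec in enumerate(catalog) if presence[i, 0]]
    callsets = {}
    for caller, dropout in [("cutesv", 0.05), ("svim", 0.10), ("sniffles", 0.10)]:
        keep = rng.random(len(carried)) > dropout
        callsets[caller] = SVCatalog(
            [jittered(r, rng, f"{caller}_{k}") for k, (r, kp) in
             enumerate(zip(carried, keep)) if kp]
        )
    consensus = consensus_filter(callsets, MergePolicy(caller_priority=tuple(callsets)))
    print(f"consensus for {first}: {len(carried)} true SVs; "
          f"{', '.join(f'{c}={len(s)}' for c, s in callsets.items())}; "
          f">=2-caller consensus keeps {len(consensus)}")

    # --- cross-sample merge ------------------------------------------------
    per_sample = {}
    for j, sample in enumerate(matrix.sample_ids):
        recs = [jittered(rec, rng, f"{sample}_{i}")
                for i, rec in enumerate(catalog) if presence[i, j]]
        per_sample[sample] = SVCatalog(recs)
    merged, merged_presence = merge_samples(per_sample, order=manifest.merge_order())
    n_carried = int(presence.any(axis=1).sum())
    print(f"merged {sum(len(s) for s in per_sample.values())} per-sample calls "
          f"into {len(merged)} nonredundant SVs "
          f"(cohort catalog has {n_carried} SVs with >= 1 carrier)")

    growth = cumulative_growth(merged_presence, manifest.merge_order())
    pd.DataFrame({"sample": manifest.merge_order(), "cumulative_svs": growth}).to_csv(
        OUT / "growth_curve.tsv", sep="\t", index=False)
    print(f"growth curve: {growth[0]} SVs after first sample, "
          f"{growth[-1]} after all {len(growth)} (wrote growth_curve.tsv)")

    # --- sharing classes, control absence, annotation ----------------------
    sharing, counts = classify_sharing(matrix)
    print("sharing classes:", ", ".join(f"{k}={v}" for k, v in counts.items()))

    ctrl_ids, ctrl_types = control_absent(matrix, manifest, catalog)
    print(f"control-absent SVs (0/0 in every called low-altitude sample): "
          f"{len(ctrl_ids)} ({', '.join(f'{k}={v}' for k, v in sorted(ctrl_types.items()))})")

    genes = read_bed(COHORT / "genes.bed")
    exons = read_bed(COHORT / "exons.bed")
    repeats = read_bed(COHORT / "repeats.bed")
    ins_side = pd.read_csv(COHORT / "ins_te_labels.tsv", sep="\t")
    ins_labels = dict(zip(ins_side["sv_id"], ins_side["te_label"]))
    regions = annotate_regions(catalog, genes, exons)
    te = tag_te(catalog, repeats, ins_labels=ins_labels)
    print("region labels:", ", ".join(f"{k}={v}" for k, v in
                                      regions.value_counts().items()))
    print(f"TE-derived SVs: {int(te.notna().sum())} "
          f"({100 * te.notna().mean():.1f}% of catalog)")

    table = pd.DataFrame({
        "sharing_class": sharing,
        "control_absent": pd.Series({s: s in set(ctrl_ids) for s in catalog.ids}),
        "region": regions,
        "te_label": te,
    })
    table.index.name = "sv_id"
    table.to_csv(OUT / "catalog_annotated.tsv", sep="\t")
    print(f"wrote {OUT}/catalog_annotated.tsv")


if __name__ == "__main__":
    main()
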