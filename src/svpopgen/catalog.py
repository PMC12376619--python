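"""Cohort SV catalog construction and annotation.

Builds a nonredundant multi-sample catalog from per-caller and per-sample
call sets by single-linkage breakpoint clustering (calls of the same type on
the same chromosome link when both breakpoints lie within a maximum distance,
500 bp by default), then classifies and annotates it: sample-sharing classes,
cumulative discovery curve, genic-region labels, transposable-element tagging
by reciprocal overlap, and the control-population absence filter used to
nominate altitude-restricted SVs.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    SPAN_TYPES,
    GenotypeMatrix,
    IntervalSet,
    PopulationManifest,
    SVCatalog,
    SVRecord,
)


@dataclass
class MergePolicy:
    """Breakpoint-clustering policy for consensus and cross-sample merging."""

    max_breakpoint_dist: int = 500
    require_same_type: bool = True
    min_caller_support: int = 2
    caller_priority: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.max_breakpoint_dist < 0:
            raise ValueError("max_breakpoint_dist must be >= 0")
        if self.min_caller_support < 1:
            raise ValueError("min_caller_support must be >= 1")


SHARING_CLASSES = ("shared", "major", "minor", "singleton")


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _group_key(rec: SVRecord, same_type: bool) -> tuple:
    key: tuple = (rec.chrom,)
    if same_type:
        key += (rec.svtype,)
    if rec.svtype == "BND":
        key += (rec.mate_chrom,)
    return key


def _single_linkage_clusters(
    records: Sequence[SVRecord], max_dist: int, require_same_type: bool = True
) -> list[list[int]]:
    """Single-linkage clusters of record indices.

    Two calls link when they share chromosome (and type, and BND mate
    chromosome) and both breakpoints lie within ``max_dist``:
    |start1-start2| <= d and |end1-end2| <= d.  Links are transitive, so a
    chain of nearby calls collapses into one cluster even when its extremes
    are farther apart than d.
    """
    groups: dict[tuple, list[int]] = {}
    for i, rec in enumerate(records):
        groups.setdefault(_group_key(rec, require_same_type), []).append(i)
    clusters: list[list[int]] = []
    for idxs in groups.values():
        idxs = sorted(idxs, key=lambda i: (records[i].start, records[i].end))
        uf = _UnionFind(len(idxs))
        # sorted by start: only pairs with start diff <= d can link
        lo = 0
        for j in range(len(idxs)):
            sj = records[idxs[j]].start
            while records[idxs[lo]].start < sj - max_dist:
                lo += 1
            for k in range(lo, j):
                ri, rj = records[idxs[k]], records[idxs[j]]
                if abs(ri.start - rj.start) <= max_dist and abs(ri.end - rj.end) <= max_dist:
                    uf.union(k, j)
        members: dict[int, list[int]] = {}
        for k in range(len(idxs)):
            members.setdefault(uf.find(k), []).append(idxs[k])
        clusters.extend(members.values())
    return clusters


def consensus_filter(
    callsets: Mapping[str, SVCatalog], policy: MergePolicy | None = None
) -> SVCatalog:
    """Retain one sample's SVs supported by >= min_caller_support callers.

    ``callsets`` maps caller name -> that caller's catalog for one sample.
    Same-type calls whose breakpoints cluster within the policy distance
    across enough distinct callers are kept; the representative is the call
    from the first supporting caller in priority order (default: the order
    callers are given), and its caller-support count is recorded under
    ``info["SUPP"]``.
    """
    policy = policy or MergePolicy()
    callers = list(callsets)
    if len(callers) < policy.min_caller_support:
        raise ValueError(
            f"{len(callers)} caller(s) provided but min_caller_support="
            f"{policy.min_caller_support}"
        )
    priority = list(policy.caller_priority or callers)
    records: list[SVRecord] = []
    origin: list[str] = []
    for caller in callers:
        for rec in callsets[caller]:
            records.append(rec)
            origin.append(caller)
    clusters = _single_linkage_clusters(
        records, policy.max_breakpoint_dist, policy.require_same_type
    )
    kept: list[SVRecord] = []
    for cluster in clusters:
        supp = {origin[i] for i in cluster}
        if len(supp) < policy.min_caller_support:
            continue
        rep_idx = min(
            cluster,
            key=lambda i: (priority.index(origin[i]), records[i].start, records[i].id),
        )
        rep = records[rep_idx]
        info = dict(rep.info)
        info["SUPP"] = str(len(supp))
        kept.append(
            SVRecord(
                id=rep.id, chrom=rep.chrom, start=rep.start, end=rep.end,
                svtype=rep.svtype, svlen=rep.svlen,
                mate_chrom=rep.mate_chrom, mate_pos=rep.mate_pos, info=info,
            )
        )
    kept.sort(key=lambda r: (r.chrom, r.start, r.end, r.svtype, r.id))
    return SVCatalog(kept)


def merge_samples(
    callsets: Mapping[str, SVCatalog],
    policy: MergePolicy | None = None,
    order: Sequence[str] | None = None,
) -> tuple[SVCatalog, GenotypeMatrix]:
    """Merge per-sample catalogs into one nonredundant catalog + presence matrix.

    Cross-sample calls cluster by the same single-linkage rule as
    :func:`consensus_filter`.  Each cluster yields one representative record
    — the call from the earliest sample in ``order`` (leftmost on ties) —
    and the presence matrix marks every contributing sample as a carrier
    (HET code).  Output ids are ``SV<n>`` in (chrom, start) order, which is
    stable for a documented sample order.
    """
    policy = policy or MergePolicy()
    order = list(order or callsets)
    unknown = set(callsets) - set(order)
    if unknown:
        raise ValueError(f"samples missing from order: {sorted(unknown)}")
    sample_rank = {s: i for i, s in enumerate(order)}
    records: list[SVRecord] = []
    origin: list[str] = []
    for sample in order:
        if sample not in callsets:
            continue
        for rec in callsets[sample]:
            records.append(rec)
            origin.append(sample)
    clusters = _single_linkage_clusters(
        records, policy.max_breakpoint_dist, policy.require_same_type
    )
    reps: list[tuple[SVRecord, set[str]]] = []
    for cluster in clusters:
        rep_idx = min(
            cluster,
            key=lambda i: (sample_rank[origin[i]], records[i].start, records[i].id),
        )
        carriers = {origin[i] for i in cluster}
        reps.append((records[rep_idx], carriers))
    reps.sort(key=lambda rc: (rc[0].chrom, rc[0].start, rc[0].end, rc[0].svtype))
    width = max(5, len(str(len(reps))))
    out_records: list[SVRecord] = []
    gt = np.full((len(reps), len(order)), HOM_REF, dtype=np.int8)
    for i, (rep, carriers) in enumerate(reps):
        new_id = f"SV{i + 1:0{width}d}"
        out_records.append(
            SVRecord(
                id=new_id, chrom=rep.chrom, start=rep.start, end=rep.end,
                svtype=rep.svtype, svlen=rep.svlen,
                mate_chrom=rep.mate_chrom, mate_pos=rep.mate_pos,
                info=dict(rep.info),
            )
        )
        for s in carriers:
            gt[i, sample_rank[s]] = HET
    catalog = SVCatalog(out_records)
    return catalog, GenotypeMatrix(catalog.ids, order, gt)


def cumulative_growth(
    matrix: GenotypeMatrix, order: Sequence[str] | None = None
) -> list[int]:
    """Cumulative nonredundant SV count as samples are added in ``order``.

    Entry k is the number of catalog SVs carried by at least one of the
    first k+1 samples; the final entry equals the number of SVs with any
    carrier.
    """
    order = list(order or matrix.sample_ids)
    unknown = set(order) - set(matrix.sample_ids)
    if unknown:
        raise ValueError(f"unknown samples in order: {sorted(unknown)}")
    presence = matrix.presence()
    idx = matrix.sample_indices(order)
    seen = np.zeros(len(matrix.sv_ids), dtype=bool)
    counts = []
    for j in idx:
        seen |= presence[:, j]
        counts.append(int(seen.sum()))
    return counts


def classify_sharing(
    matrix: GenotypeMatrix, n_samples: int | None = None
) -> tuple[pd.Series, dict[str, int]]:
    """Classify each SV as shared / major / minor / singleton by carrier count.

    shared: carried by all N samples; major: by >= ceil(N/2) but not all;
    singleton: by exactly one; minor: the rest.  SVs with zero carriers get
    a null class and are excluded from the counts (the classes partition
    SVs with >= 1 carrier).
    """
    n = n_samples if n_samples is not None else len(matrix.sample_ids)
    if n <= 0:
        raise ValueError("cohort size must be positive")
    n_major = math.ceil(n / 2)
    carriers = matrix.presence().sum(axis=1)
    labels = []
    for c in carriers:
        if c == 0:
            labels.append(None)
        elif c == n:
            labels.append("shared")
        elif c == 1:
            labels.append("singleton")
        elif c >= n_major:
            labels.append("major")
        else:
            labels.append("minor")
    series = pd.Series(labels, index=matrix.sv_ids, name="sharing_class")
    counts = {cls: int((series == cls).sum()) for cls in SHARING_CLASSES}
    return series, counts


def major_threshold(n_samples: int) -> int:
    """Carrier-count threshold for the major class: ceil(N/2)."""
    return math.ceil(n_samples / 2)


def control_absent(
    matrix: GenotypeMatrix,
    manifest: PopulationManifest,
    catalog: SVCatalog | None = None,
    control_pops: Sequence[str] | None = None,
) -> tuple[list[str], dict[str, int]]:
    """SVs homozygous-reference in every called control sample.

    Controls are the manifest's control-role samples, optionally restricted
    to ``control_pops``.  Missing control genotypes are ignored.  Returns
    the qualifying SV ids (restricted to SVs with at least one carrier in
    the cohort) and, when a catalog is supplied, counts per SV type.
    """
    controls = manifest.samples_with_role("control")
    if control_pops is not None:
        controls = [s for s in controls if manifest[s].population in control_pops]
    if not controls:
        raise ValueError("no control samples in manifest")
    idx = matrix.sample_indices(controls)
    sub = matrix.gt[:, idx]
    all_ref = ((sub == HOM_REF) | (sub == MISSING)).all(axis=1)
    any_carrier = matrix.presence().any(axis=1)
    keep = all_ref & any_carrier
    ids = [sv for sv, k in zip(matrix.sv_ids, keep) if k]
    type_counts: dict[str, int] = {}
    if catalog is not None:
        type_counts = dict(Counter(catalog[sv].svtype for sv in ids))
    return ids, type_counts


REGION_LABELS = ("exonic", "intronic", "upstream_downstream", "intergenic")


def annotate_regions(
    catalog: SVCatalog,
    genes: IntervalSet,
    exons: IntervalSet,
    flank: int = 5000,
) -> pd.Series:
    """Assign each SV a genic-region label with exonic-first precedence.

    exonic > intronic > upstream_downstream (within ``flank`` bp of a gene
    span) > intergenic.  Span types (DEL/DUP/INV) classify by any overlap of
    their interval; INS and BND by their point position.  An empty gene set
    yields all-intergenic.
    """
    labels = []
    for rec in catalog:
        if rec.svtype in SPAN_TYPES:
            start, end = rec.start, rec.end
        else:
            start = end = rec.start
        if exons.overlapping(rec.chrom, start, end):
            labels.append("exonic")
        elif genes.overlapping(rec.chrom, start, end):
            labels.append("intronic")
        elif genes.overlapping(rec.chrom, start - flank, end + flank):
            labels.append("upstream_downstream")
        else:
            labels.append("intergenic")
    return pd.Series(labels, index=catalog.ids, name="region")


def reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    """Minimum of the two overlap fractions for 1-based inclusive intervals."""
    ov = min(a_end, b_end) - max(a_start, b_start) + 1
    if ov <= 0:
        return 0.0
    len_a = a_end - a_start + 1
    len_b = b_end - b_start + 1
    return min(ov / len_a, ov / len_b)


def tag_te(
    catalog: SVCatalog,
    repeats: IntervalSet,
    ins_labels: Mapping[str, str] | None = None,
    min_reciprocal: float = 0.8,
) -> pd.Series:
    """Label SVs derived from transposable elements / repeats.

    DEL and DUP spans are tagged when some repeat interval reciprocally
    overlaps them by >= ``min_reciprocal`` (both fractions, 80% by default);
    the label is the class of the best-overlapping repeat, or "repeat" when
    the repeat track carries no class.  INS labels come from the sidecar
    mapping (sequence-alignment tagging of inserted sequence happens
    upstream).  Untagged SVs get None.
    """
    if not (0 < min_reciprocal <= 1):
        raise ValueError("min_reciprocal must be in (0, 1]")
    ins_labels = ins_labels or {}
    labels: list[str | None] = []
    for rec in catalog:
        label: str | None = None
        if rec.svtype in ("DEL", "DUP"):
            best = 0.0
            for r_start, r_end, r_label in repeats.overlapping(rec.chrom, rec.start, rec.end):
                ro = reciprocal_overlap(rec.start, rec.end, r_start, r_end)
                if ro >= min_reciprocal and ro > best:
                    best = ro
                    label = r_label if r_label is not None else "repeat"
        elif rec.svtype == "INS":
            label = ins_labels.get(rec.id)
        labels.append(label)
    return pd.Series(labels, index=catalog.ids, name="te_label", dtype=object)
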