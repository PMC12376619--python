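"""Data model and file I/O for structural-variant cohorts.

The in-memory model is VCF-centric: all coordinates are 1-based inclusive.
BED input (0-based half-open) is converted at the boundary.  An SV is a
single record with a type drawn from {DEL, INS, DUP, INV, BND}; insertions
and break-ends are point events (``end == start``).  SV lengths are stored
unsigned; the VCF sign convention (negative SVLEN for deletions) is
re-applied on write.

Genotypes live in a dense :class:`GenotypeMatrix` with four states; missing
(``./.``) is a first-class state that every downstream allele count excludes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pysam
from intervaltree import IntervalTree

# Genotype codes used throughout the package.
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

GT_LABELS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}

SV_TYPES = ("DEL", "INS", "DUP", "INV", "BND")
#: SV types that span an interval on the reference (vs point events).
SPAN_TYPES = frozenset({"DEL", "DUP", "INV"})

MIN_SV_LEN = 50

ROLES = ("target", "control", "donor")


class SVFormatError(ValueError):
    """Raised on malformed SV input (bad VCF record, bad BED line...)."""


@dataclass
class SVRecord:
    """One structural variant in 1-based coordinates.

    Follows the VCF anchor-base convention for span types (DEL/DUP/INV):
    ``start`` is the anchor POS, ``end`` the INFO/END base, and
    ``svlen = end - start`` is the affected length, so END = POS + |SVLEN|
    exactly as htslib derives it for symbolic alleles.  INS and BND are
    point events (``end == start``); an INS ``svlen`` is the inserted
    length.
    """

    id: str
    chrom: str
    start: int
    end: int
    svtype: str
    svlen: int
    mate_chrom: str | None = None
    mate_pos: int | None = None
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise SVFormatError(f"unknown SVTYPE {self.svtype!r} for record {self.id}")
        if self.end < self.start:
            raise SVFormatError(f"end < start for record {self.id}")
        if self.svtype == "BND":
            if self.mate_chrom is None or self.mate_pos is None:
                raise SVFormatError(f"BND record {self.id} lacks mate coordinates")
        elif self.svlen < MIN_SV_LEN:
            raise SVFormatError(
                f"record {self.id}: SVLEN {self.svlen} < minimum {MIN_SV_LEN} bp"
            )
        if self.svtype in SPAN_TYPES and self.end - self.start != self.svlen:
            raise SVFormatError(
                f"record {self.id}: END - POS = {self.end - self.start} "
                f"does not match SVLEN {self.svlen}"
            )
        if self.svtype in ("INS", "BND") and self.end != self.start:
            raise SVFormatError(f"point-type record {self.id} must have end == start")

    @property
    def midpoint(self) -> int:
        """Midpoint used for hotspot scans: floor((start+end)/2), start for points."""
        if self.svtype in SPAN_TYPES:
            return (self.start + self.end) // 2
        return self.start


class SVCatalog:
    """Ordered, id-unique collection of :class:`SVRecord`."""

    def __init__(self, records: Iterable[SVRecord] = ()) -> None:
        self.records: list[SVRecord] = list(records)
        self._by_id = {r.id: r for r in self.records}
        if len(self._by_id) != len(self.records):
            raise SVFormatError("duplicate SV ids in catalog")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SVRecord]:
        return iter(self.records)

    def __getitem__(self, sv_id: str) -> SVRecord:
        return self._by_id[sv_id]

    def __contains__(self, sv_id: str) -> bool:
        return sv_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.chrom, None)
        return list(seen)

    def type_counts(self) -> dict[str, int]:
        out = {t: 0 for t in SV_TYPES}
        for r in self.records:
            out[r.svtype] += 1
        return out


class GenotypeMatrix:
    """SV x sample diploid genotypes in {HOM_REF, HET, HOM_ALT, MISSING}."""

    def __init__(self, sv_ids: Sequence[str], sample_ids: Sequence[str], gt: np.ndarray):
        gt = np.asarray(gt, dtype=np.int8)
        if gt.shape != (len(sv_ids), len(sample_ids)):
            raise ValueError(
                f"genotype array shape {gt.shape} does not match "
                f"{len(sv_ids)} SVs x {len(sample_ids)} samples"
            )
        bad = ~np.isin(gt, (HOM_REF, HET, HOM_ALT, MISSING))
        if bad.any():
            raise ValueError("genotype values outside the 4-state set")
        self.sv_ids = list(sv_ids)
        self.sample_ids = list(sample_ids)
        self.gt = gt
        self._sv_index = {s: i for i, s in enumerate(self.sv_ids)}
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.gt.shape

    def sv_row(self, sv_id: str) -> np.ndarray:
        return self.gt[self._sv_index[sv_id]]

    def sample_indices(self, sample_ids: Iterable[str]) -> np.ndarray:
        return np.array([self._sample_index[s] for s in sample_ids], dtype=int)

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_indices(sample_ids)
        return GenotypeMatrix(self.sv_ids, list(sample_ids), self.gt[:, idx])

    def presence(self) -> np.ndarray:
        """Boolean SV x sample carrier mask (>= 1 ALT allele)."""
        return (self.gt == HET) | (self.gt == HOM_ALT)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sv_ids == other.sv_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.gt, other.gt)
        )


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    population: str
    role: str
    order_index: int


class PopulationManifest:
    """sample -> (population, role, merge-order index)."""

    def __init__(self, entries: Iterable[ManifestEntry]):
        self.entries: dict[str, ManifestEntry] = {}
        for e in entries:
            if e.sample_id in self.entries:
                raise SVFormatError(f"duplicate sample id {e.sample_id!r} in manifest")
            if e.role not in ROLES:
                raise SVFormatError(
                    f"unknown role {e.role!r} for sample {e.sample_id!r}; "
                    f"expected one of {ROLES}"
                )
            self.entries[e.sample_id] = e

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.entries

    def __getitem__(self, sample_id: str) -> ManifestEntry:
        return self.entries[sample_id]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.entries)

    def samples_with_role(self, role: str) -> list[str]:
        return [s for s, e in self.entries.items() if e.role == role]

    def samples_in_population(self, population: str) -> list[str]:
        return [s for s, e in self.entries.items() if e.population == population]

    def populations(self, role: str | None = None) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries.values():
            if role is None or e.role == role:
                seen.setdefault(e.population, None)
        return list(seen)

    def merge_order(self) -> list[str]:
        return sorted(self.entries, key=lambda s: (self.entries[s].order_index, s))


class IntervalSet:
    """Labelled genomic intervals in 1-based inclusive coordinates.

    Overlap queries are served by per-chromosome interval trees.  Intervals
    are kept as given — overlapping intervals are not merged.
    """

    def __init__(self, intervals: Iterable[tuple] = ()):
        # each item: (chrom, start, end[, label])
        self.intervals: list[tuple[str, int, int, str | None]] = []
        for iv in intervals:
            chrom, start, end = iv[0], int(iv[1]), int(iv[2])
            label = iv[3] if len(iv) > 3 else None
            if start > end:
                raise SVFormatError(f"interval start > end: {chrom}:{start}-{end}")
            self.intervals.append((chrom, start, end, label))
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end, label in self.intervals:
            # IntervalTree is half-open; store [start, end+1)
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, label)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def overlapping(self, chrom: str, start: int, end: int) -> list[tuple[int, int, str | None]]:
        """All intervals overlapping [start, end] on chrom (1-based inclusive)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.begin, iv.end - 1, iv.data) for iv in tree.overlap(start, end + 1))

    def total_bp(self) -> int:
        return sum(end - start + 1 for _, start, end, _ in self.intervals)


# ---------------------------------------------------------------------------
# VCF I/O


def _gt_code(gt_tuple) -> int:
    if gt_tuple is None:
        return MISSING
    alleles = [a for a in gt_tuple if a is not None]
    if len(alleles) != 2 or any(a not in (0, 1) for a in alleles):
        return MISSING
    n_alt = sum(alleles)
    return (HOM_REF, HET, HOM_ALT)[n_alt]


def read_sv_vcf(path: str | Path) -> tuple[SVCatalog, GenotypeMatrix]:
    """Read a multi-sample SV VCF into a catalog and genotype matrix.

    Requires INFO/SVTYPE on every record; INFO/SVLEN and INFO/END are used
    when present (INS and BND fall back to ``end = start``).  Genotypes that
    are absent or not diploid biallelic are recorded as MISSING; a summary
    warning reports how many cells were affected.
    """
    path = str(path)
    records: list[SVRecord] = []
    gt_rows: list[list[int]] = []
    n_malformed = 0
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for i, rec in enumerate(vf.fetch() if vf.index is not None else vf):
            info = dict(rec.info)
            svtype = info.pop("SVTYPE", None)
            if svtype is None:
                raise SVFormatError(
                    f"record {rec.chrom}:{rec.pos} (#{i + 1}) lacks INFO/SVTYPE"
                )
            svlen = info.pop("SVLEN", None)
            if isinstance(svlen, (tuple, list)):
                svlen = svlen[0]
            start = rec.pos  # pysam .pos is 1-based
            if svtype in ("INS", "BND"):
                end = start
            else:
                # htslib resolves INFO/END and SVLEN into .stop (END = POS + |SVLEN|)
                end = rec.stop
            if svlen is None:
                svlen = end - start if svtype in SPAN_TYPES else 0
            svlen = abs(int(svlen))
            if svtype in SPAN_TYPES:
                end = start + svlen  # keep END consistent when only SVLEN was given
            mate_chrom = info.pop("CHR2", None)
            mate_pos = info.pop("POS2", None)
            if mate_pos is not None:
                mate_pos = int(mate_pos)
            extra = {}
            for k, v in info.items():
                if isinstance(v, (tuple, list)):
                    v = ",".join(str(x) for x in v)
                extra[k] = str(v)
            sv_id = rec.id or f"sv_{i + 1}"
            records.append(
                SVRecord(
                    id=sv_id, chrom=rec.chrom, start=start, end=end,
                    svtype=svtype, svlen=svlen,
                    mate_chrom=mate_chrom, mate_pos=mate_pos, info=extra,
                )
            )
            row = []
            for s in samples:
                code = _gt_code(rec.samples[s].get("GT"))
                row.append(code)
            # count cells that were present but unusable
            for s in samples:
                raw = rec.samples[s].get("GT")
                if raw is not None and _gt_code(raw) == MISSING and any(
                    a is not None for a in raw
                ):
                    n_malformed += 1
            gt_rows.append(row)
    if n_malformed:
        warnings.warn(f"{n_malformed} malformed genotype cells set to missing")
    catalog = SVCatalog(records)
    gt = (
        np.array(gt_rows, dtype=np.int8)
        if gt_rows
        else np.zeros((0, len(samples)), dtype=np.int8)
    )
    return catalog, GenotypeMatrix(catalog.ids, samples, gt)


_BASE_INFO_HEADERS = [
    ('SVTYPE', '1', 'String', 'Type of structural variant'),
    ('SVLEN', '1', 'Integer', 'Length of structural variant'),
    ('END', '1', 'Integer', 'End position of structural variant'),
    ('CHR2', '1', 'String', 'Mate chromosome for BND'),
    ('POS2', '1', 'Integer', 'Mate position for BND'),
]


def write_sv_vcf(
    catalog: SVCatalog,
    matrix: GenotypeMatrix,
    path: str | Path,
    chrom_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write catalog + genotypes as VCF 4.2 with symbolic ALT alleles.

    DEL records carry negative SVLEN per the VCF sign convention; all other
    types carry the unsigned length.  INFO/END is derived by htslib from
    SVLEN (END = POS + |SVLEN| for span types, END = POS for points), which
    matches the record's ``end`` by the data-model invariant.  Extra
    ``info`` entries are emitted as String INFO fields declared on the fly.
    """
    if catalog.ids != matrix.sv_ids:
        raise ValueError("catalog and matrix SV ids do not match")
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    for key, num, typ, desc in _BASE_INFO_HEADERS:
        header.info.add(key, num, typ, desc)
    extra_keys: dict[str, None] = {}
    for rec in catalog:
        for k in rec.info:
            extra_keys.setdefault(k, None)
    for k in extra_keys:
        header.info.add(k, "1", "String", "Passthrough annotation")
    header.formats.add("GT", "1", "String", "Genotype")
    chroms = catalog.chromosomes()
    if chrom_lengths:
        for c in chrom_lengths:
            if c not in chroms:
                chroms.append(c)
    for c in chroms:
        if chrom_lengths and c in chrom_lengths:
            header.contigs.add(c, length=int(chrom_lengths[c]))
        else:
            header.contigs.add(c)
    for s in matrix.sample_ids:
        header.add_sample(s)
    gt_tuples = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1), MISSING: (None, None)}
    # htslib warns once about the transient END=0 state of a fresh record
    verbosity = pysam.set_verbosity(0)
    try:
        _write_records(catalog, matrix, path, header, gt_tuples)
    finally:
        pysam.set_verbosity(verbosity)


def _write_records(catalog, matrix, path, header, gt_tuples) -> None:
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i, rec in enumerate(catalog):
            vrec = out.new_record(
                contig=rec.chrom,
                start=rec.start - 1,
                alleles=("N", f"<{rec.svtype}>"),
                id=rec.id,
            )
            vrec.info["SVTYPE"] = rec.svtype
            if rec.svtype == "BND":
                vrec.info["CHR2"] = rec.mate_chrom
                vrec.info["POS2"] = rec.mate_pos
            elif rec.svtype == "DEL":
                vrec.info["SVLEN"] = -rec.svlen
            else:
                vrec.info["SVLEN"] = rec.svlen
            for k, v in rec.info.items():
                vrec.info[k] = str(v)
            for j, s in enumerate(matrix.sample_ids):
                vrec.samples[s]["GT"] = gt_tuples[int(matrix.gt[i, j])]
            out.write(vrec)


def write_snp_vcf(
    sample_ids: Sequence[str],
    chrom: str,
    positions: Sequence[int],
    genotypes: np.ndarray,
    path: str | Path,
) -> None:
    """Write a biallelic SNP VCF (A->T at every site) from a dosage matrix.

    ``genotypes`` is samples x sites with values in {0, 1, 2, -1}.
    """
    genotypes = np.asarray(genotypes)
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    header.formats.add("GT", "1", "String", "Genotype")
    header.contigs.add(chrom)
    for s in sample_ids:
        header.add_sample(s)
    gt_tuples = {0: (0, 0), 1: (0, 1), 2: (1, 1), -1: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, pos in enumerate(positions):
            vrec = out.new_record(contig=chrom, start=int(pos) - 1, alleles=("A", "T"))
            for i, s in enumerate(sample_ids):
                vrec.samples[s]["GT"] = gt_tuples[int(genotypes[i, j])]
            out.write(vrec)


def read_snp_vcf(path: str | Path) -> tuple[list[str], np.ndarray, list[int]]:
    """Read a biallelic SNP VCF into (sample_ids, samples x sites dosages, positions)."""
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        positions: list[int] = []
        cols: list[list[int]] = []
        for rec in vf:
            positions.append(rec.pos)
            col = []
            for s in samples:
                code = _gt_code(rec.samples[s].get("GT"))
                col.append(-1 if code == MISSING else code)
            cols.append(col)
    geno = np.array(cols, dtype=np.int8).T if cols else np.zeros((len(samples), 0), np.int8)
    return samples, geno, positions


# ---------------------------------------------------------------------------
# BED and manifest I/O


def read_bed(path: str | Path) -> IntervalSet:
    """Read BED3+ into an IntervalSet (0-based half-open -> 1-based inclusive).

    Column 4, when present, becomes the interval label.  Lines with
    ``start >= end`` in BED coordinates are rejected with a message naming
    the line.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise SVFormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, bed_start, bed_end = fields[0], int(fields[1]), int(fields[2])
            if bed_start >= bed_end:
                raise SVFormatError(
                    f"{path}:{lineno}: BED start {bed_start} >= end {bed_end}"
                )
            label = fields[3] if len(fields) > 3 else None
            intervals.append((chrom, bed_start + 1, bed_end, label))
    return IntervalSet(intervals)


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    """Write an IntervalSet as BED (internal 1-based inclusive -> 0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, start, end, label in intervals:
            cols = [chrom, str(start - 1), str(end)]
            if label is not None:
                cols.append(str(label))
            fh.write("\t".join(cols) + "\n")


def read_manifest(path: str | Path, roles_optional: bool = False) -> PopulationManifest:
    """Read a sample manifest TSV with columns sample_id, population, role[, order_index].

    With ``roles_optional`` a missing role column defaults every sample to
    the target role.  Order index defaults to file order.
    """
    entries = []
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip().lower() for f in fields]
                if "sample_id" not in header or "population" not in header:
                    raise SVFormatError(
                        f"{path}: manifest must have sample_id and population columns"
                    )
                if "role" not in header and not roles_optional:
                    raise SVFormatError(
                        f"{path}: manifest lacks a role column (pass roles_optional=True "
                        "to default all samples to target)"
                    )
                continue
            row = dict(zip(header, fields))
            role = row.get("role", "target") or "target"
            order = int(row["order_index"]) if row.get("order_index") else len(entries)
            entries.append(
                ManifestEntry(
                    sample_id=row["sample_id"].strip(),
                    population=row["population"].strip(),
                    role=role.strip(),
                    order_index=order,
                )
            )
    return PopulationManifest(entries)


def write_manifest(manifest: PopulationManifest, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpopulation\trole\torder_index\n")
        for e in manifest.entries.values():
            fh.write(f"{e.sample_id}\t{e.population}\t{e.role}\t{e.order_index}\n")
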