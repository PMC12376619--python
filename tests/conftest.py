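import numpy as np
import pytest

from svpopgen.io import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GenotypeMatrix,
    ManifestEntry,
    PopulationManifest,
    SVCatalog,
    SVRecord,
)


def make_record(id="sv1", chrom="chr1", start=1000, end=1100, svtype="DEL", svlen=None,
                **kwargs):
    if svlen is None:
        svlen = end - start if svtype in ("DEL", "DUP", "INV") else 100
    if svtype in ("INS", "BND"):
        end = start
    if svtype == "BND":
        kwargs.setdefault("mate_chrom", "chr2")
        kwargs.setdefault("mate_pos", 500)
        svlen = 0
    return SVRecord(id=id, chrom=chrom, start=start, end=end, svtype=svtype,
                    svlen=svlen, **kwargs)


def make_matrix(rows, sample_ids=None):
    """rows: dict sv_id -> list of genotype codes."""
    sv_ids = list(rows)
    gt = np.array([rows[s] for s in sv_ids], dtype=np.int8)
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(gt.shape[1])]
    return GenotypeMatrix(sv_ids, sample_ids, gt)


def make_manifest(spec):
    """spec: list of (sample_id, population, role)."""
    return PopulationManifest(
        ManifestEntry(s, p, r, i) for i, (s, p, r) in enumerate(spec)
    )


@pytest.fixture
def toy_catalog():
    return SVCatalog(
        [
            make_record("del1", "chr1", 1000, 1100, "DEL"),
            make_record("ins1", "chr1", 5000, 5000, "INS", svlen=300),
            make_record("inv1", "chr2", 2000, 4000, "INV"),
            make_record("dup1", "chr2", 9000, 9600, "DUP"),
            make_record("bnd1", "chr3", 100, 100, "BND"),
        ]
    )


@pytest.fixture
def toy_matrix(toy_catalog):
    gt = np.array(
        [
            [HOM_REF, HET, HOM_ALT, MISSING],
            [HET, HET, HET, HET],
            [HOM_REF, HOM_REF, HOM_REF, HOM_REF],
            [HOM_ALT, HOM_ALT, HOM_ALT, HOM_ALT],
            [HOM_REF, MISSING, HET, HOM_REF],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(toy_catalog.ids, ["s1", "s2", "s3", "s4"], gt)
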