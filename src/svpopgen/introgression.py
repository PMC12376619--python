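"""Donor-introgression classification and haplotype-tree validation.

An SV is a *candidate* introgression when it is fixed among called donor
(yak) genotypes, absent (homozygous reference) from every called control
(low-altitude) genotype, carried by at least one target sample, and
adequately genotyped in every role group.  Candidates are *validated* by the
haplotype signal in the SV's 50-kb flanking window: an allele-sharing (IBS)
distance matrix over flanking SNPs feeds a neighbor-joining tree, and the
candidate passes when the smallest clade spanning all donors contains every
target carrier and no non-carrier cattle sample — the algorithmic form of
"the carrier haplotypes cluster with the donor".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as SkbioDistanceMatrix
from skbio.tree import TreeNode, nj

from .io import HOM_REF, MISSING, GenotypeMatrix, PopulationManifest
from .popgen import allele_freq, carrier_freq


@dataclass
class IntrogressionPolicy:
    """Thresholds for the donor-fixed / control-absent candidate rule."""

    donor_fixed_min: float = 1.0
    control_max: float = 0.0
    target_min_carriers: int = 1
    max_missing_frac: float = 0.2

    def __post_init__(self) -> None:
        if not (0 <= self.donor_fixed_min <= 1):
            raise ValueError("donor_fixed_min must be in [0, 1]")
        if not (0 <= self.control_max <= 1):
            raise ValueError("control_max must be in [0, 1]")
        if self.target_min_carriers < 0:
            raise ValueError("target_min_carriers must be >= 0")
        if not (0 <= self.max_missing_frac < 1):
            raise ValueError("max_missing_frac must be in [0, 1)")


def candidate_introgressed(
    matrix: GenotypeMatrix,
    manifest: PopulationManifest,
    policy: IntrogressionPolicy | None = None,
) -> pd.DataFrame:
    """Classify every SV against the donor-fixed / control-absent rule.

    "Fixed in the donor" means ALT allele frequency among *called* donor
    genotypes >= ``donor_fixed_min`` (a donor with a missing call does not
    break fixation); "absent from controls" means control ALT frequency <=
    ``control_max`` (0 by default: every called control is 0/0).  Each role
    group must have a called-genotype fraction >= 1 - max_missing_frac.

    Returns a per-SV frame with candidate flag, role-group frequencies and
    the reason for rejection.
    """
    policy = policy or IntrogressionPolicy()
    roles = {}
    for role in ("target", "control", "donor"):
        samples = manifest.samples_with_role(role)
        if not samples:
            raise ValueError(f"manifest has no {role}-role samples")
        roles[role] = samples
    donor_af = allele_freq(matrix, roles["donor"])
    control_af = allele_freq(matrix, roles["control"])
    target_sub = matrix.subset_samples(roles["target"]).gt
    target_carriers = ((target_sub == 1) | (target_sub == 2)).sum(axis=1)
    target_af = allele_freq(matrix, roles["target"])

    called_ok = np.ones(len(matrix.sv_ids), dtype=bool)
    for role, samples in roles.items():
        sub = matrix.subset_samples(samples).gt
        called_frac = (sub != MISSING).mean(axis=1)
        called_ok &= called_frac >= 1 - policy.max_missing_frac

    donor_fixed = np.nan_to_num(donor_af, nan=0.0) >= policy.donor_fixed_min
    control_absent = np.nan_to_num(control_af, nan=0.0) <= policy.control_max
    target_ok = target_carriers >= policy.target_min_carriers
    candidate = donor_fixed & control_absent & target_ok & called_ok

    reason = np.full(len(matrix.sv_ids), "", dtype=object)
    reason[~called_ok] = "missingness"
    reason[called_ok & ~donor_fixed] = "donor_not_fixed"
    reason[called_ok & donor_fixed & ~control_absent] = "control_carrier"
    reason[called_ok & donor_fixed & control_absent & ~target_ok] = "no_target_carrier"
    df = pd.DataFrame(
        {
            "candidate": candidate,
            "donor_af": donor_af,
            "control_af": control_af,
            "target_af": target_af,
            "target_carriers": target_carriers,
            "reject_reason": reason,
        },
        index=matrix.sv_ids,
    )
    df.index.name = "sv_id"
    return df


@dataclass
class DistanceMatrix:
    """Symmetric allele-sharing distances with per-pair site counts."""

    ids: list[str]
    values: np.ndarray
    n_sites: int = 0
    pair_sites: np.ndarray | None = None

    def to_skbio(self) -> SkbioDistanceMatrix:
        return SkbioDistanceMatrix(self.values, ids=self.ids)


def allele_sharing_distance(
    genotypes: np.ndarray, sample_ids: Sequence[str]
) -> DistanceMatrix:
    """1 - mean IBS over jointly called sites, for diploid dosage genotypes.

    ``genotypes`` is samples x sites with dosages {0, 1, 2} and -1 for
    missing.  Per-site IBS between dosages g, h is (2 - |g - h|)/2, i.e.
    1 for identical genotypes, 0.5 for one shared allele, 0 for opposite
    homozygotes.  A pair with no jointly called site is an error naming the
    pair.
    """
    G = np.asarray(genotypes, dtype=float)
    if G.ndim != 2 or G.shape[0] != len(sample_ids):
        raise ValueError("genotypes must be samples x sites matching sample_ids")
    n = G.shape[0]
    called = G >= 0
    Gm = np.where(called, G, 0.0)
    D = np.zeros((n, n))
    pair_sites = np.zeros((n, n), dtype=int)
    for i in range(n):
        joint = called[i] & called
        n_joint = joint.sum(axis=1)
        diff = np.abs(Gm[i] - Gm) * joint
        with np.errstate(divide="ignore", invalid="ignore"):
            d = (diff.sum(axis=1) / n_joint) / 2.0
        zero = n_joint == 0
        if zero.any():
            j = int(np.flatnonzero(zero)[0])
            if j != i:
                raise ValueError(
                    f"samples {sample_ids[i]!r} and {sample_ids[j]!r} share no called site"
                )
        D[i] = np.where(n_joint > 0, d, 0.0)
        pair_sites[i] = n_joint
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0  # guard symmetry against float noise
    return DistanceMatrix(
        ids=list(sample_ids), values=D, n_sites=G.shape[1], pair_sites=pair_sites
    )


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree (Saitou-Nei) from an allele-sharing distance matrix.

    NJ is consistent on additive distances: it recovers the generating tree
    topology and branch lengths exactly.  Requires >= 3 taxa.
    """
    if len(dm.ids) < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    return nj(dm.to_skbio())


def validate_candidate(
    tree: TreeNode,
    carriers: Sequence[str],
    donors: Sequence[str],
    others: Sequence[str],
) -> str:
    """"validated" iff some edge separates carriers + donors from all
    non-carrier cattle.

    Every edge of the unrooted tree bipartitions the leaves (both
    orientations are considered).  The candidate is validated when the
    smallest side containing every donor *and* every carrier excludes all
    samples in ``others`` (non-carrier cattle) — i.e. the carrier
    haplotypes cluster with the donor, with no low-altitude or non-carrier
    sample inside that cluster.  Note a carrier holding one donor and one
    cattle haplotype typically attaches as sister to the donor clade, so
    the donor-only clade is allowed to be a strict subset of the validated
    side.
    """
    leaf_names = {leaf.name for leaf in tree.tips()}
    carriers, donors, others = set(carriers), set(donors), set(others)
    missing = (carriers | donors) - leaf_names
    if missing:
        raise ValueError(f"samples absent from tree: {sorted(missing)}")
    all_leaves = frozenset(leaf_names)
    group = carriers | donors
    sides: list[frozenset] = []
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            clade = frozenset([node.name])
        else:
            clade = frozenset(leaf.name for leaf in node.tips())
        sides.append(clade)
        sides.append(all_leaves - clade)
    best: frozenset | None = None
    for s in sides:
        if group <= s and (best is None or len(s) < len(best)):
            best = s
    assert best is not None  # the full leaf set always contains the group
    if not (best & others):
        return "validated"
    return "rejected"


def introgression_frequencies(
    call_ids: Sequence[str],
    matrix: GenotypeMatrix,
    manifest: PopulationManifest,
) -> pd.DataFrame:
    """Per-population ALT and carrier frequencies for the called SVs."""
    idx = [matrix.sv_ids.index(s) for s in call_ids]
    rows = {}
    for pop in manifest.populations():
        samples = manifest.samples_in_population(pop)
        rows[f"{pop}_alt_freq"] = allele_freq(matrix, samples)[idx]
        rows[f"{pop}_carrier_freq"] = carrier_freq(matrix, samples)[idx]
    df = pd.DataFrame(rows, index=list(call_ids))
    df.index.name = "sv_id"
    return df


def validate_candidates_with_snps(
    candidate_ids: Sequence[str],
    matrix: GenotypeMatrix,
    manifest: PopulationManifest,
    snp_windows: Mapping[str, tuple[Sequence[str], np.ndarray]],
    min_carrier_validated: bool = True,
) -> pd.DataFrame:
    """Run the NJ-tree validation for each candidate SV.

    ``snp_windows`` maps sv_id -> (sample_ids, samples x sites dosage matrix)
    for the SV's flanking window.  Carriers are target-role samples carrying
    the SV; "others" are all non-carrier cattle (target + control roles) in
    the window.  Returns a frame with per-SV status in
    {validated, rejected, no_snps}.
    """
    targets = set(manifest.samples_with_role("target"))
    controls = set(manifest.samples_with_role("control"))
    donors = set(manifest.samples_with_role("donor"))
    statuses = []
    for sv_id in candidate_ids:
        if sv_id not in snp_windows:
            statuses.append("no_snps")
            continue
        sample_ids, geno = snp_windows[sv_id]
        row = matrix.sv_row(sv_id)
        carrier_mask = {
            s: (row[matrix.sample_indices([s])[0]] in (1, 2)) for s in sample_ids
        }
        carriers = [s for s in sample_ids if s in targets and carrier_mask[s]]
        window_donors = [s for s in sample_ids if s in donors]
        others = [
            s for s in sample_ids
            if s in (targets | controls) and not carrier_mask[s]
        ]
        if not carriers or len(sample_ids) < 3:
            statuses.append("rejected")
            continue
        dm = allele_sharing_distance(np.asarray(geno), list(sample_ids))
        tree = nj_tree(dm)
        statuses.append(validate_candidate(tree, carriers, window_donors, others))
    out = pd.DataFrame({"status": statuses}, index=list(candidate_ids))
    out.index.name = "sv_id"
    return out
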