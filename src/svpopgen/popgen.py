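"""Allele frequencies, Weir-Cockerham FST, windowed FST, and the di scan.

Per-site FST uses the Weir & Cockerham (1984) variance-component estimator
for diploid data: among-population (a), among-individual-within-population
(b) and within-individual (c) components computed from per-population sample
sizes, ALT allele frequencies and observed heterozygosities, with
theta_hat = a / (a + b + c).  Negative estimates are retained — clamping
would bias the genome-wide moments that the di statistic standardizes by.

The di statistic for a focal (target) group sums, over comparison
populations j, the genome-wide-standardized pairwise FST:

    d_i(s) = sum_j [theta_ij(s) - mu_ij] / sigma_ij

where mu_ij and sigma_ij are the mean and SD of theta_ij across all SVs.
Outliers are called by a one-sided upper Z test on di itself (elevated
differentiation in the focal group).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import HET, HOM_ALT, MISSING, GenotypeMatrix, PopulationManifest


def _counts(gt: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SV (n_called, n_het, n_hom_alt) for a genotype sub-matrix."""
    called = (gt != MISSING).sum(axis=1)
    het = (gt == HET).sum(axis=1)
    hom_alt = (gt == HOM_ALT).sum(axis=1)
    return called, het, hom_alt


def allele_freq(matrix: GenotypeMatrix, samples: Sequence[str] | None = None) -> np.ndarray:
    """Per-SV ALT allele frequency over the given samples (all by default).

    Missing genotypes are excluded from both numerator and denominator; an
    SV with no called genotype gets NaN.
    """
    gt = matrix.gt if samples is None else matrix.subset_samples(list(samples)).gt
    called, het, hom_alt = _counts(gt)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = (het + 2.0 * hom_alt) / (2.0 * called)
    return np.where(called > 0, freq, np.nan)


def carrier_freq(
    matrix: GenotypeMatrix,
    samples: Sequence[str] | None = None,
    as_percent: bool = False,
) -> np.ndarray:
    """Per-SV fraction of called samples carrying >= 1 ALT allele.

    With ``as_percent`` the fraction is reported as an integer percentage
    (round-half-to-even), the convention used for headline carrier rates
    like "13 out of 36 (36%)".
    """
    gt = matrix.gt if samples is None else matrix.subset_samples(list(samples)).gt
    called, het, hom_alt = _counts(gt)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (het + hom_alt) / called
    frac = np.where(called > 0, frac, np.nan)
    if as_percent:
        return np.round(frac * 100)
    return frac


@dataclass
class FstComponents:
    """Weir-Cockerham variance components per SV (arrays align with sv_ids)."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    sv_ids: list[str] = field(default_factory=list)

    @property
    def theta(self) -> np.ndarray:
        """a/(a+b+c); NaN where the denominator is <= 0 (monomorphic sites)."""
        denom = self.a + self.b + self.c
        with np.errstate(divide="ignore", invalid="ignore"):
            th = self.a / denom
        return np.where(denom > 0, th, np.nan)

    def ratio_of_sums(self) -> float:
        """Multi-SV estimate sum(a)/sum(a+b+c) over sites with defined components."""
        denom = np.nansum(self.a + self.b + self.c)
        if denom <= 0:
            return float("nan")
        return float(np.nansum(self.a) / denom)


def wc_fst(
    matrix: GenotypeMatrix, pops: Mapping[str, Sequence[str]]
) -> FstComponents:
    """Weir & Cockerham (1984) per-SV components for >= 2 populations.

    ``pops`` maps population name -> sample ids.  Populations with no called
    genotype at an SV drop out of that SV's estimate; SVs with fewer than
    two informative populations, or monomorphic across all of them, get
    zero components (theta NaN).
    """
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    n_sv = len(matrix.sv_ids)
    pop_names = list(pops)
    P = len(pop_names)
    n = np.zeros((P, n_sv))     # called diploids per pop
    p = np.zeros((P, n_sv))     # ALT freq per pop
    h = np.zeros((P, n_sv))     # observed het proportion per pop
    for k, name in enumerate(pop_names):
        sub = matrix.subset_samples(list(pops[name])).gt
        called, het, hom_alt = _counts(sub)
        n[k] = called
        with np.errstate(divide="ignore", invalid="ignore"):
            p[k] = np.where(called > 0, (het + 2.0 * hom_alt) / (2.0 * called), 0.0)
            h[k] = np.where(called > 0, het / called, 0.0)
    r = (n > 0).sum(axis=0).astype(float)        # informative populations per SV
    n_sum = n.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = n_sum / r
        n_c = (n_sum - (n**2).sum(axis=0) / n_sum) / (r - 1)
        pbar = (n * p).sum(axis=0) / n_sum
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / n_sum
        a = (nbar / n_c) * (
            s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2.0
    ok = (r >= 2) & (nbar > 1) & np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    mono = (pbar <= 0) | (pbar >= 1)
    a = np.where(ok & ~mono, a, 0.0)
    b = np.where(ok & ~mono, b, 0.0)
    c = np.where(ok & ~mono, c, 0.0)
    return FstComponents(a=a, b=b, c=c, sv_ids=list(matrix.sv_ids))


def wc_fst_site(gt_by_pop: Sequence[Sequence[int]]) -> FstComponents:
    """Single-site convenience wrapper: genotype code arrays, one per population."""
    max_n = max(len(g) for g in gt_by_pop)
    gt = np.full((len(gt_by_pop), 1, max_n), MISSING, dtype=np.int8)
    pops = {}
    sample_ids = []
    for k, genos in enumerate(gt_by_pop):
        ids = [f"p{k}_s{i}" for i in range(max_n)]
        sample_ids.extend(ids)
        pops[f"p{k}"] = ids
        gt[k, 0, : len(genos)] = np.asarray(genos, dtype=np.int8)
    matrix = GenotypeMatrix(["site"], sample_ids, gt.reshape(1, -1))
    return wc_fst(matrix, pops)


def windowed_fst(
    positions: Sequence[int],
    comps: FstComponents,
    window: int = 50_000,
    step: int = 25_000,
    chroms: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Sliding-window FST as a ratio of sums: theta_w = sum(a)/sum(a+b+c).

    Windows of ``window`` bp advance by ``step`` bp from position 1 on each
    chromosome; windows containing no sites are omitted.  A ratio of sums
    (not a mean of per-site ratios) downweights uninformative sites.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if step <= 0:
        raise ValueError("step must be positive")
    positions = np.asarray(positions)
    chrom_arr = np.asarray(chroms) if chroms is not None else np.array(["chr"] * len(positions))
    denom = comps.a + comps.b + comps.c
    rows = []
    for chrom in pd.unique(chrom_arr):
        mask = chrom_arr == chrom
        pos = positions[mask]
        a_c, d_c = comps.a[mask], denom[mask]
        order = np.argsort(pos)
        pos, a_c, d_c = pos[order], a_c[order], d_c[order]
        last = int(pos.max())
        start = 1
        while start <= last:
            end = start + window - 1
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="right")
            if hi > lo:
                d_sum = d_c[lo:hi].sum()
                fst = a_c[lo:hi].sum() / d_sum if d_sum > 0 else np.nan
                rows.append((chrom, start, end, hi - lo, fst))
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "fst"])


@dataclass
class DiResult:
    """Per-SV di values with the per-pair moments they were standardized by."""

    di: np.ndarray
    n_pairs: np.ndarray                  # comparison pairs contributing per SV
    pair_means: dict[str, float]
    pair_sds: dict[str, float]
    pair_z: dict[str, np.ndarray]
    sv_ids: list[str] = field(default_factory=list)


def di_statistic(theta_by_pair: Mapping[str, np.ndarray]) -> DiResult:
    """di = sum over comparison populations of genome-standardized FST.

    ``theta_by_pair`` maps a comparison-pair name to the per-SV theta array
    for focal-vs-that-population.  Undefined theta (NaN, monomorphic sites)
    are excluded from that pair's moments and from that SV's sum; the number
    of contributing pairs per SV is reported.  A pair whose theta values are
    constant has sigma = 0 and is rejected by name.
    """
    if not theta_by_pair:
        raise ValueError("need >= 1 comparison population")
    pair_names = list(theta_by_pair)
    n_sv = len(next(iter(theta_by_pair.values())))
    di = np.zeros(n_sv)
    n_pairs = np.zeros(n_sv, dtype=int)
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    zs: dict[str, np.ndarray] = {}
    for name in pair_names:
        theta = np.asarray(theta_by_pair[name], dtype=float)
        if len(theta) != n_sv:
            raise ValueError(f"pair {name!r}: theta length mismatch")
        finite = np.isfinite(theta)
        if finite.sum() < 2:
            raise ValueError(f"pair {name!r}: fewer than 2 defined theta values")
        mu = float(theta[finite].mean())
        sd = float(theta[finite].std(ddof=1))
        if sd == 0:
            raise ValueError(f"pair {name!r}: sigma of theta is 0")
        z = np.where(finite, (theta - mu) / sd, 0.0)
        di += z
        n_pairs += finite.astype(int)
        means[name] = mu
        sds[name] = sd
        zs[name] = np.where(finite, (theta - mu) / sd, np.nan)
    di = np.where(n_pairs > 0, di, np.nan)
    return DiResult(
        di=di, n_pairs=n_pairs, pair_means=means, pair_sds=sds, pair_z=zs,
    )


def di_outliers(
    result: DiResult, alpha: float = 0.001, method: str = "ztest"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flag di outliers at level ``alpha``.

    ``method="ztest"`` (default) standardizes di by its own mean/SD and
    flags the one-sided upper normal tail p < alpha (critical z ~ 3.0902 at
    alpha = 0.001).  Because di sums standardized FST over only a handful of
    comparison populations, its null distribution is right-skewed and the
    normal tail over-flags relative to nominal alpha; ``method="empirical"``
    instead flags the top alpha fraction by rank (upper empirical quantile),
    which is calibrated by construction.  Returns (flags, z, p).
    """
    di = result.di
    finite = np.isfinite(di)
    if finite.sum() < 2:
        raise ValueError("need >= 2 finite di values")
    mu = di[finite].mean()
    sd = di[finite].std(ddof=1)
    if sd == 0:
        raise ValueError("sd of di is 0")
    z = np.where(finite, (di - mu) / sd, np.nan)
    if method == "ztest":
        p = stats.norm.sf(z)
        flags = np.where(finite, p < alpha, False)
    elif method == "empirical":
        order = stats.rankdata(np.where(finite, di, -np.inf), method="average")
        p = (len(di) - order + 0.5) / finite.sum()
        flags = np.where(finite, p < alpha, False)
    else:
        raise ValueError(f"unknown method {method!r}")
    return flags, z, p


def di_scan(
    matrix: GenotypeMatrix,
    manifest: PopulationManifest,
    mode: str = "pooled",
    alpha: float = 0.001,
) -> pd.DataFrame:
    """End-to-end di scan: focal target group vs each control population.

    ``mode="pooled"`` (default) pools all target-role samples into one focal
    group contrasted against each control-role population separately;
    ``mode="per_population"`` instead returns one scan per target population.
    Returns a per-SV table with di, Z, p and the outlier flag (columns are
    prefixed by target population in per-population mode).
    """
    controls = manifest.populations(role="control")
    if not controls:
        raise ValueError("no control populations in manifest")
    if mode == "pooled":
        focal_groups = {"target": manifest.samples_with_role("target")}
    elif mode == "per_population":
        focal_groups = {
            pop: manifest.samples_in_population(pop)
            for pop in manifest.populations(role="target")
        }
    else:
        raise ValueError(f"unknown mode {mode!r}")
    frames = []
    for focal_name, focal_samples in focal_groups.items():
        if not focal_samples:
            raise ValueError(f"focal group {focal_name!r} has no samples")
        theta_by_pair = {}
        for ctrl in controls:
            comps = wc_fst(
                matrix,
                {"focal": focal_samples, ctrl: manifest.samples_in_population(ctrl)},
            )
            theta_by_pair[ctrl] = comps.theta
        res = di_statistic(theta_by_pair)
        flags, z, p = di_outliers(res, alpha=alpha)
        prefix = "" if mode == "pooled" else f"{focal_name}_"
        df = pd.DataFrame(
            {
                f"{prefix}di": res.di,
                f"{prefix}n_pairs": res.n_pairs,
                f"{prefix}z": z,
                f"{prefix}p": p,
                f"{prefix}outlier": flags,
            },
            index=matrix.sv_ids,
        )
        frames.append(df)
    out = pd.concat(frames, axis=1)
    out.index.name = "sv_id"
    return out
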