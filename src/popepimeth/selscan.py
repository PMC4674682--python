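"""Per-SNP selection statistics: F_ST, LSBL, EHH/iHS, LD pruning, tail flags.

F_ST is the Weir–Cockerham variance-components estimator θ (negative values
are retained).  The locus-specific branch length decomposes the three
pairwise F_ST values among populations A, B and an outgroup C into per-branch
lengths, LSBL_A = (F_AB + F_AC − F_BC)/2.  Extended haplotype homozygosity
EHH(x) is the probability that two carrier haplotypes of a core allele are
identical from the core out to x; integrating it over physical distance for
ancestral- and derived-allele carriers separately gives iHH_A and iHH_D, and
the unstandardized iHS = ln(iHH_A/iHH_D) is then standardized within derived
allele-frequency bins (0.025 wide) so that scores are comparable across
frequencies.  Extreme scores are flagged against the genome-wide empirical
top-5% quantile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "weir_cockerham_fst",
    "lsbl",
    "EhhCurve",
    "ehh",
    "ihs",
    "standardize_ihs",
    "ld_prune",
    "top_tail_flags",
]


# ---------------------------------------------------------------------------
# F_ST


def weir_cockerham_fst(dosages_a: np.ndarray, dosages_b: np.ndarray) -> np.ndarray:
    """Per-SNP Weir–Cockerham θ for two diploid samples.

    ``dosages_*`` are samples x SNPs in {0,1,2}.  Monomorphic-in-both SNPs
    return NaN.  Negative estimates (no differentiation) are retained.
    """
    da = np.asarray(dosages_a, dtype=float)
    db = np.asarray(dosages_b, dtype=float)
    if da.shape[0] < 2 or db.shape[0] < 2:
        raise ValueError("need at least 2 diploid samples per population")
    r = 2.0
    n_i = np.array([da.shape[0], db.shape[0]], dtype=float)
    p_i = np.vstack([da.mean(axis=0) / 2.0, db.mean(axis=0) / 2.0])
    h_i = np.vstack([(da == 1).mean(axis=0), (db == 1).mean(axis=0)])

    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1.0)
    pbar = (n_i[:, None] * p_i).sum(axis=0) / (r * nbar)
    s2 = (n_i[:, None] * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
    hbar = (n_i[:, None] * h_i).sum(axis=0) / (r * nbar)

    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
    )
    c = hbar / 2.0
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / denom
    mono = (pbar == 0) | (pbar == 1)
    theta[mono | (denom == 0)] = np.nan
    return theta


def lsbl(fst_ab: np.ndarray, fst_ac: np.ndarray, fst_bc: np.ndarray):
    """Locus-specific branch lengths from three pairwise F_ST vectors.

    Returns (LSBL_A, LSBL_B, LSBL_C); LSBL_A + LSBL_B = F_ST(A,B) by
    construction.  Missing pairwise values propagate to NaN.
    """
    fst_ab = np.asarray(fst_ab, float)
    fst_ac = np.asarray(fst_ac, float)
    fst_bc = np.asarray(fst_bc, float)
    a = (fst_ab + fst_ac - fst_bc) / 2.0
    b = (fst_ab + fst_bc - fst_ac) / 2.0
    c = (fst_ac + fst_bc - fst_ab) / 2.0
    return a, b, c


# ---------------------------------------------------------------------------
# EHH / iHS


@dataclass
class EhhCurve:
    """EHH decay outward from a core allele, both directions.

    ``left``/``right`` are (distance bp >= 0, EHH) arrays starting at (0, 1).
    """

    focal_idx: int
    core_allele: int
    left: np.ndarray  # (k, 2)
    right: np.ndarray
    n_carriers: int


def _ehh_decay(
    haps: np.ndarray,
    positions: np.ndarray,
    focal: int,
    step: int,
    stop_below: float = 0.0,
):
    """March outward (step=+1 right, -1 left) updating identity classes.

    Stops once EHH reaches zero, or first drops below ``stop_below`` (the
    below-threshold point is still recorded so integration can use it).
    """
    n = haps.shape[0]
    pairs_total = n * (n - 1) / 2.0
    labels = np.zeros(n, dtype=np.int64)
    out = [(0.0, 1.0)]
    j = focal + step
    while 0 <= j < haps.shape[1]:
        key = labels * 2 + haps[:, j]
        _, labels = np.unique(key, return_inverse=True)
        counts = np.bincount(labels)
        same = (counts * (counts - 1) / 2.0).sum()
        e = same / pairs_total
        out.append((abs(float(positions[j] - positions[focal])), e))
        if same == 0 or e < stop_below:
            break
        j += step
    return np.array(out)


def ehh(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    focal_idx: int,
    core_allele: int,
) -> EhhCurve:
    """EHH curve among carriers of ``core_allele`` at the focal SNP."""
    haps = np.asarray(haplotypes)
    carriers = haps[:, focal_idx] == core_allele
    k = int(carriers.sum())
    if k < 2:
        raise ValueError("fewer than 2 carriers of the core allele")
    sub = haps[carriers]
    left = _ehh_decay(sub, positions, focal_idx, -1)
    right = _ehh_decay(sub, positions, focal_idx, +1)
    return EhhCurve(focal_idx, core_allele, left, right, k)


def _ihh_from_curve(curve: np.ndarray, cutoff: float, max_gap: float, chrom_span: float):
    """Trapezoid area until EHH first drops below cutoff.

    Returns (area, ok); ok is False when the curve never reaches the cutoff
    before the chromosome end, or a distance gap exceeds ``max_gap``.
    """
    d = curve[:, 0]
    e = curve[:, 1]
    below = np.flatnonzero(e < cutoff)
    if len(below) == 0:
        return np.nan, False
    stop = below[0]
    d = d[: stop + 1]
    e = e[: stop + 1]
    if np.any(np.diff(d) > max_gap):
        return np.nan, False
    return float(np.trapezoid(e, d)), True


def ihs(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    ancestral_is_zero: bool = True,
    ehh_cutoff: float = 0.05,
    max_gap: float = 200_000.0,
    min_carriers: int = 2,
    snp_indices: np.ndarray | None = None,
) -> pd.DataFrame:
    """Unstandardized iHS = ln(iHH_ancestral / iHH_derived) per SNP.

    Allele 0 is ancestral (flip with ``ancestral_is_zero=False``).  SNPs are
    skipped, with a reason, when either allele class has too few carriers or
    when either EHH curve fails to decay below ``ehh_cutoff`` before the
    chromosome end or across a gap larger than ``max_gap``.
    """
    haps = np.asarray(haplotypes)
    positions = np.asarray(positions, dtype=float)
    n_snps = haps.shape[1]
    idxs = np.arange(n_snps) if snp_indices is None else np.asarray(snp_indices)
    anc, der = (0, 1) if ancestral_is_zero else (1, 0)
    rows = []
    span = positions[-1] - positions[0] if n_snps else 0.0
    for j in idxs:
        daf = float((haps[:, j] == der).mean())
        rec = {"snp_idx": int(j), "daf": daf, "ihs_unstd": np.nan, "reason": ""}
        if daf in (0.0, 1.0):
            rec["reason"] = "monomorphic"
            rows.append(rec)
            continue
        n_d = int((haps[:, j] == der).sum())
        n_a = haps.shape[0] - n_d
        if n_d < min_carriers or n_a < min_carriers:
            rec["reason"] = "too-few-carriers"
            rows.append(rec)
            continue
        areas = {}
        ok_all = True
        for name, allele in (("A", anc), ("D", der)):
            sub = haps[haps[:, j] == allele]
            left = _ehh_decay(sub, positions, j, -1, stop_below=ehh_cutoff)
            right = _ehh_decay(sub, positions, j, +1, stop_below=ehh_cutoff)
            aL, okL = _ihh_from_curve(left, ehh_cutoff, max_gap, span)
            aR, okR = _ihh_from_curve(right, ehh_cutoff, max_gap, span)
            if not (okL and okR):
                ok_all = False
                rec["reason"] = "ehh-no-decay"
                break
            areas[name] = aL + aR
        if not ok_all:
            rows.append(rec)
            continue
        if areas["D"] <= 0:
            rec["reason"] = "zero-derived-ihh"
            rows.append(rec)
            continue
        if areas["A"] <= 0:
            rec["reason"] = "zero-ancestral-ihh"
            rows.append(rec)
            continue
        rec["ihs_unstd"] = float(np.log(areas["A"] / areas["D"]))
        rows.append(rec)
    return pd.DataFrame(rows)


def standardize_ihs(
    ihs_unstd: np.ndarray, daf: np.ndarray, bin_width: float = 0.025
) -> np.ndarray:
    """Standardize iHS within derived-allele-frequency bins.

    Bins are left-closed right-open over (0,1) in ``bin_width`` steps, the
    last bin closed on the right.  Within each bin the mean is subtracted
    and the n−1 standard deviation divided out; bins with fewer than 2
    scores, or zero spread, yield missing values.
    """
    x = np.asarray(ihs_unstd, dtype=float)
    d = np.asarray(daf, dtype=float)
    out = np.full_like(x, np.nan)
    nbins = int(round(1.0 / bin_width))
    bins = np.minimum((d / bin_width).astype(int), nbins - 1)
    ok = np.isfinite(x) & (d > 0) & (d < 1)
    for b in np.unique(bins[ok]):
        mask = ok & (bins == b)
        if mask.sum() < 2:
            continue
        mu = x[mask].mean()
        sd = x[mask].std(ddof=1)
        if sd == 0:
            continue
        out[mask] = (x[mask] - mu) / sd
    return out


# ---------------------------------------------------------------------------
# LD pruning and tail flags


def ld_prune(
    dosages: np.ndarray,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_threshold: float = 0.8,
) -> np.ndarray:
    """Greedy sliding-window pruning of SNPs in strong LD (plink-style
    ``--indep-pairwise 50 5 0.8``); of any correlated pair the
    later-positioned SNP is removed.  Returns a boolean keep mask over the
    position-sorted SNP columns."""
    G = np.asarray(dosages, dtype=float)
    n_snps = G.shape[1]
    keep = np.ones(n_snps, dtype=bool)
    start = 0
    while start < n_snps:
        win = np.arange(start, min(start + window_snps, n_snps))
        live = win[keep[win]]
        if len(live) > 1:
            X = G[:, live] - G[:, live].mean(axis=0)
            norms = np.sqrt((X**2).sum(axis=0))
            ok = norms > 0
            with np.errstate(invalid="ignore", divide="ignore"):
                R = (X.T @ X) / np.outer(norms, norms)
            r2 = R**2
            alive = np.ones(len(live), dtype=bool)
            for ii in range(len(live)):
                if not alive[ii] or not ok[ii]:
                    continue
                hits = np.flatnonzero(alive & ok & (r2[ii] > r2_threshold))
                hits = hits[hits > ii]
                alive[hits] = False
            keep[live[~alive]] = False
        if start + window_snps >= n_snps:
            break
        start += step_snps
    return keep


def pairwise_r2(dosages: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    """Genotype-correlation r² between two SNP index sets (len_a x len_b)."""
    G = np.asarray(dosages, dtype=float)
    A = G[:, idx_a] - G[:, idx_a].mean(axis=0)
    B = G[:, idx_b] - G[:, idx_b].mean(axis=0)
    sa = np.sqrt((A**2).sum(axis=0))
    sb = np.sqrt((B**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (A.T @ B) / np.outer(sa, sb)
    return r**2


def top_tail_flags(
    scores: np.ndarray, tail_fraction: float = 0.05, absolute: bool = False
) -> np.ndarray:
    """Flag scores in the genome-wide top tail.

    The flag is True where the score (or |score|) reaches the empirical
    (1 − tail_fraction) quantile of non-missing values; ties at the quantile
    are all flagged; missing scores are never flagged.
    """
    x = np.asarray(scores, dtype=float)
    if absolute:
        x = np.abs(x)
    ok = np.isfinite(x)
    if ok.sum() < 20:
        raise ValueError("need at least 20 non-missing scores")
    q = np.quantile(x[ok], 1.0 - tail_fraction)
    flags = np.zeros(x.shape, dtype=bool)
    flags[ok] = x[ok] >= q
    return flags
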