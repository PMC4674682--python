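"""Enrichment statistics linking methylation, genotype and selection results.

Covers: 2x2 odds-ratio tests for genomic-region colocalization (chi-square
p), Cochran–Mantel–Haenszel tests of selection-score enrichment among meQTL
SNPs stratified by derived-allele-frequency bins, a logistic-occupancy PWM
affinity score with a top-5% high-affinity rule, probe-count-bias-weighted
gene-category over-representation (Wallenius noncentral hypergeometric), and
the two GWAS-catalog resampling tests (gene-based with probe-count matching;
SNP-based with LD-aware expansion).

The CMH statistic uses Cochran's multinomial variance (denominator n³), so
with a single stratum it reduces exactly to the Pearson chi-square without
continuity correction; the common odds ratio is Mantel–Haenszel.  All
resampling p-values carry the +1/(n+1) pseudocount and are never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .selscan import ld_prune, pairwise_r2

__all__ = [
    "EnrichResult",
    "region_enrichment_or",
    "cmh_enrichment",
    "background_snps_near_probes",
    "pwm_affinity",
    "weighted_category_test",
    "gwas_gene_enrichment",
    "gwas_snp_enrichment",
]


@dataclass
class EnrichResult:
    odds_ratio: float
    log_or_se: float
    pvalue: float
    method: str
    counts: object = None
    strata_used: int = 1
    strata_dropped: int = 0
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# 2x2 odds ratio with chi-square p


def _table(target: np.ndarray, region: np.ndarray) -> tuple[float, float, float, float]:
    a = float(np.sum(target & region))
    b = float(np.sum(target & ~region))
    c = float(np.sum(~target & region))
    d = float(np.sum(~target & ~region))
    return a, b, c, d


def region_enrichment_or(target: np.ndarray, region: np.ndarray) -> EnrichResult:
    """OR = (target in-region / target out) / (background in / background out)
    with background = non-target sites; Haldane–Anscombe +0.5 on zero cells;
    Pearson 1-df chi-square p (no continuity correction)."""
    target = np.asarray(target, bool)
    region = np.asarray(region, bool)
    if target.sum() == 0:
        return EnrichResult(np.nan, np.nan, np.nan, "chi-square", extra={"note": "empty target"})
    a, b, c, d = _table(target, region)
    corrected = False
    aa, bb, cc, dd = a, b, c, d
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    orr = (aa / bb) / (cc / dd)
    se = float(np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd))
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        p = np.nan
    else:
        x2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
        p = float(stats.chi2.sf(x2, 1))
    return EnrichResult(
        float(orr), se, p, "chi-square", counts=(a, b, c, d),
        extra={"zero_cell_corrected": corrected},
    )


# ---------------------------------------------------------------------------
# stratified CMH


def cmh_enrichment(
    high_flags: np.ndarray,
    target_flags: np.ndarray,
    strata: np.ndarray,
) -> EnrichResult:
    """Mantel–Haenszel common OR and Cochran chi-square over 2x2 strata.

    Rows are target membership (e.g. meQTL vs background SNP), columns the
    high-score flag; ``strata`` assigns each site to a stratum (e.g. DAF bin
    of width 0.1).  Strata with any zero row/column margin are dropped and
    counted; the test statistic T = (Σ(a_i − E_i))²/ΣV_i with
    V_i = r1·r2·c1·c2/n³ reduces exactly to the Pearson chi-square when only
    one stratum exists."""
    high = np.asarray(high_flags, bool)
    tgt = np.asarray(target_flags, bool)
    strata = np.asarray(strata)
    num_or = den_or = 0.0
    sum_dev = sum_var = 0.0
    used = dropped = 0
    tables = []
    for s in pd.unique(strata):
        m = strata == s
        a, b, c, d = _table(tgt[m], high[m])
        n = a + b + c + d
        r1, r2 = a + b, c + d
        c1, c2 = a + c, b + d
        if min(r1, r2, c1, c2) == 0 or n == 0:
            dropped += 1
            continue
        used += 1
        tables.append((a, b, c, d))
        num_or += a * d / n
        den_or += b * c / n
        sum_dev += a - r1 * c1 / n
        sum_var += r1 * r2 * c1 * c2 / n**3
    if used == 0:
        return EnrichResult(np.nan, np.nan, np.nan, "CMH", strata_dropped=dropped,
                            extra={"note": "all strata degenerate"})
    if den_or == 0 or num_or == 0:
        # zero-cell-only strata: correct each table
        num_or = sum((a + 0.5) * (d + 0.5) / (a + b + c + d + 2) for a, b, c, d in tables)
        den_or = sum((b + 0.5) * (c + 0.5) / (a + b + c + d + 2) for a, b, c, d in tables)
    orr = num_or / den_or
    # Robins–Breslow–Greenland variance of log MH OR
    se = _rbg_se(tables)
    if sum_var > 0:
        t = sum_dev**2 / sum_var
        p = float(stats.chi2.sf(t, 1))
    else:
        p = np.nan
    return EnrichResult(float(orr), se, p, "CMH", counts=tables,
                        strata_used=used, strata_dropped=dropped)


def _rbg_se(tables: list[tuple[float, float, float, float]]) -> float:
    sr = ss = spq = rsum = ssum = 0.0
    for a, b, c, d in tables:
        n = a + b + c + d
        r = a * d / n
        s = b * c / n
        p = (a + d) / n
        q = (b + c) / n
        sr += p * r
        ss += q * s
        spq += p * s + q * r
        rsum += r
        ssum += s
    if rsum == 0 or ssum == 0:
        return np.nan
    var = sr / (2 * rsum**2) + spq / (2 * rsum * ssum) + ss / (2 * ssum**2)
    return float(np.sqrt(var))


# ---------------------------------------------------------------------------
# background SNP selection


def background_snps_near_probes(
    snp_annot: pd.DataFrame,
    probe_annot: pd.DataFrame,
    window_bp: int = 20_000,
    exclude: set | None = None,
    dosages_all: np.ndarray | None = None,
    prune_r2: float | None = 0.8,
) -> pd.Index:
    """SNPs within ±window_bp/2 (inclusive) of any probe, minus ``exclude``
    (e.g. the meQTL SNPs), optionally LD-pruned at r² > ``prune_r2``."""
    half = window_bp // 2
    keep = np.zeros(len(snp_annot), dtype=bool)
    for chrom, probes in probe_annot.groupby("chrom"):
        m = (snp_annot["chrom"] == chrom).to_numpy()
        if not m.any():
            continue
        ppos = np.sort(probes["pos"].to_numpy(int))
        spos = snp_annot.loc[m, "pos"].to_numpy(int)
        j = np.searchsorted(ppos, spos)
        dist_r = np.where(j < len(ppos), np.abs(ppos[np.clip(j, 0, len(ppos) - 1)] - spos), np.inf)
        dist_l = np.where(j > 0, np.abs(spos - ppos[np.clip(j - 1, 0, len(ppos) - 1)]), np.inf)
        keep[m] = np.minimum(dist_l, dist_r) <= half
    ids = snp_annot.index[keep]
    if exclude:
        ids = ids[~ids.isin(exclude)]
    if prune_r2 is not None and dosages_all is not None and len(ids):
        cols = snp_annot.index.get_indexer(ids)
        order = np.argsort(snp_annot.loc[ids, "pos"].to_numpy(), kind="stable")
        mask = ld_prune(dosages_all[:, cols[order]], r2_threshold=prune_r2)
        ids = ids[order][mask]
    return ids


# ---------------------------------------------------------------------------
# PWM affinity (logistic occupancy surrogate)


def _pwm_logodds(counts: np.ndarray, pseudocount: float = 0.5) -> np.ndarray:
    p = (np.asarray(counts, float) + pseudocount)
    p = p / p.sum(axis=0, keepdims=True)
    return np.log(p / 0.25)


_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = str.maketrans("ACGT", "TGCA")


def pwm_affinity(
    sequences: list[str],
    pwms: dict[str, np.ndarray],
    lam: float = 1.0,
    top_fraction: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Occupancy-style affinity of each sequence for each motif.

    Per window w (both strands): term = 1/(1 + exp(ΔE_w/λ)) with
    ΔE_w = best-possible log-odds − window log-odds; the affinity is the sum
    over windows, so a sequence containing the motif consensus gains the
    maximal single-window contribution 0.5.  Sequences containing N are
    skipped for every motif (NaN).  Returns (scores, high-affinity flags at
    the per-motif top fifth percentile).
    """
    n = len(sequences)
    scores = pd.DataFrame(index=range(n), columns=list(pwms), dtype=float)
    enc = []
    for s in sequences:
        s = s.upper()
        if any(ch not in _BASE_IDX for ch in s):
            enc.append(None)
        else:
            enc.append(
                (
                    np.fromiter((_BASE_IDX[c] for c in s), int, len(s)),
                    np.fromiter((_BASE_IDX[c] for c in s.translate(_COMP)[::-1]), int, len(s)),
                )
            )
    for name, counts in pwms.items():
        lo = _pwm_logodds(counts)
        L = lo.shape[1]
        best = lo.max(axis=0).sum()
        col = np.full(n, np.nan)
        for i, e in enumerate(enc):
            if e is None:
                continue
            total = 0.0
            for strand in e:
                if len(strand) < L:
                    continue
                for w in range(len(strand) - L + 1):
                    llr = lo[strand[w : w + L], np.arange(L)].sum()
                    total += 1.0 / (1.0 + np.exp((best - llr) / lam))
            col[i] = total
        scores[name] = col
    flags = pd.DataFrame(False, index=scores.index, columns=scores.columns)
    for name in scores:
        v = scores[name]
        ok = v.notna()
        if ok.any():
            q = np.quantile(v[ok], 1.0 - top_fraction)
            flags.loc[ok, name] = v[ok] >= q
    return scores, flags


# ---------------------------------------------------------------------------
# probe-count-bias-weighted category over-representation


def weighted_category_test(
    target_genes: set,
    categories: dict[str, list[str]],
    probes_per_gene: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Category over-representation corrected for probe-count selection bias.

    Genes with more probes have more chances to harbour a DMS; the selection
    bias P(target | probes-per-gene) is estimated by monotone (isotonic)
    regression, each category's Wallenius odds is the mean bias of member
    genes relative to non-members, and the enrichment p comes from the
    Wallenius noncentral hypergeometric tail (central hypergeometric when
    the odds are 1).  BH adjustment across categories.
    """
    from sklearn.isotonic import IsotonicRegression

    universe = probes_per_gene.index
    tgt = np.asarray(universe.isin(target_genes), dtype=float)
    x = probes_per_gene.to_numpy(float)
    n_target = int(tgt.sum())
    N = len(universe)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    bias = np.maximum(iso.fit_transform(x, tgt), 1e-6)
    rows = []
    for name, genes in categories.items():
        member = universe.isin(genes)
        K = int(member.sum())
        if K == 0:
            continue
        obs = int((member & (tgt == 1)).sum())
        mean_in = bias[member].mean()
        mean_out = bias[~member].mean() if K < N else mean_in
        odds = float(mean_in / mean_out)
        if abs(odds - 1.0) < 1e-9 or K == N:
            p = float(stats.hypergeom.sf(obs - 1, N, K, n_target))
            expected = K * n_target / N
        else:
            dist = stats.nchypergeom_wallenius(N, K, n_target, odds)
            p = float(dist.sf(obs - 1))
            expected = float(dist.mean())
        rows.append(
            {"category": name, "size": K, "observed": obs, "expected": expected,
             "odds": odds, "pvalue": min(p, 1.0)}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = multipletests(out["pvalue"], method="fdr_bh")[1]
        out["significant"] = out["p_adj"] < alpha
    return out


# ---------------------------------------------------------------------------
# GWAS gene-based resampling


def _stratified_null_draws(
    universe_n: int,
    bin_members: list[np.ndarray],
    bin_take: list[int],
    n_resamples: int,
    rng: np.random.Generator,
):
    """Yield per-bin index matrices (n_resamples x k), sampled without
    replacement within each resample."""
    for members, k in zip(bin_members, bin_take):
        if k == 0 or len(members) == 0:
            yield None
            continue
        k = min(k, len(members))
        ranks = rng.random((n_resamples, len(members))).argpartition(k - 1, axis=1)[:, :k]
        yield members[ranks]


def gwas_gene_enrichment(
    target_genes: set,
    catalog: pd.DataFrame,
    probes_per_gene: pd.Series,
    n_resamples: int = 10_000,
    seed: int = 0,
    p_threshold: float = 5e-8,
    trait_min_genes: int = 5,
    n_bins: int = 10,
) -> tuple[EnrichResult, pd.DataFrame]:
    """Gene-based GWAS enrichment with probe-count-matched resampling.

    Null gene sets of the target's size are drawn from the array genes,
    stratified by probe-count quantile bins so the null matches the target's
    probes-per-gene distribution; the target is enriched when its proportion
    of GWAS genes exceeds the null in ≥95% of draws.  Per-trait tests run
    only for traits with more than ``trait_min_genes`` target genes.
    """
    rng = np.random.default_rng(seed)
    universe = probes_per_gene.index
    tgt_mask = np.asarray(universe.isin(target_genes))
    n = int(tgt_mask.sum())
    hits = catalog[catalog["pvalue"] < p_threshold]
    gwas_genes = set(hits["reported_gene"])
    gwas_vec = np.asarray(universe.isin(gwas_genes))
    if n == 0 or len(hits) == 0:
        return (
            EnrichResult(np.nan, np.nan, 1.0, "resampling",
                         extra={"observed_prop": 0.0, "note": "empty target or catalog"}),
            pd.DataFrame(),
        )
    obs_count = int((tgt_mask & gwas_vec).sum())

    # probe-count bins (quantile; collapses when counts are uniform)
    try:
        bins = pd.qcut(probes_per_gene, q=n_bins, duplicates="drop", labels=False)
    except ValueError:
        bins = pd.Series(0, index=universe)
    bins = bins.fillna(0).astype(int)
    bin_members, bin_take = [], []
    for b in sorted(bins.unique()):
        in_bin = (bins == b).to_numpy()
        bin_members.append(np.flatnonzero(in_bin))
        bin_take.append(int((in_bin & tgt_mask).sum()))

    null_counts = np.zeros(n_resamples, dtype=int)
    trait_vecs = {}
    for trait, grp in hits.groupby("trait"):
        tg = set(grp["reported_gene"])
        if int((tgt_mask & np.asarray(universe.isin(tg))).sum()) > trait_min_genes:
            trait_vecs[trait] = np.asarray(universe.isin(tg))
    trait_null = {t: np.zeros(n_resamples, dtype=int) for t in trait_vecs}
    for draws in _stratified_null_draws(len(universe), bin_members, bin_take, n_resamples, rng):
        if draws is None:
            continue
        null_counts += gwas_vec[draws].sum(axis=1)
        for t, v in trait_vecs.items():
            trait_null[t] += v[draws].sum(axis=1)
    p = (int((null_counts >= obs_count).sum()) + 1) / (n_resamples + 1)
    overall = EnrichResult(
        odds_ratio=float(obs_count / max(null_counts.mean(), 1e-12)),
        log_or_se=np.nan,
        pvalue=p,
        method="resampling",
        extra={"observed": obs_count, "expected": float(null_counts.mean()), "n": n},
    )
    trait_rows = []
    for t, v in trait_vecs.items():
        oc = int((tgt_mask & v).sum())
        tp = (int((trait_null[t] >= oc).sum()) + 1) / (n_resamples + 1)
        trait_rows.append(
            {"trait": t, "observed": oc, "expected": float(trait_null[t].mean()), "pvalue": tp}
        )
    traits = pd.DataFrame(trait_rows)
    if len(traits):
        traits["p_adj"] = multipletests(traits["pvalue"], method="fdr_bh")[1]
    return overall, traits


# ---------------------------------------------------------------------------
# GWAS SNP-based resampling with LD expansion


def _ld_hit_flags(
    candidates: pd.Index,
    catalog_snps: set,
    snp_annot: pd.DataFrame,
    dosages_all: np.ndarray,
    r2: float = 0.8,
    window_bp: int = 500_000,
) -> np.ndarray:
    """For each candidate SNP: does its r²>threshold neighbourhood (self
    included) contain a catalog hit?"""
    flags = np.zeros(len(candidates), dtype=bool)
    catalog_idx = snp_annot.index.isin(catalog_snps)
    pos = snp_annot["pos"].to_numpy(int)
    chroms = snp_annot["chrom"].to_numpy()
    for i, snp in enumerate(candidates):
        j = snp_annot.index.get_loc(snp)
        if catalog_idx[j]:
            flags[i] = True
            continue
        near = (
            (chroms == chroms[j])
            & (np.abs(pos - pos[j]) <= window_bp)
            & catalog_idx
        )
        cand = np.flatnonzero(near)
        if len(cand) == 0:
            continue
        rr = pairwise_r2(dosages_all, np.array([j]), cand)[0]
        flags[i] = bool(np.any(rr > r2))
    return flags


def gwas_snp_enrichment(
    meqtl_snps: pd.Index,
    catalog_snps: set,
    snp_annot: pd.DataFrame,
    dosages_all: np.ndarray,
    background: pd.Index,
    r2: float = 0.8,
    n_resamples: int = 10_000,
    seed: int = 0,
    background_flags: np.ndarray | None = None,
) -> EnrichResult:
    """SNP-based GWAS enrichment: after LD pruning, the proportion of meQTL
    SNPs whose r²>0.8 neighbourhood contains a catalog best hit, against the
    same proportion in resampled sets of independent probe-proximal SNPs."""
    rng = np.random.default_rng(seed)
    ids = meqtl_snps
    if len(ids) == 0:
        return EnrichResult(np.nan, np.nan, 1.0, "resampling", extra={"note": "no meQTL SNPs"})
    cols = snp_annot.index.get_indexer(ids)
    order = np.argsort(snp_annot.loc[ids, "pos"].to_numpy(), kind="stable")
    mask = ld_prune(dosages_all[:, cols[order]], r2_threshold=r2)
    pruned = ids[order][mask]
    obs_flags = _ld_hit_flags(pruned, catalog_snps, snp_annot, dosages_all, r2)
    obs = float(obs_flags.mean())
    k = len(pruned)
    if background_flags is None:
        bg_flags = _ld_hit_flags(background, catalog_snps, snp_annot, dosages_all, r2)
    else:
        bg_flags = np.asarray(background_flags, bool)
    if len(background) < k:
        raise ValueError("background smaller than the pruned meQTL set")
    ranks = rng.random((n_resamples, len(background))).argpartition(k - 1, axis=1)[:, :k]
    null = bg_flags[ranks].mean(axis=1)
    p = (int((null >= obs).sum()) + 1) / (n_resamples + 1)
    return EnrichResult(
        odds_ratio=float(obs / max(null.mean(), 1e-12)),
        log_or_se=np.nan,
        pvalue=p,
        method="resampling",
        extra={"observed_prop": obs, "expected_prop": float(null.mean()), "n_pruned": k},
    )
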