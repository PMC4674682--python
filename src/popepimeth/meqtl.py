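"""Multi-population cis-meQTL mapping by configuration Bayes-factor averaging.

For every probe–SNP pair within a 200-kb cis window, per-population effect
estimates (β̂_s, se_s) come from OLS of adjusted M-values on allele dosage
plus covariates.  Each "configuration" c — a nonempty subset of populations
in which the SNP is active — receives a Wakefield approximate Bayes factor

    ABF_s(W) = sqrt(V_s/(V_s+W)) · exp( z_s²/2 · W/(V_s+W) ),   z_s = β̂_s/se_s

with BF_c the product of ABF_s over populations in c (inactive populations
contribute 1), averaged over a grid of prior effect-size variances W.
Genome-wide configuration weights w_c and the no-meQTL mass π0 are estimated
by EM on the marginal likelihood Σ log(π0 + (1−π0)·Σ_c w_c·BF_c).  Sites are
called by Bayesian FDR on posterior null probabilities; the reported SNP set
is the smallest set whose summed best-SNP posteriors reach 0.85, and
configuration conflicts among best SNPs are resolved by the highest-posterior
SNP (two distinct configurations) or by dropping the site (more than two).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .methio import MethylMatrix

__all__ = [
    "DEFAULT_GRID",
    "enumerate_cis_pairs",
    "filter_snps_maf",
    "subgroup_summary_stats",
    "configuration_log_bayes_factors",
    "fit_hierarchical_weights",
    "call_meqtls",
    "classify_interaction",
    "meqtl_variance_explained",
    "genotype_pc1",
    "CisMeqtlScan",
    "MeqtlResults",
]

# Prior effect-size standard deviations on the M scale; variances W = sd².
# The grid spans effects plausibly detectable at cohort-scale sample sizes;
# W far below the sampling variance makes the alternative indistinguishable
# from the null and destroys identifiability of (pi0, w), so no near-null
# grid points are included by default.  Override via the ``grid`` argument.
DEFAULT_GRID = tuple(float(w) ** 2 for w in (0.1, 0.2, 0.4, 0.8))


# ---------------------------------------------------------------------------
# pair enumeration and SNP filtering


def enumerate_cis_pairs(
    probe_annot: pd.DataFrame,
    snp_annot: pd.DataFrame,
    window_bp: int = 200_000,
) -> pd.DataFrame:
    """All probe–SNP pairs with |pos_SNP − pos_probe| ≤ window_bp/2, same
    chromosome.  A "200-kb window around the site" is read as ±100 kb
    inclusive."""
    half = window_bp // 2
    out = []
    for chrom, snps in snp_annot.groupby("chrom"):
        probes = probe_annot[probe_annot["chrom"] == chrom]
        if probes.empty:
            continue
        spos = snps["pos"].to_numpy(int)
        order = np.argsort(spos)
        spos_sorted = spos[order]
        sids = snps.index.to_numpy()[order]
        for probe, ppos in zip(probes.index, probes["pos"].to_numpy(int)):
            lo = np.searchsorted(spos_sorted, ppos - half, side="left")
            hi = np.searchsorted(spos_sorted, ppos + half, side="right")
            for j in range(lo, hi):
                out.append((probe, sids[j], int(spos_sorted[j] - ppos)))
    return pd.DataFrame(out, columns=["probe", "snp", "distance"])


def filter_snps_maf(
    dosages: dict[str, np.ndarray], snp_ids: pd.Index, min_maf: float = 0.10
) -> pd.Index:
    """Retain SNPs whose minor-allele frequency is ≥ min_maf in at least one
    population (inclusive threshold)."""
    keep = np.zeros(len(snp_ids), dtype=bool)
    for pop, d in dosages.items():
        if d.shape[0] < 2:
            raise ValueError(f"population {pop} has fewer than 2 samples")
        f = d.mean(axis=0) / 2.0
        maf = np.minimum(f, 1.0 - f)
        keep |= maf >= min_maf
    return snp_ids[keep]


def genotype_pc1(dosages_all: np.ndarray) -> np.ndarray:
    """First principal component of the centered dosage matrix (ancestry axis)."""
    X = dosages_all - dosages_all.mean(axis=0, keepdims=True)
    # economical: PC scores from the sample-side eigen decomposition
    G = X @ X.T
    vals, vecs = np.linalg.eigh(G)
    pc1 = vecs[:, -1] * np.sqrt(max(vals[-1], 0.0))
    return pc1


# ---------------------------------------------------------------------------
# per-population summary statistics


def _residualize(mat: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of each column of ``mat`` on the column space of Z."""
    coef, *_ = np.linalg.lstsq(Z, mat, rcond=None)
    return mat - Z @ coef


def subgroup_summary_stats(
    pairs: pd.DataFrame,
    methyl: MethylMatrix,
    dosages: dict[str, np.ndarray],
    snp_ids: pd.Index,
    covariates: pd.DataFrame,
    pop_labels: list[str],
    covariate_terms: list[str] | None = None,
) -> dict:
    """Per-population OLS effect and s.e. for every cis pair.

    Covariates (and an intercept) are projected out of both methylation and
    dosage within each population (Frisch–Waugh), so the per-pair slope is a
    simple ratio of cross-products; its s.e. uses n − k − 1 residual df.
    Populations where a SNP has zero dosage variance are flagged unusable for
    the pairs involving it.
    """
    covariate_terms = covariate_terms or []
    snp_pos = {s: j for j, s in enumerate(snp_ids)}
    probe_pos = {p: i for i, p in enumerate(methyl.probes)}
    pair_probe = np.fromiter((probe_pos[p] for p in pairs["probe"]), int, len(pairs))
    pair_snp = np.fromiter((snp_pos[s] for s in pairs["snp"]), int, len(pairs))

    n_pairs = len(pairs)
    n_pops = len(pop_labels)
    beta = np.full((n_pairs, n_pops), np.nan)
    se = np.full((n_pairs, n_pops), np.nan)
    nobs = np.zeros(n_pops, dtype=int)
    usable = np.zeros((n_pairs, n_pops), dtype=bool)

    sample_pop = covariates["population"]
    for s_idx, pop in enumerate(pop_labels):
        samples = covariates.index[sample_pop == pop]
        n = len(samples)
        nobs[s_idx] = n
        cov = covariates.loc[samples]
        cols = [np.ones(n)]
        for t in covariate_terms:
            c = cov[t]
            if not np.issubdtype(c.dtype, np.number):
                c = c.astype("category").cat.codes
            v = c.to_numpy(float)
            if np.std(v) > 0:
                cols.append(v)
        Z = np.column_stack(cols)
        k = np.linalg.matrix_rank(Z)
        dfree = n - k - 1
        if dfree <= 0:
            raise ValueError(f"population {pop}: not enough samples for covariates")
        M = methyl.df.loc[:, samples].to_numpy(float)  # probes x n
        G = dosages[pop].astype(float)  # n x snps
        g_var_ok = G.std(axis=0) > 0
        Mres = _residualize(M.T, Z).T  # probes x n
        Gres = _residualize(G, Z)  # n x snps
        gss = (Gres**2).sum(axis=0)

        # group pairs by probe for cache-friendly slicing
        order = np.argsort(pair_probe, kind="stable")
        for start in _runs(pair_probe[order]):
            idx = order[start[0] : start[1]]
            pi = pair_probe[idx[0]]
            sj = pair_snp[idx]
            ok = g_var_ok[sj]
            if not ok.any():
                continue
            m = Mres[pi]
            g = Gres[:, sj[ok]]
            gs = gss[sj[ok]]
            b = (m @ g) / gs
            rss = (m @ m) - b**2 * gs
            sigma2 = np.maximum(rss, 0.0) / dfree
            s = np.sqrt(sigma2 / gs)
            rows = idx[ok]
            beta[rows, s_idx] = b
            se[rows, s_idx] = s
            usable[rows, s_idx] = True
    se = np.where(se <= 0, np.nan, se)
    usable &= np.isfinite(se)
    return {
        "beta": beta,
        "se": se,
        "usable": usable,
        "n": nobs,
        "pop_labels": list(pop_labels),
        "pairs": pairs.reset_index(drop=True),
    }


def _runs(sorted_vals: np.ndarray):
    """(start, stop) index ranges of equal consecutive values."""
    if len(sorted_vals) == 0:
        return
    breaks = np.flatnonzero(np.diff(sorted_vals)) + 1
    edges = np.concatenate(([0], breaks, [len(sorted_vals)]))
    for a, b in zip(edges[:-1], edges[1:]):
        yield (a, b)


# ---------------------------------------------------------------------------
# configuration Bayes factors


def all_configurations(pop_labels: list[str]) -> list[tuple[str, ...]]:
    out = []
    for r in range(1, len(pop_labels) + 1):
        out.extend(itertools.combinations(pop_labels, r))
    return out


def configuration_log_bayes_factors(
    stats: dict, grid: tuple[float, ...] = DEFAULT_GRID
) -> tuple[np.ndarray, list[tuple[str, ...]]]:
    """log BF_c for every nonempty configuration, grid-averaged.

    Unusable populations contribute a factor of 1 whatever the
    configuration.  Returns (n_pairs x n_configs log BFs, config list).
    """
    if len(grid) == 0:
        raise ValueError("grid must be nonempty")
    if any(w <= 0 for w in grid):
        raise ValueError("prior variances must be positive")
    beta, se, usable = stats["beta"], stats["se"], stats["usable"]
    pop_labels = stats["pop_labels"]
    V = se**2
    z2 = (beta / se) ** 2
    n_pairs, n_pops = beta.shape
    n_grid = len(grid)
    # ln ABF per (pair, pop, grid point); unusable -> 0 (factor 1)
    lnabf = np.zeros((n_pairs, n_pops, n_grid))
    for gi, W in enumerate(grid):
        with np.errstate(invalid="ignore", divide="ignore"):
            val = 0.5 * np.log(V / (V + W)) + 0.5 * z2 * (W / (V + W))
        lnabf[:, :, gi] = np.where(usable, val, 0.0)
    configs = all_configurations(pop_labels)
    lbf = np.empty((n_pairs, len(configs)))
    for ci, c in enumerate(configs):
        sel = [pop_labels.index(p) for p in c]
        per_grid = lnabf[:, sel, :].sum(axis=1)  # n_pairs x n_grid
        lbf[:, ci] = logsumexp(per_grid, axis=1) - np.log(n_grid)
    return lbf, configs


# ---------------------------------------------------------------------------
# hierarchical weights (EM)


@dataclass
class ConfigModel:
    configs: list[tuple[str, ...]]
    weights: np.ndarray
    pi0: float
    loglik_path: list[float] = field(default_factory=list)
    converged: bool = True
    degenerate: bool = False

    def posterior(self, lbf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(P(null) per pair, P(c) per pair x config); rows sum to one."""
        lw = np.log(np.maximum(self.weights, 1e-300))
        if self.pi0 <= 0:
            lp0 = -np.inf
            l1 = 0.0
        elif self.pi0 >= 1:
            lp0, l1 = 0.0, -np.inf
        else:
            lp0, l1 = np.log(self.pi0), np.log1p(-self.pi0)
        a = l1 + lw[None, :] + lbf
        s = logsumexp(a, axis=1)
        denom = np.logaddexp(lp0, s)
        p_null = np.exp(lp0 - denom)
        p_c = np.exp(a - denom[:, None])
        return p_null, p_c


def fit_hierarchical_weights(
    lbf: np.ndarray,
    configs: list[tuple[str, ...]],
    pi0_init: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 1000,
    pi0_method: str = "em",
) -> ConfigModel:
    """EM for (π0, w_c) maximizing Σ log(π0 + (1−π0)·Σ_c w_c·BF_c).

    ``pi0_method='conservative'`` fixes π0 at the fraction of pairs whose
    best configuration BF is below 1 and estimates only the weights.
    """
    n_pairs, n_configs = lbf.shape
    if n_pairs < 1:
        raise ValueError("no pairs")
    if np.allclose(lbf, 0.0):
        model = ConfigModel(configs, np.full(n_configs, 1.0 / n_configs), pi0_init)
        model.degenerate = True
        warnings.warn("all Bayes factors are 1: hierarchical model unidentifiable")
        return model
    pi0 = float(pi0_init)
    fixed_pi0 = pi0_method == "conservative"
    if fixed_pi0:
        pi0 = float(np.mean(lbf.max(axis=1) < 0.0))
        pi0 = min(max(pi0, 1e-6), 1 - 1e-6)
    w = np.full(n_configs, 1.0 / n_configs)
    path: list[float] = []
    converged = False
    for _ in range(max_iter):
        lw = np.log(np.maximum(w, 1e-300))
        a = np.log1p(-pi0) + lw[None, :] + lbf
        s = logsumexp(a, axis=1)
        denom = np.logaddexp(np.log(pi0), s)
        ll = float(denom.sum())
        if path and ll < path[-1] - 1e-8:
            warnings.warn("EM log-likelihood decreased; numerical trouble")
        r0 = np.exp(np.log(pi0) - denom)
        rc = np.exp(a - denom[:, None])
        if not fixed_pi0:
            pi0 = float(np.clip(r0.mean(), 1e-9, 1 - 1e-9))
        colsum = rc.sum(axis=0)
        total = colsum.sum()
        w = colsum / total if total > 0 else np.full(n_configs, 1.0 / n_configs)
        if path and abs(ll - path[-1]) < tol:
            path.append(ll)
            converged = True
            break
        path.append(ll)
    if not converged:
        warnings.warn("EM did not converge; returning best iterate")
    return ConfigModel(configs, w, pi0, path, converged)


# ---------------------------------------------------------------------------
# calling


def call_meqtls(
    pairs: pd.DataFrame,
    lbf: np.ndarray,
    model: ConfigModel,
    fdr: float = 0.01,
    best_posterior: float = 0.85,
) -> pd.DataFrame:
    """Site-level Bayesian-FDR calls with best-SNP sets and configurations.

    A site's Bayes factor averages its cis SNPs' configuration-averaged BFs
    (uniform prior over SNPs); calling walks sites in increasing posterior
    null probability while the running mean stays at or below ``fdr``.
    """
    lw = np.log(np.maximum(model.weights, 1e-300))
    pair_score = logsumexp(lw[None, :] + lbf, axis=1)  # log Σ_c w_c BF_c per pair
    best_cfg_idx = np.argmax(lw[None, :] + lbf, axis=1)

    rows = []
    lp0 = np.log(model.pi0) if model.pi0 > 0 else -np.inf
    l1 = np.log1p(-model.pi0) if model.pi0 < 1 else -np.inf
    for probe, grp in pairs.groupby("probe", sort=False):
        idx = grp.index.to_numpy()
        site_lbf = logsumexp(pair_score[idx]) - np.log(len(idx))
        denom = np.logaddexp(lp0, l1 + site_lbf)
        p_null = float(np.exp(lp0 - denom))
        # best-SNP posteriors within the site
        q = np.exp(pair_score[idx] - logsumexp(pair_score[idx]))
        order = np.argsort(-q, kind="stable")
        cum = np.cumsum(q[order])
        k = int(np.searchsorted(cum, best_posterior) + 1)
        k = min(k, len(order))
        chosen = idx[order[:k]]
        snps = pairs.loc[chosen, "snp"].tolist()
        cfgs = [model.configs[best_cfg_idx[j]] for j in chosen]
        distinct = sorted(set(cfgs))
        if len(distinct) == 1:
            cfg = distinct[0]
            dropped = False
        elif len(distinct) == 2:
            cfg = cfgs[0]  # highest-posterior SNP decides
            dropped = False
        else:
            cfg = None
            dropped = True
        rows.append(
            {
                "probe": probe,
                "p_null": p_null,
                "best_snps": ",".join(snps),
                "best_snp": snps[0],
                "best_posterior_sum": float(cum[k - 1]),
                "configuration": ",".join(cfg) if cfg else "",
                "n_distinct_configs": len(distinct),
                "dropped_config_conflict": dropped,
            }
        )
    sites = pd.DataFrame(rows).sort_values("p_null", kind="stable").reset_index(drop=True)
    if len(sites):
        running = np.cumsum(sites["p_null"].to_numpy()) / np.arange(1, len(sites) + 1)
        called = running <= fdr
        # Bayesian FDR is a prefix rule on the sorted list
        if called.any():
            last = np.max(np.flatnonzero(called))
            called = np.arange(len(sites)) <= last
        sites["called"] = called & ~sites["dropped_config_conflict"]
    else:
        sites["called"] = pd.Series(dtype=bool)
    return sites


# ---------------------------------------------------------------------------
# interaction classification and variance explained


def classify_interaction(
    calls: pd.DataFrame,
    methyl: MethylMatrix,
    dosages_all: np.ndarray,
    snp_ids: pd.Index,
    covariates: pd.DataFrame,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Two-way ANOVA (M ~ population + genotype + population×genotype) per
    called site; sites whose BH-adjusted interaction p is below ``alpha``
    are classed G×G/G×E, the rest frequency-driven."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    snp_pos = {s: j for j, s in enumerate(snp_ids)}
    probe_pos = {p: i for i, p in enumerate(methyl.probes)}
    pops = covariates["population"].to_numpy()
    rows = []
    for _, call in calls.iterrows():
        if not call.get("called", True):
            continue
        pi = probe_pos[call["probe"]]
        g = dosages_all[:, snp_pos[call["best_snp"]]].astype(float)
        usable_pops = [p for p in np.unique(pops) if g[pops == p].std() > 0]
        if len(usable_pops) < 2:
            rows.append({"probe": call["probe"], "p_interaction": np.nan, "note": "single-pop"})
            continue
        mask = np.isin(pops, usable_pops)
        df = pd.DataFrame(
            {"m": methyl.values[pi, mask], "pop": pops[mask], "g": g[mask]}
        )
        fit = smf.ols("m ~ C(pop) + g + C(pop):g", data=df).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        ss = tab["sum_sq"]
        total = ss.sum()
        rows.append(
            {
                "probe": call["probe"],
                "p_interaction": float(tab.loc["C(pop):g", "PR(>F)"]),
                "var_pop": float(ss.get("C(pop)", np.nan) / total),
                "var_geno": float(ss.get("g", np.nan) / total),
                "var_interaction": float(ss.loc["C(pop):g"] / total),
                "note": "",
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        ok = out["p_interaction"].notna()
        adj = np.full(len(out), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(out.loc[ok, "p_interaction"], method="fdr_bh")[1]
        out["p_interaction_adj"] = adj
        out["interaction_class"] = np.where(
            out["p_interaction_adj"] < alpha, "GxGxE",
            np.where(np.isnan(adj), "unresolved", "frequency-driven"),
        )
    return out


def meqtl_variance_explained(
    calls: pd.DataFrame,
    methyl: MethylMatrix,
    dosages: dict[str, np.ndarray],
    snp_ids: pd.Index,
    covariates: pd.DataFrame,
    pop_labels: list[str],
) -> pd.DataFrame:
    """Per-population R² of the dosage-only regression for each called site."""
    snp_pos = {s: j for j, s in enumerate(snp_ids)}
    probe_pos = {p: i for i, p in enumerate(methyl.probes)}
    sample_pop = covariates["population"]
    rows = []
    for _, call in calls.iterrows():
        if not call.get("called", True):
            continue
        pi = probe_pos[call["probe"]]
        rec = {"probe": call["probe"], "snp": call["best_snp"]}
        for pop in pop_labels:
            samples = covariates.index[sample_pop == pop]
            m = methyl.df.loc[:, samples].to_numpy(float)[pi]
            g = dosages[pop][:, snp_pos[call["best_snp"]]].astype(float)
            if g.std() == 0 or m.std() == 0:
                rec[f"r2_{pop}"] = np.nan
            else:
                rec[f"r2_{pop}"] = float(np.corrcoef(m, g)[0, 1] ** 2)
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model / results facade


class CisMeqtlScan:
    """cis-meQTL scan across populations, statsmodels-style.

    Parameters
    ----------
    methyl : MethylMatrix
        Covariate-adjusted M-values (probes x samples).
    dosages : dict
        population -> samples x SNPs dosage matrix (metadata order per pop).
    snp_annot, probe_annot : DataFrame
        1-based positions; ``snp_annot`` indexed by SNP id.
    covariates : DataFrame
        Indexed by sample, includes a ``population`` column.  A first
        genotype principal component is added automatically.
    """

    def __init__(
        self,
        methyl: MethylMatrix,
        dosages: dict[str, np.ndarray],
        snp_annot: pd.DataFrame,
        probe_annot: pd.DataFrame,
        covariates: pd.DataFrame,
        covariate_terms: list[str] | None = None,
        window_bp: int = 200_000,
        min_maf: float = 0.10,
        grid: tuple[float, ...] = DEFAULT_GRID,
    ):
        self.methyl = methyl
        self.dosages = dosages
        self.snp_annot = snp_annot
        self.probe_annot = probe_annot
        self.covariates = covariates.copy()
        self.covariate_terms = list(covariate_terms or [])
        self.window_bp = window_bp
        self.min_maf = min_maf
        self.grid = grid
        self.pop_labels = [p for p in covariates["population"].unique()]

    def fit(
        self,
        fdr: float = 0.01,
        best_posterior: float = 0.85,
        pi0_method: str = "em",
        classify: bool = True,
    ) -> "MeqtlResults":
        snp_ids = self.snp_annot.index
        kept = filter_snps_maf(self.dosages, snp_ids, self.min_maf)
        kept_mask = snp_ids.isin(kept)
        snp_sub = self.snp_annot.loc[kept]
        dos_sub = {p: d[:, kept_mask] for p, d in self.dosages.items()}
        dosages_all = np.vstack([dos_sub[p] for p in self.pop_labels])

        cov = self.covariates.copy()
        cov["geno_pc1"] = genotype_pc1(dosages_all.astype(float))
        terms = self.covariate_terms + ["geno_pc1"]

        pairs = enumerate_cis_pairs(self.probe_annot, snp_sub, self.window_bp)
        if pairs.empty:
            raise ValueError("no cis pairs within the window")
        stats = subgroup_summary_stats(
            pairs, self.methyl, dos_sub, kept, cov, self.pop_labels, terms
        )
        lbf, configs = configuration_log_bayes_factors(stats, self.grid)
        model = fit_hierarchical_weights(lbf, configs, pi0_method=pi0_method)
        calls = call_meqtls(pairs, lbf, model, fdr, best_posterior)
        called = calls[calls["called"]]
        r2 = meqtl_variance_explained(
            called, self.methyl, dos_sub, kept, cov, self.pop_labels
        )
        inter = (
            classify_interaction(called, self.methyl, dosages_all, kept, cov)
            if classify and len(called)
            else pd.DataFrame()
        )
        return MeqtlResults(
            self, pairs, stats, lbf, model, calls, r2, inter, kept
        )


@dataclass
class MeqtlResults:
    model_spec: CisMeqtlScan
    pairs: pd.DataFrame
    stats: dict
    lbf: np.ndarray
    config_model: ConfigModel
    calls: pd.DataFrame
    r2: pd.DataFrame
    interactions: pd.DataFrame
    snps_kept: pd.Index

    @property
    def called(self) -> pd.DataFrame:
        return self.calls[self.calls["called"]]

    @property
    def pi0(self) -> float:
        return self.config_model.pi0

    def summary(self) -> str:
        w = self.config_model.weights
        cfgs = self.config_model.configs
        top = np.argsort(-w)[:5]
        lines = [
            "cis-meQTL scan (configuration Bayesian model averaging)",
            f"  SNPs after MAF filter : {len(self.snps_kept)}",
            f"  cis pairs             : {len(self.pairs)}",
            f"  sites tested          : {self.calls.shape[0]}",
            f"  pi0 (no-meQTL mass)   : {self.pi0:.3f}",
            f"  sites called          : {len(self.called)}",
            "  top configuration weights:",
        ]
        for i in top:
            lines.append(f"    {'+'.join(cfgs[i]):<24s} {w[i]:.3f}")
        return "\n".join(lines)
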