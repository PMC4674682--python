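"""Synthetic cohort generator.

Builds genotype/haplotype panels, whole-blood methylomes and annotation
tracks with the statistical structure a population-epigenomics study of
hunter-gatherer and farmer groups assumes, so every downstream stage of the
pipeline can be exercised and calibrated against known ground truth.

The generative model, in brief:

* per-population allele frequencies follow the Balding–Nichols model — a
  Beta(p(1−F)/F, (1−p)(1−F)/F) draw around the ancestral frequency p, with F
  the per-population divergence coefficient;
* phased haplotypes come from a founder-copying mosaic: a small founder panel
  is drawn site-wise from the population frequencies, and each sample
  haplotype copies one founder, switching founders between adjacent SNPs with
  probability 1−exp(−rho·distance) — enough linkage structure for EHH/iHS
  work at desk scale without a coalescent;
* recent positive selection is injected by handing a fraction q of one
  population's haplotypes an identical copied segment around a focal derived
  allele;
* methylation M-values are additive: probe baseline + population/habitat
  effects + per-dosage meQTL effects (in the configured active populations
  only) + age + sex + cell-composition terms + Gaussian noise; a designated
  panel of probes instead reflects mixtures of reference leukocyte β
  profiles, which the deconvolution stage later inverts.

All randomness flows from one root seed through labelled independent streams
(see :mod:`popepimeth._rng`), so identical designs reproduce bit-identical
cohorts and individual stages can be replayed in isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .methio import CellReferencePanel, MethylMatrix, beta_to_m, m_to_beta

__all__ = [
    "CohortDesign",
    "MeqtlSpec",
    "DmsSpec",
    "SimTruth",
    "SyntheticCohort",
    "simulate_population_frequencies",
    "simulate_haplotypes",
    "inject_sweep",
    "simulate_methylome",
    "simulate_annotations",
    "simulate_cohort",
    "default_cell_panel",
    "effect_for_r2",
    "region_class",
    "write_cohort",
]

REGION_CLASSES = [
    "distal_promoter",
    "proximal_promoter",
    "5utr",
    "first_exon",
    "gene_body",
    "3utr",
    "intergenic",
]

_BLOOD_BASE = {
    "Gran": 0.55,
    "Mono": 0.08,
    "Bcell": 0.08,
    "CD4T": 0.15,
    "CD8T": 0.08,
    "NK": 0.06,
}


@dataclass
class MeqtlSpec:
    """A planted cis-meQTL: per-dosage M-scale effect, active populations."""

    probe: str
    snp: str
    effect: float
    active: tuple[str, ...]


@dataclass
class DmsSpec:
    """A planted differential-methylation effect for one factor level."""

    probe: str
    factor: str  # "population" or "habitat"
    effects: dict[str, float]  # level -> additive ΔM offset


@dataclass
class CohortDesign:
    """Everything needed to generate one synthetic cohort deterministically."""

    populations: dict[str, int]  # label -> diploid sample size
    habitat: dict[str, str]
    lifestyle: dict[str, str]
    f_div: dict[str, float]
    n_snps: int
    n_probes: int
    genome_layout: dict[str, int]  # chromosome -> length (bp)
    meqtl_spec: list[MeqtlSpec] = field(default_factory=list)
    dms_spec: list[DmsSpec] = field(default_factory=list)
    cell_panel: CellReferencePanel | None = None
    age_range: tuple[float, float] = (18.0, 70.0)
    sex_ratio: float = 0.5
    noise_sd: float = 0.3
    rho: float = 1e-5  # per-bp founder switch rate
    n_founders: int = 12
    sweeps: list[tuple[str, str, float, int]] = field(default_factory=list)
    # (snp, population, carrier fraction, span bp)
    seed: int = 0

    def __post_init__(self):
        for pop, n in self.populations.items():
            if n < 2:
                raise ValueError(f"population {pop} needs >= 2 samples")
        for pop, f in self.f_div.items():
            if not (0 <= f < 1):
                raise ValueError(f"F divergence for {pop} must be in [0,1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_snps <= 0 or self.n_probes <= 0:
            raise ValueError("n_snps and n_probes must be positive")

    @property
    def pop_labels(self) -> list[str]:
        return list(self.populations)

    @property
    def n_samples(self) -> int:
        return sum(self.populations.values())


@dataclass
class SimTruth:
    """Ground truth recorded during simulation, for recovery scoring."""

    cell_proportions: pd.DataFrame
    ages: pd.Series
    dms_effects: pd.DataFrame  # probe, factor, level, delta_m
    meqtl_effects: pd.DataFrame  # probe, snp, effect, configuration
    sweeps: pd.DataFrame  # snp, population, carrier_fraction, span_bp


@dataclass
class SyntheticCohort:
    design: CohortDesign
    snp_annot: pd.DataFrame  # index snp: chrom, pos, ref, alt, ancestral, freq_<pop>
    probe_annot: pd.DataFrame
    haplotypes: dict[str, np.ndarray]  # pop -> (2n x S) int8
    metadata: pd.DataFrame  # index sample: population, habitat, lifestyle, sex, age
    methyl: MethylMatrix  # M scale, includes cell-panel probes
    truth: SimTruth
    tracks: dict[str, pd.DataFrame]
    gwas_catalog: pd.DataFrame
    gene_sets: dict[str, list[str]]
    pwms: dict[str, np.ndarray]
    panel: CellReferencePanel

    @property
    def dosages(self) -> dict[str, np.ndarray]:
        """Per-population diploid dosage matrices (samples x SNPs) in {0,1,2}."""
        return {
            pop: (h[0::2] + h[1::2]).astype(np.int8) for pop, h in self.haplotypes.items()
        }

    @property
    def all_dosages(self) -> np.ndarray:
        """Dosages stacked in metadata row order."""
        return np.vstack([self.dosages[p] for p in self.design.pop_labels])

    def pop_of_sample(self) -> pd.Series:
        return self.metadata["population"]


# ---------------------------------------------------------------------------
# allele frequencies


def simulate_population_frequencies(
    p_anc: np.ndarray,
    f_div: Mapping[str, float] | Sequence[float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Balding–Nichols per-population frequencies around ancestral ``p_anc``.

    For F > 0 each population's frequency is Beta(p(1−F)/F, (1−p)(1−F)/F),
    which has mean p and variance F·p(1−p); F = 0 returns p exactly.
    """
    p_anc = np.asarray(p_anc, dtype=float)
    if np.any((p_anc <= 0) | (p_anc >= 1)):
        raise ValueError("ancestral frequencies must lie strictly in (0,1)")
    fs = list(f_div.values()) if isinstance(f_div, Mapping) else list(f_div)
    out = np.empty((len(fs), len(p_anc)))
    for i, f in enumerate(fs):
        if not (0 <= f < 1):
            raise ValueError("F divergence must be in [0,1)")
        if f == 0:
            out[i] = p_anc
        else:
            c = (1.0 - f) / f
            out[i] = rng.beta(p_anc * c, (1.0 - p_anc) * c)
    return out


# ---------------------------------------------------------------------------
# haplotypes


def simulate_haplotypes(
    freqs: np.ndarray,
    n_hap: int,
    positions: np.ndarray,
    rho: float,
    rng: np.random.Generator,
    n_founders: int = 12,
) -> np.ndarray:
    """Founder-copying mosaic haplotypes for one population.

    A founder panel of ``n_founders`` haplotypes is drawn site-wise Bernoulli
    from ``freqs``; each sample haplotype copies a founder and switches to a
    uniformly chosen founder between adjacent SNPs with probability
    1−exp(−rho·distance).  Marginal frequencies match ``freqs`` in
    expectation; adjacent-SNP LD decays with distance and with rho.
    """
    if n_hap % 2:
        raise ValueError("n_hap must be even (diploid pairing)")
    if rho < 0:
        raise ValueError("rho must be >= 0")
    freqs = np.asarray(freqs, dtype=float)
    n_snps = len(freqs)
    if n_snps == 0:
        return np.zeros((n_hap, 0), dtype=np.int8)
    positions = np.asarray(positions, dtype=float)
    founders = (rng.random((n_founders, n_snps)) < freqs).astype(np.int8)
    if n_founders == 1 or n_snps == 1:
        idx = rng.integers(0, n_founders, size=n_hap)
        return founders[idx].copy()
    gaps = np.diff(positions)
    p_switch = 1.0 - np.exp(-rho * np.maximum(gaps, 0.0))
    haps = np.empty((n_hap, n_snps), dtype=np.int8)
    for h in range(n_hap):
        switch = rng.random(n_snps - 1) < p_switch
        n_seg = int(switch.sum()) + 1
        founder_ids = rng.integers(0, n_founders, size=n_seg)
        path = np.empty(n_snps, dtype=np.int64)
        path[0] = founder_ids[0]
        seg = np.cumsum(np.concatenate(([0], switch.astype(np.int64))))
        path = founder_ids[seg]
        haps[h] = founders[path, np.arange(n_snps)]
    return haps


def inject_sweep(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    focal_idx: int,
    carrier_fraction: float,
    span_bp: int,
    rng: np.random.Generator,
    chrom_length: int | None = None,
) -> tuple[np.ndarray, dict]:
    """Plant a hard-sweep-like signal in one population's haplotypes.

    A fraction ``carrier_fraction`` of haplotypes receives the derived allele
    at ``focal_idx`` plus a bitwise-identical copied segment over
    ±span_bp/2; all other haplotypes get the ancestral allele at the focal
    SNP and are otherwise untouched.
    """
    if not (0 < carrier_fraction < 1):
        raise ValueError("carrier fraction must lie in (0,1)")
    if span_bp <= 0:
        raise ValueError("span_bp must be positive")
    haps = np.asarray(haplotypes).copy()
    n_hap, n_snps = haps.shape
    if not (0 <= focal_idx < n_snps):
        raise ValueError(f"focal SNP index {focal_idx} not in panel")
    pos = np.asarray(positions)
    half = span_bp / 2
    lo, hi = pos[focal_idx] - half, pos[focal_idx] + half
    if chrom_length is not None and (lo < 1 or hi > chrom_length):
        warnings.warn("sweep span truncated at chromosome ends")
        lo, hi = max(lo, 1), min(hi, chrom_length)
    in_span = (pos >= lo) & (pos <= hi)
    k = int(round(carrier_fraction * n_hap))
    k = min(max(k, 1), n_hap - 1)
    carriers = rng.choice(n_hap, size=k, replace=False)
    template = haps[carriers[0], in_span].copy()
    haps[np.ix_(carriers, np.where(in_span)[0])] = template
    haps[:, focal_idx] = 0
    haps[carriers, focal_idx] = 1
    truth = {
        "focal_idx": int(focal_idx),
        "carriers": np.sort(carriers),
        "carrier_fraction": k / n_hap,
        "span_bp": int(span_bp),
    }
    return haps, truth


# ---------------------------------------------------------------------------
# methylome


def effect_for_r2(r2: float, freq: float, noise_sd: float) -> float:
    """Per-dosage M-scale effect size giving theoretical variance explained
    ``r2`` at allele frequency ``freq`` under HWE (dosage variance 2pq)."""
    var_g = 2.0 * freq * (1.0 - freq)
    return float(np.sqrt(r2 / (1.0 - r2) * noise_sd**2 / var_g))


def default_cell_panel(rng: np.random.Generator, n_panel_probes: int = 200) -> CellReferencePanel:
    """Six-leukocyte reference panel with well-separated β profiles."""
    types = list(_BLOOD_BASE)
    probes = [f"cp{i:04d}" for i in range(n_panel_probes)]
    # anchor each probe at a random base level, push cell types apart
    base = rng.uniform(0.15, 0.85, size=(n_panel_probes, 1))
    sep = rng.uniform(-0.45, 0.45, size=(n_panel_probes, len(types)))
    prof = np.clip(base + sep, 0.02, 0.98)
    return CellReferencePanel(types, probes, prof)


def _sample_metadata(design: CohortDesign, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for pop, n in design.populations.items():
        for i in range(n):
            rows.append(
                {
                    "sample": f"{pop}_{i:03d}",
                    "population": pop,
                    "habitat": design.habitat.get(pop, "forest"),
                    "lifestyle": design.lifestyle.get(pop, "AGR"),
                }
            )
    meta = pd.DataFrame(rows).set_index("sample")
    n = len(meta)
    meta["sex"] = np.where(rng.random(n) < design.sex_ratio, "F", "M")
    meta["age"] = rng.uniform(*design.age_range, size=n).round(1)
    return meta


def simulate_methylome(
    design: CohortDesign,
    dosages: Mapping[str, np.ndarray],
    snp_index: pd.Index,
    metadata: pd.DataFrame,
    rng: np.random.Generator,
    panel: CellReferencePanel | None = None,
) -> tuple[MethylMatrix, SimTruth]:
    """Additive M-scale methylome plus ground truth.

    M(probe, sample) = μ_probe + planted factor effects + planted meQTL
    effects × dosage (active populations only) + a_probe·(age−mean) +
    s_probe·sex + Σ_k c_probe,k·(cellprop_k − mean) + N(0, noise_sd²).
    Cell-panel probes are instead mixtures of the reference β profiles.
    """
    panel = panel or design.cell_panel
    if panel is None:
        raise ValueError("a cell reference panel is required")
    pops = design.pop_labels
    n = len(metadata)
    probes = [f"cg{i:06d}" for i in range(design.n_probes)]
    probe_pos = {p: i for i, p in enumerate(probes)}
    snp_pos = {s: i for i, s in enumerate(snp_index)}
    for spec in design.meqtl_spec:
        if spec.probe not in probe_pos:
            raise ValueError(f"meqtl_spec references unknown probe {spec.probe}")
        if spec.snp not in snp_pos:
            raise ValueError(f"meqtl_spec references unknown SNP {spec.snp}")

    # baseline: bimodal like a real array
    comp = rng.choice(3, size=design.n_probes, p=[0.4, 0.4, 0.2])
    mu = np.where(
        comp == 0,
        rng.normal(-3.0, 0.7, design.n_probes),
        np.where(comp == 1, rng.normal(3.0, 0.7, design.n_probes), rng.normal(0.0, 1.0, design.n_probes)),
    )

    # nuisance covariate coefficients (sparse but nonzero ensemble-wide)
    age_coef = np.where(rng.random(design.n_probes) < 0.1, rng.normal(0, 0.01, design.n_probes), 0.0)
    sex_coef = np.where(rng.random(design.n_probes) < 0.1, rng.normal(0, 0.2, design.n_probes), 0.0)
    k_cells = len(panel.cell_types)
    cell_coef = np.where(
        rng.random((design.n_probes, k_cells)) < 0.2,
        rng.normal(0, 0.5, (design.n_probes, k_cells)),
        0.0,
    )

    # true cell proportions: Dirichlet around typical whole blood
    base = np.array([_BLOOD_BASE[t] for t in panel.cell_types], dtype=float)
    base = base / base.sum()
    cellprops = rng.dirichlet(base * 60.0, size=n)
    cp = pd.DataFrame(cellprops, index=metadata.index, columns=panel.cell_types)

    age_c = metadata["age"].to_numpy(float) - metadata["age"].mean()
    sex_num = (metadata["sex"] == "F").to_numpy(float)
    cell_c = cellprops - cellprops.mean(axis=0)

    M = np.tile(mu[:, None], (1, n))
    M += age_coef[:, None] * age_c[None, :]
    M += sex_coef[:, None] * sex_num[None, :]
    M += cell_coef @ cell_c.T

    dms_rows = []
    for spec in design.dms_spec:
        pi = probe_pos[spec.probe]
        col = metadata[spec.factor]
        for level, dm in spec.effects.items():
            M[pi, (col == level).to_numpy()] += dm
            dms_rows.append(
                {"probe": spec.probe, "factor": spec.factor, "level": level, "delta_m": dm}
            )

    # meQTL effects: dosage acts only inside the active-population set
    sample_pop = metadata["population"].to_numpy()
    full_dosage = np.vstack([dosages[p] for p in pops])  # metadata row order
    meqtl_rows = []
    for spec in design.meqtl_spec:
        pi, si = probe_pos[spec.probe], snp_pos[spec.snp]
        active_mask = np.isin(sample_pop, list(spec.active))
        M[pi, active_mask] += spec.effect * full_dosage[active_mask, si]
        meqtl_rows.append(
            {
                "probe": spec.probe,
                "snp": spec.snp,
                "effect": spec.effect,
                "configuration": ",".join(sorted(spec.active)),
            }
        )

    M += rng.normal(0.0, design.noise_sd, size=M.shape)

    # panel probes: mixtures of reference β profiles + β-scale noise
    mix_beta = panel.profiles @ cellprops.T  # panel probes x samples
    mix_beta = np.clip(mix_beta + rng.normal(0, 0.01, mix_beta.shape), 1e-3, 1 - 1e-3)
    panel_M = beta_to_m(mix_beta)

    all_values = np.vstack([M, panel_M])
    all_probes = probes + list(panel.probe_ids)
    matrix = MethylMatrix(all_values, pd.Index(all_probes), metadata.index, "M")
    truth = SimTruth(
        cell_proportions=cp,
        ages=metadata["age"].copy(),
        dms_effects=pd.DataFrame(dms_rows, columns=["probe", "factor", "level", "delta_m"]),
        meqtl_effects=pd.DataFrame(
            meqtl_rows, columns=["probe", "snp", "effect", "configuration"]
        ),
        sweeps=pd.DataFrame(columns=["snp", "population", "carrier_fraction", "span_bp"]),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# positions / annotations


def _layout_positions(
    genome_layout: Mapping[str, int], n_sites: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sorted (chrom, 1-based position) pairs allocated by chromosome length."""
    chroms = list(genome_layout)
    lengths = np.array([genome_layout[c] for c in chroms], dtype=float)
    alloc = np.maximum(1, np.round(n_sites * lengths / lengths.sum()).astype(int))
    # fix rounding so counts sum exactly
    while alloc.sum() > n_sites:
        alloc[np.argmax(alloc)] -= 1
    while alloc.sum() < n_sites:
        alloc[np.argmax(lengths)] += 1
    out_chrom, out_pos = [], []
    for c, k in zip(chroms, alloc):
        pos = np.sort(rng.choice(np.arange(1, genome_layout[c]), size=k, replace=False))
        out_chrom.extend([c] * k)
        out_pos.extend(pos.tolist())
    return np.array(out_chrom), np.array(out_pos, dtype=int)


def region_class(offset: int, gene_length: int = 10000) -> str:
    """Genic region class from a probe's offset to its gene's TSS.

    Negative offsets are upstream: −1500..−201 bp is the distal promoter,
    −200..−1 the proximal promoter; downstream the gene runs 5′UTR, first
    exon, body, 3′UTR over ``gene_length`` bp; everything else is intergenic.
    """
    if -1500 <= offset <= -201:
        return "distal_promoter"
    if -200 <= offset <= -1:
        return "proximal_promoter"
    if 0 <= offset <= 199:
        return "5utr"
    if 200 <= offset <= 499:
        return "first_exon"
    if 500 <= offset <= gene_length - 501:
        return "gene_body"
    if gene_length - 500 <= offset <= gene_length:
        return "3utr"
    return "intergenic"


_TRAITS = [
    "height",
    "body_mass_index",
    "age_at_menarche",
    "malaria_resistance",
    "type2_diabetes",
    "immune_response",
    "blood_pressure",
    "lipid_levels",
    "bone_density",
    "asthma",
    "haemoglobin",
    "inflammation",
]


def simulate_annotations(
    design: CohortDesign,
    probe_chrom: np.ndarray,
    probe_pos: np.ndarray,
    snp_annot: pd.DataFrame,
    rng: np.random.Generator,
    panel: CellReferencePanel | None = None,
    n_genes: int | None = None,
    gene_length: int = 10000,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], pd.DataFrame, dict[str, list[str]], dict[str, np.ndarray]]:
    """Probe annotation, interval tracks, toy GWAS catalog, gene sets, PWMs."""
    n_probes = len(probe_pos)
    probes = [f"cg{i:06d}" for i in range(n_probes)]
    n_genes = n_genes or max(50, n_probes // 8)

    # genes: TSS laid out along the genome, probes attach to the nearest TSS
    gchrom, gtss = _layout_positions(design.genome_layout, n_genes, rng)
    genes = [f"gene{i:05d}" for i in range(n_genes)]
    gene_of = np.empty(n_probes, dtype=object)
    classes = np.empty(n_probes, dtype=object)
    for c in design.genome_layout:
        gmask = gchrom == c
        pmask = probe_chrom == c
        if not pmask.any():
            continue
        if not gmask.any():
            gene_of[pmask] = "none"
            classes[pmask] = "intergenic"
            continue
        tss = gtss[gmask]
        gids = np.asarray(genes, dtype=object)[gmask]
        k = np.searchsorted(tss, probe_pos[pmask])
        k = np.clip(k, 0, len(tss) - 1)
        kl = np.clip(k - 1, 0, len(tss) - 1)
        use_left = np.abs(probe_pos[pmask] - tss[kl]) < np.abs(probe_pos[pmask] - tss[k])
        nearest = np.where(use_left, kl, k)
        gene_of[pmask] = gids[nearest]
        offs = probe_pos[pmask] - tss[nearest]
        classes[pmask] = [region_class(int(o), gene_length) for o in offs]

    # random 30-bp context sequence around each probe (for PWM affinities)
    seqs = ["".join(s) for s in rng.choice(list("ACGT"), size=(n_probes, 30))]

    planted = {s.probe for s in design.meqtl_spec} | {s.probe for s in design.dms_spec}
    cross = (rng.random(n_probes) < 0.01) & ~np.isin(probes, list(planted))
    snp_freq = np.where(
        (rng.random(n_probes) < 0.02) & ~np.isin(probes, list(planted)),
        rng.uniform(0.011, 0.2, n_probes),
        0.0,
    )
    probe_annot = pd.DataFrame(
        {
            "probe": probes,
            "chrom": probe_chrom,
            "pos": probe_pos,
            "gene": gene_of,
            "region_class": classes,
            "cross_hybridizing": cross,
            "snp_in_probe_maxfreq": snp_freq,
            "cell_predictor": False,
            "sex_chromosome": False,
            "seq30": seqs,
        }
    ).set_index("probe")
    if panel is not None:
        pa = pd.DataFrame(
            {
                "chrom": [list(design.genome_layout)[0]] * len(panel.probe_ids),
                "pos": np.arange(1, len(panel.probe_ids) + 1),
                "gene": "none",
                "region_class": "intergenic",
                "cross_hybridizing": False,
                "snp_in_probe_maxfreq": 0.0,
                "cell_predictor": True,
                "sex_chromosome": False,
                "seq30": ["".join(s) for s in rng.choice(list("ACGT"), size=(len(panel.probe_ids), 30))],
            },
            index=pd.Index(panel.probe_ids, name="probe"),
        )
        probe_annot = pd.concat([probe_annot, pa])

    # interval tracks: histone-mark-like narrow peaks covering ~10% of genome
    tracks = {}
    for mark in ("H3K4me1", "H3K4me3", "H3K27me3"):
        rows = []
        for c, L in design.genome_layout.items():
            n_peaks = max(3, L // 200000)
            starts = np.sort(rng.integers(1, max(2, L - 2000), size=n_peaks))
            widths = rng.integers(500, 5000, size=n_peaks)
            for s, w in zip(starts, widths):
                rows.append({"chrom": c, "start": int(s), "end": int(min(s + w, L))})
        tracks[mark] = pd.DataFrame(rows)

    # toy GWAS catalog: a subset of SNPs carry trait associations
    n_hits = max(20, len(snp_annot) // 20)
    hit_snps = rng.choice(snp_annot.index.to_numpy(), size=n_hits, replace=False)
    hit_rows = []
    probe_gene = probe_annot.loc[~probe_annot["cell_predictor"], ["chrom", "pos", "gene"]]
    for s in hit_snps:
        srow = snp_annot.loc[s]
        same = probe_gene[probe_gene["chrom"] == srow["chrom"]]
        if len(same):
            g = same.iloc[(same["pos"] - srow["pos"]).abs().argmin()]["gene"]
        else:
            g = "none"
        hit_rows.append(
            {
                "snp": s,
                "reported_gene": g,
                "trait": rng.choice(_TRAITS),
                "pvalue": float(10 ** rng.uniform(-30, -4)),
            }
        )
    gwas = pd.DataFrame(hit_rows)

    # gene sets: random categories of variable size
    gene_sets = {}
    for i in range(30):
        size = int(rng.integers(5, max(6, n_genes // 5)))
        members = rng.choice(genes, size=min(size, n_genes), replace=False)
        gene_sets[f"CAT{i:03d}"] = sorted(members.tolist())

    # PWMs: random count matrices, JASPAR-style
    pwms = {}
    for i in range(8):
        L = int(rng.integers(6, 13))
        counts = rng.integers(0, 40, size=(4, L)).astype(float)
        counts[rng.integers(0, 4, size=L), np.arange(L)] += 60  # a consensus
        pwms[f"MA{i:04d}.1"] = counts
    return probe_annot, tracks, gwas, gene_sets, pwms


# ---------------------------------------------------------------------------
# top-level cohort generation


def simulate_cohort(design: CohortDesign) -> SyntheticCohort:
    """Generate a complete synthetic cohort from a :class:`CohortDesign`."""
    seed = design.seed
    rng_freq = stage_rng(seed, "frequencies")
    rng_hap = stage_rng(seed, "haplotypes")
    rng_sweep = stage_rng(seed, "sweeps")
    rng_meta = stage_rng(seed, "metadata")
    rng_meth = stage_rng(seed, "methylome")
    rng_annot = stage_rng(seed, "annotations")
    rng_panel = stage_rng(seed, "cellpanel")

    pops = design.pop_labels
    panel = design.cell_panel or default_cell_panel(rng_panel)

    snp_chrom, snp_pos = _layout_positions(design.genome_layout, design.n_snps, rng_freq)
    p_anc = rng_freq.uniform(0.05, 0.95, size=design.n_snps)
    freqs = simulate_population_frequencies(p_anc, [design.f_div[p] for p in pops], rng_freq)

    snp_ids = [f"rs{i:06d}" for i in range(design.n_snps)]
    ref_alt = np.array([["A", "G"], ["C", "T"], ["G", "A"], ["T", "C"]])
    ra = ref_alt[rng_freq.integers(0, 4, size=design.n_snps)]
    snp_annot = pd.DataFrame(
        {
            "chrom": snp_chrom,
            "pos": snp_pos,
            "ref": ra[:, 0],
            "alt": ra[:, 1],
            "ancestral": ra[:, 0],  # reference allele (code 0) is ancestral
        },
        index=pd.Index(snp_ids, name="snp"),
    )

    haplotypes: dict[str, np.ndarray] = {}
    for i, pop in enumerate(pops):
        per_chrom = []
        for c in design.genome_layout:
            mask = snp_chrom == c
            per_chrom.append(
                simulate_haplotypes(
                    freqs[i, mask],
                    2 * design.populations[pop],
                    snp_pos[mask],
                    design.rho,
                    rng_hap,
                    design.n_founders,
                )
            )
        haplotypes[pop] = np.hstack(per_chrom)

    sweep_rows = []
    snp_lookup = {s: j for j, s in enumerate(snp_ids)}
    for snp, pop, q, span in design.sweeps:
        if snp not in snp_lookup:
            raise ValueError(f"sweep focal SNP {snp} absent from panel")
        j = snp_lookup[snp]
        c = snp_chrom[j]
        mask = snp_chrom == c
        local = int(np.searchsorted(np.where(mask)[0], j))
        sub = haplotypes[pop][:, mask]
        sub, tr = inject_sweep(
            sub, snp_pos[mask], local, q, span, rng_sweep, design.genome_layout[c]
        )
        haplotypes[pop][:, mask] = sub
        sweep_rows.append(
            {"snp": snp, "population": pop, "carrier_fraction": tr["carrier_fraction"], "span_bp": span}
        )

    for pop in pops:
        haplotypes[pop] = np.ascontiguousarray(haplotypes[pop])

    # realized per-population derived (alt) allele frequencies
    for i, pop in enumerate(pops):
        snp_annot[f"freq_{pop}"] = haplotypes[pop].mean(axis=0)

    metadata = _sample_metadata(design, rng_meta)
    dosages = {p: (haplotypes[p][0::2] + haplotypes[p][1::2]).astype(np.int8) for p in pops}
    methyl, truth = simulate_methylome(
        design, dosages, pd.Index(snp_ids), metadata, rng_meth, panel
    )
    truth.sweeps = pd.DataFrame(
        sweep_rows, columns=["snp", "population", "carrier_fraction", "span_bp"]
    )

    probe_chrom, probe_pos = _layout_positions(design.genome_layout, design.n_probes, rng_annot)
    # planted meQTL probes must sit within the cis window of their SNP: pin them
    probe_idx = {f"cg{i:06d}": i for i in range(design.n_probes)}
    for spec in design.meqtl_spec:
        j = snp_lookup[spec.snp]
        pi = probe_idx[spec.probe]
        probe_chrom[pi] = snp_chrom[j]
        probe_pos[pi] = max(1, snp_pos[j] + int(rng_annot.integers(-50000, 50001)))
    probe_annot, tracks, gwas, gene_sets, pwms = simulate_annotations(
        design, probe_chrom, probe_pos, snp_annot, rng_annot, panel
    )

    return SyntheticCohort(
        design=design,
        snp_annot=snp_annot,
        probe_annot=probe_annot,
        haplotypes=haplotypes,
        metadata=metadata,
        methyl=methyl,
        truth=truth,
        tracks=tracks,
        gwas_catalog=gwas,
        gene_sets=gene_sets,
        pwms=pwms,
        panel=panel,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str) -> None:
    """Write all cohort artifacts as plain text under ``outdir``."""
    import os

    from . import io as pio

    os.makedirs(outdir, exist_ok=True)
    cohort.methyl.to_tsv(os.path.join(outdir, "methylation_M.tsv"))
    cohort.metadata.to_csv(os.path.join(outdir, "metadata.tsv"), sep="\t")
    cohort.probe_annot.to_csv(os.path.join(outdir, "probes.tsv"), sep="\t")
    cohort.snp_annot.to_csv(os.path.join(outdir, "snps.tsv"), sep="\t")
    samples, haps = [], []
    for pop in cohort.design.pop_labels:
        n = cohort.design.populations[pop]
        samples.extend(f"{pop}_{i:03d}" for i in range(n))
        haps.append(cohort.haplotypes[pop])
    pio.write_vcf(
        os.path.join(outdir, "genotypes.vcf"),
        cohort.snp_annot,
        np.vstack(haps),
        samples,
    )
    for name, track in cohort.tracks.items():
        pio.write_narrowpeak(track, os.path.join(outdir, f"{name}.narrowPeak"))
    cohort.gwas_catalog.to_csv(os.path.join(outdir, "gwas_catalog.tsv"), sep="\t", index=False)
    pio.write_gmt(cohort.gene_sets, os.path.join(outdir, "gene_sets.gmt"))
    pio.write_jaspar_pwms(cohort.pwms, os.path.join(outdir, "pwms.jaspar"))
    cohort.truth.cell_proportions.to_csv(os.path.join(outdir, "truth_cellprops.tsv"), sep="\t")
    cohort.truth.dms_effects.to_csv(os.path.join(outdir, "truth_dms.tsv"), sep="\t", index=False)
    cohort.truth.meqtl_effects.to_csv(os.path.join(outdir, "truth_meqtl.tsv"), sep="\t", index=False)
    cohort.truth.sweeps.to_csv(os.path.join(outdir, "truth_sweeps.tsv"), sep="\t", index=False)
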