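"""Methylation matrix container, probe filtering, cell deconvolution, adjustment.

The array reports a methylation fraction β in (0,1) per probe; linear
modelling is done on the logit-like M-value, M = log2(β/(1−β)).  The two
scales are lossless views of each other and :class:`MethylMatrix` carries a
scale tag so conversions are explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "MethylMatrix",
    "CellReferencePanel",
    "beta_to_m",
    "m_to_beta",
    "convert_scale",
    "filter_probes",
    "estimate_cell_proportions",
    "adjust_mvalues",
    "annotate_sites_with_intervals",
]


def beta_to_m(beta: np.ndarray) -> np.ndarray:
    """M = log2(β / (1−β)).  β must lie strictly in (0,1)."""
    beta = np.asarray(beta, dtype=float)
    bad = (beta <= 0) | (beta >= 1)
    if np.any(bad):
        raise ValueError(
            f"{int(bad.sum())} beta values at or outside (0,1); M is infinite there"
        )
    return np.log2(beta / (1.0 - beta))


def m_to_beta(m: np.ndarray) -> np.ndarray:
    """β = 2^M / (2^M + 1), the exact inverse of :func:`beta_to_m`."""
    m = np.asarray(m, dtype=float)
    # expm form keeps the round trip exact to ~1e-16 for moderate M
    return 1.0 / (1.0 + np.exp2(-m))


@dataclass
class MethylMatrix:
    """Probes x samples methylation values with a lossless β↔M dual view."""

    values: np.ndarray
    probes: pd.Index
    samples: pd.Index
    scale: str = "M"  # "M" or "beta"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.probes = pd.Index(self.probes)
        self.samples = pd.Index(self.samples)
        if self.values.shape != (len(self.probes), len(self.samples)):
            raise ValueError("values shape does not match probe/sample ids")
        if self.scale not in ("M", "beta"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite methylation values")

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, scale: str = "M") -> "MethylMatrix":
        return cls(df.to_numpy(float), df.index, df.columns, scale)

    @classmethod
    def from_tsv(cls, path: str, scale: str = "M") -> "MethylMatrix":
        from .io import read_methylation_tsv

        return cls.from_dataframe(read_methylation_tsv(path), scale)

    # -- views --------------------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probes, columns=self.samples)

    def to_m(self) -> "MethylMatrix":
        return convert_scale(self, "M")

    def to_beta(self) -> "MethylMatrix":
        return convert_scale(self, "beta")

    def to_tsv(self, path: str) -> None:
        from .io import write_methylation_tsv

        write_methylation_tsv(self.df, path)

    def subset_probes(self, keep) -> "MethylMatrix":
        mask = self.probes.isin(keep)
        return MethylMatrix(self.values[mask], self.probes[mask], self.samples, self.scale)


def convert_scale(matrix: MethylMatrix, target: str) -> MethylMatrix:
    if target not in ("M", "beta"):
        raise ValueError(f"unknown target scale {target!r}")
    if matrix.scale == target:
        return matrix
    if target == "M":
        vals = beta_to_m(matrix.values)
    else:
        vals = m_to_beta(matrix.values)
    return MethylMatrix(vals, matrix.probes, matrix.samples, target)


# ---------------------------------------------------------------------------
# probe filtering


def filter_probes(
    matrix: MethylMatrix,
    annot: pd.DataFrame,
    snp_maxfreq_threshold: float = 0.01,
) -> tuple[MethylMatrix, dict[str, int]]:
    """Drop unreliable probes, mirroring standard 450K hygiene.

    Removal rules, applied in order with per-rule counts: (1) probes flagged
    as potentially cross-hybridizing, (2) probes on sex chromosomes, (3)
    probes whose interrogated CpG or probe body carries a SNP above
    ``snp_maxfreq_threshold`` in any study population (the annotation column
    ``snp_in_probe_maxfreq`` holds the max over populations), (4) probes used
    as cell-composition predictors.
    """
    missing = matrix.probes.difference(annot.index)
    if len(missing):
        raise ValueError(f"probes missing annotation: {list(missing[:10])}")
    ann = annot.loc[matrix.probes]
    alive = np.ones(len(matrix.probes), dtype=bool)
    report: dict[str, int] = {}

    rules = [
        ("cross_hybridizing", ann["cross_hybridizing"].to_numpy(bool)),
        ("sex_chromosome", ann["sex_chromosome"].to_numpy(bool)),
        (
            "snp_in_probe",
            ann["snp_in_probe_maxfreq"].to_numpy(float) > snp_maxfreq_threshold,
        ),
        ("cell_predictor", ann["cell_predictor"].to_numpy(bool)),
    ]
    for name, hit in rules:
        removed = alive & hit
        report[name] = int(removed.sum())
        alive &= ~hit
    report["retained"] = int(alive.sum())
    out = MethylMatrix(
        matrix.values[alive], matrix.probes[alive], matrix.samples, matrix.scale
    )
    return out, report


# ---------------------------------------------------------------------------
# reference-based cell deconvolution


@dataclass
class CellReferencePanel:
    """Reference β profiles of purified leukocyte types over a probe subset."""

    cell_types: list[str]
    probe_ids: list[str]
    profiles: np.ndarray = field(repr=False)  # panel probes x cell types, β scale

    def __post_init__(self):
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.shape != (len(self.probe_ids), len(self.cell_types)):
            raise ValueError("profile shape mismatch")
        if np.any((self.profiles <= 0) | (self.profiles >= 1)):
            raise ValueError("reference β profiles must lie in (0,1)")
        d = self.profiles
        for i in range(d.shape[1]):
            for j in range(i + 1, d.shape[1]):
                if np.allclose(d[:, i], d[:, j]):
                    raise ValueError("reference profiles must be pairwise distinct")


def estimate_cell_proportions(
    matrix: MethylMatrix, panel: CellReferencePanel
) -> tuple[pd.DataFrame, pd.Series]:
    """Nonnegative least squares of each sample's β against the reference
    profiles, rescaled to sum to one.

    Returns (proportions samples x cell types, residual norm per sample).
    """
    beta = matrix.to_beta()
    present = [p for p in panel.probe_ids if p in set(beta.probes)]
    if len(present) < len(panel.cell_types):
        raise ValueError(
            f"only {len(present)} panel probes present for {len(panel.cell_types)} "
            "cell types: rank deficient"
        )
    idx = [panel.probe_ids.index(p) for p in present]
    A = panel.profiles[idx]
    B = beta.df.loc[present].to_numpy(float)
    props = np.zeros((len(beta.samples), len(panel.cell_types)))
    resid = np.zeros(len(beta.samples))
    for i in range(B.shape[1]):
        w, r = nnls(A, B[:, i])
        total = w.sum()
        props[i] = w / total if total > 0 else 1.0 / len(w)
        resid[i] = r
    out = pd.DataFrame(props, index=beta.samples, columns=panel.cell_types)
    return out, pd.Series(resid, index=beta.samples, name="residual_norm")


# ---------------------------------------------------------------------------
# covariate adjustment


def adjust_mvalues(
    matrix: MethylMatrix,
    covariates: pd.DataFrame,
    terms: list[str],
) -> MethylMatrix:
    """Residualize M-values on nuisance covariates, keeping each probe's mean.

    ``terms`` name numeric columns of ``covariates`` (e.g. age, sex indicator,
    cell-proportion columns).  The design factor of interest (population or
    habitat) is deliberately NOT listed here, so downstream group contrasts
    remain unbiased.  Categorical-looking columns are coerced via codes.
    """
    if matrix.scale != "M":
        matrix = matrix.to_m()
    cols = []
    for t in terms:
        col = covariates[t]
        if col.isna().any():
            raise ValueError(f"missing values in covariate {t!r}")
        if not np.issubdtype(col.dtype, np.number):
            col = col.astype("category").cat.codes
        cols.append(col.to_numpy(float))
    if not cols:
        return matrix
    Z = np.column_stack(cols)
    Zc = Z - Z.mean(axis=0)
    # drop identically-zero (constant) covariates: nothing to remove
    keep = Zc.std(axis=0) > 0
    Zc = Zc[:, keep]
    if Zc.shape[1] == 0:
        return matrix
    rank = np.linalg.matrix_rank(Zc)
    if rank < Zc.shape[1]:
        raise ValueError(
            f"collinear covariates among {list(np.asarray(terms)[keep])}: rank {rank} < {Zc.shape[1]}"
        )
    coef, *_ = np.linalg.lstsq(Zc, matrix.values.T, rcond=None)
    adjusted = matrix.values - (Zc @ coef).T
    return MethylMatrix(adjusted, matrix.probes, matrix.samples, "M")


# ---------------------------------------------------------------------------
# interval colocalization


def annotate_sites_with_intervals(
    chroms: np.ndarray,
    positions: np.ndarray,
    track: pd.DataFrame,
) -> np.ndarray:
    """Flag which 1-based site positions fall inside any track interval.

    ``track`` carries 1-based inclusive ``chrom``/``start``/``end`` columns
    (the readers in :mod:`popepimeth.io` produce this convention from BED's
    0-based half-open records).
    """
    chroms = np.asarray(chroms)
    positions = np.asarray(positions, dtype=int)
    site_chroms = set(np.unique(chroms))
    track_chroms = set(track["chrom"].unique())
    unmatched = site_chroms - track_chroms
    if unmatched and not site_chroms & track_chroms:
        raise ValueError(f"chromosome names unmatched between sites and track: {sorted(unmatched)}")
    flags = np.zeros(len(positions), dtype=bool)
    for chrom, grp in track.groupby("chrom"):
        mask = chroms == chrom
        if not mask.any():
            continue
        ivals = grp.sort_values("start")
        starts = ivals["start"].to_numpy(int)
        ends = ivals["end"].to_numpy(int)
        # merge overlapping intervals so searchsorted is sufficient
        mstart, mend = [starts[0]], [ends[0]]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= mend[-1] + 1:
                mend[-1] = max(mend[-1], e)
            else:
                mstart.append(s)
                mend.append(e)
        ms = np.array(mstart)
        me = np.array(mend)
        pos = positions[mask]
        k = np.searchsorted(ms, pos, side="right") - 1
        inside = (k >= 0) & (pos <= me[np.clip(k, 0, len(me) - 1)])
        flags[mask] = inside
    return flags
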