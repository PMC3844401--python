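"""Per-pair differential expression with empirical-Bayes variance moderation.

The pipeline consumes a normalized log2 expression matrix (probe/gene rows,
sample columns — e.g. RMA output) and a sample sheet mapping samples to
populations and populations to ontology classes.  For each ordered population
pair it fits the two-group contrast per gene, shrinks the residual variances
toward a common prior estimated from all genes, and thresholds the moderated
results into up/down gene sets (default: > 1.5-fold and BH-adjusted p < 0.05).

The moderated t follows the standard hierarchical model for microarray data:
the gene-wise residual variance s_g^2 (d_g df) is combined with a prior
(d0, s0^2) as

    s~_g^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g)

and t_g = log2FC_g / (s~_g * sqrt(1/n_i + 1/n_j)) is referred to a t
distribution on d0 + d_g degrees of freedom.  (d0, s0^2) are estimated by
method of moments on log s_g^2, matching the moments of log F-distributed
variance ratios via digamma/trigamma identities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = [
    "ExpressionMatrix",
    "SampleSheet",
    "DEResult",
    "moderated_de",
    "bh_adjust",
    "threshold_gene_sets",
    "estimate_variance_prior",
    "collapse_probes",
    "quantile_normalize",
]


class ExpressionMatrix:
    """Log2-scale expression values, genes x samples, no missing entries."""

    def __init__(self, data: pd.DataFrame):
        if data.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        if data.index.has_duplicates:
            raise ValidationError("duplicate gene identifiers in expression matrix")
        if data.columns.has_duplicates:
            raise ValidationError("duplicate sample identifiers in expression matrix")
        self.data = data.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @classmethod
    def read_tsv(cls, path_or_buf: str | IO[str]) -> "ExpressionMatrix":
        return cls(pd.read_csv(path_or_buf, sep="\t", index_col=0))

    def write_tsv(self, path_or_buf: str | IO[str]) -> None:
        self.data.to_csv(path_or_buf, sep="\t", index_label="gene")


@dataclass
class SampleSheet:
    """Maps samples to populations and populations to ontology classes.

    Every sample belongs to exactly one population, every population to
    exactly one class; multiple populations may share a class (same cell type
    sampled e.g. from different anatomical sites).
    """

    sample_to_population: dict[str, str]
    population_to_class: dict[str, str]
    population_metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pops = set(self.sample_to_population.values())
        missing = sorted(pops - set(self.population_to_class))
        if missing:
            raise ValidationError("populations without a class mapping: " + ", ".join(missing))

    @property
    def populations(self) -> list[str]:
        return sorted(set(self.sample_to_population.values()))

    def samples_of(self, population: str) -> list[str]:
        return sorted(s for s, p in self.sample_to_population.items() if p == population)

    @classmethod
    def read_tsv(cls, path_or_buf: str | IO[str]) -> "SampleSheet":
        df = pd.read_csv(path_or_buf, sep="\t", dtype=str)
        required = {"sample", "population", "class"}
        if not required.issubset(df.columns):
            raise ValidationError(f"sample sheet needs columns {sorted(required)}")
        s2p = dict(zip(df["sample"], df["population"]))
        if len(s2p) != len(df):
            raise ValidationError("duplicate sample identifiers in sample sheet")
        p2c: dict[str, str] = {}
        for pop, cls_ in zip(df["population"], df["class"]):
            if pop in p2c and p2c[pop] != cls_:
                raise ValidationError(f"population {pop!r} mapped to more than one class")
            p2c[pop] = cls_
        meta = {}
        if "site" in df.columns:
            meta = {p: s for p, s in zip(df["population"], df["site"].fillna(""))}
        return cls(s2p, p2c, meta)

    def write_tsv(self, path_or_buf: str | IO[str]) -> None:
        rows = [
            {
                "sample": s,
                "population": p,
                "class": self.population_to_class[p],
                "site": self.population_metadata.get(p, ""),
            }
            for s, p in sorted(self.sample_to_population.items())
        ]
        pd.DataFrame(rows).to_csv(path_or_buf, sep="\t", index=False)


@dataclass
class DEResult:
    """Differential-expression statistics for one ordered population pair.

    ``log2_fold_change`` is mean(population_i) - mean(population_j), so
    positive values are up in the first population.  ``zero_variance`` flags
    genes whose moderated variance was exactly zero (noiseless data): their t
    is reported as sign(log2FC)*inf with p = 0 (p = 1 when the fold change is
    also zero).
    """

    pair: tuple[str, str]
    genes: list[str]
    log2_fold_change: np.ndarray
    t_statistic: np.ndarray
    p_value: np.ndarray
    adj_p_value: np.ndarray
    prior_df: float
    prior_var: float
    residual_df: float
    zero_variance: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "log2_fold_change": self.log2_fold_change,
                "t": self.t_statistic,
                "p_value": self.p_value,
                "adj_p_value": self.adj_p_value,
            },
            index=pd.Index(self.genes, name="gene"),
        )


def bh_adjust(pvals: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if x <= 0:
        raise ValueError("trigamma inverse requires x > 0")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments estimate of the variance prior (d0, s0^2).

    Matches the first two moments of log s_g^2 under s_g^2 ~ s0^2 F(df, d0).
    Genes with zero variance are excluded from the moment fit.  Returns
    ``d0 = inf`` (full pooling) when the moment estimate is non-finite, and
    ``(inf, 0.0)`` when every gene has zero residual variance.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        return np.inf, 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    if e.size < 2:
        return np.inf, float(np.exp(emean))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if not np.isfinite(evar) or evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    if not (np.isfinite(d0) and np.isfinite(s0_sq)):
        return np.inf, float(np.exp(emean))
    return d0, s0_sq


def moderated_de(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    pair: tuple[str, str],
    min_replicates: int = 2,
    prior_df: float | None = None,
) -> DEResult:
    """Two-group moderated-t contrast for one ordered population pair.

    ``prior_df`` overrides the estimated d0 (``0`` disables shrinkage and
    recovers the classical pooled two-sample t; ``inf`` pools fully).
    """
    pop_i, pop_j = pair
    groups = []
    for pop in pair:
        samples = sheet.samples_of(pop)
        if len(samples) < min_replicates:
            raise ValidationError(
                f"population {pop!r} has {len(samples)} samples; "
                f"need >= {min_replicates} for variance estimation"
            )
        missing = [s for s in samples if s not in matrix.data.columns]
        if missing:
            raise ValidationError(f"samples missing from matrix: {', '.join(missing)}")
        groups.append(matrix.data[samples].to_numpy())

    xi, xj = groups
    ni, nj = xi.shape[1], xj.shape[1]
    mean_i, mean_j = xi.mean(axis=1), xj.mean(axis=1)
    lfc = mean_i - mean_j
    dg = ni + nj - 2
    ss = ((xi - mean_i[:, None]) ** 2).sum(axis=1) + ((xj - mean_j[:, None]) ** 2).sum(axis=1)
    s2 = ss / dg

    if prior_df is None:
        d0, s0_sq = estimate_variance_prior(s2, dg)
    else:
        d0 = float(prior_df)
        _, s0_sq = estimate_variance_prior(s2, dg) if d0 > 0 else (None, 0.0)

    if np.isinf(d0):
        s2_mod = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_mod = (d0 * s0_sq + dg * s2) / (d0 + dg)
        df_total = d0 + dg

    se = np.sqrt(s2_mod * (1.0 / ni + 1.0 / nj))
    zero_var = se == 0.0
    t = np.zeros_like(lfc)
    nz = ~zero_var
    t[nz] = lfc[nz] / se[nz]
    # zero moderated variance (noiseless data): t = sign(lfc)*inf, 0/0 -> 0
    tz = np.zeros(int(zero_var.sum()))
    sign_z = np.sign(lfc[zero_var])
    tz[sign_z > 0] = np.inf
    tz[sign_z < 0] = -np.inf
    t[zero_var] = tz

    p = np.ones_like(lfc)
    p[nz] = 2.0 * stats.t.sf(np.abs(t[nz]), df_total)
    p[zero_var & (lfc != 0)] = 0.0
    np.clip(p, 0.0, 1.0, out=p)

    return DEResult(
        pair=(pop_i, pop_j),
        genes=matrix.genes,
        log2_fold_change=lfc,
        t_statistic=t,
        p_value=p,
        adj_p_value=bh_adjust(p),
        prior_df=d0,
        prior_var=s0_sq,
        residual_df=dg,
        zero_variance=zero_var,
    )


def threshold_gene_sets(
    de: DEResult, fold_threshold: float = 1.5, alpha: float = 0.05
) -> tuple[dict[str, float], dict[str, float]]:
    """Split a DE result into up/down gene sets (strict thresholds).

    A gene is up when its linear fold change exceeds ``fold_threshold`` and
    its BH-adjusted p-value is below ``alpha``; down symmetrically.  Returned
    maps are gene -> log2 fold change (positive in up, negative in down).
    """
    if fold_threshold <= 1.0:
        raise ValidationError("fold_threshold must exceed 1 (linear scale)")
    if not (0.0 < alpha <= 1.0):
        raise ValidationError("alpha must lie in (0, 1]")
    log_thr = np.log2(fold_threshold)
    sig = de.adj_p_value < alpha
    up_mask = sig & (de.log2_fold_change > log_thr)
    down_mask = sig & (de.log2_fold_change < -log_thr)
    genes = np.asarray(de.genes)
    up = {str(g): float(fc) for g, fc in zip(genes[up_mask], de.log2_fold_change[up_mask])}
    down = {str(g): float(fc) for g, fc in zip(genes[down_mask], de.log2_fold_change[down_mask])}
    return up, down


def collapse_probes(matrix: ExpressionMatrix, probe_to_gene: Mapping[str, str]) -> ExpressionMatrix:
    """Collapse probe rows to genes, keeping the probe with highest mean.

    Probes absent from the mapping are dropped.  Optional convenience for
    probe-level matrices; the pipeline otherwise uses row ids as-is.
    """
    df = matrix.data
    keep = df.index.intersection(list(probe_to_gene))
    df = df.loc[keep]
    order = df.mean(axis=1).sort_values(ascending=False).index
    df = df.loc[order]
    gene_ids = df.index.map(probe_to_gene)
    first = ~pd.Index(gene_ids).duplicated(keep="first")
    collapsed = df.loc[first]
    collapsed.index = pd.Index(gene_ids[first], name="gene")
    return ExpressionMatrix(collapsed.sort_index())


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize columns to a common distribution (mean of sorted)."""
    df = matrix.data
    ranks = df.rank(method="average")
    mean_sorted = np.sort(df.to_numpy(), axis=0).mean(axis=1)
    normed = ranks.apply(lambda r: np.interp(r, np.arange(1, len(r) + 1), mean_sorted))
    return ExpressionMatrix(pd.DataFrame(normed, index=df.index, columns=df.columns))
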