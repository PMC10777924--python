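"""Expression quantification and differential expression.

Normalization follows the median-of-ratios scheme; testing is a negative
binomial Wald test with method-of-moments dispersion shrunk toward a fitted
mean-dispersion trend (``alpha = a0 + a1/mean``), with Benjamini-Hochberg
adjustment across rows.  This is DESeq2-equivalent in design, not
bit-identical.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .models import ReferenceAnnotation

DE_LFC_THRESHOLD = 1.0
DE_PADJ_THRESHOLD = 0.05
LFC_PSEUDOCOUNT = 0.5
HIGH_EXPRESSION_FPKM = 60.0
DISPERSION_PRIOR_DF = 8.0


def fpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """FPKM[i,j] = counts[i,j] * 1e9 / (length[i] * total_mapped[j])."""
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("all feature lengths must be positive")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("every sample must have a positive library size")
    return counts * 1e9 / np.outer(lengths.to_numpy(), totals.to_numpy())


def expression_classes(
    fpkm_matrix: pd.DataFrame,
    design: Mapping[str, str],
    high_threshold: float = HIGH_EXPRESSION_FPKM,
) -> Dict[str, object]:
    """Highly expressed rows per sample (FPKM > threshold, strict) and
    commonly expressed rows per tissue (FPKM > 0 in every replicate), plus
    Venn-style intersection counts across tissues."""
    highly = {
        sample: set(fpkm_matrix.index[fpkm_matrix[sample] > high_threshold])
        for sample in fpkm_matrix.columns
    }
    tissues = sorted(set(design.values()))
    common: Dict[str, set] = {}
    for t in tissues:
        samples = [s for s, tt in design.items() if tt == t]
        mask = (fpkm_matrix[samples] > 0).all(axis=1)
        common[t] = set(fpkm_matrix.index[mask])
    venn: Dict[str, int] = {}
    for r in range(1, 2 ** len(tissues)):
        included = [t for i, t in enumerate(tissues) if r >> i & 1]
        excluded = [t for t in tissues if t not in included]
        members = set(fpkm_matrix.index)
        for t in included:
            members &= common[t]
        for t in excluded:
            members -= common[t]
        venn["&".join(included)] = len(members)
    return {
        "highly_expressed": highly,
        "commonly_expressed": common,
        "venn": venn,
    }


def size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios normalization factors.

    Uses rows with all-positive counts; with ``pseudo_reference=True`` the
    geometric mean is computed over counts+1 for all rows instead (fallback
    when no row is all-positive).
    """
    x = counts.to_numpy(dtype=float)
    if pseudo_reference:
        x = x + 1.0
        rows = np.ones(x.shape[0], dtype=bool)
    else:
        rows = (x > 0).all(axis=1)
        if not rows.any():
            raise ValueError(
                "no row with all-positive counts; rerun with pseudo_reference=True"
            )
    logs = np.log(x[rows])
    geomean = np.exp(logs.mean(axis=1))
    ratios = x[rows] / geomean[:, None]
    return pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _fit_dispersion_trend(means: np.ndarray, alphas: np.ndarray) -> Tuple[float, float]:
    """Least-squares fit of alpha ~ a0 + a1/mean over informative rows."""
    ok = (means > 1.0) & (alphas > 0)
    if ok.sum() < 10:
        med = float(np.median(alphas[alphas > 0])) if (alphas > 0).any() else 0.01
        return med, 0.0
    x = 1.0 / means[ok]
    y = alphas[ok]
    a1, a0 = np.polyfit(x, y, 1)
    a0 = max(float(a0), 1e-8)
    a1 = max(float(a1), 0.0)
    return a0, a1


def nb_test(
    counts: pd.DataFrame,
    design: Mapping[str, str],
    pair: Tuple[str, str],
    factors: Optional[pd.Series] = None,
    prior_df: float = DISPERSION_PRIOR_DF,
    lfc_threshold: float = DE_LFC_THRESHOLD,
    padj_threshold: float = DE_PADJ_THRESHOLD,
) -> pd.DataFrame:
    """Per-row NB Wald test of tissue ``pair[1]`` versus ``pair[0]``.

    Returns a frame with baseMean, log2fc (log2 of pair[1] over pair[0]),
    p, padj, and is_de (|log2fc| > 1 and padj < 0.05).  All-zero rows get
    log2fc = 0 and p = 1 by convention.
    """
    t_ref, t_alt = pair
    samples_ref = [s for s, t in design.items() if t == t_ref and s in counts.columns]
    samples_alt = [s for s, t in design.items() if t == t_alt and s in counts.columns]
    if len(samples_ref) < 2 or len(samples_alt) < 2:
        raise ValueError("need at least two replicates per tissue in the pair")
    sub = counts[samples_ref + samples_alt]
    if factors is None:
        try:
            factors = size_factors(sub)
        except ValueError:
            factors = size_factors(sub, pseudo_reference=True)
    norm = sub / factors.reindex(sub.columns)
    a = norm[samples_ref].to_numpy(dtype=float)
    b = norm[samples_alt].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    m_a = a.mean(axis=1)
    m_b = b.mean(axis=1)
    base_mean = norm.mean(axis=1).to_numpy()

    # pooled method-of-moments dispersion
    ss = ((a - m_a[:, None]) ** 2).sum(axis=1) + ((b - m_b[:, None]) ** 2).sum(axis=1)
    df = na + nb - 2
    pooled_var = ss / df
    pooled_mean = (na * m_a + nb * m_b) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = np.where(
            pooled_mean > 0, (pooled_var - pooled_mean) / pooled_mean**2, 0.0
        )
    alpha_mom = np.clip(alpha_mom, 0.0, 10.0)
    a0, a1 = _fit_dispersion_trend(pooled_mean, alpha_mom)
    alpha_trend = a0 + a1 / np.maximum(pooled_mean, 1e-8)
    alpha = (df * alpha_mom + prior_df * alpha_trend) / (df + prior_df)

    ma = m_a + LFC_PSEUDOCOUNT
    mb = m_b + LFC_PSEUDOCOUNT
    log2fc = np.log2(mb / ma)
    # delta-method SE of log2 fold-change under NB variance mu + alpha*mu^2
    var_a = (ma + alpha * ma**2) / (na * ma**2)
    var_b = (mb + alpha * mb**2) / (nb * mb**2)
    se = np.sqrt(var_a + var_b) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(wald))
    all_zero = (sub.to_numpy() == 0).all(axis=1)
    log2fc[all_zero] = 0.0
    p[all_zero] = 1.0
    p = np.clip(p, 0.0, 1.0)
    padj = bh_adjust(p)
    result = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2fc": log2fc,
            "p": p,
            "padj": padj,
        },
        index=sub.index,
    )
    result["is_de"] = (np.abs(result["log2fc"]) > lfc_threshold) & (
        result["padj"] < padj_threshold
    )
    return result


def gene_level_counts(
    counts: pd.DataFrame, ann: ReferenceAnnotation
) -> Tuple[pd.DataFrame, pd.Series]:
    """Sum member-transcript counts per gene; gene length = union-exon length."""
    mapping = {iso.id: g.id for g in ann.genes for iso in g.isoforms}
    grouped = counts.groupby([mapping.get(i, i) for i in counts.index]).sum()
    lengths = pd.Series(
        {g.id: g.union_exon_length for g in ann.genes}, name="length"
    ).reindex(grouped.index)
    return grouped, lengths


def transcript_lengths(ann: ReferenceAnnotation) -> pd.Series:
    return pd.Series(
        {iso.id: iso.exonic_length for iso in ann.transcripts}, name="length"
    )
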