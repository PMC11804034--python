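"""Differential eccGene abundance between cancer and noncancer samples.

The count matrix holds, per gene and sample, the number of eccDNA records
overlapping that gene (a record overlapping several genes increments each
of them). Differential assessment follows the classic exact-test route for
negative-binomial counts: library-size normalization to the geometric-mean
library, a single common dispersion estimated by method of moments across
genes, and a conditional two-sided exact test on pooled group sums; with
dispersion 0 this degenerates to the binomial/Poisson exact test. This is
a behavioral approximation of edgeR's classic pipeline (no TMM, no
tagwise shrinkage); the matrix can be exported for edgeR on real data.

The reported filter is the study criterion: fold change >= 2 (either
direction) and BH-adjusted p < 0.05.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .records import SampleProfile

log = logging.getLogger("bilecirc")


def build_count_matrix(profiles: list[SampleProfile],
                       gene_hits: dict[str, dict[str, list[str]]],
                       fractional: bool = False) -> pd.DataFrame:
    """Genes x samples matrix of eccDNA-per-gene counts.

    ``gene_hits`` maps sample id -> (ecc id -> overlapping gene ids). Each
    record contributes 1 to every gene it overlaps; with ``fractional`` the
    contribution is split 1/k over its k genes instead. Empty samples keep
    their (all-zero) column with a logged warning.
    """
    counts: dict[str, dict[str, float]] = {}
    sample_ids = [p.sample_id for p in profiles]
    for p in profiles:
        col: dict[str, float] = {}
        hits = gene_hits.get(p.sample_id, {})
        for rec in p.eccdna:
            genes = hits.get(rec.id, [])
            w = 1.0 / len(genes) if (fractional and genes) else 1.0
            for g in genes:
                col[g] = col.get(g, 0.0) + w
        if not p.eccdna:
            log.warning("sample %s has zero eccDNA; zero column retained",
                        p.sample_id)
        counts[p.sample_id] = col
    genes = sorted({g for col in counts.values() for g in col})
    mat = pd.DataFrame(0.0, index=genes, columns=sample_ids)
    for sid, col in counts.items():
        for g, v in col.items():
            mat.loc[g, sid] = v
    return mat if fractional else mat.round().astype(int)


def library_sizes(matrix: pd.DataFrame,
                  profiles: list[SampleProfile] | None = None) -> pd.Series:
    """Library size per sample: total eccDNA count when profiles are given,
    else the column sum."""
    if profiles is not None:
        return pd.Series({p.sample_id: max(len(p.eccdna), 1)
                          for p in profiles})[matrix.columns]
    return matrix.sum(axis=0).clip(lower=1)


def estimate_common_dispersion(scaled: np.ndarray, groups: np.ndarray) -> float:
    """Method-of-moments common NB dispersion across genes.

    Pools (variance - mean) against mean^2 within each group, so group
    mean differences do not inflate the estimate. Clipped at 0.
    """
    num = den = 0.0
    for g in np.unique(groups):
        sub = scaled[:, groups == g]
        if sub.shape[1] < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += float(np.sum(v - m))
        den += float(np.sum(m ** 2))
    return max(num / den, 0.0) if den > 0 else 0.0


def _nb_pmf(k: np.ndarray, mean: float, dispersion: float) -> np.ndarray:
    if mean <= 0:
        return (k == 0).astype(float)
    if dispersion <= 0:
        return stats.poisson.pmf(k, mean)
    r = 1.0 / dispersion
    return stats.nbinom.pmf(k, r, r / (r + mean))


def nb_exact_pvalue(s1: int, n1: int, s2: int, n2: int,
                    dispersion: float) -> float:
    """Two-sided conditional exact p for pooled group sums.

    The sum of n i.i.d. NB(mu, phi) counts is NB with mean n*mu and
    dispersion phi/n. Conditioning on the total, the p value sums the
    probabilities of all splits no more likely than the observed one
    (edgeR's doubling-free convention). dispersion 0 reduces the
    conditional law to Binomial(total, n1/(n1+n2)).
    """
    total = s1 + s2
    if total == 0:
        return 1.0
    mu = total / (n1 + n2)
    k = np.arange(total + 1)
    p1 = _nb_pmf(k, n1 * mu, dispersion / n1)
    p2 = _nb_pmf(k[::-1], n2 * mu, dispersion / n2)
    joint = p1 * p2
    tot = joint.sum()
    if tot <= 0:
        return 1.0
    obs = joint[s1]
    return float(min(joint[joint <= obs * (1 + 1e-10)].sum() / tot, 1.0))


def nb_exact_test(matrix: pd.DataFrame, groups: dict[str, str],
                  dispersion: float | None = None,
                  lib_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Per-gene NB exact test of cancer vs noncancer counts.

    Counts are proportion-scaled to the geometric-mean library and rounded;
    fold change is the ratio of normalized group means with pseudo-count
    0.5 (cancer over noncancer). ``lib_sizes`` should be the per-sample
    total eccDNA counts where available (column sums are a fallback that
    is composition-sensitive when many genes shift). Requires >= 2
    samples per group.
    """
    glab = np.array([groups[c] for c in matrix.columns])
    n1 = int((glab == "cancer").sum())
    n2 = int((glab == "noncancer").sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples per group")
    if lib_sizes is None:
        lib_sizes = library_sizes(matrix)
    libs = lib_sizes[matrix.columns].to_numpy(dtype=float)
    if np.any(libs <= 0):
        raise ValueError("zero library size")
    geo = float(np.exp(np.mean(np.log(libs))))
    scaled = np.rint(matrix.to_numpy(dtype=float) * (geo / libs)).astype(int)
    if dispersion is None:
        dispersion = estimate_common_dispersion(scaled.astype(float), glab)
    c_mask, n_mask = glab == "cancer", glab == "noncancer"
    rows = []
    for gi, gene in enumerate(matrix.index):
        s1 = int(scaled[gi, c_mask].sum())
        s2 = int(scaled[gi, n_mask].sum())
        p = nb_exact_pvalue(s1, n1, s2, n2, dispersion)
        fc = (s1 / n1 + 0.5) / (s2 / n2 + 0.5)
        rows.append({"gene": gene, "cancer_mean": s1 / n1,
                     "noncancer_mean": s2 / n2, "fold_change": fc,
                     "log2_fold_change": float(np.log2(fc)), "p": p})
    df = pd.DataFrame(rows).set_index("gene")
    df["padj"] = bh_adjust(df["p"].to_numpy())
    df["direction"] = np.where(df["fold_change"] >= 1, "up", "down")
    df.attrs["dispersion"] = dispersion
    return df


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1] if p.size else p


def filter_differential(results: pd.DataFrame, fc_threshold: float = 2.0,
                        padj_threshold: float = 0.05) -> pd.DataFrame:
    """Apply the study filter: |fold| >= threshold (inclusive) and
    padj < threshold (strict). Adds a ``passes_filter`` column and returns
    the annotated table; up/down lists come from ``direction``."""
    res = results.copy()
    up = (res["fold_change"] >= fc_threshold) & (res["padj"] < padj_threshold)
    down = (res["fold_change"] <= 1.0 / fc_threshold) & \
        (res["padj"] < padj_threshold)
    res["passes_filter"] = up | down
    return res


def differential_gene_lists(results: pd.DataFrame, fc_threshold: float = 2.0,
                            padj_threshold: float = 0.05
                            ) -> tuple[list[str], list[str]]:
    res = filter_differential(results, fc_threshold, padj_threshold)
    up = res.index[res["passes_filter"] & (res["direction"] == "up")]
    down = res.index[res["passes_filter"] & (res["direction"] == "down")]
    return sorted(up), sorted(down)
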