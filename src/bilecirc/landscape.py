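"""Cohort-level landscape statistics of called eccDNA.

Covers the descriptive profile of the two groups: eccDNA count per mapped
read, size distributions (cumulative curve, histogram, KDE peaks), length
bin comparisons, chromosome-of-origin distribution normalized by
chromosome length, and 1-Mb window coverage tracks.

Group comparisons use a two-tailed unpaired t test when both groups pass
Shapiro-Wilk normality at alpha = 0.05, otherwise the Mann-Whitney
rank-sum test (a paired signed-rank variant is available for paired use).
p values are reported raw with BH-adjusted values alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats
from statsmodels.stats.multitest import multipletests

from .records import SampleProfile

DEFAULT_BINS = ((0, 250), (250, 500), (500, 1000), (1000, 2000))


def count_per_mapped_read(profile: SampleProfile) -> float:
    """eccDNA records per downsampled mapped read."""
    if profile.downsampled_read_count <= 0:
        raise ValueError("no mapped reads")
    return len(profile.eccdna) / profile.downsampled_read_count


# ------------------------------------------------------------------ sizes

@dataclass
class SizeProfileSummary:
    lengths: np.ndarray
    cumulative_x: np.ndarray
    cumulative_y: np.ndarray
    histogram: tuple[np.ndarray, np.ndarray]  # (counts, edges)
    peaks: list[tuple[float, float]]  # (center bp, prominence)


def cumulative_size_curve(lengths: np.ndarray, upper: int = 2000
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Empirical cumulative frequency on (0, upper]; nondecreasing, <= 1."""
    lengths = np.asarray(lengths)
    x = np.arange(1, upper + 1)
    y = np.searchsorted(np.sort(lengths), x, side="right") / len(lengths)
    return x, y


def detect_size_peaks(lengths, bandwidth_bp: float = 25.0,
                      prominence_frac: float = 0.05,
                      size_range: tuple[float, float] = (0, 2000),
                      grid_step: float | None = None
                      ) -> list[tuple[float, float]]:
    """KDE peak detection on the size distribution.

    A Gaussian kernel of width ``bandwidth_bp`` is applied on a regular
    grid over ``size_range``; peaks are local maxima with prominence
    >= ``prominence_frac`` x the global density maximum, returned sorted by
    center. Requires >= 100 lengths in range.
    """
    lengths = np.asarray(lengths, dtype=float)
    lo, hi = size_range
    in_range = lengths[(lengths > lo) & (lengths <= hi)]
    if len(in_range) < 100:
        raise ValueError(f"need >= 100 lengths in range, got {len(in_range)}")
    step = grid_step if grid_step is not None else bandwidth_bp / 10.0
    edges = np.arange(lo, hi + step, step)
    hist, _ = np.histogram(in_range, bins=edges)
    # nearest padding keeps a flat density flat at the range boundaries
    # (zero padding would turn the whole interior into one broad peak)
    density = ndimage.gaussian_filter1d(hist.astype(float),
                                        sigma=bandwidth_bp / step,
                                        mode="nearest")
    if density.max() <= 0:
        return []
    idx, props = signal.find_peaks(density,
                                   prominence=prominence_frac * density.max())
    centers = (edges[:-1] + step / 2)[idx]
    return sorted(zip(centers.tolist(),
                      (props["prominences"] / density.max()).tolist()))


def size_profile(lengths, upper: int = 2000, **peak_kwargs) -> SizeProfileSummary:
    lengths = np.asarray(lengths)
    x, y = cumulative_size_curve(lengths, upper)
    hist = np.histogram(lengths[(lengths > 0) & (lengths <= upper)],
                        bins=np.arange(0, upper + 50, 50))
    return SizeProfileSummary(lengths, x, y, hist,
                              detect_size_peaks(lengths, **peak_kwargs))


# ------------------------------------------------------------------ group tests

def _group_test(a: np.ndarray, b: np.ndarray, paired: bool = False
                ) -> tuple[str, float]:
    """Normality-gated two-sample test; returns (test name, p value)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        return "not_applicable", np.nan
    normal = True
    for x in (a, b):
        if len(x) < 3 or np.ptp(x) == 0:
            normal = False
            break
        normal &= stats.shapiro(x).pvalue >= 0.05
    if normal:
        return "t", float(stats.ttest_ind(a, b).pvalue)
    if paired:
        return "wilcoxon_signed_rank", float(stats.wilcoxon(a, b).pvalue)
    try:
        return "mannwhitney", float(stats.mannwhitneyu(
            a, b, alternative="two-sided").pvalue)
    except ValueError:  # all values identical
        return "mannwhitney", 1.0


def compare_length_bins(cancer: list[SampleProfile],
                        noncancer: list[SampleProfile],
                        bins=DEFAULT_BINS, paired: bool = False) -> pd.DataFrame:
    """Per-bin fraction of each sample's circles, compared across groups.

    Bin edges are half-open [lo, hi). Returns a table with group means, the
    chosen test, raw p and BH-adjusted p per bin.
    """
    if not cancer or not noncancer:
        raise ValueError("both groups must be non-empty")

    def fractions(profiles):
        rows = []
        for p in profiles:
            lens = np.array([r.length for r in p.eccdna])
            n = max(len(lens), 1)
            rows.append([((lens >= lo) & (lens < hi)).sum() / n
                         for lo, hi in bins])
        return np.array(rows)

    fc, fn = fractions(cancer), fractions(noncancer)
    rows = []
    for bi, (lo, hi) in enumerate(bins):
        test, p = _group_test(fc[:, bi], fn[:, bi], paired)
        rows.append({"bin": f"{lo}-{hi}", "cancer_mean": fc[:, bi].mean(),
                     "noncancer_mean": fn[:, bi].mean(), "test": test,
                     "p": p})
    df = pd.DataFrame(rows)
    df["padj"] = _bh_with_nan(df["p"].to_numpy())
    return df


def _bh_with_nan(p: np.ndarray) -> np.ndarray:
    out = np.full_like(p, np.nan, dtype=float)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ------------------------------------------------------------------ genome distribution

@dataclass
class GenomeDistribution:
    chrom_fractions: pd.DataFrame  # samples x chromosomes, sums to 1 per row
    chrom_tests: pd.DataFrame | None
    window_coverage: pd.DataFrame | None = None  # chrom,start,end + per-sample cols
    window_median: pd.DataFrame | None = None


def chromosome_distribution(profiles: list[SampleProfile],
                            chrom_lengths: dict[str, int],
                            length_normalize: bool = True) -> pd.DataFrame:
    """Per-sample per-chromosome eccDNA fraction.

    With ``length_normalize`` the count per chromosome is first converted
    to a density per Mb, then renormalized to sum to 1 per sample (the
    chromosome-preference view). Records on unknown chromosomes raise.
    """
    chroms = list(chrom_lengths)
    mb = np.array([chrom_lengths[c] / 1e6 for c in chroms])
    rows = {}
    for p in profiles:
        counts = dict.fromkeys(chroms, 0)
        for rec in p.eccdna:
            for c in rec.chroms:
                if c not in counts:
                    raise KeyError(f"record {rec.id} on unknown chromosome {c}")
            counts[next(iter(rec.chroms))] += 1  # origin chrom = first segment's
        v = np.array([counts[c] for c in chroms], dtype=float)
        if length_normalize:
            v = v / mb
        tot = v.sum()
        rows[p.sample_id] = v / tot if tot else v
    return pd.DataFrame.from_dict(rows, orient="index", columns=chroms)


def chromosome_group_tests(fractions: pd.DataFrame, groups: dict[str, str]
                           ) -> pd.DataFrame:
    """Per-chromosome cancer-vs-noncancer comparison of fractions."""
    g = pd.Series(groups)
    rows = []
    for chrom in fractions.columns:
        a = fractions.loc[g[fractions.index] == "cancer", chrom].to_numpy()
        b = fractions.loc[g[fractions.index] == "noncancer", chrom].to_numpy()
        test, p = _group_test(a, b)
        rows.append({"chrom": chrom, "cancer_mean": a.mean() if len(a) else np.nan,
                     "noncancer_mean": b.mean() if len(b) else np.nan,
                     "test": test, "p": p})
    df = pd.DataFrame(rows)
    df["padj"] = _bh_with_nan(df["p"].to_numpy())
    return df


def genome_distribution(profiles: list[SampleProfile],
                        chrom_lengths: dict[str, int],
                        window_bp: int = 1_000_000) -> GenomeDistribution:
    frac = chromosome_distribution(profiles, chrom_lengths)
    groups = {p.sample_id: p.group for p in profiles}
    tests = chromosome_group_tests(frac, groups) if len(set(
        groups.values()) - {"unknown"}) == 2 else None
    cov = window_coverage(profiles, chrom_lengths, window_bp)
    sample_cols = [p.sample_id for p in profiles]
    med = cov[["chrom", "start", "end"]].copy()
    med["median"] = cov[sample_cols].median(axis=1)
    return GenomeDistribution(frac, tests, cov, med)


def window_coverage(profiles: list[SampleProfile],
                    chrom_lengths: dict[str, int],
                    window_bp: int = 1_000_000,
                    normalize: bool = True) -> pd.DataFrame:
    """Summed eccDNA overlap bp per genomic window, per sample.

    Windows tile each chromosome (last window may be short). With
    ``normalize`` each sample's track is scaled to mean 1 over its covered
    (nonzero) windows. Returns a long table: chrom, start, end, one column
    per sample.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    windows = []
    for chrom, ln in chrom_lengths.items():
        for ws in range(0, ln, window_bp):
            windows.append((chrom, ws, min(ws + window_bp, ln)))
    index = {(c, s): i for i, (c, s, _) in enumerate(windows)}
    df = pd.DataFrame(windows, columns=["chrom", "start", "end"])
    for p in profiles:
        track = np.zeros(len(windows))
        for rec in p.eccdna:
            for seg in rec.segments:
                w0 = seg.start // window_bp * window_bp
                for ws in range(w0, seg.end, window_bp):
                    i = index.get((seg.chrom, ws))
                    if i is None:
                        continue
                    ov = min(seg.end, ws + window_bp) - max(seg.start, ws)
                    track[i] += max(ov, 0)
        if normalize:
            covered = track > 0
            if covered.any():
                track = track / track[covered].mean()
        df[p.sample_id] = track
    return df
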