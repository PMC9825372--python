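"""Concordance statistics between isolation methods and hemispheres.

Coverage tracks are binned along a chromosome (100 bp by default), bin
values are normalized to counts-per-million of the chromosome's total
signal (rank-preserving, so the Spearman statistic is unaffected by the
constant), and paired bins are compared with Spearman's rank correlation.
A comparison passes the concordance rule when rho > 0.5 and the two-sided
p-value is below 2.2e-16 (reported as "<2.2e-16" when it underflows).

Gene-length bias of a differential-expression result is summarized as the
Spearman correlation of log2 fold change with gene length plus a decile
table; two results are compared by the difference of those correlations
with a seeded sign-flip permutation p-value (an added statistic, not a
re-derivation of any published test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CoverageTrack, GenomeAnnotation

__all__ = [
    "P_RULE",
    "BinnedTrack",
    "ConcordanceResult",
    "bin_coverage",
    "spearman",
    "compare_tracks",
    "length_bias_summary",
    "compare_length_bias",
]

P_RULE = 2.2e-16  # reporting/rule threshold for "highly concordant"
RHO_RULE = 0.5


@dataclass
class BinnedTrack:
    chrom: str
    bin_size: int
    raw: np.ndarray  # summed depth x overlap per bin
    values: np.ndarray  # CPM-normalized

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if (self.raw < 0).any():
            raise ValueError("bin values must be non-negative")


@dataclass
class ConcordanceResult:
    rho: float
    p: float
    n: int
    passes_rule: bool

    @property
    def p_display(self) -> str:
        return f"<{P_RULE:g}" if self.p < P_RULE else f"{self.p:g}"


def bin_coverage(
    track: CoverageTrack,
    chrom: str,
    bin_size: int = 100,
    chrom_length: int | None = None,
) -> BinnedTrack:
    """Bin one chromosome of a coverage track.

    Each bin's raw value is the integral of depth over its overlap with the
    track; the sum over bins equals the track's total signal on the
    chromosome exactly.  Values are normalized to counts-per-million of
    that total (all-zero with a warning if there is no signal).
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if chrom not in track.data:
        raise ValueError(f"chromosome {chrom!r} absent from track")
    starts, ends, depths = track.data[chrom]
    if chrom_length is None:
        chrom_length = int(ends.max()) if len(ends) else bin_size
    n_bins = int(np.ceil(chrom_length / bin_size))
    raw = np.zeros(n_bins)
    if len(starts):
        first_bin = starts // bin_size
        last_bin = (ends - 1) // bin_size
        span = (last_bin - first_bin + 1).astype(np.int64)
        # explode each interval into its covered bins
        bins = np.repeat(first_bin, span) + _ranges(span)
        depth_rep = np.repeat(depths, span)
        s_rep = np.repeat(starts, span)
        e_rep = np.repeat(ends, span)
        bin_lo = bins * bin_size
        bin_hi = bin_lo + bin_size
        overlap = np.minimum(e_rep, bin_hi) - np.maximum(s_rep, bin_lo)
        np.add.at(raw, bins, depth_rep * overlap)
    total = raw.sum()
    if total > 0:
        values = raw / total * 1e6
    else:
        import warnings

        warnings.warn(f"no signal on {chrom}; returning all-zero bins", stacklevel=2)
        values = raw.copy()
    return BinnedTrack(chrom=chrom, bin_size=bin_size, raw=raw, values=values)


def _ranges(lengths: np.ndarray) -> np.ndarray:
    """Concatenated arange(l) for each l in lengths."""
    if len(lengths) == 0:
        return np.array([], dtype=np.int64)
    total = int(lengths.sum())
    out = np.ones(total, dtype=np.int64)
    out[0] = 0
    ends = np.cumsum(lengths)[:-1]
    out[ends] = -(lengths[:-1] - 1)
    return np.cumsum(out)


def spearman(x, y) -> ConcordanceResult:
    """Spearman rank correlation with average ranks for ties.

    p is the large-sample t approximation; NaN rho when either vector has
    zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (same length)")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return ConcordanceResult(rho=float("nan"), p=float("nan"), n=n,
                                 passes_rule=False)
    rho, p = stats.spearmanr(x, y)
    rho, p = float(rho), float(p)
    passes = bool(rho > RHO_RULE and p < P_RULE)
    return ConcordanceResult(rho=rho, p=p, n=n, passes_rule=passes)


def compare_tracks(
    a: CoverageTrack,
    b: CoverageTrack,
    chrom: str,
    bin_size: int = 100,
    drop_joint_zero: bool = True,
) -> ConcordanceResult:
    """Spearman concordance of two coverage tracks on one chromosome.

    Both tracks are binned on a common grid; bins with zero signal in both
    tracks contribute pure ties and are excluded by default.
    """
    for name, t in (("a", a), ("b", b)):
        if chrom not in t.data:
            raise ValueError(f"chromosome {chrom!r} absent from track {name}")
    length = max(
        int(a.data[chrom][1].max()) if len(a.data[chrom][1]) else 0,
        int(b.data[chrom][1].max()) if len(b.data[chrom][1]) else 0,
    )
    ba = bin_coverage(a, chrom, bin_size, chrom_length=length)
    bb = bin_coverage(b, chrom, bin_size, chrom_length=length)
    va, vb = ba.values, bb.values
    if drop_joint_zero:
        keep = (ba.raw > 0) | (bb.raw > 0)
        va, vb = va[keep], vb[keep]
    return spearman(va, vb)


# ---------------------------------------------------------------------------
# gene-length bias
# ---------------------------------------------------------------------------


def length_bias_summary(de, genome: GenomeAnnotation, label: str = "") -> dict:
    """Correlation of log2 fold change with gene length plus a decile table.

    Returns ``{"label", "spearman": ConcordanceResult, "deciles": DataFrame}``
    where the decile table gives per-length-decile gene counts and mean and
    median log2fc.
    """
    lengths = {g.gene_id: g.gene_length for g in genome.genes}
    t = de.table.dropna(subset=["log2fc"])
    common = [g for g in t.index if g in lengths]
    lfc = t.loc[common, "log2fc"].to_numpy()
    length = np.array([lengths[g] for g in common], dtype=float)
    res = spearman(length, lfc)
    dec = pd.qcut(length, 10, labels=False, duplicates="drop")
    table = (
        pd.DataFrame({"decile": dec, "length": length, "log2fc": lfc})
        .groupby("decile")
        .agg(n=("log2fc", "size"), mean_length=("length", "mean"),
             mean_log2fc=("log2fc", "mean"), median_log2fc=("log2fc", "median"))
        .reset_index()
    )
    return {"label": label, "spearman": res, "deciles": table}


def compare_length_bias(
    de_a,
    de_b,
    genome: GenomeAnnotation,
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict:
    """Difference of length-bias correlations with a permutation p-value.

    The observed statistic is rho_a - rho_b (Spearman of log2fc vs gene
    length under each result).  The null exchanges the two methods' fold
    changes gene-wise (seeded sign-flip permutation), so the p-value asks
    whether one method is more length-biased than the other.
    """
    lengths = {g.gene_id: g.gene_length for g in genome.genes}
    common = [
        g
        for g in de_a.table.index
        if g in de_b.table.index
        and g in lengths
        and np.isfinite(de_a.table.at[g, "log2fc"])
        and np.isfinite(de_b.table.at[g, "log2fc"])
    ]
    la = de_a.table.loc[common, "log2fc"].to_numpy()
    lb = de_b.table.loc[common, "log2fc"].to_numpy()
    length = np.array([lengths[g] for g in common], dtype=float)
    length_rank = stats.rankdata(length)

    def rho(v: np.ndarray) -> float:
        return float(np.corrcoef(length_rank, stats.rankdata(v))[0, 1])

    observed = rho(la) - rho(lb)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        flip = rng.random(len(common)) < 0.5
        pa = np.where(flip, lb, la)
        pb = np.where(flip, la, lb)
        null[i] = rho(pa) - rho(pb)
    p = float((np.sum(np.abs(null) >= abs(observed)) + 1) / (n_perm + 1))
    return {
        "rho_a": rho(la),
        "rho_b": rho(lb),
        "difference": observed,
        "p_permutation": p,
        "n_genes": len(common),
        "n_perm": n_perm,
    }
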