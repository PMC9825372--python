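"""Sparse-enrichment peak calling from bedGraph coverage.

The unit of calling is the *signal block*: a maximal run of strictly
positive depth, scored by its AUC (sum of depth x length).  Peaks are the
blocks whose AUC survives either a numeric top-fraction threshold or a
threshold chosen against an IgG control track, the latter with an
empirical false-discovery estimate used for per-sample QC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import CoverageTrack, SampleDesign

__all__ = [
    "SignalBlock",
    "PeakSet",
    "segment_blocks",
    "call_peaks_numeric",
    "call_peaks_with_control",
    "qc_filter_samples",
]

FDR_QC_CUTOFF = 0.1  # samples with empirical FDR above this are excluded


@dataclass(frozen=True)
class SignalBlock:
    """A maximal contiguous run of positive coverage.

    ``auc`` is the integral of depth over the block (depth x bp); ``max_depth``
    is the highest depth reached anywhere inside it.
    """

    chrom: str
    start: int
    end: int
    auc: float
    max_depth: float


@dataclass
class PeakSet:
    """Called peaks plus the thresholding metadata that produced them."""

    peaks: list[SignalBlock]
    mode: str  # "stringent" | "relaxed"
    threshold_type: str  # "numeric" | "control"
    auc_threshold: float
    numeric_fraction: float | None = None
    empirical_fdr: float | None = None
    sample: SampleDesign | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("stringent", "relaxed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.threshold_type not in ("numeric", "control"):
            raise ValueError(f"unknown threshold_type {self.threshold_type!r}")
        self.peaks = sorted(self.peaks, key=lambda b: (b.chrom, b.start, b.end))

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def qc_fail(self) -> bool:
        """True when the control-based empirical FDR exceeds the QC cutoff."""
        return self.empirical_fdr is not None and self.empirical_fdr > FDR_QC_CUTOFF


def segment_blocks(track: CoverageTrack, max_gap: int = 0) -> list[SignalBlock]:
    """Decompose a coverage track into maximal positive-depth blocks.

    Blocks separated by zero-depth gaps are never merged by default
    (``max_gap=0``); a positive ``max_gap`` merges blocks whose gap is at
    most that many bp, in which case the gap contributes nothing to AUC.
    """
    blocks: list[SignalBlock] = []
    for chrom in track.chroms:
        starts, ends, depths = track.data[chrom]
        pos = depths > 0
        if not pos.any():
            continue
        s, e, d = starts[pos], ends[pos], depths[pos]
        gaps = s[1:] - e[:-1]
        breaks = np.flatnonzero(gaps > max_gap)
        run_start = np.concatenate([[0], breaks + 1])
        run_end = np.concatenate([breaks, [len(s) - 1]])
        auc_parts = (e - s) * d
        cum = np.concatenate([[0.0], np.cumsum(auc_parts)])
        for i0, i1 in zip(run_start, run_end):
            blocks.append(
                SignalBlock(
                    chrom=chrom,
                    start=int(s[i0]),
                    end=int(e[i1]),
                    auc=float(cum[i1 + 1] - cum[i0]),
                    max_depth=float(d[i0 : i1 + 1].max()),
                )
            )
    return blocks


def call_peaks_numeric(
    blocks: list[SignalBlock],
    fraction: float = 0.01,
    mode: str = "stringent",
    sample: SampleDesign | None = None,
) -> PeakSet:
    """Keep the top-``fraction`` of blocks by AUC.

    The AUC threshold is the empirical (1 - fraction)-quantile of block AUCs
    with "higher" (ceiling) interpolation, so the kept fraction never
    exceeds the request except through ties; ties at the threshold are all
    kept.  ``stringent`` mode additionally requires max_depth to clear the
    (1 - fraction)-quantile of block max depths; ``relaxed`` gates on AUC
    alone.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if mode not in ("stringent", "relaxed"):
        raise ValueError(f"unknown mode {mode!r}")
    if not blocks:
        warnings.warn("no signal blocks: returning empty PeakSet", stacklevel=2)
        return PeakSet(peaks=[], mode=mode, threshold_type="numeric",
                       auc_threshold=float("inf"), numeric_fraction=fraction,
                       sample=sample)
    aucs = np.array([b.auc for b in blocks])
    thr = float(np.quantile(aucs, 1.0 - fraction, method="higher"))
    keep = aucs >= thr
    if mode == "stringent":
        maxima = np.array([b.max_depth for b in blocks])
        depth_thr = float(np.quantile(maxima, 1.0 - fraction, method="higher"))
        keep &= maxima >= depth_thr
    kept = [b for b, k in zip(blocks, keep) if k]
    return PeakSet(peaks=kept, mode=mode, threshold_type="numeric",
                   auc_threshold=thr, numeric_fraction=fraction, sample=sample)


def control_threshold_scan(
    target_aucs: np.ndarray, control_aucs: np.ndarray
) -> tuple[float, float]:
    """Choose the AUC threshold against a control block population.

    Candidate thresholds are the union of observed AUC values; the chosen
    threshold maximizes ``frac(target >= t) - frac(control >= t)``, with the
    smallest such t on ties.  Returns ``(threshold, empirical_fdr)`` where
    the empirical FDR is ``#control >= t / #target >= t``.
    """
    target_aucs = np.asarray(target_aucs, dtype=float)
    control_aucs = np.asarray(control_aucs, dtype=float)
    candidates = np.unique(np.concatenate([target_aucs, control_aucs]))
    t_sorted = np.sort(target_aucs)
    c_sorted = np.sort(control_aucs)
    n_t, n_c = len(t_sorted), len(c_sorted)
    # count of values >= t via searchsorted on the left side
    t_ge = n_t - np.searchsorted(t_sorted, candidates, side="left")
    c_ge = n_c - np.searchsorted(c_sorted, candidates, side="left")
    diff = t_ge / n_t - c_ge / n_c
    best = float(diff.max())
    # float-tolerant tie set so e.g. 3/5 - 2/5 ties with exact 0.2
    winners = candidates[diff >= best - 1e-12]
    if len(winners) == len(candidates):
        warnings.warn(
            "all candidate thresholds give the same target-control difference; "
            "choosing the smallest",
            stacklevel=2,
        )
    thr = float(winners.min())
    i = int(np.searchsorted(candidates, thr))
    n_target_kept = int(t_ge[i])
    fdr = float(c_ge[i] / n_target_kept) if n_target_kept else float("nan")
    return thr, fdr


def call_peaks_with_control(
    target_blocks: list[SignalBlock],
    control_blocks: list[SignalBlock],
    mode: str = "stringent",
    sample: SampleDesign | None = None,
) -> PeakSet:
    """Call peaks with the threshold set against an IgG control track.

    The sample is flagged QC-fail when the empirical FDR exceeds 0.1.
    ``stringent`` mode additionally requires max_depth at or above the
    control's maximum block depth; ``relaxed`` gates on AUC alone.
    """
    if not target_blocks or not control_blocks:
        raise ValueError("control-mode calling requires nonempty target and control blocks")
    target_aucs = np.array([b.auc for b in target_blocks])
    control_aucs = np.array([b.auc for b in control_blocks])
    thr, fdr = control_threshold_scan(target_aucs, control_aucs)
    keep = target_aucs >= thr
    if mode == "stringent":
        maxima = np.array([b.max_depth for b in target_blocks])
        ctl_maxima = np.array([b.max_depth for b in control_blocks])
        frac_kept = keep.mean()
        if 0 < frac_kept < 1:
            depth_thr = float(np.quantile(maxima, 1.0 - frac_kept, method="higher"))
        else:
            depth_thr = float(ctl_maxima.max())
        keep &= maxima >= min(depth_thr, float(np.max(maxima)))
    kept = [b for b, k in zip(target_blocks, keep) if k]
    return PeakSet(peaks=kept, mode=mode, threshold_type="control",
                   auc_threshold=thr, empirical_fdr=fdr, sample=sample)


def qc_filter_samples(
    peaksets: dict[str, PeakSet] | list[PeakSet],
) -> tuple[list[PeakSet], list[dict]]:
    """Drop control-mode peak sets whose empirical FDR exceeds 0.1.

    Numeric-mode sets carry no FDR and are always retained.  Returns the
    retained sets and an exclusion report (one dict per dropped set).
    """
    if isinstance(peaksets, dict):
        items = list(peaksets.items())
    else:
        items = [(ps.sample.sample_id if ps.sample else f"set_{i}", ps)
                 for i, ps in enumerate(peaksets)]
    retained, report = [], []
    for name, ps in items:
        if ps.threshold_type == "control" and ps.qc_fail:
            report.append(
                {
                    "sample": name,
                    "reason": f"empirical FDR {ps.empirical_fdr:.3f} > {FDR_QC_CUTOFF}",
                    "empirical_fdr": ps.empirical_fdr,
                }
            )
        else:
            retained.append(ps)
    return retained, report
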