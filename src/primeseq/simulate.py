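"""Synthetic paired TRAP-seq / CUT&RUN study generator with planted truth.

Every downstream stage of the pipeline is exercised against data whose
ground truth is known: gene models placed on synthetic chromosomes, NB
count matrices with planted condition-specific log fold changes across the
behavioral groups (exercise x learning), and sparse coverage tracks with
planted antibody- and condition-specific peaks linked to the planted DEGs
(the priming structure).

Counts follow the NB model used by the differential-expression module:
``counts ~ NB(mean = s_j * mu_g * 2^(x_j . lfc_g), dispersion alpha_g)``
with log-normal baseline means and dispersions.  Coverage is generated as
Poisson depth on 10-bp tiles (background everywhere, an extra
``lambda_bg * fold`` Poisson component inside planted peaks whose
condition set matches) and run-length-encoded into bedGraph-style tracks;
IgG tracks contain background only.

Planted DEG magnitudes are drawn at or above the DEG-calling threshold
plus a margin of 0.2 log2 units so that power experiments are separated
from threshold-boundary behavior (tested separately).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .de import DEFAULT_LFC_CUT
from .io import (
    CountMatrix,
    CoverageTrack,
    GeneModel,
    GenomeAnnotation,
    SampleDesign,
)

__all__ = [
    "GROUPS",
    "BASELINE_GROUP",
    "SimulationParams",
    "TruthRecord",
    "FixtureStudy",
    "make_genome",
    "simulate_counts",
    "simulate_coverage",
    "make_fixture_study",
]

BASELINE_GROUP = "SED_none"
GROUPS = ("ELE_none", "ELE_3min", "SED_3min", "SED_10min")
ANTIBODIES = ("H4K8ac", "H3K27me3")
CONDITIONS = ("ELE", "SED")

_SEED_MOD = 2**31 - 1


@dataclass
class SimulationParams:
    """Knobs of the synthetic study; defaults are the study conditions.

    Counts: log-normal baseline means (median 150, sigma 1.0 in ln units,
    with planted-DEG genes floored at 100 so planted effects sit in the
    robustly expressed range a behavioral DEG panel occupies); log-normal
    NB dispersions with median 0.01 (isogenic animals, purified neuronal
    populations) and sigma 0.5; library-size factors log-normal with sigma
    0.15.  Planted |lfc| is uniform on [log2(1.3)+0.2, 2.0] log2 units.

    Coverage: Poisson background at 0.002 per 10-bp tile (antibody-directed
    cleavage leaves very few stray fragments outside true binding sites),
    a within-peak rate of ``background_lambda * peak_fold`` (default fold
    1750, i.e. ~3.5 expected fragments per tile inside a peak; CUT&RUN
    peak-over-background enrichment is of this order), peak widths uniform
    on [400, 1200] bp, IgG background equal to the target background.
    """

    n_genes: int = 1500
    # counts
    mean_log_mu: float = float(np.log(150.0))
    sd_log_mu: float = 1.0
    deg_mu_floor: float = 100.0
    alpha_log_mean: float = float(np.log(0.01))
    alpha_log_sd: float = 0.5
    size_factor_log_sd: float = 0.15
    deg_fraction: float = 0.1
    lfc_min: float = DEFAULT_LFC_CUT + 0.2
    lfc_max: float = 2.0
    hemisphere_deg_fraction: float = 0.0
    hemisphere_lfc: float = 0.5
    # coverage
    tile: int = 10
    background_lambda: float = 0.002
    peak_fold: float = 1750.0
    igg_lambda: float = 0.002
    peak_width_min: int = 400
    peak_width_max: int = 1200

    def __post_init__(self) -> None:
        positive = [
            self.n_genes >= 0,
            self.deg_mu_floor > 0,
            self.size_factor_log_sd >= 0,
            self.lfc_min > 0,
            self.lfc_max >= self.lfc_min,
            self.tile > 0,
            self.background_lambda >= 0,
            self.peak_fold >= 0,
            self.igg_lambda >= 0,
            0 < self.peak_width_min <= self.peak_width_max,
        ]
        if not all(positive):
            raise ValueError("simulation parameters out of range")
        if not 0 <= self.deg_fraction <= 1:
            raise ValueError("deg_fraction must be in [0, 1]")


@dataclass
class TruthRecord:
    """Planted ground truth for one simulated study.

    ``lfc``: genes x contrast-group log2 fold changes vs baseline.
    ``mark_dynamics``: per antibody, planted gene sets with status in
    {new, lost, shared} (genes absent from all three have no peak).
    ``intended_class``: per direction, gene -> {cGAME, cGAMES, cGAMS};
    genes not listed are "none".  ``peaks``: planted peak table with
    chrom/start/end/antibody/conditions/fold/gene_id.
    """

    lfc: pd.DataFrame
    mark_dynamics: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    intended_class: dict[str, dict[str, str]] = field(default_factory=dict)
    peaks: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chrom", "start", "end", "antibody", "conditions", "fold", "gene_id"]
        )
    )

    def __post_init__(self) -> None:
        for ab, statuses in self.mark_dynamics.items():
            sets = [statuses.get(k, set()) for k in ("new", "lost", "shared")]
            for i in range(3):
                for j in range(i + 1, 3):
                    if sets[i] & sets[j]:
                        raise ValueError(
                            f"{ab}: a gene cannot have two planted mark statuses"
                        )
        for direction, mapping in self.intended_class.items():
            bad = set(mapping.values()) - {"cGAME", "cGAMES", "cGAMS"}
            if bad:
                raise ValueError(f"unknown intended classes {bad}")
        # every planted "new" H4K8ac gene must have an ELE-only peak
        new_h4 = self.mark_dynamics.get("H4K8ac", {}).get("new", set())
        if new_h4 and len(self.peaks):
            ele_only = set(
                self.peaks.loc[
                    (self.peaks["antibody"] == "H4K8ac")
                    & (self.peaks["conditions"] == "ELE"),
                    "gene_id",
                ]
            )
            if not new_h4 <= ele_only:
                raise ValueError("planted new H4K8ac genes lack an ELE-only peak")

    def deg_flag(self) -> pd.DataFrame:
        """Sign of the planted fold change per gene and contrast."""
        return np.sign(self.lfc).astype(int)

    def class_members(self, direction: str, cls: str) -> set[str]:
        return {
            g for g, c in self.intended_class.get(direction, {}).items() if c == cls
        }


@dataclass
class FixtureStudy:
    """An end-to-end synthetic study bundle."""

    genome: GenomeAnnotation
    counts: CountMatrix
    design: list[SampleDesign]
    tracks: dict[tuple[str, str], CoverageTrack]  # (antibody, condition)
    igg: dict[str, CoverageTrack]  # condition -> IgG track
    truth: TruthRecord
    noise_free: bool = False


class CapacityError(ValueError):
    """Genes cannot be placed within the requested chromosome sizes."""


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def make_genome(
    n_genes: int,
    chrom_sizes: dict[str, int],
    seed: int,
    min_gap: int = 10_000,
    gene_length_range: tuple[int, int] = (2_000, 10_000),
    edge_margin: int = 5_000,
) -> GenomeAnnotation:
    """Place non-overlapping genes with >= ``min_gap`` bp between them.

    Genes carry 2-10 exons, random strand, and are laid down left to right
    per chromosome with random gaps; deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    lo, hi = gene_length_range
    chroms = sorted(chrom_sizes)
    capacity = sum(
        max(0, chrom_sizes[c] - 2 * edge_margin) for c in chroms
    )
    if n_genes * (hi + min_gap) > capacity:
        raise CapacityError(
            f"cannot place {n_genes} genes of up to {hi} bp with {min_gap} bp "
            f"gaps in {capacity} bp of usable sequence"
        )
    genes: list[GeneModel] = []
    per_chrom = _split_gene_counts(n_genes, [chrom_sizes[c] for c in chroms])
    gid = 0
    for chrom, k in zip(chroms, per_chrom):
        cursor = edge_margin
        limit = chrom_sizes[chrom] - edge_margin
        slack = limit - cursor - k * (hi + min_gap)
        for _ in range(k):
            gap_extra = int(rng.integers(0, max(1, slack // max(1, k))))
            start = cursor + gap_extra
            length = int(rng.integers(lo, hi + 1))
            end = start + length
            if end > limit:
                raise CapacityError(f"ran out of room on {chrom}")
            strand = "+" if rng.random() < 0.5 else "-"
            exons = _random_exons(rng, start, end)
            genes.append(
                GeneModel(
                    gene_id=f"g{gid:05d}",
                    chrom=chrom,
                    strand=strand,
                    tx_start=start,
                    tx_end=end,
                    exons=exons,
                )
            )
            gid += 1
            cursor = end + min_gap
    return GenomeAnnotation(genes=genes, chrom_sizes=dict(chrom_sizes))


def _split_gene_counts(n: int, sizes: list[int]) -> list[int]:
    total = sum(sizes)
    counts = [int(round(n * s / total)) for s in sizes]
    while sum(counts) > n:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < n:
        counts[int(np.argmin(counts))] += 1
    return counts


def _random_exons(rng: np.random.Generator, start: int, end: int):
    n_exons = int(rng.integers(2, 11))
    length = end - start
    n_points = 2 * n_exons
    if length <= n_points + 2:
        return ((start, end),)
    offsets = np.sort(rng.choice(np.arange(1, length), size=n_points, replace=False))
    exons = []
    for i in range(0, n_points, 2):
        s, e = start + int(offsets[i]), start + int(offsets[i + 1])
        if e > s:
            exons.append((s, e))
    if not exons:
        exons = [(start, end)]
    # anchor first/last exon at the gene bounds so the body is transcribed
    first_s, first_e = exons[0]
    exons[0] = (start, first_e)
    last_s, last_e = exons[-1]
    exons[-1] = (last_s, end)
    return tuple(exons)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB2 sample via the gamma-Poisson mixture; Poisson at the alpha floor."""
    out = np.empty_like(mean, dtype=np.int64)
    tiny = alpha < 1e-7
    if tiny.any():
        out[tiny] = rng.poisson(mean[tiny])
    big = ~tiny
    if big.any():
        shape = 1.0 / alpha[big]
        lam = rng.gamma(shape, mean[big] * alpha[big])
        out[big] = rng.poisson(lam)
    return out


def simulate_counts(
    genome: GenomeAnnotation,
    design: list[SampleDesign],
    params: SimulationParams,
    seed: int,
    truth: TruthRecord | None = None,
    noise_free: bool = False,
) -> tuple[CountMatrix, TruthRecord]:
    """Simulate an NB count matrix over the design's behavioral groups.

    When ``truth`` is supplied its ``lfc`` table defines the planted
    effects; otherwise ``deg_fraction`` of genes per contrast group get a
    planted fold change with |lfc| >= log2(1.3)+0.2 and random sign.
    ``noise_free=True`` replaces sampling with rounded expected counts and
    unit size factors (for exact end-to-end recovery experiments).
    """
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in genome.genes]
    G = len(gene_ids)
    groups = [s.group for s in design]
    labels = list(pd.unique(np.asarray(groups)))
    contrasts = [g for g in labels if g != BASELINE_GROUP]
    for lab in labels:
        if groups.count(lab) < 2:
            raise ValueError(f"group {lab} has fewer than 2 samples")

    if truth is None:
        lfc = pd.DataFrame(0.0, index=gene_ids, columns=contrasts)
        n_deg = int(round(params.deg_fraction * G))
        for c in contrasts:
            chosen = rng.choice(G, size=n_deg, replace=False)
            mag = rng.uniform(params.lfc_min, params.lfc_max, size=n_deg)
            sign = np.where(rng.random(n_deg) < 0.5, 1.0, -1.0)
            lfc.iloc[chosen, lfc.columns.get_loc(c)] = mag * sign
        truth = TruthRecord(lfc=lfc)
    else:
        lfc = truth.lfc.reindex(index=gene_ids).fillna(0.0)

    mu = np.exp(rng.normal(params.mean_log_mu, params.sd_log_mu, size=G))
    planted = (lfc.to_numpy() != 0).any(axis=1)
    mu = np.where(planted, np.maximum(mu, params.deg_mu_floor), mu)
    alpha = np.exp(rng.normal(params.alpha_log_mean, params.alpha_log_sd, size=G))
    if noise_free:
        sf = np.ones(len(design))
    else:
        sf = np.exp(rng.normal(0.0, params.size_factor_log_sd, size=len(design)))

    hem_lfc = np.zeros(G)
    if params.hemisphere_deg_fraction > 0:
        n_h = int(round(params.hemisphere_deg_fraction * G))
        chosen = rng.choice(G, size=n_h, replace=False)
        hem_lfc[chosen] = params.hemisphere_lfc * np.where(
            rng.random(n_h) < 0.5, 1.0, -1.0
        )

    counts = np.empty((G, len(design)), dtype=np.int64)
    for j, s in enumerate(design):
        g_lfc = lfc[s.group].to_numpy() if s.group in lfc.columns else np.zeros(G)
        h = hem_lfc if s.hemisphere == "R" else 0.0
        mean_j = sf[j] * mu * np.exp2(g_lfc + h)
        if noise_free:
            counts[:, j] = np.round(mean_j).astype(np.int64)
        else:
            counts[:, j] = _nb_draw(rng, mean_j, alpha)
    cm = CountMatrix(gene_ids=gene_ids, samples=list(design), counts=counts)
    return cm, truth


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------


def simulate_coverage(
    genome: GenomeAnnotation,
    truth: TruthRecord,
    antibody: str,
    condition: str,
    params: SimulationParams,
    seed: int,
    noise_free: bool = False,
) -> CoverageTrack:
    """Simulate one antibody x condition coverage track on 10-bp tiles.

    Background depth is Poisson(``background_lambda``) per tile
    (``igg_lambda`` for IgG).  Inside a planted peak whose condition set
    contains ``condition``, the tile rate becomes ``background_lambda *
    fold`` (the enrichment fold multiplies the local rate, so fold = 1 is
    indistinguishable from background; with zero background the fold is
    read as the absolute per-tile rate).  IgG tracks never carry planted
    peaks.  ``noise_free`` drops the background and writes the
    deterministic peak depth instead.
    """
    rng = np.random.default_rng(seed)
    tile = params.tile
    lam_bg = params.igg_lambda if antibody == "IgG" else params.background_lambda
    peaks = truth.peaks
    if antibody != "IgG" and len(peaks):
        peaks = peaks[
            (peaks["antibody"] == antibody)
            & peaks["conditions"].map(lambda cs: condition in cs.split("|"))
        ]
    else:
        peaks = peaks.iloc[0:0]
    data = {}
    for chrom in sorted(genome.chrom_sizes):
        size = genome.chrom_sizes[chrom]
        n_tiles = int(np.ceil(size / tile))
        if noise_free:
            depth = np.zeros(n_tiles, dtype=np.float64)
        else:
            depth = rng.poisson(lam_bg, size=n_tiles).astype(np.float64)
        for _, pk in peaks[peaks["chrom"] == chrom].iterrows():
            s, e = int(pk["start"]), int(pk["end"])
            if s < 0 or e > size:
                raise ValueError(
                    f"planted peak [{s},{e}) outside {chrom} (size {size})"
                )
            t0, t1 = s // tile, int(np.ceil(e / tile))
            base = params.background_lambda if params.background_lambda > 0 else 1.0
            lam_peak = base * float(pk["fold"])
            if noise_free:
                depth[t0:t1] = max(1.0, round(lam_peak))
            else:
                depth[t0:t1] = rng.poisson(lam_peak, size=t1 - t0)
        data[chrom] = _rle_tiles(depth, tile, size)
    sample = SampleDesign(
        sample_id=f"{antibody}_{condition}",
        exercise="ELE" if condition == "ELE" else "SED",
        assay="CUTRUN",
        antibody=antibody,
    )
    return CoverageTrack(sample=sample, data=data)


def _rle_tiles(depth: np.ndarray, tile: int, size: int):
    """Run-length encode tile depths into bedGraph intervals (zeros omitted)."""
    change = np.flatnonzero(np.diff(depth) != 0)
    run_starts = np.concatenate([[0], change + 1])
    run_ends = np.concatenate([change + 1, [len(depth)]])
    values = depth[run_starts]
    keep = values > 0
    starts = (run_starts[keep] * tile).astype(np.int64)
    ends = np.minimum(run_ends[keep] * tile, size).astype(np.int64)
    return starts, ends, values[keep].astype(np.float64)


# ---------------------------------------------------------------------------
# the end-to-end fixture study
# ---------------------------------------------------------------------------

#: Planted class sizes per direction (genes per class).
DEFAULT_CLASS_SIZES = {
    "up": {"cGAMES": 200, "cGAME": 150, "cGAMS": 100},
    "down": {"cGAMES": 80, "cGAME": 80, "cGAMS": 60},
}

#: Planted fraction of each class carrying each ELE-induced mark change.
DEFAULT_PRIMING = {
    ("up", "cGAMES"): {("H4K8ac", "new"): 0.40, ("H3K27me3", "lost"): 0.10},
    ("up", "cGAME"): {("H4K8ac", "new"): 0.30, ("H3K27me3", "lost"): 0.10},
    ("up", "cGAMS"): {("H4K8ac", "new"): 0.10},
    ("down", "cGAMES"): {("H3K27me3", "new"): 0.10, ("H4K8ac", "lost"): 0.05},
    ("down", "cGAME"): {("H3K27me3", "new"): 0.10, ("H4K8ac", "lost"): 0.05},
}

#: Fraction of all genes carrying a condition-shared peak per antibody
#: (active promoters for the acetyl mark, broad repressive domains for the
#: methyl mark).
SHARED_PEAK_FRACTION = {"H4K8ac": 0.45, "H3K27me3": 0.15}

#: Extra single-group DEGs outside the classes (exercise-alone response and
#: a small subthreshold-learning response), per direction.
EXTRA_DEGS = {"ELE_none": 60, "SED_3min": 40}

GROUP_SIZES = {BASELINE_GROUP: 3, "ELE_none": 3, "ELE_3min": 3,
               "SED_3min": 2, "SED_10min": 2}


def _default_design() -> list[SampleDesign]:
    design = []
    for group, n in GROUP_SIZES.items():
        exercise, learning = group.split("_")
        for i in range(n):
            design.append(
                SampleDesign(
                    sample_id=f"{group}_r{i + 1}",
                    exercise=exercise,
                    learning=learning,
                )
            )
    return design


def make_fixture_study(
    seed: int,
    params: SimulationParams | None = None,
    class_sizes: dict | None = None,
    priming: dict | None = None,
    noise_free: bool = False,
) -> FixtureStudy:
    """Generate a full paired study with planted priming structure.

    Behavioral groups: baseline (no exercise, no learning), exercise alone,
    exercise + 3 min learning, sedentary + 3 min, sedentary + 10 min
    (n = 3 exercised / baseline, n = 2 sedentary learners: the unbalanced
    design).  Class genes get fold changes in their defining groups only;
    planted fractions of each class receive new/lost peaks and a planted
    set of unrelated genes carries condition-shared peaks.  ``noise_free``
    yields deterministic counts and coverage for exact recovery tests.
    """
    params = params or SimulationParams()
    class_sizes = class_sizes if class_sizes is not None else DEFAULT_CLASS_SIZES
    priming = priming if priming is not None else DEFAULT_PRIMING
    rng = np.random.default_rng(seed)
    n_per_chrom = max(1, params.n_genes // 2) if params.n_genes else 0
    # ~18 kb of footprint per gene (10 kb gap + <=10 kb gene), with headroom
    chrom_len = max(100_000, int(n_per_chrom * 25_000))
    chrom_sizes = {"chr1": chrom_len, "chr2": chrom_len}
    genome = make_genome(
        params.n_genes, chrom_sizes, seed=int(rng.integers(_SEED_MOD))
    )
    gene_ids = [g.gene_id for g in genome.genes]
    design = _default_design()

    # --- assign classes ------------------------------------------------
    total_class = sum(sum(v.values()) for v in class_sizes.values())
    n_extra = sum(EXTRA_DEGS.values()) * 2 if total_class else 0
    if total_class + n_extra > len(gene_ids):
        raise ValueError("n_genes too small for the requested class sizes")
    shuffled = list(rng.permutation(gene_ids))
    cursor = 0
    intended: dict[str, dict[str, str]] = {"up": {}, "down": {}}
    lfc = pd.DataFrame(0.0, index=gene_ids, columns=list(GROUPS))
    class_groups = {
        "cGAMES": ["ELE_3min", "SED_10min"],
        "cGAME": ["ELE_3min"],
        "cGAMS": ["SED_10min"],
    }
    for direction, sizes in class_sizes.items():
        sign = 1.0 if direction == "up" else -1.0
        for cls, size in sizes.items():
            members = shuffled[cursor : cursor + size]
            cursor += size
            for g in members:
                intended[direction][g] = cls
            mags = rng.uniform(params.lfc_min, params.lfc_max, size=size)
            for grp in class_groups[cls]:
                lfc.loc[members, grp] = sign * mags
    for grp, n in (EXTRA_DEGS.items() if total_class else []):
        for sign in (1.0, -1.0):
            members = shuffled[cursor : cursor + n]
            cursor += n
            mags = rng.uniform(params.lfc_min, params.lfc_max, size=n)
            lfc.loc[members, grp] = sign * mags

    # --- mark dynamics and planted peaks --------------------------------
    dynamics: dict[str, dict[str, set[str]]] = {
        ab: {"new": set(), "lost": set(), "shared": set()} for ab in ANTIBODIES
    }
    for (direction, cls), mark_map in priming.items():
        members = sorted(intended[direction].keys())
        members = [g for g in members if intended[direction][g] == cls]
        for (antibody, status), frac in mark_map.items():
            k = int(round(frac * len(members)))
            free = [g for g in members if g not in _claimed(dynamics[antibody])]
            chosen = list(rng.permutation(free))[:k]
            dynamics[antibody][status].update(chosen)
    for antibody, frac in SHARED_PEAK_FRACTION.items():
        claimed = _claimed(dynamics[antibody])
        free = [g for g in gene_ids if g not in claimed]
        k = int(round(frac * len(gene_ids)))
        chosen = list(rng.permutation(free))[: min(k, len(free))]
        dynamics[antibody]["shared"].update(chosen)

    by_id = genome.by_id
    peak_rows = []
    status_conditions = {"new": "ELE", "lost": "SED", "shared": "ELE|SED"}
    for antibody in ANTIBODIES:
        for status, genes in dynamics[antibody].items():
            for g in sorted(genes):
                gene = by_id[g]
                width = int(rng.integers(params.peak_width_min, params.peak_width_max + 1))
                if antibody == "H4K8ac":
                    center = gene.tss  # acetyl peaks sit at promoters
                else:
                    center = (gene.tx_start + gene.tx_end) // 2
                size = genome.chrom_sizes[gene.chrom]
                start = max(0, center - width // 2)
                end = min(size, start + width)
                peak_rows.append(
                    {
                        "chrom": gene.chrom,
                        "start": start,
                        "end": end,
                        "antibody": antibody,
                        "conditions": status_conditions[status],
                        "fold": params.peak_fold,
                        "gene_id": g,
                    }
                )
    peaks = pd.DataFrame(
        peak_rows,
        columns=["chrom", "start", "end", "antibody", "conditions", "fold", "gene_id"],
    )
    truth = TruthRecord(
        lfc=lfc, mark_dynamics=dynamics, intended_class=intended, peaks=peaks
    )

    counts, truth = simulate_counts(
        genome, design, params, seed=int(rng.integers(_SEED_MOD)),
        truth=truth, noise_free=noise_free,
    )
    tracks = {}
    for antibody in ANTIBODIES:
        for condition in CONDITIONS:
            tracks[(antibody, condition)] = simulate_coverage(
                genome, truth, antibody, condition, params,
                seed=int(rng.integers(_SEED_MOD)), noise_free=noise_free,
            )
    igg = {}
    for condition in CONDITIONS:
        igg[condition] = simulate_coverage(
            genome, truth, "IgG", condition, params,
            seed=int(rng.integers(_SEED_MOD)), noise_free=noise_free,
        )
    return FixtureStudy(
        genome=genome, counts=counts, design=design, tracks=tracks,
        igg=igg, truth=truth, noise_free=noise_free,
    )


def _claimed(statuses: dict[str, set[str]]) -> set[str]:
    out: set[str] = set()
    for s in statuses.values():
        out |= s
    return out
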