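"""Priming integration: mark dynamics, DEG overlap, class calling, fractions.

The central question: which genes did early-life exercise (ELE) leave with
an altered chromatin state (a "new" or "lost" histone-mark peak) such that
a later learning stimulus changes their expression?  Genes are classified
from the four behavioral groups' DEG sets (all relative to the
no-exercise / no-learning baseline):

* ``cGAMES`` - changed in BOTH threshold-learning groups (3 min for
  exercised mice, 10 min for sedentary mice);
* ``cGAME`` - changed in the exercised threshold group only (not in any
  other group, including exercise alone);
* ``cGAMS`` - changed in the sedentary threshold group only.

"Priming" is then quantified per class as the fraction of genes carrying
an ELE-induced permissive change for up-genes (new H4K8ac or lost
H3K27me3) or a repressive change for down-genes (new H3K27me3 or lost
H4K8ac).  A z-score concordance asks whether primed genes move in the same
direction in the exercised-3-min and sedentary-10-min groups.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import annotate as _annotate
from . import de as _de
from . import peaks as _peaks
from .io import CountMatrix, CoverageTrack, GenomeAnnotation

__all__ = [
    "GROUP_ELE_ALONE",
    "GROUP_ELE_3MIN",
    "GROUP_SED_3MIN",
    "GROUP_SED_10MIN",
    "MarkDynamics",
    "GameClassification",
    "PrimingReport",
    "mark_dynamics",
    "intersect_dynamics_degs",
    "classify_game",
    "priming_fractions",
    "zscore_concordance",
    "round_half_up_percent",
    "run_study",
    "run_pipeline",
]

GROUP_ELE_ALONE = "ELE_none"
GROUP_ELE_3MIN = "ELE_3min"
GROUP_SED_3MIN = "SED_3min"
GROUP_SED_10MIN = "SED_10min"
REQUIRED_GROUPS = (GROUP_ELE_ALONE, GROUP_ELE_3MIN, GROUP_SED_3MIN, GROUP_SED_10MIN)

UP_PRIMING_MARKS = (("H4K8ac", "new"), ("H3K27me3", "lost"))
DOWN_PRIMING_MARKS = (("H3K27me3", "new"), ("H4K8ac", "lost"))


@dataclass
class MarkDynamics:
    """Gene-level peak-presence change between conditions for one antibody."""

    antibody: str
    new: set[str]  # present in ELE, absent in SED
    lost: set[str]  # present in SED, absent in ELE
    shared: set[str]  # present in both

    def __post_init__(self) -> None:
        if (self.new & self.lost) or (self.new & self.shared) or (self.lost & self.shared):
            raise ValueError("new/lost/shared must be pairwise disjoint")

    def status_set(self, status: str) -> set[str]:
        return getattr(self, status)


@dataclass
class GameClassification:
    """cGAME / cGAMES / cGAMS gene sets per direction."""

    classes: dict[str, dict[str, set[str]]]  # direction -> class -> genes
    groups_used: tuple[str, ...] = REQUIRED_GROUPS

    def __post_init__(self) -> None:
        for direction, mapping in self.classes.items():
            game = mapping.get("cGAME", set())
            games = mapping.get("cGAMES", set())
            gams = mapping.get("cGAMS", set())
            if game & games or game & gams:
                raise ValueError(
                    f"{direction}: cGAME must be disjoint from cGAMES and cGAMS"
                )

    def members(self, direction: str, cls: str) -> set[str]:
        return self.classes.get(direction, {}).get(cls, set())


@dataclass
class PrimingReport:
    """Per-class priming counts and fractions plus z-score concordance."""

    rows: pd.DataFrame  # one row per (direction, class)
    zscores: pd.DataFrame | None = None
    concordance: float | None = None
    n_zero_sd_excluded: int = 0

    def to_json_dict(self) -> dict:
        records = []
        for rec in self.rows.to_dict(orient="records"):
            records.append(
                {
                    k: (None if isinstance(v, float) and math.isnan(v) else v)
                    for k, v in rec.items()
                }
            )
        return {
            "classes": records,
            "concordance": None
            if self.concordance is None or (isinstance(self.concordance, float) and math.isnan(self.concordance))
            else self.concordance,
            "n_zero_sd_excluded": self.n_zero_sd_excluded,
        }


def round_half_up_percent(fraction: float) -> int:
    """Display rounding of a fraction to whole percent, half away from zero
    (58/145 -> 40, 76/256 -> 30)."""
    return int(math.floor(fraction * 100 + 0.5))


# ---------------------------------------------------------------------------
# mark dynamics and DEG overlap
# ---------------------------------------------------------------------------


def mark_dynamics(
    presence: Mapping[tuple[str, str], set[str]], antibody: str
) -> MarkDynamics:
    """Set algebra over gene-level peak presence in ELE vs SED."""
    try:
        ele = set(presence[(antibody, "ELE")])
        sed = set(presence[(antibody, "SED")])
    except KeyError as exc:
        raise ValueError(
            f"presence map lacks condition {exc} for antibody {antibody!r}"
        ) from None
    return MarkDynamics(
        antibody=antibody, new=ele - sed, lost=sed - ele, shared=ele & sed
    )


def intersect_dynamics_degs(
    dynamics: Mapping[str, MarkDynamics], degs: _de.DEGSets
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All antibody x {new, lost, shared} x {up, down} intersections.

    Returns ``(table, co_occurrence)``: the 12-cell overlap table (count
    and sorted gene list per cell) and the pairwise co-occurrence counts
    between cells (genes appearing in two cells at once, supporting
    "N also had ..." statements).
    """
    rows = []
    cells: dict[tuple[str, str, str], set[str]] = {}
    for ab, dyn in dynamics.items():
        for status in ("new", "lost", "shared"):
            for direction, deg_set in (("up", degs.up), ("down", degs.down)):
                genes = dyn.status_set(status) & deg_set
                cells[(ab, status, direction)] = genes
                rows.append(
                    {
                        "antibody": ab,
                        "status": status,
                        "direction": direction,
                        "count": len(genes),
                        "genes": ",".join(sorted(genes)),
                    }
                )
    table = pd.DataFrame(rows)
    keys = list(cells)
    co_rows = []
    for i, k1 in enumerate(keys):
        for k2 in keys[i + 1 :]:
            both = cells[k1] & cells[k2]
            if both:
                co_rows.append(
                    {
                        "cell_a": "/".join(k1),
                        "cell_b": "/".join(k2),
                        "count": len(both),
                        "genes": ",".join(sorted(both)),
                    }
                )
    co = pd.DataFrame(co_rows, columns=["cell_a", "cell_b", "count", "genes"])
    return table, co


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_game(
    deg_by_group: Mapping[str, _de.DEGSets],
    exclude_ele_alone: bool = True,
) -> GameClassification:
    """Classify genes into cGAME / cGAMES / cGAMS per direction.

    All DEG sets are relative to the no-exercise / no-learning baseline.
    Per direction d:

    * cGAMES = deg(ELE+3min, d) & deg(SED+10min, d)
    * cGAME  = deg(ELE+3min, d) - [deg(ELE alone, d) | deg(SED+3min, d)
      | deg(SED+10min, d)]
    * cGAMS  = deg(SED+10min, d) - [deg(ELE alone, d) | deg(SED+3min, d)
      | deg(ELE+3min, d)]

    ``exclude_ele_alone=False`` drops the exercise-alone group from the
    exclusion unions (the laxer reading of "not changed in any other
    group").
    """
    missing = [g for g in REQUIRED_GROUPS if g not in deg_by_group]
    if missing:
        raise ValueError(f"missing DEG sets for groups: {missing}")
    classes: dict[str, dict[str, set[str]]] = {}
    for direction in ("up", "down"):
        sets = {
            g: (deg_by_group[g].up if direction == "up" else deg_by_group[g].down)
            for g in REQUIRED_GROUPS
        }
        ele_alone = sets[GROUP_ELE_ALONE] if exclude_ele_alone else set()
        cgames = sets[GROUP_ELE_3MIN] & sets[GROUP_SED_10MIN]
        cgame = sets[GROUP_ELE_3MIN] - (
            ele_alone | sets[GROUP_SED_3MIN] | sets[GROUP_SED_10MIN]
        )
        cgams = sets[GROUP_SED_10MIN] - (
            ele_alone | sets[GROUP_SED_3MIN] | sets[GROUP_ELE_3MIN]
        )
        classes[direction] = {"cGAME": cgame, "cGAMES": cgames, "cGAMS": cgams}
    return GameClassification(classes=classes)


def priming_fractions(
    classification: GameClassification,
    dynamics: Mapping[str, MarkDynamics],
) -> PrimingReport:
    """Quantify ELE-induced mark changes per class and direction.

    Up-classes are scored against new H4K8ac and lost H3K27me3 (permissive
    changes); down-classes against new H3K27me3 and lost H4K8ac
    (repressive changes).  The union fraction and each component are
    reported; empty classes carry NaN fractions with count 0.  Display
    percentages use half-up rounding.
    """
    rows = []
    for direction in ("up", "down"):
        marks = UP_PRIMING_MARKS if direction == "up" else DOWN_PRIMING_MARKS
        for cls in ("cGAME", "cGAMES", "cGAMS"):
            members = classification.members(direction, cls)
            total = len(members)
            primed_union: set[str] = set()
            component_counts = {}
            for antibody, status in marks:
                dyn = dynamics.get(antibody)
                genes = dyn.status_set(status) & members if dyn else set()
                component_counts[f"n_{status}_{antibody}"] = len(genes)
                primed_union |= genes
            frac = len(primed_union) / total if total else float("nan")
            rows.append(
                {
                    "direction": direction,
                    "class": cls,
                    "total": total,
                    **component_counts,
                    "n_primed": len(primed_union),
                    "fraction_primed": frac,
                    "percent_primed": round_half_up_percent(frac)
                    if total
                    else None,
                    "primed_genes": ",".join(sorted(primed_union)),
                }
            )
    return PrimingReport(rows=pd.DataFrame(rows))


def zscore_concordance(
    lfc_matrix: pd.DataFrame,
    primed_genes: set[str] | Sequence[str],
    group_a: str = GROUP_ELE_3MIN,
    group_b: str = GROUP_SED_10MIN,
) -> tuple[pd.DataFrame, float, int]:
    """Row z-scores of per-group fold changes and sign concordance.

    ``lfc_matrix`` is genes x groups (log2 fold change vs baseline; by
    default the three learning-relevant groups).  Each row is centered and
    scaled by its own mean/SD across groups; rows with zero SD are excluded
    and counted.  Concordance is the fraction of primed genes whose
    z-scores in ``group_a`` and ``group_b`` share a sign.  Returns
    ``(zscores, concordance, n_excluded)``; concordance is NaN when no
    primed gene survives.
    """
    if lfc_matrix.shape[1] < 2:
        raise ValueError("need at least two groups for z-scores")
    values = lfc_matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    keep = (sd[:, 0] > 0) & np.isfinite(sd[:, 0])
    n_excluded = int((~keep).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (values - mean) / sd
    zdf = pd.DataFrame(z[keep], index=lfc_matrix.index[keep], columns=lfc_matrix.columns)
    primed = [g for g in set(primed_genes) if g in zdf.index]
    if not primed:
        return zdf, float("nan"), n_excluded
    za = zdf.loc[primed, group_a].to_numpy()
    zb = zdf.loc[primed, group_b].to_numpy()
    concordance = float(np.mean(np.sign(za) == np.sign(zb)))
    return zdf, concordance, n_excluded


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


@dataclass
class StudyReport:
    """Everything the integrated pipeline computes."""

    deg_by_group: dict[str, _de.DEGSets]
    de_by_group: dict[str, _de.DEResult]
    peaksets: dict[tuple[str, str], _peaks.PeakSet]
    qc_exclusions: list[dict]
    presence: dict[tuple[str, str], set[str]]
    dynamics: dict[str, MarkDynamics]
    region: dict[tuple[str, str], _annotate.RegionDistribution]
    classification: GameClassification
    priming: PrimingReport
    overlap_tables: dict[str, pd.DataFrame]
    thresholds: dict


def run_study(
    genome: GenomeAnnotation,
    counts: CountMatrix,
    tracks: Mapping[tuple[str, str], CoverageTrack],
    igg: Mapping[str, CoverageTrack] | None = None,
    lfc_cut: float = _de.DEFAULT_LFC_CUT,
    p_cut: float = _de.DEFAULT_P_CUT,
    use: str = "p",
    peak_mode: str = "relaxed",
    peak_threshold: str = "control",
    numeric_fraction: float = 0.01,
    tss_window: int = 3000,
    downstream_window: int = 3000,
) -> StudyReport:
    """Run the integrated analysis on in-memory objects.

    Stages: per-group NB Wald differential expression against the baseline
    group -> peak calling per antibody x condition (against the matching
    IgG track, or numeric top-fraction when ``peak_threshold="numeric"``)
    -> annotation -> gene-level presence and ELE/SED dynamics -> class
    calling -> priming fractions -> z-score concordance.  Errors at any
    stage propagate with the stage named.
    """
    thresholds = {
        "lfc_cut": lfc_cut,
        "p_cut": p_cut,
        "use": use,
        "peak_mode": peak_mode,
        "peak_threshold": peak_threshold,
        "numeric_fraction": numeric_fraction,
        "tss_window": tss_window,
        "downstream_window": downstream_window,
    }
    # --- differential expression ---------------------------------------
    try:
        sf = _de.median_ratio_size_factors(counts)
    except ValueError:
        sf = _de.median_ratio_size_factors(counts, pseudo_reference=True)
    groups = [s.group for s in counts.samples]
    de_by_group: dict[str, _de.DEResult] = {}
    deg_by_group: dict[str, _de.DEGSets] = {}
    for grp in REQUIRED_GROUPS:
        if grp not in groups:
            raise RuntimeError(f"differential_expression: group {grp!r} absent")
        try:
            res = _de.nb_wald_test(counts, f"group:{grp}:{_baseline(groups)}")
        except Exception as exc:  # pragma: no cover - stage labeling
            raise RuntimeError(f"differential_expression[{grp}]: {exc}") from exc
        de_by_group[grp] = res
        deg_by_group[grp] = _de.call_degs(res, lfc_cut=lfc_cut, p_cut=p_cut, use=use)

    # --- peak calling ----------------------------------------------------
    peaksets: dict[tuple[str, str], _peaks.PeakSet] = {}
    for (antibody, condition), track in tracks.items():
        try:
            blocks = _peaks.segment_blocks(track)
            if peak_threshold == "control":
                if igg is None or condition not in igg:
                    raise ValueError(f"no IgG control for condition {condition!r}")
                ctl_blocks = _peaks.segment_blocks(igg[condition])
                if not blocks or not ctl_blocks:
                    # a signal-free track yields no peaks rather than an error
                    ps = _peaks.PeakSet(
                        peaks=[], mode=peak_mode, threshold_type="control",
                        auc_threshold=float("inf"), sample=track.sample,
                    )
                else:
                    ps = _peaks.call_peaks_with_control(
                        blocks, ctl_blocks, mode=peak_mode, sample=track.sample
                    )
            else:
                ps = _peaks.call_peaks_numeric(
                    blocks, fraction=numeric_fraction, mode=peak_mode,
                    sample=track.sample,
                )
        except Exception as exc:
            raise RuntimeError(f"peak_calling[{antibody},{condition}]: {exc}") from exc
        peaksets[(antibody, condition)] = ps
    retained, qc_report = _peaks.qc_filter_samples(
        {f"{ab}_{cond}": ps for (ab, cond), ps in peaksets.items()}
    )
    excluded_names = {r["sample"] for r in qc_report}

    # --- annotation and presence ----------------------------------------
    annotated: dict[tuple[str, str], list] = {}
    region: dict[tuple[str, str], _annotate.RegionDistribution] = {}
    for key, ps in peaksets.items():
        name = f"{key[0]}_{key[1]}"
        if name in excluded_names:
            annotated[key] = []
            continue
        try:
            anns = _annotate.annotate_peaks(
                ps, genome, tss_window=tss_window, downstream_window=downstream_window
            )
        except Exception as exc:
            raise RuntimeError(f"peak_annotation[{key}]: {exc}") from exc
        annotated[key] = anns
        if anns:
            region[key] = _annotate.region_distribution(anns)
    presence = _annotate.gene_peak_presence(annotated)

    # --- dynamics, classes, priming --------------------------------------
    antibodies = sorted({ab for ab, _ in tracks})
    dynamics = {}
    for ab in antibodies:
        presence.setdefault((ab, "ELE"), set())
        presence.setdefault((ab, "SED"), set())
        dynamics[ab] = mark_dynamics(presence, ab)
    classification = classify_game(deg_by_group)
    priming = priming_fractions(classification, dynamics)

    overlap_tables = {}
    for grp in (GROUP_ELE_3MIN, GROUP_SED_10MIN):
        table, co = intersect_dynamics_degs(dynamics, deg_by_group[grp])
        overlap_tables[grp] = table
        overlap_tables[f"{grp}_cooccurrence"] = co

    # --- z-score concordance over the three learning-relevant groups -----
    lfc_cols = [GROUP_ELE_3MIN, GROUP_SED_3MIN, GROUP_SED_10MIN]
    lfc_matrix = pd.DataFrame(
        {g: de_by_group[g].table["log2fc"] for g in lfc_cols}
    ).dropna()
    primed_genes: set[str] = set()
    for direction in ("up", "down"):
        for cls in ("cGAME", "cGAMES"):
            row = priming.rows[
                (priming.rows["direction"] == direction) & (priming.rows["class"] == cls)
            ]
            genes = row.iloc[0]["primed_genes"]
            if genes:
                primed_genes |= set(genes.split(","))
    z, concordance, n_excl = zscore_concordance(lfc_matrix, primed_genes)
    priming.zscores = z
    priming.concordance = concordance
    priming.n_zero_sd_excluded = n_excl

    return StudyReport(
        deg_by_group=deg_by_group,
        de_by_group=de_by_group,
        peaksets=peaksets,
        qc_exclusions=qc_report,
        presence=presence,
        dynamics=dynamics,
        region=region,
        classification=classification,
        priming=priming,
        overlap_tables=overlap_tables,
        thresholds=thresholds,
    )


def _baseline(groups: list[str]) -> str:
    if "SED_none" not in groups:
        raise RuntimeError("differential_expression: baseline group SED_none absent")
    return "SED_none"


def write_study_report(report: StudyReport, out_dir: str | Path) -> None:
    """Write the pipeline outputs as deterministic text tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for direction, mapping in sorted(report.classification.classes.items()):
        for cls, genes in sorted(mapping.items()):
            for g in sorted(genes):
                rows.append({"direction": direction, "class": cls, "gene_id": g})
    pd.DataFrame(rows, columns=["direction", "class", "gene_id"]).to_csv(
        out / "game_classes.tsv", sep="\t", index=False
    )
    for name, table in sorted(report.overlap_tables.items()):
        table.to_csv(out / f"overlap_{name}.tsv", sep="\t", index=False)
    payload = report.priming.to_json_dict()
    payload["thresholds"] = report.thresholds
    payload["qc_exclusions"] = report.qc_exclusions
    with open(out / "priming_report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, allow_nan=False, default=str)
    if report.priming.zscores is not None:
        report.priming.zscores.round(6).rename_axis("gene_id").to_csv(
            out / "zscore_matrix.tsv", sep="\t"
        )
    for grp, degs in sorted(report.deg_by_group.items()):
        with open(out / f"degs_{grp}_up.txt", "w") as fh:
            fh.write("\n".join(sorted(degs.up)) + ("\n" if degs.up else ""))
        with open(out / f"degs_{grp}_down.txt", "w") as fh:
            fh.write("\n".join(sorted(degs.down)) + ("\n" if degs.down else ""))


def run_pipeline(config: Mapping | str | Path, out_dir: str | Path | None = None) -> StudyReport:
    """File-based front end to :func:`run_study`.

    ``config`` is a mapping (or YAML file path) with keys ``counts``,
    ``design``, ``genes``, optional ``chrom_sizes``, ``tracks`` (mapping
    "antibody,condition" -> bedGraph path), optional ``igg`` (condition ->
    bedGraph path), and optional threshold overrides matching
    :func:`run_study`'s keyword arguments.
    """
    from . import io as _io

    if isinstance(config, (str, Path)):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = dict(config)
    design = _io.read_design_table(cfg["design"])
    counts = _io.read_count_table(cfg["counts"], design=design)
    sizes = _io.read_chrom_sizes(cfg["chrom_sizes"]) if cfg.get("chrom_sizes") else None
    genome = _io.read_gene_annotation(cfg["genes"], chrom_sizes=sizes)
    tracks = {}
    for key, path in cfg.get("tracks", {}).items():
        antibody, condition = [x.strip() for x in key.split(",")]
        tracks[(antibody, condition)] = _io.read_bedgraph(path)
    igg = {cond: _io.read_bedgraph(path) for cond, path in cfg.get("igg", {}).items()}
    kwargs = {
        k: cfg[k]
        for k in (
            "lfc_cut", "p_cut", "use", "peak_mode", "peak_threshold",
            "numeric_fraction", "tss_window", "downstream_window",
        )
        if k in cfg
    }
    report = run_study(genome, counts, tracks, igg or None, **kwargs)
    if out_dir is not None:
        write_study_report(report, out_dir)
    return report
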