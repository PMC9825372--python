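"""Data model and readers/writers for count tables, design tables, gene
annotations, bedGraph coverage, and BED peak output.

All genomic coordinates inside the package are 0-based half-open (BED
convention).  Conversion to/from 1-based formats (GTF) happens only at the
I/O boundary.  Count and design tables are plain tab-separated text; the
design table is keyed by ``sample_id`` and kept separate from the count
table so the counts format stays minimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "GenomeAnnotation",
    "SampleDesign",
    "CountMatrix",
    "CoverageTrack",
    "ParseError",
    "read_count_table",
    "write_count_table",
    "read_design_table",
    "write_design_table",
    "read_bedgraph",
    "write_bedgraph",
    "read_gene_annotation",
    "read_chrom_sizes",
    "write_peaks_bed",
    "read_peaks_bed",
]

EXERCISE_LEVELS = ("SED", "ELE")
LEARNING_LEVELS = ("none", "3min", "10min")
HEMISPHERE_LEVELS = ("L", "R", "both")
ISOLATION_LEVELS = ("simultaneous", "separate")
ASSAY_LEVELS = ("RNA", "CUTRUN")
ANTIBODY_LEVELS = ("H4K8ac", "H3K27me3", "IgG", "NA")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A single gene-level transcript model.

    ``tx_start``/``tx_end`` are 0-based half-open; ``exons`` are sorted,
    non-overlapping half-open intervals contained in the gene body.  The TSS
    is ``tx_start`` on the + strand and ``tx_end - 1`` on the - strand.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: unknown strand {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError(
                f"{self.gene_id}: tx_start {self.tx_start} must be < tx_end {self.tx_end}"
            )
        prev_end = None
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(
                    f"{self.gene_id}: exon [{s},{e}) outside gene body "
                    f"[{self.tx_start},{self.tx_end})"
                )
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def gene_length(self) -> int:
        return self.tx_end - self.tx_start

    @property
    def tes(self) -> int:
        """Transcription end site (last transcribed base)."""
        return self.tx_end - 1 if self.strand == "+" else self.tx_start

    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if e0 < s1:
                out.append((e0, s1))
        return tuple(out)


@dataclass
class GenomeAnnotation:
    """A gene-level genome annotation plus chromosome sizes."""

    genes: list[GeneModel]
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            size = self.chrom_sizes.get(g.chrom)
            if size is None:
                raise ValueError(f"{g.gene_id}: chrom {g.chrom!r} not in chrom_sizes")
            if g.tx_end > size:
                raise ValueError(
                    f"{g.gene_id}: tx_end {g.tx_end} beyond chrom {g.chrom} size {size}"
                )

    @property
    def by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return [g for g in self.genes if g.chrom == chrom]


@dataclass(frozen=True)
class SampleDesign:
    """Experimental metadata for one sample.

    Closed factor vocabularies: exercise in {ELE, SED}; learning in
    {none, 3min, 10min}; hemisphere in {L, R, both}; isolation in
    {simultaneous, separate}; assay in {RNA, CUTRUN}; antibody is "NA" for
    RNA samples and one of {H4K8ac, H3K27me3, IgG} for CUT&RUN samples.
    """

    sample_id: str
    exercise: str = "SED"
    learning: str = "none"
    hemisphere: str = "both"
    isolation: str = "simultaneous"
    assay: str = "RNA"
    antibody: str = "NA"

    def __post_init__(self) -> None:
        checks = [
            ("exercise", self.exercise, EXERCISE_LEVELS),
            ("learning", self.learning, LEARNING_LEVELS),
            ("hemisphere", self.hemisphere, HEMISPHERE_LEVELS),
            ("isolation", self.isolation, ISOLATION_LEVELS),
            ("assay", self.assay, ASSAY_LEVELS),
            ("antibody", self.antibody, ANTIBODY_LEVELS),
        ]
        for name, value, levels in checks:
            if value not in levels:
                raise ValueError(f"{self.sample_id}: {name}={value!r} not in {levels}")
        if (self.antibody == "NA") != (self.assay == "RNA"):
            raise ValueError(
                f"{self.sample_id}: antibody must be 'NA' iff assay is 'RNA' "
                f"(got assay={self.assay!r}, antibody={self.antibody!r})"
            )

    @property
    def group(self) -> str:
        """Behavioral group label, e.g. ``SED_none`` or ``ELE_3min``."""
        return f"{self.exercise}_{self.learning}"


@dataclass
class CountMatrix:
    """Genes x samples integer count matrix with per-sample design."""

    gene_ids: list[str]
    samples: list[SampleDesign]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        sids = [s.sample_id for s in self.samples]
        if len(set(sids)) != len(sids):
            raise ValueError("duplicate sample ids")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def design_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": s.sample_id,
                "exercise": s.exercise,
                "learning": s.learning,
                "hemisphere": s.hemisphere,
                "isolation": s.isolation,
                "assay": s.assay,
                "antibody": s.antibody,
            }
            for s in self.samples
        ]
        return pd.DataFrame(rows).set_index("sample_id")

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        index = {s.sample_id: j for j, s in enumerate(self.samples)}
        cols = [index[sid] for sid in sample_ids]
        return CountMatrix(
            gene_ids=list(self.gene_ids),
            samples=[self.samples[j] for j in cols],
            counts=self.counts[:, cols].copy(),
        )


@dataclass
class CoverageTrack:
    """Sorted, non-overlapping per-base coverage intervals (one sample).

    Stored per chromosome as parallel numpy arrays (starts, ends, depths).
    Zero-depth intervals are permitted (gaps are implicitly zero as well).
    """

    sample: SampleDesign | None
    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        clean: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, depths) in self.data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            depths = np.asarray(depths, dtype=np.float64)
            order = np.argsort(starts, kind="stable")
            starts, ends, depths = starts[order], ends[order], depths[order]
            if (ends <= starts).any():
                i = int(np.argmax(ends <= starts))
                raise ParseError(
                    f"{chrom}: interval end {ends[i]} <= start {starts[i]}"
                )
            if (starts[1:] < ends[:-1]).any():
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise ParseError(
                    f"{chrom}: overlapping intervals at "
                    f"[{starts[i]},{ends[i]}) and [{starts[i + 1]},{ends[i + 1]})"
                )
            if (depths < 0).any():
                raise ParseError(f"{chrom}: negative depth")
            clean[chrom] = (starts, ends, depths)
        self.data = clean

    @property
    def chroms(self) -> list[str]:
        return sorted(self.data)

    def intervals(self) -> Iterable[tuple[str, int, int, float]]:
        for chrom in self.chroms:
            starts, ends, depths = self.data[chrom]
            for s, e, d in zip(starts, ends, depths):
                yield chrom, int(s), int(e), float(d)

    def total_signal(self, chrom: str | None = None) -> float:
        """Integral of depth over length (optionally one chromosome)."""
        chroms = [chrom] if chrom is not None else self.chroms
        total = 0.0
        for c in chroms:
            starts, ends, depths = self.data[c]
            total += float(np.sum((ends - starts) * depths))
        return total


# ---------------------------------------------------------------------------
# count and design tables
# ---------------------------------------------------------------------------


def read_design_table(path: str | Path) -> list[SampleDesign]:
    """Read a tab-separated design table (first column ``sample_id``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ParseError("design table must have a 'sample_id' column")
    designs = []
    known = {"sample_id", "exercise", "learning", "hemisphere", "isolation", "assay", "antibody"}
    for _, row in df.iterrows():
        kwargs = {k: row[k] for k in df.columns if k in known and pd.notna(row[k])}
        designs.append(SampleDesign(**kwargs))
    return designs


def write_design_table(designs: Sequence[SampleDesign], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "exercise": s.exercise,
            "learning": s.learning,
            "hemisphere": s.hemisphere,
            "isolation": s.isolation,
            "assay": s.assay,
            "antibody": s.antibody,
        }
        for s in designs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_count_table(
    path: str | Path, design: Sequence[SampleDesign] | None = None
) -> CountMatrix:
    """Read a tab-separated count table (first column: gene ids).

    Every body cell must be a non-negative integer; violations are reported
    with the offending gene and sample.  When ``design`` is given, columns
    are matched against it by sample id (order taken from the table) and
    every table column must have a design row.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise ParseError("count table needs a gene-id column and >=1 sample column")
    sample_ids = header[1:]
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    gene_ids = [str(g) for g in df.index]
    if len(set(gene_ids)) != len(gene_ids):
        dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise ParseError(f"duplicate gene id(s): {', '.join(dupes[:5])}")
    values = np.empty((len(gene_ids), len(sample_ids)), dtype=np.int64)
    for j, sid in enumerate(sample_ids):
        col = df.iloc[:, j]
        for i, raw in enumerate(col):
            try:
                x = int(raw)
                if x < 0 or str(int(raw)) != str(raw).strip():
                    raise ValueError
            except (TypeError, ValueError):
                raise ParseError(
                    f"non-integer or negative count {raw!r} at "
                    f"(gene {gene_ids[i]!r}, sample {sid!r})"
                ) from None
            values[i, j] = x
    if design is not None:
        by_id = {s.sample_id: s for s in design}
        missing = [sid for sid in sample_ids if sid not in by_id]
        if missing:
            raise ParseError(f"samples missing from design table: {missing}")
        samples = [by_id[sid] for sid in sample_ids]
    else:
        samples = [SampleDesign(sample_id=sid) for sid in sample_ids]
    return CountMatrix(gene_ids=gene_ids, samples=samples, counts=values)


def write_count_table(cm: CountMatrix, path: str | Path) -> None:
    cm.to_frame().rename_axis("gene_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


def _merge_adjacent_equal(
    starts: np.ndarray, ends: np.ndarray, depths: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Merge runs of intervals that touch (end == next start) at equal depth."""
    if len(starts) == 0:
        return starts, ends, depths
    breaks = np.flatnonzero((starts[1:] != ends[:-1]) | (depths[1:] != depths[:-1]))
    run_starts = np.concatenate([[0], breaks + 1])
    run_ends = np.concatenate([breaks, [len(starts) - 1]])
    return starts[run_starts], ends[run_ends], depths[run_starts]


def read_bedgraph(path: str | Path, sample: SampleDesign | None = None) -> CoverageTrack:
    """Read a 4-column bedGraph into a sorted, merged CoverageTrack.

    Touching intervals with equal depth are merged; zero-depth lines are
    retained.  Overlapping intervals or end <= start raise :class:`ParseError`.
    """
    chroms: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"line {lineno}: expected 4 columns, got {len(parts)}")
            chrom, s, e, d = parts[0], parts[1], parts[2], parts[3]
            try:
                s_i, e_i, d_f = int(s), int(e), float(d)
            except ValueError:
                raise ParseError(f"line {lineno}: malformed fields {parts[:4]}") from None
            if e_i <= s_i:
                raise ParseError(f"line {lineno}: end {e_i} <= start {s_i}")
            chroms.setdefault(chrom, []).append((s_i, e_i, d_f))
    data = {}
    for chrom, triples in chroms.items():
        triples.sort()
        starts = np.array([t[0] for t in triples], dtype=np.int64)
        ends = np.array([t[1] for t in triples], dtype=np.int64)
        depths = np.array([t[2] for t in triples], dtype=np.float64)
        if (starts[1:] < ends[:-1]).any():
            i = int(np.argmax(starts[1:] < ends[:-1]))
            raise ParseError(
                f"{chrom}: overlapping intervals "
                f"[{starts[i]},{ends[i]}) and [{starts[i + 1]},{ends[i + 1]})"
            )
        data[chrom] = _merge_adjacent_equal(starts, ends, depths)
    return CoverageTrack(sample=sample, data=data)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e, d in track.intervals():
            d_str = f"{int(d)}" if float(d).is_integer() else f"{d:g}"
            fh.write(f"{chrom}\t{s}\t{e}\t{d_str}\n")


# ---------------------------------------------------------------------------
# gene annotation (minimal GTF or BED12) and chrom sizes
# ---------------------------------------------------------------------------


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            chrom, length = line.split("\t")[:2]
            sizes[chrom] = int(length)
    return sizes


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " in chunk:
            key, _, value = chunk.partition(" ")
            out[key] = value.strip().strip('"')
    return out


def _read_gtf(path: str | Path) -> list[GeneModel]:
    gene_bounds: dict[str, tuple[str, str, int, int]] = {}
    gene_exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ParseError(f"line {lineno}: GTF needs 9 columns")
            chrom, _, feature, start, end, _, strand, _, attrs = parts[:9]
            if feature not in ("gene", "exon", "transcript"):
                continue
            if strand not in ("+", "-"):
                raise ParseError(f"line {lineno}: unknown strand {strand!r}")
            gid = _parse_gtf_attributes(attrs).get("gene_id")
            if gid is None:
                raise ParseError(f"line {lineno}: missing gene_id attribute")
            s, e = int(start) - 1, int(end)  # GTF is 1-based inclusive
            if feature in ("gene", "transcript"):
                prev = gene_bounds.get(gid)
                if prev is None:
                    gene_bounds[gid] = (chrom, strand, s, e)
                    order.append(gid)
                else:
                    # keep the longest model per gene
                    if e - s > prev[3] - prev[2]:
                        gene_bounds[gid] = (chrom, strand, s, e)
            else:
                gene_exons.setdefault(gid, []).append((s, e))
                if gid not in gene_bounds:
                    gene_bounds[gid] = (chrom, strand, s, e)
                    order.append(gid)
    genes = []
    for gid in order:
        chrom, strand, s, e = gene_bounds[gid]
        exons = sorted(gene_exons.get(gid, [(s, e)]))
        for xs, xe in exons:
            if xs < s or xe > e:
                raise ParseError(
                    f"{gid}: exon [{xs},{xe}) outside gene body [{s},{e})"
                )
        genes.append(
            GeneModel(gene_id=gid, chrom=chrom, strand=strand, tx_start=s, tx_end=e,
                      exons=tuple(exons))
        )
    return genes


def _read_bed12(path: str | Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ParseError(f"line {lineno}: BED12 needs 12 columns")
            chrom, start, end, name, _, strand = parts[:6]
            if strand not in ("+", "-"):
                raise ParseError(f"line {lineno}: unknown strand {strand!r}")
            s, e = int(start), int(end)
            n_blocks = int(parts[9])
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ParseError(f"line {lineno}: block count mismatch")
            exons = tuple((s + o, s + o + z) for o, z in zip(offsets, sizes))
            genes.append(
                GeneModel(gene_id=name, chrom=chrom, strand=strand,
                          tx_start=s, tx_end=e, exons=exons)
            )
    return genes


def read_gene_annotation(
    path: str | Path, chrom_sizes: Mapping[str, int] | None = None
) -> GenomeAnnotation:
    """Read a gene annotation from minimal GTF (gene/exon features) or BED12.

    Format is sniffed from the first data line.  When ``chrom_sizes`` is not
    supplied, each chromosome's size is inferred as the maximum gene end on
    it (sufficient for annotation; supply real sizes for coverage work).
    """
    path = Path(path)
    fmt = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            ncol = len(line.split("\t"))
            fmt = "bed12" if ncol >= 12 and line.split("\t")[9].isdigit() else "gtf"
            break
    if fmt is None:
        genes: list[GeneModel] = []
    elif fmt == "bed12":
        genes = _read_bed12(path)
    else:
        genes = _read_gtf(path)
    if chrom_sizes is None:
        sizes: dict[str, int] = {}
        for g in genes:
            sizes[g.chrom] = max(sizes.get(g.chrom, 0), g.tx_end)
        chrom_sizes = sizes
    return GenomeAnnotation(genes=genes, chrom_sizes=dict(chrom_sizes))


def write_gene_annotation_gtf(genome: GenomeAnnotation, path: str | Path) -> None:
    """Write a minimal GTF with gene and exon features (1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genome.genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\tprimeseq\tgene\t{g.tx_start + 1}\t{g.tx_end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tprimeseq\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# peak BED output
# ---------------------------------------------------------------------------


def write_peaks_bed(peaks, path: str | Path) -> None:
    """Write a PeakSet (or iterable of SignalBlock) as sorted 6-column BED.

    Columns: chrom, start, end, name, AUC score, strand(".").
    """
    blocks = getattr(peaks, "peaks", peaks)
    blocks = sorted(blocks, key=lambda b: (b.chrom, b.start, b.end))
    with open(path, "w") as fh:
        fh.write("# chrom\tstart\tend\tname\tauc\tstrand\n")
        for i, b in enumerate(blocks, start=1):
            score = f"{int(b.auc)}" if float(b.auc).is_integer() else f"{b.auc:g}"
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\tpeak_{i}\t{score}\t.\n")


def read_peaks_bed(path: str | Path) -> list:
    """Read peaks written by :func:`write_peaks_bed` back as SignalBlocks.

    ``max_depth`` is not stored in BED6 and is reconstructed as NaN.
    """
    from .peaks import SignalBlock

    blocks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, s, e, _, score, _ = line.split("\t")[:6]
            blocks.append(
                SignalBlock(chrom=chrom, start=int(s), end=int(e),
                            auc=float(score), max_depth=float("nan"))
            )
    return blocks
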