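"""Synthetic annotated genome for methylation-reprogramming experiments.

Generates coordinate-only genomes (no nucleotide sequence) whose loci fall
into the sequence classes that behave distinctly during a demethylation/
remethylation wave: imprinted germline DMDs, gDMD-like loci, repeat-element
classes with different methylation retention, generic genic/intergenic
background, and unmethylated CpG-island promoters.  All coordinates are
0-based half-open, in memory and on disk (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class LocusClass(str, Enum):
    """Sequence classes with distinct methylation-inheritance behaviour."""

    IMPRINTED_GDMD = "IMPRINTED_GDMD"
    GDMD_LIKE = "GDMD_LIKE"
    RE_LINE = "RE_LINE"
    RE_SINE = "RE_SINE"
    RE_IAP = "RE_IAP"
    RE_SATELLITE = "RE_SATELLITE"
    GENIC_BODY = "GENIC_BODY"
    INTERGENIC = "INTERGENIC"
    CGI_PROMOTER_UNMETH = "CGI_PROMOTER_UNMETH"


#: Fixed mapping from repeat locus classes to the class strings written to the
#: repeats BED file (and read back by the annotation layer).
REPEAT_CLASS_NAMES: dict[LocusClass, str] = {
    LocusClass.RE_LINE: "LINE",
    LocusClass.RE_SINE: "SINE",
    LocusClass.RE_IAP: "IAP",
    LocusClass.RE_SATELLITE: "Satellite",
}

#: The eight-label genomic feature vocabulary used throughout the package.
FEATURES: tuple[str, ...] = (
    "promoter-TSS",
    "5UTR",
    "exon",
    "intron",
    "TTS",
    "3UTR",
    "noncoding",
    "intergenic",
)

GENE_CLASSES = (
    LocusClass.IMPRINTED_GDMD,
    LocusClass.GDMD_LIKE,
    LocusClass.GENIC_BODY,
    LocusClass.CGI_PROMOTER_UNMETH,
)

_GENE_PREFIX = {
    LocusClass.IMPRINTED_GDMD: "Imp",
    LocusClass.GDMD_LIKE: "Gdl",
    LocusClass.GENIC_BODY: "Gene",
    LocusClass.CGI_PROMOTER_UNMETH: "Cgi",
}

#: Default locus lengths (bp) per class.
DEFAULT_LOCUS_LENGTHS: dict[LocusClass, int] = {
    LocusClass.IMPRINTED_GDMD: 1000,
    LocusClass.GDMD_LIKE: 800,
    LocusClass.RE_LINE: 600,
    LocusClass.RE_SINE: 300,
    LocusClass.RE_IAP: 500,
    LocusClass.RE_SATELLITE: 400,
    LocusClass.GENIC_BODY: 2000,
    LocusClass.INTERGENIC: 1000,
    LocusClass.CGI_PROMOTER_UNMETH: 800,
}

#: Default class counts for the stock 2 x 5 Mb genome.  The imprinted and
#: gDMD-like counts mirror the catalogue sizes of the experiment this package
#: models (15 imprinted genes; 75 non-imprinted loci with comparable loss).
DEFAULT_CLASS_COUNTS: dict[LocusClass, int] = {
    LocusClass.IMPRINTED_GDMD: 15,
    LocusClass.GDMD_LIKE: 75,
    LocusClass.RE_LINE: 600,
    LocusClass.RE_SINE: 600,
    LocusClass.RE_IAP: 300,
    LocusClass.RE_SATELLITE: 200,
    LocusClass.GENIC_BODY: 1200,
    LocusClass.INTERGENIC: 900,
    LocusClass.CGI_PROMOTER_UNMETH: 150,
}

DEFAULT_CHROMOSOMES: tuple[tuple[str, int], ...] = (
    ("chr1", 5_000_000),
    ("chr2", 5_000_000),
)


class GenomeSizingError(ValueError):
    """Requested loci do not fit on the given chromosomes."""


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome layout and seed for a synthetic genome."""

    chromosomes: tuple[tuple[str, int], ...] = DEFAULT_CHROMOSOMES
    rng_seed: int = 0

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)


@dataclass
class AnnotatedLocus:
    """One locus of the synthetic genome.

    ``feature`` is the locus's primary genomic-feature label (one of
    :data:`FEATURES`); genic loci additionally expand into sub-feature
    intervals via :func:`gene_feature_intervals`.
    """

    locus_id: int
    chrom: str
    start: int
    end: int
    strand: str
    locus_class: LocusClass
    gene_id: str | None = None
    feature: str = "intergenic"
    cgi_flag: bool = False
    repeat_class: str | None = None
    hyper_prone: bool = False

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"locus {self.locus_id}: start must be < end")
        if self.feature not in FEATURES:
            raise ValueError(f"unknown feature label {self.feature!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start position for gene-bearing loci."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class CpGSite:
    chrom: str
    pos: int
    locus_id: int


def _place_on_chromosome(
    rng: np.random.Generator, chrom: str, length: int, lengths: list[int],
    min_gap: int = 1,
) -> list[tuple[int, int]]:
    """Place loci of the given lengths on one chromosome, non-overlapping,
    separated by random gaps of at least ``min_gap`` bp.  Returns
    (start, end) pairs in order."""
    n = len(lengths)
    if n == 0:
        return []
    total = sum(lengths)
    free = length - total - (n + 1) * min_gap
    if free < 0:
        raise GenomeSizingError(
            f"chromosome {chrom!r} ({length} bp) too small for {n} loci "
            f"totalling {total} bp plus {min_gap} bp gaps"
        )
    weights = rng.random(n + 1)
    gaps = np.floor(free * weights / weights.sum()).astype(int) + min_gap
    coords = []
    cursor = 0
    for i, loc_len in enumerate(lengths):
        cursor += int(gaps[i])
        coords.append((cursor, cursor + loc_len))
        cursor += loc_len
    return coords


def build_genome(
    spec: GenomeSpec,
    class_counts: Mapping[LocusClass, int] | None = None,
    cpg_density: int = 10,
    locus_lengths: Mapping[LocusClass, int] | None = None,
    hyper_fraction: float = 0.01,
    min_gap: int = 1200,
) -> tuple[list[AnnotatedLocus], list[CpGSite]]:
    """Build a synthetic annotated genome.

    Parameters
    ----------
    spec
        Chromosome layout and RNG seed; the same spec always yields the same
        genome.
    class_counts
        Number of loci per :class:`LocusClass` (defaults to the stock genome).
    cpg_density
        CpG sites per locus (each locus gets at least one).
    hyper_fraction
        Fraction of INTERGENIC loci flagged ``hyper_prone`` — loci that start
        lowly methylated and are prone to methylation gain during recovery.
    min_gap
        Minimum distance between adjacent loci.  The default (1200 bp)
        exceeds the promoter/TTS annotation windows so that a locus's tiles
        are never captured by a neighbouring gene's windows, keeping
        gene-level attribution unambiguous on the synthetic genome.

    Returns
    -------
    (loci, sites)
        Non-overlapping loci (per chromosome) and their CpG sites, both
        deterministic under ``spec.rng_seed``.
    """
    if cpg_density < 1:
        raise ValueError("cpg_density must be >= 1")
    counts = dict(DEFAULT_CLASS_COUNTS if class_counts is None else class_counts)
    if any(c < 0 for c in counts.values()):
        raise ValueError("class counts must be >= 0")
    lengths_by_class = dict(DEFAULT_LOCUS_LENGTHS)
    if locus_lengths:
        lengths_by_class.update(locus_lengths)

    rng = np.random.default_rng(spec.rng_seed)

    plan: list[LocusClass] = []
    for cls in LocusClass:  # fixed iteration order for determinism
        plan.extend([cls] * counts.get(cls, 0))
    order = rng.permutation(len(plan))
    plan = [plan[i] for i in order]

    # split loci among chromosomes proportionally to chromosome length
    chrom_names = [c for c, _ in spec.chromosomes]
    chrom_sizes = np.array([l for _, l in spec.chromosomes], dtype=float)
    shares = np.cumsum(chrom_sizes / chrom_sizes.sum())
    bounds = np.floor(shares * len(plan)).astype(int)
    bounds[-1] = len(plan)

    loci: list[AnnotatedLocus] = []
    gene_counters = {cls: 0 for cls in GENE_CLASSES}
    locus_id = 0
    lo = 0
    for ci, chrom in enumerate(chrom_names):
        chunk = plan[lo : bounds[ci]]
        lo = bounds[ci]
        lens = [lengths_by_class[cls] for cls in chunk]
        coords = _place_on_chromosome(
            rng, chrom, int(chrom_sizes[ci]), lens, min_gap=min_gap
        )
        for cls, (start, end) in zip(chunk, coords):
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = None
            if cls in GENE_CLASSES:
                gene_counters[cls] += 1
                gene_id = f"{_GENE_PREFIX[cls]}{gene_counters[cls]:04d}"
            if cls in (LocusClass.IMPRINTED_GDMD, LocusClass.GDMD_LIKE,
                       LocusClass.CGI_PROMOTER_UNMETH):
                feature = "promoter-TSS"
            elif cls is LocusClass.GENIC_BODY:
                feature = "intron"
            else:
                feature = "intergenic"
            loci.append(
                AnnotatedLocus(
                    locus_id=locus_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    locus_class=cls,
                    gene_id=gene_id,
                    feature=feature,
                    cgi_flag=cls in (LocusClass.IMPRINTED_GDMD,
                                     LocusClass.CGI_PROMOTER_UNMETH),
                    repeat_class=REPEAT_CLASS_NAMES.get(cls),
                )
            )
            locus_id += 1

    intergenic_ids = [l.locus_id for l in loci
                      if l.locus_class is LocusClass.INTERGENIC]
    n_hyper = int(round(hyper_fraction * len(intergenic_ids)))
    if n_hyper > 0:
        chosen = rng.choice(len(intergenic_ids), size=n_hyper, replace=False)
        hyper_set = {intergenic_ids[i] for i in chosen}
        for l in loci:
            if l.locus_id in hyper_set:
                l.hyper_prone = True

    sites: list[CpGSite] = []
    for locus in loci:
        k = min(cpg_density, locus.length)
        offsets = np.sort(rng.choice(locus.length, size=k, replace=False))
        sites.extend(
            CpGSite(locus.chrom, int(locus.start + off), locus.locus_id)
            for off in offsets
        )
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return loci, sites


def loci_frame(loci: Sequence[AnnotatedLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "locus_id": [l.locus_id for l in loci],
            "chrom": [l.chrom for l in loci],
            "start": [l.start for l in loci],
            "end": [l.end for l in loci],
            "strand": [l.strand for l in loci],
            "locus_class": [l.locus_class.value for l in loci],
            "gene_id": [l.gene_id for l in loci],
            "feature": [l.feature for l in loci],
            "cgi_flag": [l.cgi_flag for l in loci],
            "repeat_class": [l.repeat_class for l in loci],
            "hyper_prone": [l.hyper_prone for l in loci],
        }
    )


def sites_frame(sites: Sequence[CpGSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "locus_id": [s.locus_id for s in sites],
        }
    )


def genes_frame(loci: Sequence[AnnotatedLocus]) -> pd.DataFrame:
    """One row per gene-bearing locus with its TSS and strand (for TSS
    metaprofiles and candidate ranking)."""
    rows = [l for l in loci if l.gene_id is not None]
    return pd.DataFrame(
        {
            "gene_id": [l.gene_id for l in rows],
            "chrom": [l.chrom for l in rows],
            "tss": [l.tss for l in rows],
            "tts": [l.tts for l in rows],
            "strand": [l.strand for l in rows],
            "locus_class": [l.locus_class.value for l in rows],
        }
    )


# Genic-body sub-feature layout as fractions of locus length, 5' to 3'.
_BODY_LAYOUT = (
    ("5UTR", 0.10),
    ("exon", 0.15),
    ("intron", 0.30),
    ("exon", 0.15),
    ("intron", 0.20),
    ("3UTR", 0.10),
)


def gene_feature_intervals(
    loci: Sequence[AnnotatedLocus],
    chrom_lengths: Mapping[str, int],
    promoter_flank: int = 1000,
    tts_flank: int = 1000,
) -> pd.DataFrame:
    """Expand gene-bearing loci into feature intervals.

    Genic bodies split into 5UTR/exon/intron/3UTR blocks plus promoter-TSS
    and TTS windows (anchor +/- flank, clipped to the chromosome); promoter
    classes (imprinted gDMDs, gDMD-like loci, CGI promoters) contribute a
    single promoter-TSS window around the locus midpoint.
    """
    rows: list[tuple] = []

    def _window(chrom: str, anchor: int, flank: int) -> tuple[int, int]:
        return (max(0, anchor - flank),
                min(chrom_lengths[chrom], anchor + flank + 1))

    for l in loci:
        if l.gene_id is None:
            continue
        if l.locus_class is LocusClass.GENIC_BODY:
            s, e = _window(l.chrom, l.tss, promoter_flank)
            rows.append((l.chrom, s, e, l.gene_id, l.strand, "promoter-TSS"))
            s, e = _window(l.chrom, l.tts, tts_flank)
            rows.append((l.chrom, s, e, l.gene_id, l.strand, "TTS"))
            layout = _BODY_LAYOUT if l.strand == "+" else tuple(reversed(_BODY_LAYOUT))
            cursor = l.start
            for i, (label, frac) in enumerate(layout):
                end = l.end if i == len(layout) - 1 else cursor + int(round(frac * l.length))
                rows.append((l.chrom, cursor, end, l.gene_id, l.strand, label))
                cursor = end
        else:
            mid = (l.start + l.end) // 2
            s, e = _window(l.chrom, mid, promoter_flank)
            rows.append((l.chrom, s, e, l.gene_id, l.strand, "promoter-TSS"))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "gene_id", "strand", "feature"]
    )


def write_annotation(
    loci: Sequence[AnnotatedLocus],
    outdir: str | Path,
    chrom_lengths: Mapping[str, int] | None = None,
    promoter_flank: int = 1000,
    tts_flank: int = 1000,
) -> dict[str, Path]:
    """Write the three BED annotation files for a genome.

    * ``genes.bed`` — BED6 + feature column (gene feature intervals)
    * ``cgis.bed`` — BED4 (CpG islands)
    * ``repeats.bed`` — BED6 + repeat-class column

    Returns the mapping of file kind to path.  The files round-trip through
    :func:`remethyl.io.read_bed` losslessly.
    """
    from . import io as _io  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if chrom_lengths is None:
        # no clipping bound supplied: use max locus end per chromosome + flank
        chrom_lengths = {}
        for l in loci:
            bound = l.end + max(promoter_flank, tts_flank) + 1
            chrom_lengths[l.chrom] = max(chrom_lengths.get(l.chrom, 0), bound)

    genes = gene_feature_intervals(loci, chrom_lengths, promoter_flank, tts_flank)
    genes_bed = genes.rename(columns={"gene_id": "name"})
    genes_bed["score"] = 0
    genes_bed = genes_bed[["chrom", "start", "end", "name", "score", "strand", "feature"]]

    cgis = pd.DataFrame(
        [
            (l.chrom, l.start, l.end, l.gene_id or f"cgi_{l.locus_id}")
            for l in loci
            if l.cgi_flag
        ],
        columns=["chrom", "start", "end", "name"],
    )

    reps = pd.DataFrame(
        [
            (l.chrom, l.start, l.end, f"re_{l.locus_id}", 0, l.strand, l.repeat_class)
            for l in loci
            if l.repeat_class is not None
        ],
        columns=["chrom", "start", "end", "name", "score", "strand", "repeat_class"],
    )

    paths = {
        "genes": outdir / "genes.bed",
        "cgis": outdir / "cgis.bed",
        "repeats": outdir / "repeats.bed",
    }
    _io.write_bed(genes_bed, paths["genes"], dialect="bed6+feature")
    _io.write_bed(cgis, paths["cgis"], dialect="bed4")
    _io.write_bed(reps, paths["repeats"], dialect="bed6+class")
    return paths
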