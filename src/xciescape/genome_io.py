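"""Readers/writers for the on-disk formats and the shared annotation data model.

All coordinates are 0-based half-open internally.  Gene models travel as a
BED12 dialect in which the ``name`` column packs ``gene_id|transcript_id|
meta_status[|PAR]``, ``thickStart``/``thickEnd`` carry the promoter CpG
island (``thickStart == thickEnd`` means "no island"), and the block fields
carry exons.  A GTF dialect (gene/transcript/exon features with ``gene_id``
and ``transcript_id`` attributes) is accepted on read and converted.

Signal comes in as bedGraph; queries are length-weighted means and regions
with less than half their bases covered return a missing value rather than
zero — a gap in a coverage track is absence of evidence, not evidence of
absence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING_COVERAGE_FRACTION = 0.5  # regions covered below this fraction -> missing

VALID_META_STATUS = {"escape", "subject", "variable", "unknown"}
VALID_REGION_KINDS = {"promoter", "exon", "enhancer", "island", "flank"}


class ParseError(ValueError):
    """Raised for malformed input files; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = f"{path}:{line}: " if line is not None else ""
        super().__init__(f"{loc}{message}")
        self.path = path
        self.line = line


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    """One transcript model with its TSS, exons and optional CpG island.

    ``tss`` is the transcription start position in 0-based coordinates: the
    interval start on the + strand and ``end - 1`` on the − strand.
    ``meta_status`` is the literature-consensus XCI status used as a
    training/reference label ("escape", "subject", "variable", "unknown");
    pseudoautosomal genes are flagged so they can be excluded from
    escape-gene sets.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cpg_island: tuple[int, int] | None = None
    is_PAR: bool = False
    meta_status: str = "unknown"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand symbol {self.strand!r}")
        if self.meta_status not in VALID_META_STATUS:
            raise ValueError(f"unknown meta_status {self.meta_status!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"zero-length or inverted exon ({s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValueError("overlapping exons")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class SampleInfo:
    """Sample-sheet record; ``sex`` is required for any female-vs-male step."""

    sample_id: str
    sex: str
    tissue: str = ""
    dataset: str = ""
    skewed_xi: bool | None = None

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")


@dataclass
class Region:
    chrom: str
    start: int
    end: int
    strand: str = "+"
    linked_id: str = ""
    clipped: bool = False

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty region [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RegionSet:
    name: str
    kind: str
    intervals: list[Region] = field(default_factory=list)

    def __post_init__(self):
        if self.kind not in VALID_REGION_KINDS:
            raise ValueError(f"unknown region kind {self.kind!r}")

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self):
        return len(self.intervals)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def _normalise_strand(symbol: str) -> str:
    # tolerate the unicode minus that word processors like to substitute
    if symbol in ("+",):
        return "+"
    if symbol in ("-", "−"):
        return "-"
    raise ValueError(f"unknown strand symbol {symbol!r}")


def _parse_bed12_line(fields: list[str]) -> GeneAnnotation:
    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    if end <= start:
        raise ValueError(f"end {end} <= start {start}")
    name = fields[3] if len(fields) > 3 else ""
    strand = _normalise_strand(fields[5]) if len(fields) > 5 else "+"
    parts = name.split("|")
    gene_id = parts[0] if parts[0] else name
    transcript_id = parts[1] if len(parts) > 1 and parts[1] else gene_id
    meta_status = parts[2] if len(parts) > 2 and parts[2] else "unknown"
    is_par = len(parts) > 3 and parts[3] == "PAR"

    cpg_island = None
    if len(fields) > 7:
        thick_start, thick_end = int(fields[6]), int(fields[7])
        if thick_end > thick_start:
            cpg_island = (thick_start, thick_end)

    exons: list[tuple[int, int]] = []
    if len(fields) > 11:
        count = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",") if x]
        starts = [int(x) for x in fields[11].rstrip(",").split(",") if x]
        if len(sizes) != count or len(starts) != count:
            raise ValueError("blockCount disagrees with blockSizes/blockStarts")
        for size, off in zip(sizes, starts):
            if size <= 0:
                raise ValueError("zero-length exon block")
            exons.append((start + off, start + off + size))
    if not exons:
        exons = [(start, end)]

    return GeneAnnotation(
        gene_id=gene_id, transcript_id=transcript_id, chrom=chrom,
        strand=strand, start=start, end=end, exons=exons,
        cpg_island=cpg_island, is_PAR=is_par, meta_status=meta_status,
    )


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().strip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def _read_gtf(path) -> list[GeneAnnotation]:
    transcripts: dict[str, dict] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError("GTF line has fewer than 9 fields", path, lineno)
            chrom, _src, feature, start1, end1, _score, strand, _frame, attr_text = fields[:9]
            if feature not in ("transcript", "exon"):
                continue
            try:
                start, end = int(start1) - 1, int(end1)  # GTF is 1-based closed
                strand = _normalise_strand(strand)
            except ValueError as exc:
                raise ParseError(str(exc), path, lineno) from exc
            if end <= start:
                raise ParseError(f"end {end1} <= start {start1}", path, lineno)
            attrs = _parse_gtf_attributes(attr_text)
            tid = attrs.get("transcript_id")
            if tid is None:
                raise ParseError("missing transcript_id attribute", path, lineno)
            rec = transcripts.setdefault(
                tid, {"gene_id": attrs.get("gene_id", tid), "chrom": chrom,
                      "strand": strand, "start": start, "end": end, "exons": []})
            if feature == "transcript":
                rec["start"], rec["end"] = start, end
            else:
                rec["exons"].append((start, end))
                rec["start"] = min(rec["start"], start)
                rec["end"] = max(rec["end"], end)

    out = []
    for tid, rec in transcripts.items():
        out.append(GeneAnnotation(
            gene_id=rec["gene_id"], transcript_id=tid, chrom=rec["chrom"],
            strand=rec["strand"], start=rec["start"], end=rec["end"],
            exons=rec["exons"] or [(rec["start"], rec["end"])]))
    return out


def read_gene_models(path) -> list[GeneAnnotation]:
    """Read transcript models from BED12 (native dialect) or GTF.

    The format is sniffed from the first data line.  Malformed lines raise
    :class:`ParseError` carrying the file name and line number.
    """
    path = Path(path)
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if line and not line.startswith(("#", "track", "browser")):
                first = line
                break
        else:
            return []
    n_fields = len(first.split("\t"))
    looks_gtf = n_fields >= 9 and not first.split("\t")[1].isdigit()
    if looks_gtf:
        return _read_gtf(path)

    genes: list[GeneAnnotation] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            try:
                genes.append(_parse_bed12_line(line.split("\t")))
            except (ValueError, IndexError) as exc:
                raise ParseError(str(exc), path, lineno) from exc
    return genes


def write_gene_models(genes: Iterable[GeneAnnotation], path) -> None:
    """Write transcript models in the BED12 dialect ``read_gene_models`` reads."""
    with open(path, "w") as handle:
        for g in genes:
            name = f"{g.gene_id}|{g.transcript_id}|{g.meta_status}"
            if g.is_PAR:
                name += "|PAR"
            thick = g.cpg_island if g.cpg_island else (g.start, g.start)
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offs = ",".join(str(s - g.start) for s, e in g.exons)
            handle.write("\t".join(map(str, [
                g.chrom, g.start, g.end, name, 0, g.strand,
                thick[0], thick[1], "0", len(g.exons), sizes, offs])) + "\n")


def promoter_regions(genes: Sequence[GeneAnnotation], width: int = 500) -> RegionSet:
    """Strand-aware promoter windows of ``width`` bases upstream of each TSS.

    On the + strand this is ``[tss - width, tss)``; on the − strand
    ``[tss + 1, tss + 1 + width)``.  Windows running off the chromosome
    start are clipped and flagged.  The promoter never overlaps positions
    downstream of the TSS.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    regions = []
    for g in genes:
        if g.strand == "+":
            start, end = g.tss - width, g.tss
        else:
            start, end = g.tss + 1, g.tss + 1 + width
        clipped = start < 0
        start = max(start, 0)
        regions.append(Region(g.chrom, start, end, g.strand, g.transcript_id, clipped))
    return RegionSet(name=f"promoters_{width}bp", kind="promoter", intervals=regions)


# ---------------------------------------------------------------------------
# Signal tracks
# ---------------------------------------------------------------------------

class SignalTrack:
    """Sparse interval signal (bedGraph semantics) with length-weighted queries."""

    def __init__(self, intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._by_chrom = intervals

    @property
    def chroms(self) -> list[str]:
        return list(self._by_chrom)

    def total_signal(self) -> float:
        """Sum of value x length over every covered base (all chromosomes)."""
        total = 0.0
        for starts, ends, values in self._by_chrom.values():
            total += float(np.sum((ends - starts) * values))
        return total

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean over ``[start, end)``; NaN when under-covered.

        Covered-base fraction below ``MISSING_COVERAGE_FRACTION`` returns NaN:
        uncovered positions are missing, never zero.
        """
        if end <= start:
            raise ValueError("empty query interval")
        if chrom not in self._by_chrom:
            return math.nan
        starts, ends, values = self._by_chrom[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if hi <= lo:
            return math.nan
        seg_start = np.maximum(starts[lo:hi], start)
        seg_end = np.minimum(ends[lo:hi], end)
        lengths = seg_end - seg_start
        covered = int(lengths.sum())
        if covered / (end - start) < MISSING_COVERAGE_FRACTION:
            return math.nan
        return float(np.sum(lengths * values[lo:hi]) / covered)

    def mean_over_regions(self, regions: Iterable[Region]) -> float:
        """Length-weighted mean across several regions (e.g. a transcript's exons)."""
        num = 0.0
        den = 0
        total_len = 0
        for r in regions:
            total_len += r.length
            m = self.mean_over(r.chrom, r.start, r.end)
            if not math.isnan(m):
                num += m * r.length
                den += r.length
        if total_len == 0 or den / total_len < MISSING_COVERAGE_FRACTION:
            return math.nan
        return num / den

    def scale(self, factor: float) -> "SignalTrack":
        return SignalTrack({c: (s, e, v * factor) for c, (s, e, v) in self._by_chrom.items()})


def read_signal(path) -> SignalTrack:
    """Read a bedGraph file (``chrom start end value``) into a SignalTrack.

    Intervals must be sorted and non-overlapping within each chromosome;
    NaN values are rejected.
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError("bedGraph line needs 4 fields", path, lineno)
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if end <= start:
                raise ParseError(f"end {end} <= start {start}", path, lineno)
            if math.isnan(value):
                raise ParseError("NaN signal value", path, lineno)
            rows = per_chrom.setdefault(chrom, [])
            if rows:
                if start < rows[-1][0]:
                    raise ParseError("unsorted bedGraph input", path, lineno)
                if start < rows[-1][1]:
                    raise ParseError("overlapping bedGraph intervals", path, lineno)
            rows.append((start, end, value))

    arrays = {}
    for chrom, rows in per_chrom.items():
        arr = np.asarray(rows, dtype=float)
        arrays[chrom] = (arr[:, 0].astype(int), arr[:, 1].astype(int), arr[:, 2])
    return SignalTrack(arrays)


def write_signal(track: SignalTrack, path) -> None:
    with open(path, "w") as handle:
        for chrom in track.chroms:
            starts, ends, values = track._by_chrom[chrom]
            for s, e, v in zip(starts, ends, values):
                handle.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

_GT_CODE = {"0/0": 0.0, "0|0": 0.0, "0/1": 1.0, "1/0": 1.0, "0|1": 1.0,
            "1|0": 1.0, "1/1": 2.0, "1|1": 2.0}


def read_genotypes(path) -> pd.DataFrame:
    """Read a sample x locus genotype dosage matrix ({0, 1, 2}, NaN = missing).

    Accepts a minimal VCF (``CHROM POS ID REF ALT QUAL FILTER INFO FORMAT``
    plus GT sample columns) or a wide TSV whose first column is
    ``sample_id`` and remaining columns are locus ids.  Triallelic loci are
    an error — the association machinery assumes biallelic sites.
    """
    path = Path(path)
    with open(path) as handle:
        first = handle.readline()
    if first.startswith("##") or first.startswith("#CHROM"):
        return _read_vcf(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ".", ""])
    return df.astype(float)


def _read_vcf(path) -> pd.DataFrame:
    samples: list[str] = []
    loci: list[str] = []
    rows: list[list[float]] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            chrom, pos, vid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if "," in alt:
                raise ParseError(f"triallelic locus {vid or chrom + ':' + pos}", path, lineno)
            locus = vid if vid not in (".", "") else f"{chrom}:{pos}"
            loci.append(locus)
            row = []
            for entry in fields[9:]:
                gt = entry.split(":")[0]
                row.append(_GT_CODE.get(gt, math.nan))
            rows.append(row)
    mat = pd.DataFrame(rows, index=loci, columns=samples).T
    mat.index.name = "sample_id"
    return mat.astype(float)


def write_vcf(genotypes: pd.DataFrame, path, ref: str = "A", alt: str = "G",
              loci_info: pd.DataFrame | None = None) -> None:
    """Write a sample x locus dosage matrix as minimal VCF.

    ``loci_info``, when given, is indexed by locus id with columns
    ``chrom``, ``pos``, ``ref``, ``alt``.
    """
    inv = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(genotypes.index) + "\n")
        for j, locus in enumerate(genotypes.columns):
            if loci_info is not None and locus in loci_info.index:
                info = loci_info.loc[locus]
                chrom, pos, r, a = info["chrom"], int(info["pos"]), info["ref"], info["alt"]
            else:
                chrom, pos, r, a = "chrU", j + 1, ref, alt
            gts = [inv.get(float(v), "./.") if not math.isnan(float(v)) else "./."
                   for v in genotypes[locus]]
            handle.write(f"{chrom}\t{pos}\t{locus}\t{r}\t{a}\t.\tPASS\t.\tGT\t"
                         + "\t".join(gts) + "\n")


def consensus_genotypes(matrices: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Per-locus consensus across repeated arrays for the same samples.

    All non-missing calls agree -> that value; any disagreement -> missing.
    """
    if not matrices:
        raise ValueError("no genotype matrices given")
    samples = sorted(set().union(*(m.index for m in matrices)))
    loci = sorted(set().union(*(m.columns for m in matrices)))
    stack = np.full((len(matrices), len(samples), len(loci)), np.nan)
    for k, m in enumerate(matrices):
        aligned = m.reindex(index=samples, columns=loci)
        stack[k] = aligned.to_numpy(dtype=float)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices are fine
        lo = np.nanmin(stack, axis=0)
        hi = np.nanmax(stack, axis=0)
    out = np.where(np.isnan(lo) | (lo != hi), np.nan, lo)
    return pd.DataFrame(out, index=pd.Index(samples, name="sample_id"), columns=loci)


# ---------------------------------------------------------------------------
# Sample sheets
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> list[SampleInfo]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "sex"}
    if not required.issubset(df.columns):
        raise ParseError(f"sample sheet needs columns {sorted(required)}", path)
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"duplicate sample_id {dup!r}", path)
    out = []
    for _, row in df.iterrows():
        skew = row.get("skewed_xi")
        skew_val = None if pd.isna(skew) or skew == "" else str(skew).lower() in ("1", "true", "yes")
        out.append(SampleInfo(
            sample_id=row["sample_id"], sex=row["sex"],
            tissue=str(row.get("tissue", "") or ""),
            dataset=str(row.get("dataset", "") or ""),
            skewed_xi=skew_val))
    return out


def write_sample_sheet(samples: Iterable[SampleInfo], path) -> None:
    with open(path, "w") as handle:
        handle.write("sample_id\tsex\ttissue\tdataset\tskewed_xi\n")
        for s in samples:
            skew = "" if s.skewed_xi is None else str(s.skewed_xi).lower()
            handle.write(f"{s.sample_id}\t{s.sex}\t{s.tissue}\t{s.dataset}\t{skew}\n")
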