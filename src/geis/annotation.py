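"""Exon-length statistics from GFF3 gene models.

Parses GENCODE-style GFF3/GTF annotation into per-transcript exon/CDS
models and computes the distribution of exon lengths, with UTRs included
(full exon) or excluded (overlap with the CDS).  The quantity of interest
for intronic-marker knock-in design is the fraction of coding exons longer
than a conversion-tract budget (default 600 nt): an exon no longer than
twice the reachable tract can always be edited from its nearer flanking
intron, so ``1 - fraction_exceeding`` is the fraction of editable targets.

All internal coordinates are 0-based half-open; GFF3's 1-based inclusive
coordinates are converted at the parsing boundary.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

MODE_UTR_INCLUDED = "utr_included"
MODE_UTR_EXCLUDED = "utr_excluded"
_MODES = (MODE_UTR_INCLUDED, MODE_UTR_EXCLUDED)


class GFF3ParseError(ValueError):
    """Raised for a malformed GFF3 record; the message names the line number."""


@dataclass
class TranscriptModel:
    """One transcript: ordered exon intervals plus CDS intervals.

    Intervals are 0-based half-open tuples ``(start, end)`` in ascending
    genomic order regardless of strand.  ``cds_intervals`` may be empty for
    non-coding transcripts.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_intervals: list[tuple[int, int]] = field(default_factory=list)

    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"transcript {self.transcript_id}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )
        prev_end = -1
        for start, end in self.exons:
            if end <= start:
                raise ValueError(
                    f"transcript {self.transcript_id}: empty exon [{start},{end})"
                )
            if start < prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end
        for cstart, cend in self.cds_intervals:
            hosts = [
                (s, e) for s, e in self.exons if s <= cstart and cend <= e
            ]
            if len(hosts) != 1:
                raise ValueError(
                    f"transcript {self.transcript_id}: CDS [{cstart},{cend}) is "
                    f"not contained in exactly one exon"
                )

    @property
    def total_cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)


@dataclass
class ExonRecord:
    """One exon of one transcript with UTR-included and coding lengths.

    ``exon_index`` and the first/last flags follow transcription order
    (strand-aware), not genomic order.
    """

    transcript_id: str
    exon_index: int
    length_full: int
    length_coding: int
    is_first: bool
    is_last: bool
    chrom: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"


@dataclass
class LengthDistribution:
    """Histogram of exon lengths; ``sum(counts) == n_total``."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_total: int
    mode: str

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValueError("bin_edges must be strictly increasing")
        if int(self.counts.sum()) != self.n_total:
            raise ValueError("histogram counts do not sum to n_total")


def _open_maybe_gzip(source):
    if hasattr(source, "read"):
        return source, False
    path = str(source)
    if path.endswith(".gz"):
        return gzip.open(path, "rt"), True
    return open(path, "rt"), True


def _iter_lines(source) -> Iterable[str]:
    if isinstance(source, str) and "\n" in source:
        yield from io.StringIO(source)
        return
    if isinstance(source, (list, tuple)):
        yield from source
        return
    handle, owned = _open_maybe_gzip(source)
    try:
        yield from handle
    finally:
        if owned:
            handle.close()


def parse_gff3(source, protein_coding_only: bool = True) -> list[TranscriptModel]:
    """Parse GFF3 (or GTF) exon/CDS rows into :class:`TranscriptModel` objects.

    Parameters
    ----------
    source:
        Path (plain or ``.gz``), open text handle, multi-line string, or an
        iterable of lines.
    protein_coding_only:
        When a ``transcript_type``/``transcript_biotype`` tag is present on a
        row, keep only ``protein_coding`` transcripts.  Rows without any such
        tag are always kept, so untagged toy annotations parse unfiltered.

    Returns
    -------
    list of TranscriptModel, one per transcript with at least one exon, in
    order of first appearance.  Features on unplaced contigs are retained.

    Raises
    ------
    GFF3ParseError
        For a malformed row (wrong column count, non-integer or inverted
        coordinates, missing strand); the message names the 1-based line
        number.  A CDS row whose transcript never appears with an exon is
        skipped with a logged warning, not an error.
    """
    models: dict[str, TranscriptModel] = {}
    orphan_cds: dict[str, int] = {}

    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GFF3ParseError(
                f"line {lineno}: expected 9 tab-separated columns, got {len(fields)}"
            )
        ftype = fields[2]
        if ftype not in ("exon", "CDS"):
            continue
        try:
            feat = feature_from_line(line)
        except Exception as exc:  # gffutils raises assorted exception types
            raise GFF3ParseError(f"line {lineno}: {exc}") from exc
        try:
            start1, end1 = int(fields[3]), int(fields[4])
        except ValueError as exc:
            raise GFF3ParseError(f"line {lineno}: non-integer coordinates") from exc
        if end1 < start1:
            raise GFF3ParseError(
                f"line {lineno}: end ({end1}) < start ({start1})"
            )
        strand = fields[6]
        if strand not in ("+", "-"):
            raise GFF3ParseError(
                f"line {lineno}: strand {strand!r} is not '+' or '-'; "
                f"first/last-exon assignment requires a stranded feature"
            )

        ttype = None
        for key in ("transcript_type", "transcript_biotype"):
            if key in feat.attributes:
                ttype = feat.attributes[key][0]
                break
        if protein_coding_only and ttype is not None and ttype != "protein_coding":
            continue

        tid = None
        if "transcript_id" in feat.attributes:
            tid = feat.attributes["transcript_id"][0]
        elif "Parent" in feat.attributes:
            tid = feat.attributes["Parent"][0].split(":")[-1]
        if tid is None:
            if ftype == "CDS":
                orphan_cds[f"line {lineno}"] = lineno
                continue
            raise GFF3ParseError(
                f"line {lineno}: exon row without transcript_id or Parent"
            )
        gid = feat.attributes["gene_id"][0] if "gene_id" in feat.attributes else tid

        interval = (start1 - 1, end1)  # to 0-based half-open
        if ftype == "exon":
            model = models.setdefault(
                tid, TranscriptModel(tid, gid, fields[0], strand)
            )
            model.exons.append(interval)
        else:
            if tid in models:
                models[tid].cds_intervals.append(interval)
            else:
                orphan_cds[tid] = lineno

    # CDS rows seen before their transcript's first exon row
    for tid, lineno in list(orphan_cds.items()):
        if tid in models:
            logger.warning(
                "CDS at line %d preceded its transcript's exons; dropped", lineno
            )
        else:
            logger.warning(
                "skipping CDS without a parent transcript (%s, line %d)", tid, lineno
            )

    result = []
    for model in models.values():
        model.exons.sort()
        model.cds_intervals.sort()
        model.validate()
        result.append(model)
    return result


def write_gff3(models: Sequence[TranscriptModel], handle) -> None:
    """Serialize transcript models back to minimal GFF3 exon/CDS rows."""
    handle.write("##gff-version 3\n")
    for m in models:
        for s, e in m.exons:
            handle.write(
                f"{m.chrom}\tgeis\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                f"gene_id={m.gene_id};transcript_id={m.transcript_id}\n"
            )
        for s, e in m.cds_intervals:
            handle.write(
                f"{m.chrom}\tgeis\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t0\t"
                f"gene_id={m.gene_id};transcript_id={m.transcript_id}\n"
            )


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def exon_records(
    models: Iterable[TranscriptModel], dedupe: bool = False
) -> list[ExonRecord]:
    """Flatten transcript models to per-(transcript, exon) records.

    ``length_coding`` is the summed overlap of the exon with its
    transcript's CDS intervals (0 for fully untranslated exons).  With
    ``dedupe=True``, exons sharing ``(chrom, start, end, strand)`` across
    transcripts are collapsed to a single record; the default counts each
    transcript's copy, matching a naive per-row scan of the annotation.
    """
    records: list[ExonRecord] = []
    seen: set[tuple[str, int, int, str]] = set()
    for m in models:
        n = len(m.exons)
        for genomic_i, (s, e) in enumerate(m.exons):
            rank = genomic_i + 1 if m.strand == "+" else n - genomic_i
            key = (m.chrom, s, e, m.strand)
            if dedupe:
                if key in seen:
                    continue
                seen.add(key)
            coding = sum(_overlap((s, e), c) for c in m.cds_intervals)
            records.append(
                ExonRecord(
                    transcript_id=m.transcript_id,
                    exon_index=rank,
                    length_full=e - s,
                    length_coding=coding,
                    is_first=rank == 1,
                    is_last=rank == n,
                    chrom=m.chrom,
                    start=s,
                    end=e,
                    strand=m.strand,
                )
            )
    return records


def _lengths(records: Sequence[ExonRecord], mode: str) -> np.ndarray:
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    if mode == MODE_UTR_EXCLUDED:
        vals = [r.length_coding for r in records if r.length_coding > 0]
    else:
        vals = [r.length_full for r in records]
    return np.asarray(vals, dtype=int)


def fraction_exceeding(
    records: Sequence[ExonRecord], threshold_nt: int, mode: str = MODE_UTR_EXCLUDED
) -> float:
    """Fraction of exons strictly longer than ``threshold_nt``.

    In ``utr_excluded`` mode the coding length is used and fully
    untranslated exons are excluded from the denominator.  An empty record
    set after filtering raises rather than silently returning 0.
    """
    lengths = _lengths(records, mode)
    if lengths.size == 0:
        raise ValueError(f"no exons with positive length in mode {mode!r}")
    return float(np.count_nonzero(lengths > threshold_nt) / lengths.size)


def length_distribution(
    records: Sequence[ExonRecord],
    mode: str = MODE_UTR_EXCLUDED,
    bin_width: int = 100,
) -> LengthDistribution:
    """Histogram of exon lengths with an unbounded final bin (nothing is dropped)."""
    lengths = _lengths(records, mode)
    if lengths.size == 0:
        raise ValueError(f"no exons with positive length in mode {mode!r}")
    upper = int(np.ceil(lengths.max() / bin_width)) * bin_width
    edges = np.append(np.arange(0, upper + bin_width, bin_width), np.inf)
    counts, _ = np.histogram(lengths, bins=edges)
    return LengthDistribution(edges, counts, int(lengths.size), mode)


@dataclass
class EditabilityReport:
    """Summary of how many exons fit under a conversion-tract budget."""

    n_exons_full: int
    n_exons_coding: int
    threshold_nt: int
    fraction_exceeding_full: float
    fraction_exceeding_coding: float
    fraction_editable: float
    n_long_coding: int
    n_long_coding_first_or_last: int
    n_long_full: int
    n_long_full_first_or_last: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def editability_report(
    models: Iterable[TranscriptModel],
    max_exon_nt: int = 600,
    dedupe: bool = False,
) -> EditabilityReport:
    """Fraction of exons editable from a flanking intron under a tract budget.

    An exon is editable when its coding length does not exceed
    ``max_exon_nt``: the nearer flanking intron then needs a conversion
    tract no longer than half that budget.  The report also counts how many
    of the over-budget exons are first or last exons, whose length is
    typically inflated by UTRs.
    """
    records = exon_records(models, dedupe=dedupe)
    if not records:
        raise ValueError("no exons in input models")
    frac_full = fraction_exceeding(records, max_exon_nt, MODE_UTR_INCLUDED)
    frac_coding = fraction_exceeding(records, max_exon_nt, MODE_UTR_EXCLUDED)
    long_coding = [
        r for r in records if r.length_coding > max_exon_nt
    ]
    long_full = [r for r in records if r.length_full > max_exon_nt]
    return EditabilityReport(
        n_exons_full=len(records),
        n_exons_coding=sum(1 for r in records if r.length_coding > 0),
        threshold_nt=max_exon_nt,
        fraction_exceeding_full=frac_full,
        fraction_exceeding_coding=frac_coding,
        fraction_editable=1.0 - frac_coding,
        n_long_coding=len(long_coding),
        n_long_coding_first_or_last=sum(
            1 for r in long_coding if r.is_first or r.is_last
        ),
        n_long_full=len(long_full),
        n_long_full_first_or_last=sum(
            1 for r in long_full if r.is_first or r.is_last
        ),
    )
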