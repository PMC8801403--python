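"""Per-amplicon incorporation calls for designed variants.

Each Sanger amplicon reports one repair event: the read is globally aligned
to the wild-type reference spanning the genotyping amplicon, and every
designed variant is called ``converted`` (the designed alternate allele is
present), ``unconverted`` (the reference allele is intact) or ``ambiguous``
(truncated read, non-designed change, or an alignment gap at the site).
The resulting reads x variants ternary matrix is the substrate for all
conversion-tract statistics.

Indel calls compare the read segment between aligned anchor columns against
the expected reference/alternate window, which makes them insensitive to
where the aligner happens to place an equivalent gap (e.g. in a
homopolymer).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .design import VariantSpec, reverse_complement

logger = logging.getLogger(__name__)

CONVERTED = 1
UNCONVERTED = 0
AMBIGUOUS = -1

_CALL_LABELS = {CONVERTED: "converted", UNCONVERTED: "unconverted", AMBIGUOUS: "ambiguous"}
_LABEL_CALLS = {v: k for k, v in _CALL_LABELS.items()}


@dataclass
class AmpliconRead:
    read_id: str
    sequence: str
    locus: str = ""

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence or set(self.sequence) - set("ACGTN"):
            raise ValueError(f"read {self.read_id}: sequence must be non-empty ACGTN")


@dataclass
class AlignScoring:
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0   # score of the first base of a gap
    gap_extend: float = -2.0  # score of each further base


@dataclass
class ReadAlignment:
    """Best-orientation global alignment of one read against the reference."""

    read_id: str
    strand: str                 # orientation kept: '+' as given, '-' revcomped
    score: float
    identity: float             # matches / aligned columns, end-gap runs excluded
    alignment: Align.Alignment
    oriented_sequence: str
    passed_qc: bool
    qc_reason: str = ""


def _make_aligner(scoring: AlignScoring) -> Align.PairwiseAligner:
    return Align.PairwiseAligner(
        mode="global",
        match_score=scoring.match,
        mismatch_score=scoring.mismatch,
        open_gap_score=scoring.gap_open,
        extend_gap_score=scoring.gap_extend,
    )


def _identity(alignment: Align.Alignment) -> float:
    """Fraction of identical columns over the aligned core.

    Terminal gap runs (a read shorter or longer than the reference at
    either end) are excluded from the denominator so truncated or padded
    reads are not penalized for span, only for internal disagreement.
    """
    idx = alignment.indices  # 2 x n_columns, -1 marks a gap
    n_cols = idx.shape[1]
    core_start, core_end = 0, n_cols
    while core_start < n_cols and (idx[:, core_start] < 0).any():
        core_start += 1
    while core_end > core_start and (idx[:, core_end - 1] < 0).any():
        core_end -= 1
    if core_end == core_start:
        return 0.0
    target, query = alignment.target, alignment.query
    matches = 0
    for col in range(core_start, core_end):
        ti, qi = idx[0, col], idx[1, col]
        if ti >= 0 and qi >= 0 and target[ti] == query[qi]:
            matches += 1
    return matches / (core_end - core_start)


def align_read(
    read: AmpliconRead | str,
    reference: str,
    scoring: AlignScoring | None = None,
    min_length: int = 50,
    min_identity: float = 0.9,
) -> ReadAlignment:
    """Globally align a read to the wild-type amplicon reference.

    Both the read and its reverse complement are aligned and the better
    score kept (Sanger reads arrive in either orientation).  Reads shorter
    than ``min_length`` or with core identity below ``min_identity`` are
    flagged failed-QC and should be excluded from calling.
    """
    if isinstance(read, str):
        read = AmpliconRead(read_id="read", sequence=read)
    scoring = scoring or AlignScoring()
    aligner = _make_aligner(scoring)
    reference = reference.upper()

    if len(read.sequence) < min_length:
        # still produce a forward alignment object for inspection
        aln = aligner.align(reference, read.sequence)[0]
        return ReadAlignment(
            read.read_id, "+", aln.score, _identity(aln), aln, read.sequence,
            passed_qc=False, qc_reason=f"read shorter than {min_length} nt",
        )

    best = None
    for strand, seq in (("+", read.sequence), ("-", reverse_complement(read.sequence))):
        aln = aligner.align(reference, seq)[0]
        if best is None or aln.score > best[1].score:
            best = (strand, aln, seq)
    strand, aln, seq = best
    ident = _identity(aln)
    ok = ident >= min_identity
    return ReadAlignment(
        read.read_id, strand, aln.score, ident, aln, seq,
        passed_qc=ok,
        qc_reason="" if ok else f"identity {ident:.3f} < {min_identity}",
    )


def _ref_to_read_map(alignment: Align.Alignment, ref_len: int) -> np.ndarray:
    """map[i] = read index aligned to reference position i, or -1 for a gap."""
    mapping = np.full(ref_len, -1, dtype=np.int64)
    for (ts, te), (qs, qe) in zip(*alignment.aligned):
        mapping[ts:te] = np.arange(qs, qe)
    return mapping


def call_variants(
    aln: ReadAlignment,
    variant_specs: Sequence[VariantSpec],
    reference: str,
    ref_offset: int = 0,
    indel_flank: int = 3,
) -> list[int]:
    """Ternary incorporation call for each designed variant.

    ``ref_offset`` is the locus coordinate of ``reference[0]``, translating
    each variant's ``locus_position`` onto the amplicon.  Substitutions are
    called base-for-base: converted iff the aligned read bases equal the
    alternate allele, unconverted iff they equal the reference, ambiguous
    otherwise (including any gap).  Indels are called by comparing the read
    segment between flanking aligned anchors to the expected
    reference/alternate window (``indel_flank`` nt each side).  A variant
    outside the read's aligned span — a truncated Sanger read — is
    ambiguous, never unconverted.
    """
    reference = reference.upper()
    read = aln.oriented_sequence
    mapping = _ref_to_read_map(aln.alignment, len(reference))
    calls: list[int] = []

    for v in variant_specs:
        r = v.locus_position - ref_offset
        m = len(v.ref_allele)
        if v.kind == "substitution":
            if r < 0 or r + m > len(reference):
                calls.append(AMBIGUOUS)
                continue
            idx = mapping[r : r + m]
            if (idx < 0).any():
                calls.append(AMBIGUOUS)
                continue
            # require contiguity: no inserted read bases inside the site
            if m > 1 and not (np.diff(idx) == 1).all():
                calls.append(AMBIGUOUS)
                continue
            observed = "".join(read[i] for i in idx)
            if observed == v.alt_allele:
                calls.append(CONVERTED)
            elif observed == v.ref_allele:
                calls.append(UNCONVERTED)
            else:
                calls.append(AMBIGUOUS)
            continue

        # indel: window comparison between aligned anchors
        wl = r - indel_flank
        wr = r + m + indel_flank
        if wl < 1 or wr > len(reference) - 1:
            calls.append(AMBIGUOUS)
            continue
        left_anchor = mapping[wl - 1]
        right_anchor = mapping[wr]
        if left_anchor < 0 or right_anchor < 0 or right_anchor <= left_anchor:
            calls.append(AMBIGUOUS)
            continue
        segment = read[left_anchor + 1 : right_anchor]
        expect_ref = reference[wl:wr]
        expect_alt = reference[wl:r] + v.alt_allele + reference[r + m : wr]
        if segment == expect_alt and expect_alt != expect_ref:
            calls.append(CONVERTED)
        elif segment == expect_ref:
            calls.append(UNCONVERTED)
        else:
            calls.append(AMBIGUOUS)
    return calls


@dataclass
class ReadCallMatrix:
    """Reads x designed-variants ternary call matrix.

    ``calls`` is an int8 DataFrame (rows: QC-passing reads, columns:
    variants ordered by tract distance ascending) with values
    ``CONVERTED``/``UNCONVERTED``/``AMBIGUOUS``.
    """

    calls: pd.DataFrame
    tract_distances: pd.Series          # per variant_id, nt
    identities: pd.Series               # per read_id
    qc: dict = field(default_factory=dict)

    @property
    def read_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.calls.columns)

    def to_tsv(self, path) -> None:
        labelled = self.calls.apply(lambda col: col.map(_CALL_LABELS))
        labelled.insert(0, "identity", self.identities)
        labelled.to_csv(path, sep="\t", index_label="read_id")

    @classmethod
    def from_tsv(cls, path, tract_distances: dict[str, int] | pd.Series) -> "ReadCallMatrix":
        df = pd.read_csv(path, sep="\t", index_col="read_id")
        identities = df.pop("identity")
        calls = df.apply(lambda col: col.map(_LABEL_CALLS)).astype(np.int8)
        dist = pd.Series(tract_distances).reindex(calls.columns)
        return cls(calls=calls, tract_distances=dist, identities=identities)


def build_matrix(
    reads: Sequence[AmpliconRead],
    reference: str,
    variant_specs: Sequence[VariantSpec],
    ref_offset: int = 0,
    min_identity: float = 0.9,
    min_length: int = 50,
    scoring: AlignScoring | None = None,
) -> ReadCallMatrix:
    """Align every read and call every designed variant.

    Variants are ordered by ascending tract distance in the output.  Reads
    failing QC (too short, or identity below threshold in both
    orientations) are dropped; the QC tally is recorded in ``matrix.qc``.
    Zero passing reads is an error.
    """
    if not reads:
        raise ValueError("no reads supplied")
    specs = sorted(variant_specs, key=lambda v: v.tract_distance)
    if any(v.tract_distance < 0 for v in specs):
        raise ValueError(
            "variant specs lack tract distances; assemble the donor first "
            "or set tract_distance explicitly"
        )
    rows, ids, idents = [], [], []
    n_failed = 0
    for read in reads:
        aln = align_read(read, reference, scoring=scoring,
                         min_length=min_length, min_identity=min_identity)
        if not aln.passed_qc:
            n_failed += 1
            logger.debug("read %s failed QC: %s", read.read_id, aln.qc_reason)
            continue
        rows.append(call_variants(aln, specs, reference, ref_offset=ref_offset))
        ids.append(read.read_id)
        idents.append(aln.identity)
    qc = {"n_input": len(reads), "n_passed": len(ids), "n_failed": n_failed}
    logger.info("amplicon QC: %s", qc)
    if not ids:
        raise ValueError(f"all {len(reads)} reads failed QC (min_identity={min_identity})")
    calls = pd.DataFrame(
        np.asarray(rows, dtype=np.int8),
        index=pd.Index(ids, name="read_id"),
        columns=[v.variant_id for v in specs],
    )
    distances = pd.Series({v.variant_id: v.tract_distance for v in specs})
    return ReadCallMatrix(
        calls=calls,
        tract_distances=distances.reindex(calls.columns),
        identities=pd.Series(idents, index=calls.index),
        qc=qc,
    )
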