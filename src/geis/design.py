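"""Intronic sgRNA placement and knock-in donor assembly.

The strategy places the Cas9 cut (and the selection cassette) inside an
intron so the cassette never interrupts coding sequence, and reaches the
exonic edit through the gene-conversion tract.  Guides must therefore keep
clear of the splice signals: the GT donor dinucleotide at the 5' end of the
intron, and the branch point / polypyrimidine tract / AG acceptor at its 3'
end.  Both exclusion windows are configurable via
:class:`SpliceSafetyPolicy`.

Coordinates are 0-based throughout; a cut position is the boundary index
between two bases.  Intron and exon indices are 0-based in segment order.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

POLYA_MOTIFS = ("AATAAA", "ATTAAA")

PROTOSPACER_LEN = 20
PAM_LEN = 3
# SpCas9 blunt cut: 3 nt 5' of the PAM, between protospacer positions 17|18.
CUT_OFFSET_FROM_PAM = 3


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Segment:
    kind: str  # "exon" or "intron"
    start: int
    end: int

    def __post_init__(self):
        if self.kind not in ("exon", "intron"):
            raise ValueError(f"segment kind must be exon or intron, got {self.kind!r}")
        if self.end <= self.start:
            raise ValueError(f"empty segment [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class LocusSequence:
    """A locus sequence tiled by alternating exon/intron segments.

    Introns are expected to carry canonical GT...AG boundaries; pass
    ``non_canonical_ok=True`` to represent a locus that deliberately does
    not (the invariant is then not enforced).
    """

    name: str
    sequence: str
    segments: list[Segment]
    non_canonical_ok: bool = False

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if re.search("[^ACGTN]", self.sequence):
            raise ValueError("locus sequence must be over ACGTN")
        pos = 0
        prev_kind = None
        for seg in self.segments:
            if seg.start != pos:
                raise ValueError("segments must tile the sequence without gaps")
            if seg.kind == prev_kind:
                raise ValueError("segments must alternate exon/intron")
            pos = seg.end
            prev_kind = seg.kind
        if pos != len(self.sequence):
            raise ValueError("segments do not cover the full sequence")
        if not self.non_canonical_ok:
            for seg in self.segments:
                if seg.kind != "intron":
                    continue
                s = self.sequence[seg.start : seg.end]
                if not (s.startswith("GT") and s.endswith("AG")):
                    raise ValueError(
                        f"intron [{seg.start},{seg.end}) lacks canonical GT...AG "
                        f"boundaries (flag non_canonical_ok to allow)"
                    )

    @property
    def introns(self) -> list[Segment]:
        return [s for s in self.segments if s.kind == "intron"]

    @property
    def exons(self) -> list[Segment]:
        return [s for s in self.segments if s.kind == "exon"]

    def segment_at(self, position: int) -> tuple[int, Segment]:
        for i, seg in enumerate(self.segments):
            if seg.start <= position < seg.end:
                return i, seg
        raise ValueError(f"position {position} outside locus [0,{len(self.sequence)})")


@dataclass
class SpliceSafetyPolicy:
    """Exclusion zones around splice signals, in nt.

    ``donor_window_nt`` masks the start of each intron (GT plus nearby
    donor-site context); ``acceptor_window_nt`` masks its end (branch
    point, polypyrimidine tract and AG).  Both must be at least 2 so the
    boundary dinucleotides themselves are always protected.
    """

    donor_window_nt: int = 20
    acceptor_window_nt: int = 50

    def __post_init__(self):
        if self.donor_window_nt < 2 or self.acceptor_window_nt < 2:
            raise ValueError("safety windows must be >= 2 nt to cover GT/AG")


@dataclass
class GuideCandidate:
    """A 20-mer + NGG site whose blunt cut falls in the safe intron core."""

    protospacer: str
    pam: str
    strand: str
    cut_position: int
    intron_index: int
    distances_to_boundaries: tuple[int, int]  # (to donor GT, to acceptor AG)


def _admissible(cut: int, intron: Segment, policy: SpliceSafetyPolicy) -> bool:
    return (
        intron.start + policy.donor_window_nt < cut < intron.end - policy.acceptor_window_nt
    )


def enumerate_guides(
    locus: LocusSequence,
    intron_index: int,
    policy: SpliceSafetyPolicy | None = None,
    target_position: Optional[int] = None,
) -> list[GuideCandidate]:
    """All SpCas9 sites on either strand cutting safely inside one intron.

    A site is a 20-nt protospacer followed by an NGG PAM; the blunt cut is
    3 nt 5' of the PAM.  Only the cut position is constrained to the intron
    core (intron minus both safety windows) — the protospacer itself may
    overhang.  Sites containing N anywhere in protospacer or PAM are never
    admissible.  Candidates are sorted by distance of the cut to
    ``target_position`` (ascending; default: the intron midpoint).

    An intron too short to host any safe cut yields an empty list with a
    warning, not an exception.
    """
    policy = policy or SpliceSafetyPolicy()
    introns = locus.introns
    if not 0 <= intron_index < len(introns):
        raise IndexError(f"intron_index {intron_index} out of range")
    intron = introns[intron_index]
    seq = locus.sequence
    n = len(seq)
    candidates: list[GuideCandidate] = []

    site_len = PROTOSPACER_LEN + PAM_LEN
    for i in range(0, n - site_len + 1):
        window = seq[i : i + site_len]
        if "N" in window:
            continue
        # forward: protospacer [i, i+20), PAM [i+20, i+23) = NGG
        if window[21] == "G" and window[22] == "G":
            cut = i + PROTOSPACER_LEN - CUT_OFFSET_FROM_PAM
            if _admissible(cut, intron, policy):
                candidates.append(
                    GuideCandidate(
                        protospacer=window[:20],
                        pam=window[20:],
                        strand="+",
                        cut_position=cut,
                        intron_index=intron_index,
                        distances_to_boundaries=(cut - intron.start, intron.end - cut),
                    )
                )
        # reverse: PAM CCN at [i, i+3), protospacer [i+3, i+23)
        if window[0] == "C" and window[1] == "C":
            cut = i + PAM_LEN + CUT_OFFSET_FROM_PAM
            if _admissible(cut, intron, policy):
                candidates.append(
                    GuideCandidate(
                        protospacer=reverse_complement(window[3:]),
                        pam=reverse_complement(window[:3]),
                        strand="-",
                        cut_position=cut,
                        intron_index=intron_index,
                        distances_to_boundaries=(cut - intron.start, intron.end - cut),
                    )
                )

    if not candidates:
        warnings.warn(
            f"intron {intron_index} ([{intron.start},{intron.end})) has no "
            f"admissible cut site under windows "
            f"{policy.donor_window_nt}/{policy.acceptor_window_nt}",
            stacklevel=2,
        )
        return []

    anchor = target_position if target_position is not None else (intron.start + intron.end) // 2
    candidates.sort(key=lambda g: (abs(g.cut_position - anchor), g.cut_position, g.strand))
    return candidates


@dataclass(frozen=True)
class NearestIntron:
    intron_index: int
    side: str  # "left" or "right"
    tract_budget_nt: int


def nearest_intron(locus: LocusSequence, target_position: int) -> NearestIntron:
    """The flanking intron minimizing the conversion tract to an exonic target.

    The tract budget is the distance from the target to the chosen exon
    boundary.  For an internal exon the budget never exceeds half the exon
    length (ties at the exact midpoint break toward the left, 5'-in-genome,
    intron).  A target inside an intron is an error: the cut can be placed
    in that intron directly, no conversion tract is needed.
    """
    seg_i, seg = locus.segment_at(target_position)
    if seg.kind == "intron":
        raise ValueError(
            f"position {target_position} lies in an intron; place the cut "
            f"in that intron directly instead of converting across an exon"
        )
    dist_left = target_position - seg.start
    dist_right = seg.end - target_position
    has_left = seg_i > 0
    has_right = seg_i < len(locus.segments) - 1
    if not has_left and not has_right:
        raise ValueError("single-exon locus has no flanking intron")
    introns = locus.introns
    left_intron_index = sum(1 for s in locus.segments[:seg_i] if s.kind == "intron") - 1

    if has_left and (not has_right or dist_left <= dist_right):
        return NearestIntron(left_intron_index, "left", dist_left)
    return NearestIntron(left_intron_index + 1 if has_left else 0, "right", dist_right)


@dataclass
class VariantSpec:
    """A designed edit in locus coordinates.

    kind: substitution (len(ref) == len(alt) > 0), insertion (empty ref,
    alt inserted before ``locus_position``) or deletion (empty alt).
    ``tract_distance`` is the nt from the cut to the variant's nearest
    edited base (filled in by :func:`assemble_donor`); the base immediately
    flanking the cut is at distance 1, an insertion exactly at the cut at
    distance 0.
    """

    locus_position: int
    ref_allele: str
    alt_allele: str
    variant_id: str = ""
    tract_distance: int = -1

    def __post_init__(self):
        self.ref_allele = self.ref_allele.upper()
        self.alt_allele = self.alt_allele.upper()
        if not self.ref_allele and not self.alt_allele:
            raise ValueError("variant with empty ref and alt")
        if not self.variant_id:
            self.variant_id = f"{self.kind[:3]}_{self.locus_position}"

    @property
    def kind(self) -> str:
        if not self.ref_allele:
            return "insertion"
        if not self.alt_allele:
            return "deletion"
        return "substitution"


def tract_distance(cut_position: int, variant: VariantSpec) -> int:
    """Distance (nt) from the blunt cut to the variant's nearest edited base."""
    p = variant.locus_position
    if variant.kind == "insertion":
        return abs(p - cut_position)
    span_end = p + len(variant.ref_allele)  # edited bases [p, span_end)
    if span_end <= cut_position:
        return cut_position - span_end + 1
    if p >= cut_position:
        return p - cut_position + 1
    return 0  # variant straddles the cut


def scan_terminators(seq: str, motifs: Sequence[str] = POLYA_MOTIFS) -> list[tuple[str, int]]:
    """Positions of polyadenylation-signal motifs on the given (sense) strand.

    Overlapping occurrences are reported.  A donor carrying a poly(A)
    signal upstream of the cassette risks truncating the marker transcript,
    hence the scan.
    """
    seq = seq.upper()
    hits = []
    for motif in motifs:
        for m in re.finditer(f"(?={re.escape(motif)})", seq):
            hits.append((motif, m.start()))
    hits.sort(key=lambda h: (h[1], h[0]))
    return hits


@dataclass
class DonorSafety:
    ha_ok: bool
    min_ha_nt: int
    terminator_hits: list[tuple[str, int]]


@dataclass
class DonorDesign:
    """A knock-in donor: left HA + cassette + right HA with designed variants."""

    left_ha: str
    right_ha: str
    cassette: str
    variants: list[VariantSpec]
    ha_length_nt: int
    cut_position: int
    safety: DonorSafety

    @property
    def donor_sequence(self) -> str:
        return self.left_ha + self.cassette + self.right_ha


MIN_RECOMBINOGENIC_HA_NT = 500  # arms shorter than this recombine poorly


def assemble_donor(
    locus: LocusSequence,
    cut_position: int,
    ha_length: int,
    cassette: str,
    variants: Sequence[VariantSpec] = (),
) -> DonorDesign:
    """Copy homology arms from the locus around an intronic cut and apply variants.

    The cassette is inserted exactly at the cut.  Every variant must have a
    reference allele matching the locus and fall entirely within one arm.
    ``safety.ha_ok`` records whether the arms reach the empirically
    recombinogenic length (>= 500 nt); ``safety.terminator_hits`` lists
    poly(A)-signal motifs over the whole donor in sense orientation.
    """
    if ha_length < 1:
        raise ValueError("ha_length must be >= 1")
    seg_i, seg = locus.segment_at(cut_position)
    if seg.kind != "intron":
        raise ValueError(f"cut position {cut_position} is not inside an intron")
    left_start = cut_position - ha_length
    right_end = cut_position + ha_length
    if left_start < 0 or right_end > len(locus.sequence):
        raise ValueError("homology arms extend beyond the locus sequence")

    cassette = cassette.upper()
    seq = locus.sequence
    resolved: list[VariantSpec] = []
    left_variants: list[VariantSpec] = []
    right_variants: list[VariantSpec] = []
    for v in variants:
        p, ref = v.locus_position, v.ref_allele
        if seq[p : p + len(ref)] != ref:
            raise ValueError(
                f"variant {v.variant_id}: ref allele {ref!r} does not match locus "
                f"at position {p} (found {seq[p:p + len(ref)]!r})"
            )
        edit_end = p + len(ref)
        in_left = left_start <= p and edit_end <= cut_position
        in_right = cut_position <= p and edit_end <= right_end
        if not (in_left or in_right):
            raise ValueError(
                f"variant {v.variant_id} at {p} lies outside the homology arms "
                f"[{left_start},{cut_position}) / [{cut_position},{right_end})"
            )
        rv = VariantSpec(
            locus_position=p,
            ref_allele=ref,
            alt_allele=v.alt_allele,
            variant_id=v.variant_id,
            tract_distance=tract_distance(cut_position, v),
        )
        resolved.append(rv)
        (left_variants if in_left else right_variants).append(rv)

    left = apply_variants(seq[left_start:cut_position], left_variants, offset=left_start)
    right = apply_variants(seq[cut_position:right_end], right_variants, offset=cut_position)

    donor_seq = left + cassette + right
    safety = DonorSafety(
        ha_ok=ha_length >= MIN_RECOMBINOGENIC_HA_NT,
        min_ha_nt=MIN_RECOMBINOGENIC_HA_NT,
        terminator_hits=scan_terminators(donor_seq),
    )
    return DonorDesign(
        left_ha=left,
        right_ha=right,
        cassette=cassette,
        variants=sorted(resolved, key=lambda v: v.tract_distance),
        ha_length_nt=ha_length,
        cut_position=cut_position,
        safety=safety,
    )


def load_variants_tsv(path) -> list[VariantSpec]:
    """Read a VCF-like TSV of designed variants.

    Columns: ``variant_id`` (optional), ``position`` (0-based locus
    coordinate), ``ref``, ``alt`` ('.' or empty for a null allele), and
    optionally ``tract_distance``.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    variants = []
    for _, row in df.iterrows():
        ref = "" if row["ref"] in (".", "") else row["ref"]
        alt = "" if row["alt"] in (".", "") else row["alt"]
        variants.append(
            VariantSpec(
                locus_position=int(row["position"]),
                ref_allele=ref,
                alt_allele=alt,
                variant_id=row.get("variant_id", "") or "",
                tract_distance=int(row["tract_distance"])
                if "tract_distance" in df.columns and row["tract_distance"] != ""
                else -1,
            )
        )
    return variants


def write_variants_tsv(variants: Sequence[VariantSpec], path) -> None:
    with open(path, "w") as fh:
        fh.write("variant_id\tposition\tref\talt\ttract_distance\n")
        for v in variants:
            fh.write(
                f"{v.variant_id}\t{v.locus_position}\t{v.ref_allele or '.'}\t"
                f"{v.alt_allele or '.'}\t{v.tract_distance}\n"
            )


def locus_from_fasta_bed(fasta_path, bed_path, non_canonical_ok: bool = False) -> LocusSequence:
    """Build a :class:`LocusSequence` from a FASTA record and a BED of segments.

    The BED's name column must be ``exon`` or ``intron``; intervals are in
    locus coordinates and must tile the sequence.
    """
    from Bio import SeqIO

    record = next(SeqIO.parse(str(fasta_path), "fasta"))
    segments = []
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            segments.append(Segment(fields[3], int(fields[1]), int(fields[2])))
    segments.sort(key=lambda s: s.start)
    return LocusSequence(
        name=record.id,
        sequence=str(record.seq),
        segments=segments,
        non_canonical_ok=non_canonical_ok,
    )


def apply_variants(segment: str, variants: Sequence[VariantSpec], offset: int) -> str:
    """Apply variants to ``segment`` (which starts at locus coordinate
    ``offset``), right-to-left so earlier positions stay valid.  Variants
    must fall entirely within the segment."""
    hi = offset + len(segment)
    out = segment
    for v in sorted(variants, key=lambda v: v.locus_position, reverse=True):
        if not (offset <= v.locus_position and v.locus_position + len(v.ref_allele) <= hi):
            raise ValueError(f"variant {v.variant_id} outside segment [{offset},{hi})")
        i = v.locus_position - offset
        out = out[:i] + v.alt_allele + out[i + len(v.ref_allele):]
    return out
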