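"""Seeded simulators for loci, donors, amplicon reads and clone tables.

The generator emulates the structure of an intronic-marker knock-in
experiment end to end: a gene locus with canonical splice signals, a donor
whose left homology arm carries designed variants at fixed distances from
the cut, per-molecule conversion tracts drawn from a geometric
distribution, Sanger-scale amplicon reads with iid substitution errors,
and Bernoulli clone-genotype tables for recombination-rate reporting.

Every function is deterministic under ``SimConfig.seed``.  The default
variant distances (45, 90, 171, 386, 490, 596, 696 nt) mirror a
seven-variant left-arm design; the default continuation probability
p = 0.9989 gives a survival of ~65% at ~400 nt, matching the conversion
efficiency observed at that distance in the locus this layout emulates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .amplicon_analysis import AmpliconRead, ReadCallMatrix
from .design import (
    DonorDesign,
    LocusSequence,
    Segment,
    SpliceSafetyPolicy,
    VariantSpec,
    apply_variants,
    assemble_donor,
    enumerate_guides,
    reverse_complement,
)

_BASES = np.array(list("ACGT"))
DEFAULT_DISTANCES = (45, 90, 171, 386, 490, 596, 696)


@dataclass
class SimConfig:
    """Study conditions for the simulated knock-in experiment.

    The read-level defaults correspond to one sequenced amplicon library
    (624 molecules, seven left-arm variants) with Sanger-like substitution
    error; the clone-level defaults correspond to genotyping 24 clones per
    donor type with the observed true-positive probabilities for
    single-stranded (0.875) versus double-stranded (0.417) donors.
    """

    seed: int = 0
    exon_lengths: tuple[int, ...] = (400, 600, 400)
    intron_lengths: tuple[int, ...] = (900, 900)
    cut_intron_index: int = 1
    ha_length: int = 800
    cassette: str = ""  # default: a 60-nt placeholder cassette is generated
    variant_distances: tuple[int, ...] = DEFAULT_DISTANCES
    variant_kinds: tuple[str, ...] = ("substitution",)  # cycled over variants
    tract_family: str = "geometric"
    tract_p: float = 0.9989
    n_reads: int = 624
    error_rate: float = 0.001
    indel_error_rate: float = 0.0
    non_hdr_fraction: float = 0.0
    reverse_fraction: float = 0.5
    upstream_pad: int = 30
    clone_true_positive: dict = field(
        default_factory=lambda: {"ssDNA": 0.875, "dsDNA": 0.417}
    )
    n_clones: int = 24

    def __post_init__(self):
        if self.tract_family != "geometric":
            raise ValueError(f"unknown tract family {self.tract_family!r}")
        if not 0.0 < self.tract_p < 1.0:
            raise ValueError("tract_p must be in (0, 1)")
        for name in ("error_rate", "indel_error_rate", "non_hdr_fraction",
                     "reverse_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        d = self.variant_distances
        if any(x <= 0 for x in d) or any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("variant distances must be positive and strictly increasing")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _random_intron(rng: np.random.Generator, n: int) -> str:
    """Canonical intron: GT ... branch-point A ... polypyrimidine ... AG."""
    if n < 80:
        raise ValueError(f"intron length {n} < 80 nt minimum")
    body = list(_random_bases(rng, n))
    body[0:2] = "GT"
    body[-2:] = "AG"
    for i in range(n - 12, n - 2):  # >= 10 nt polypyrimidine tract before AG
        body[i] = rng.choice(["C", "T"])
    bp_offset = int(rng.integers(20, 41))  # branch point 20-40 nt upstream of AG
    body[n - bp_offset] = "A"
    return "".join(body)


def make_locus(config: SimConfig, rng: Optional[np.random.Generator] = None) -> LocusSequence:
    """Random locus with alternating exons and canonical GT...AG introns."""
    if len(config.intron_lengths) != len(config.exon_lengths) - 1:
        raise ValueError("need one fewer intron than exons")
    rng = rng or config.rng()
    parts: list[str] = []
    segments: list[Segment] = []
    pos = 0
    for i, elen in enumerate(config.exon_lengths):
        if elen < 1:
            raise ValueError("exon lengths must be positive")
        parts.append(_random_bases(rng, elen))
        segments.append(Segment("exon", pos, pos + elen))
        pos += elen
        if i < len(config.intron_lengths):
            ilen = config.intron_lengths[i]
            parts.append(_random_intron(rng, ilen))
            segments.append(Segment("intron", pos, pos + ilen))
            pos += ilen
    return LocusSequence(name=f"sim_locus_seed{config.seed}", sequence="".join(parts),
                         segments=segments)


def pick_cut_site(
    locus: LocusSequence,
    intron_index: int,
    policy: SpliceSafetyPolicy | None = None,
) -> int:
    """Cut position of the guide nearest the intron midpoint (midpoint itself
    if the random intron happens to contain no PAM site)."""
    guides = enumerate_guides(locus, intron_index, policy=policy)
    if guides:
        return guides[0].cut_position
    intron = locus.introns[intron_index]
    return (intron.start + intron.end) // 2


def _designed_variants(
    config: SimConfig, locus: LocusSequence, cut: int, rng: np.random.Generator
) -> list[VariantSpec]:
    """Left-arm variants at the configured tract distances, kinds cycled."""
    variants = []
    for i, d in enumerate(config.variant_distances):
        kind = config.variant_kinds[i % len(config.variant_kinds)]
        if kind == "substitution":
            q = cut - d
            ref = locus.sequence[q]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            v = VariantSpec(q, ref, alt, variant_id=f"d{d}")
        elif kind == "insertion":
            p = cut - d
            alt = _random_bases(rng, 3)
            v = VariantSpec(p, "", alt, variant_id=f"d{d}")
        elif kind == "deletion":
            q = cut - d
            v = VariantSpec(q, locus.sequence[q], "", variant_id=f"d{d}")
        else:
            raise ValueError(f"unknown variant kind {kind!r}")
        variants.append(v)
    return variants


@dataclass
class SimScenario:
    """A fully assembled simulated experiment: locus, cut, donor, reference."""

    config: SimConfig
    locus: LocusSequence
    cut_position: int
    donor: DonorDesign
    reference: str      # wild-type amplicon spanned by the genotyping PCR
    ref_offset: int     # locus coordinate of reference[0]


def build_scenario(config: SimConfig) -> SimScenario:
    """Locus + guide + donor under one seed; the substrate for read simulation."""
    rng = config.rng()
    locus = make_locus(config, rng)
    cut = pick_cut_site(locus, config.cut_intron_index)
    variants = _designed_variants(config, locus, cut, rng)
    cassette = config.cassette or _random_bases(rng, 60)
    donor = assemble_donor(locus, cut, config.ha_length, cassette, variants)
    ref_start = max(0, cut - config.ha_length - config.upstream_pad)
    return SimScenario(
        config=config,
        locus=locus,
        cut_position=cut,
        donor=donor,
        reference=locus.sequence[ref_start:cut],
        ref_offset=ref_start,
    )


@dataclass
class GroundTruth:
    """Per-read truth: HDR status, drawn tract length, incorporation vector."""

    table: pd.DataFrame  # index read_id; columns: hdr, tract_length, <variant ids>
    variant_ids: list[str]

    def incorporation(self) -> pd.DataFrame:
        return self.table[self.variant_ids]


def _draw_tract_lengths(rng: np.random.Generator, p: float, n: int) -> np.ndarray:
    """L with P(L >= d) = p**d for integer d (geometric number of extensions)."""
    return rng.geometric(1.0 - p, size=n) - 1


def _apply_errors(seq: str, rng: np.random.Generator, sub_rate: float,
                  indel_rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    if sub_rate > 0:
        mask = rng.random(arr.size) < sub_rate
        for i in np.nonzero(mask)[0]:
            arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
    out = "".join(arr)
    if indel_rate > 0:
        chars = list(out)
        i = 0
        while i < len(chars):
            r = rng.random()
            if r < indel_rate / 2:
                chars.insert(i, str(rng.choice(_BASES)))
                i += 2
            elif r < indel_rate:
                del chars[i]
            else:
                i += 1
        out = "".join(chars)
    return out


def simulate_reads(
    config: SimConfig,
    scenario: SimScenario | None = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[AmpliconRead], GroundTruth, SimScenario]:
    """Amplicon reads under the per-molecule conversion-tract model.

    Each HDR molecule draws a tract length L from the configured geometric
    family and incorporates exactly the designed variants with distance
    <= L (nested incorporation); a ``non_hdr_fraction`` of molecules stays
    wild type.  Substitution (and optionally indel) sequencing errors are
    applied afterwards, and each read is emitted in a random orientation.
    """
    scenario = scenario or build_scenario(config)
    rng = rng or np.random.default_rng(config.seed + 1)  # independent of locus draw
    variants = scenario.donor.variants
    distances = np.array([v.tract_distance for v in variants], dtype=float)
    ids = [v.variant_id for v in variants]

    n = config.n_reads
    lengths = _draw_tract_lengths(rng, config.tract_p, n)
    is_hdr = rng.random(n) >= config.non_hdr_fraction
    reverse = rng.random(n) < config.reverse_fraction

    reads: list[AmpliconRead] = []
    rows = []
    for i in range(n):
        rid = f"amplicon_{i:05d}"
        if is_hdr[i]:
            conv = distances <= lengths[i]
            incorporated = [v for v, c in zip(variants, conv) if c]
            seq = apply_variants(scenario.reference, incorporated,
                                 offset=scenario.ref_offset)
        else:
            conv = np.zeros(len(variants), dtype=bool)
            seq = scenario.reference
        seq = _apply_errors(seq, rng, config.error_rate, config.indel_error_rate)
        if reverse[i]:
            seq = reverse_complement(seq)
        reads.append(AmpliconRead(rid, seq, locus=scenario.locus.name))
        rows.append([bool(is_hdr[i]), int(lengths[i]) if is_hdr[i] else -1,
                     *conv.tolist()])

    table = pd.DataFrame(
        rows,
        index=pd.Index([r.read_id for r in reads], name="read_id"),
        columns=["hdr", "tract_length", *ids],
    )
    return reads, GroundTruth(table=table, variant_ids=ids), scenario


def simulate_call_matrix(
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    ambiguous_rate: float = 0.0,
) -> tuple[ReadCallMatrix, GroundTruth]:
    """Direct matrix-level simulation (no sequences, no alignment).

    Draws per-read tract lengths and emits the resulting ternary call
    matrix, optionally censoring a random fraction of cells as ambiguous.
    Useful for statistical experiments at read counts where simulating and
    re-aligning full sequences adds nothing.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    distances = np.array(config.variant_distances, dtype=float)
    ids = [f"d{int(d)}" for d in config.variant_distances]
    n = config.n_reads
    lengths = _draw_tract_lengths(rng, config.tract_p, n)
    is_hdr = rng.random(n) >= config.non_hdr_fraction
    conv = (distances[None, :] <= lengths[:, None]) & is_hdr[:, None]
    calls = conv.astype(np.int8)
    if ambiguous_rate > 0:
        mask = rng.random(calls.shape) < ambiguous_rate
        calls[mask] = -1
    index = pd.Index([f"amplicon_{i:05d}" for i in range(n)], name="read_id")
    calls_df = pd.DataFrame(calls, index=index, columns=ids)
    truth = pd.DataFrame(
        np.column_stack([is_hdr, np.where(is_hdr, lengths, -1)]),
        index=index, columns=["hdr", "tract_length"],
    ).astype({"hdr": bool, "tract_length": int})
    truth = pd.concat([truth, pd.DataFrame(conv, index=index, columns=ids)], axis=1)
    matrix = ReadCallMatrix(
        calls=calls_df,
        tract_distances=pd.Series(dict(zip(ids, distances))),
        identities=pd.Series(1.0, index=index),
        qc={"n_input": n, "n_passed": n, "n_failed": 0, "synthetic": True},
    )
    return matrix, GroundTruth(table=truth, variant_ids=ids)


def simulate_clone_experiment(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Bernoulli clone-genotype table, one row per clone per donor type."""
    if config.n_clones <= 0:
        raise ValueError("n_clones must be positive")
    rng = rng or np.random.default_rng(config.seed + 2)
    rows = []
    for donor_type, prob in config.clone_true_positive.items():
        if not 0.0 <= prob <= 1.0:
            raise ValueError(f"true-positive probability for {donor_type} not in [0,1]")
        positives = rng.random(config.n_clones) < prob
        for i, pos in enumerate(positives):
            rows.append((f"{donor_type}_clone_{i:02d}", donor_type, bool(pos)))
    return pd.DataFrame(rows, columns=["clone_id", "donor_type", "positive"])


def write_outputs(config: SimConfig, out_dir) -> SimScenario:
    """Run the full simulation under one seed and write plain-text outputs.

    Writes locus/donor/reads FASTA, the ground-truth table and clone table
    as TSV, and a JSON echo of the configuration.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reads, truth, scenario = simulate_reads(config)

    def write_fasta(path: Path, records: Sequence[tuple[str, str]]) -> None:
        with open(path, "w") as fh:
            for name, seq in records:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

    write_fasta(out / "locus.fasta", [(scenario.locus.name, scenario.locus.sequence)])
    write_fasta(out / "donor.fasta", [("donor", scenario.donor.donor_sequence)])
    write_fasta(out / "reference.fasta", [("amplicon_reference", scenario.reference)])
    write_fasta(out / "reads.fasta", [(r.read_id, r.sequence) for r in reads])
    truth.table.to_csv(out / "truth.tsv", sep="\t")
    simulate_clone_experiment(config).to_csv(out / "clones.tsv", sep="\t", index=False)
    cfg = asdict(config)
    cfg["cut_position"] = scenario.cut_position
    cfg["ref_offset"] = scenario.ref_offset
    with open(out / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=2)
    return scenario
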