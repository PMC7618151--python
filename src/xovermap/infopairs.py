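"""Crossover-informative read-pair extraction from gamete Hi-C alignments.

A Hi-C read pair is *informative* when each of its two reads covers at
least one phased heterozygous site of the donor.  If the two reads match
different donor haplotypes a crossover occurred between them (status C);
if they match the same haplotype, none did (status N).  Each pair carries
a crossover likelihood ``lc = P(obs | crossover)`` and a non-crossover
likelihood ``ln = P(obs | no crossover)`` built from the base-quality and
phase-quality error probabilities of its two outermost SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Sequence

import pysam

from .phasing import HaplotypeBlock, PhasedHet

logger = logging.getLogger(__name__)

__all__ = [
    "SnpObservation",
    "InformativePair",
    "PairExtractionStats",
    "flip_error",
    "pair_likelihoods",
    "find_informative_pairs",
    "write_pairs_tsv",
    "read_pairs_tsv",
]


@dataclass(frozen=True)
class SnpObservation:
    """One read base observed at a phased heterozygous site.

    ``hap_match`` is 1 or 2 according to which donor haplotype the read
    base equals; ``base_err`` comes from the sequencer base quality and
    ``phase_err`` from the phasing algorithm.
    """

    pos: int
    read_base: str
    base_err: float
    phase_err: float
    hap_match: int

    def __post_init__(self) -> None:
        if self.hap_match not in (1, 2):
            raise ValueError("hap_match must be 1 or 2")
        if not 0.0 <= self.base_err <= 1.0:
            raise ValueError("base_err outside [0, 1]")


@dataclass(frozen=True)
class InformativePair:
    """A crossover-informative Hi-C read pair, reduced to its two
    outermost SNP observations.

    ``status`` is ``"C"`` when the two ends match different haplotypes and
    ``"N"`` otherwise; ``d = right.pos - left.pos`` is the insert size
    between the outermost SNPs. ``lc``/``ln`` are the crossover and
    non-crossover likelihoods (filled by :func:`pair_likelihoods`).
    """

    chrom: str
    left: SnpObservation
    right: SnpObservation
    status: str
    lc: float = 0.0
    ln: float = 1.0

    def __post_init__(self) -> None:
        if self.status not in ("C", "N"):
            raise ValueError("status must be 'C' or 'N'")
        if self.right.pos <= self.left.pos:
            raise ValueError("right SNP must be strictly right of left SNP")

    @property
    def d(self) -> int:
        """Insert size in bp between the two outermost SNPs."""
        return self.right.pos - self.left.pos


def flip_error(base_err: float, phase_err: float) -> float:
    """Probability that an end's haplotype assignment is wrong.

    Base-calling and phasing errors are independent; the assignment flips
    when exactly one of the two happened: ``e = b(1-p) + p(1-b)``.
    """
    return base_err * (1.0 - phase_err) + phase_err * (1.0 - base_err)


def pair_likelihoods(pair: InformativePair) -> tuple[float, float]:
    """Crossover / non-crossover likelihoods for one informative pair.

    For an observed C pair the haplotype calls at both ends must be right
    (or both wrong) under a true crossover, so with per-end flip errors
    ``e1, e2``: ``lc = (1-e1)(1-e2) + e1*e2`` and ``ln = e1(1-e2) + e2(1-e1)``.
    Observed N pairs use the conservative convention ``lc = 0, ln = 1``:
    they never contribute false-positive crossover mass, at the price of
    randomly distributed false negatives.
    """
    if pair.status == "N":
        return 0.0, 1.0
    e1 = flip_error(pair.left.base_err, pair.left.phase_err)
    e2 = flip_error(pair.right.base_err, pair.right.phase_err)
    lc = (1.0 - e1) * (1.0 - e2) + e1 * e2
    ln = e1 * (1.0 - e2) + e2 * (1.0 - e1)
    return lc, ln


def with_likelihoods(pair: InformativePair) -> InformativePair:
    lc, ln = pair_likelihoods(pair)
    return replace(pair, lc=lc, ln=ln)


@dataclass
class PairExtractionStats:
    """Counters reported by :func:`find_informative_pairs`."""

    n_pairs_seen: int = 0
    n_informative: int = 0
    n_inconsistent: int = 0
    n_cross_block: int = 0
    n_low_mapq: int = 0
    n_mate_missing: int = 0


def _site_index(blocks: Iterable[HaplotypeBlock]) -> dict[str, dict[int, tuple[PhasedHet, int]]]:
    """chrom -> pos -> (site, block serial), for O(1) lookup per aligned base."""
    index: dict[str, dict[int, tuple[PhasedHet, int]]] = {}
    for serial, block in enumerate(blocks):
        for site in block:
            index.setdefault(site.chrom, {})[site.pos] = (site, serial)
    return index


def _read_observations(
    read: pysam.AlignedSegment,
    sites: dict[int, tuple[PhasedHet, int]],
) -> list[tuple[SnpObservation, int]] | None:
    """SNP observations for one read, or None if internally inconsistent.

    A read whose covered SNPs match different haplotypes cannot come from a
    single gamete fragment without an error, so the whole pair is dropped.
    Bases matching neither donor allele are discarded as sequencing noise.
    """
    obs: list[tuple[SnpObservation, int]] = []
    quals = read.query_qualities
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        hit = sites.get(rpos + 1)  # pysam reference positions are 0-based
        if hit is None:
            continue
        site, block_serial = hit
        base = read.query_sequence[qpos].upper()
        if base == site.allele_h1:
            hap = 1
        elif base == site.allele_h2:
            hap = 2
        else:
            continue
        base_err = 10.0 ** (-(quals[qpos] if quals is not None else 40) / 10.0)
        obs.append(
            (
                SnpObservation(
                    pos=site.pos,
                    read_base=base,
                    base_err=base_err,
                    phase_err=site.phase_err,
                    hap_match=hap,
                ),
                block_serial,
            )
        )
    if not obs:
        return []
    haps = {o.hap_match for o, _ in obs}
    if len(haps) > 1:
        return None
    return obs


def find_informative_pairs(
    alignments,
    blocks: Sequence[HaplotypeBlock],
    min_mapq: int = 30,
) -> tuple[list[InformativePair], PairExtractionStats]:
    """Extract crossover-informative pairs from a SAM/BAM file or path.

    Emits one :class:`InformativePair` per read pair where both mates map
    to the same chromosome at mapping quality >= ``min_mapq``, each mate
    covers at least one phased het with a base matching a donor allele,
    all covered SNPs agree on the pair status, and all SNPs lie in the
    same haplotype block.  Coordinates and qualities come from the two
    outermost SNPs.  Secondary/supplementary alignments are ignored.
    """
    own = False
    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        alignments = pysam.AlignmentFile(str(alignments))
        own = True
    stats = PairExtractionStats()
    index = _site_index(blocks)
    pairs: list[InformativePair] = []
    pending: dict[str, pysam.AlignedSegment] = {}
    try:
        for read in alignments:
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or not read.is_paired
            ):
                continue
            qname = read.query_name
            mate = pending.pop(qname, None)
            if mate is None:
                pending[qname] = read
                continue
            stats.n_pairs_seen += 1
            pair = _classify_pair(mate, read, index, min_mapq, stats)
            if pair is not None:
                pairs.append(pair)
        stats.n_mate_missing = len(pending)
    finally:
        if own:
            alignments.close()
    stats.n_informative = len(pairs)
    logger.info(
        "find_informative_pairs: %d pairs seen, %d informative, %d inconsistent, "
        "%d cross-block, %d below mapq, %d without mate",
        stats.n_pairs_seen,
        stats.n_informative,
        stats.n_inconsistent,
        stats.n_cross_block,
        stats.n_low_mapq,
        stats.n_mate_missing,
    )
    return pairs, stats


def _classify_pair(r1, r2, index, min_mapq, stats) -> InformativePair | None:
    if r1.reference_name != r2.reference_name:
        return None
    if r1.mapping_quality < min_mapq or r2.mapping_quality < min_mapq:
        stats.n_low_mapq += 1
        return None
    sites = index.get(r1.reference_name)
    if not sites:
        return None
    obs1 = _read_observations(r1, sites)
    obs2 = _read_observations(r2, sites)
    if obs1 is None or obs2 is None:
        stats.n_inconsistent += 1
        return None
    if not obs1 or not obs2:
        return None  # at least one mate covers no het: not informative
    serials = {s for _, s in obs1} | {s for _, s in obs2}
    if len(serials) > 1:
        stats.n_cross_block += 1
        return None  # phase across blocks is undefined
    all_obs = sorted((o for o, _ in obs1 + obs2), key=lambda o: o.pos)
    left, right = all_obs[0], all_obs[-1]
    if right.pos == left.pos:
        return None
    status = "C" if left.hap_match != right.hap_match else "N"
    return with_likelihoods(
        InformativePair(chrom=r1.reference_name, left=left, right=right, status=status)
    )


# -- tab-delimited informative-pairs dialect ---------------------------------

_TSV_HEADER = "chrom\tleft_pos\tright_pos\tstatus\tb1\tp1\tb2\tp2"


def write_pairs_tsv(pairs: Iterable[InformativePair], path) -> None:
    """Write informative pairs as TSV: chrom, outermost SNP coordinates,
    status and the per-end base/phase error probabilities."""
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER + "\n")
        for p in pairs:
            fh.write(
                f"{p.chrom}\t{p.left.pos}\t{p.right.pos}\t{p.status}\t"
                f"{p.left.base_err:.6g}\t{p.left.phase_err:.6g}\t"
                f"{p.right.base_err:.6g}\t{p.right.phase_err:.6g}\n"
            )


def read_pairs_tsv(path) -> list[InformativePair]:
    """Read the informative-pairs TSV dialect; likelihoods are recomputed."""
    pairs: list[InformativePair] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("chrom\t") or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(f"{path}: malformed pairs line {lineno}: {line!r}")
            chrom, lp, rp, status, b1, p1, b2, p2 = fields[:8]
            left_hap = 1
            right_hap = 2 if status == "C" else 1
            left = SnpObservation(
                pos=int(lp), read_base="N", base_err=float(b1), phase_err=float(p1), hap_match=left_hap
            )
            right = SnpObservation(
                pos=int(rp), read_base="N", base_err=float(b2), phase_err=float(p2), hap_match=right_hap
            )
            pairs.append(
                with_likelihoods(
                    InformativePair(chrom=chrom, left=left, right=right, status=status)
                )
            )
    return pairs
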