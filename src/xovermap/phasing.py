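"""Phased-haplotype handling: HapCUT2 block I/O and Mendelian trio phasing.

Crossover detection compares gamete Hi-C fragments against the two phased
haplotypes of the sperm/egg donor.  The donor phase comes either from a
Hi-C-aware phasing run (HapCUT2) or, when the donor's parents have been
genotyped, from simple Mendelian transmission logic.  Both routes produce
:class:`HaplotypeBlock` objects holding :class:`PhasedHet` sites, the
currency consumed by the informative-pair finder.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "PhasedHet",
    "HaplotypeBlock",
    "read_hapcut2",
    "write_hapcut2",
    "trio_phase_records",
    "trio_phase_vcf",
    "TrioPhaseStats",
]

#: phase error cap — a phase call cannot be worse than a coin flip
MAX_PHASE_ERR = 0.5


@dataclass(frozen=True)
class PhasedHet:
    """A phased heterozygous biallelic SNP.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    pos : int
        1-based reference coordinate.
    allele_h1, allele_h2 : str
        Single bases assigned to haplotype 1 and haplotype 2.
    phase_err : float
        Probability in [0, 0.5] that the h1/h2 assignment is flipped
        relative to the rest of its block.
    """

    chrom: str
    pos: int
    allele_h1: str
    allele_h2: str
    phase_err: float = 0.0

    def __post_init__(self) -> None:
        if self.allele_h1 == self.allele_h2:
            raise ValueError(f"site {self.chrom}:{self.pos} is not heterozygous")
        if len(self.allele_h1) != 1 or len(self.allele_h2) != 1:
            raise ValueError(f"site {self.chrom}:{self.pos} is not a biallelic SNP")
        if not 0.0 <= self.phase_err <= 1.0:
            raise ValueError(f"phase_err {self.phase_err} outside [0, 1]")


@dataclass
class HaplotypeBlock:
    """An ordered run of phased heterozygous sites on one chromosome."""

    block_id: str
    sites: list[PhasedHet] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sites:
            chroms = {s.chrom for s in self.sites}
            if len(chroms) > 1:
                raise ValueError(f"block {self.block_id} spans chromosomes {chroms}")
            positions = [s.pos for s in self.sites]
            if any(b <= a for a, b in zip(positions, positions[1:])):
                raise ValueError(f"block {self.block_id} sites not strictly increasing")

    @property
    def chrom(self) -> str:
        return self.sites[0].chrom

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)


def _phase_err_from_phred(q: float) -> float:
    return min(MAX_PHASE_ERR, 10.0 ** (-q / 10.0))


def _phred_from_phase_err(p: float) -> float:
    if p <= 0.0:
        return 100.0
    return min(100.0, -10.0 * math.log10(p))


def read_hapcut2(path) -> list[HaplotypeBlock]:
    """Read phased blocks in the HapCUT2 haplotype-block text format.

    Each ``BLOCK:`` header starts a block; per-site lines carry the variant
    index, the haplotype-1 and haplotype-2 calls (``0``/``1``/``-``),
    chromosome, position, ref and alt alleles, the genotype string and
    quality columns.  The phred-scaled mismatch quality (last numeric
    column) becomes the site's ``phase_err`` via ``10**(-Q/10)``, capped at
    0.5.  Pruned sites (haplotype call ``-``) are skipped, as are
    non-biallelic records (with a warning).
    """
    blocks: list[HaplotypeBlock] = []
    current: list[PhasedHet] = []
    current_id: str | None = None
    n_block = 0

    def _flush() -> None:
        nonlocal current, current_id
        if current_id is not None:
            blocks.append(HaplotypeBlock(block_id=current_id, sites=current))
        current = []
        current_id = None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("BLOCK:"):
                _flush()
                n_block += 1
                current_id = f"block_{n_block}"
                continue
            if line.startswith("*"):
                _flush()
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 7:
                raise ValueError(f"{path}: malformed HapCUT2 line {lineno}: {line!r}")
            try:
                h1_call, h2_call = fields[1], fields[2]
                chrom = fields[3]
                pos = int(fields[4])
                ref, alt = fields[5], fields[6]
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed HapCUT2 line {lineno}: {line!r}") from exc
            if h1_call == "-" or h2_call == "-":
                continue  # pruned site
            if len(ref) != 1 or len(alt) != 1 or "," in alt:
                logger.warning("%s line %d: non-biallelic-SNP record skipped", path, lineno)
                continue
            if h1_call not in ("0", "1") or h2_call not in ("0", "1") or h1_call == h2_call:
                logger.warning("%s line %d: non-heterozygous call skipped", path, lineno)
                continue
            mismatch_q = 100.0
            for tok in reversed(fields[7:]):
                try:
                    mismatch_q = float(tok)
                    break
                except ValueError:
                    continue
            allele_h1 = ref if h1_call == "0" else alt
            allele_h2 = ref if h2_call == "0" else alt
            if current_id is None:  # tolerate headerless single-block files
                n_block += 1
                current_id = f"block_{n_block}"
            current.append(
                PhasedHet(
                    chrom=chrom,
                    pos=pos,
                    allele_h1=allele_h1,
                    allele_h2=allele_h2,
                    phase_err=_phase_err_from_phred(mismatch_q),
                )
            )
    _flush()
    return blocks


def write_hapcut2(blocks: Sequence[HaplotypeBlock], path) -> None:
    """Write blocks in the HapCUT2 block dialect re-readable by
    :func:`read_hapcut2`.

    Haplotype 1 is emitted as the ``0`` (ref) call, so ``allele_h1`` becomes
    the ref column and ``allele_h2`` the alt column; ``phase_err`` is stored
    as a phred-scaled mismatch quality (two decimals, capped at Q100).
    """
    if not blocks:
        logger.warning("write_hapcut2: no blocks to write; emitting empty file")
    index = 0
    with open(path, "w") as fh:
        for block in blocks:
            if not block.sites:
                continue
            span = block.sites[-1].pos - block.sites[0].pos
            fh.write(
                f"BLOCK: offset: {index + 1} len: {len(block.sites)} "
                f"phased: {len(block.sites)} SPAN: {span} fragments 0\n"
            )
            for site in block.sites:
                index += 1
                q = _phred_from_phase_err(site.phase_err)
                fh.write(
                    f"{index}\t0\t1\t{site.chrom}\t{site.pos}\t"
                    f"{site.allele_h1}\t{site.allele_h2}\t0/1\t0\t0.00\t{q:.2f}\n"
                )
            fh.write("********\n")


@dataclass
class TrioPhaseStats:
    """Bookkeeping for a trio-phasing run."""

    n_child_het: int = 0
    n_phased: int = 0
    n_both_parents_het: int = 0
    n_mendelian_violation: int = 0


def _phase_one_site(
    child: tuple[str, str],
    parent1: tuple[str, str],
    parent2: tuple[str, str],
) -> tuple[str, str] | None:
    """Resolve which child allele came from which parent.

    Returns ``(h1_allele, h2_allele)`` with h1 inherited from parent1, or
    ``None`` when the site is unphaseable (both parents heterozygous, or no
    consistent transmission exists).
    """
    a, b = child
    p1 = set(parent1)
    p2 = set(parent2)
    # both child alleles must be present somewhere in the parents
    if not ({a, b} <= (p1 | p2)):
        return None
    if len(p1) == 2 and len(p2) == 2:
        return None  # both parents het: transmission ambiguous
    # enumerate consistent transmissions (x from p1, y from p2)
    assignments = {(x, y) for x, y in ((a, b), (b, a)) if x in p1 and y in p2}
    if len(assignments) != 1:
        return None
    return assignments.pop()


def trio_phase_records(
    child: Iterable[tuple[str, int, tuple[str, str]]],
    parent1: dict[tuple[str, int], tuple[str, str]],
    parent2: dict[tuple[str, int], tuple[str, str]],
) -> tuple[list[HaplotypeBlock], TrioPhaseStats]:
    """Phase child-heterozygous SNPs by Mendelian transmission.

    Parameters
    ----------
    child : iterable of (chrom, pos, (allele_a, allele_b))
        Heterozygous biallelic genotypes of the donor, coordinate-sorted.
    parent1, parent2 : dict mapping (chrom, pos) -> (allele, allele)
        Parental genotypes at the same loci.

    Returns
    -------
    blocks, stats
        One :class:`HaplotypeBlock` per chromosome; the allele inherited
        from ``parent1`` goes to haplotype 1.  Phased sites get
        ``phase_err = 0``.  Sites where both parents are heterozygous are
        unphaseable and omitted; sites with a child allele absent from both
        parents are Mendelian violations, skipped and counted.
    """
    stats = TrioPhaseStats()
    per_chrom: dict[str, list[PhasedHet]] = {}
    for chrom, pos, alleles in child:
        a, b = alleles
        if a == b or len(a) != 1 or len(b) != 1:
            continue
        stats.n_child_het += 1
        key = (chrom, pos)
        if key not in parent1 or key not in parent2:
            continue
        g1, g2 = parent1[key], parent2[key]
        if not ({a, b} <= (set(g1) | set(g2))):
            stats.n_mendelian_violation += 1
            continue
        if len(set(g1)) == 2 and len(set(g2)) == 2:
            stats.n_both_parents_het += 1
            continue
        phased = _phase_one_site((a, b), g1, g2)
        if phased is None:
            continue
        h1, h2 = phased
        per_chrom.setdefault(chrom, []).append(
            PhasedHet(chrom=chrom, pos=pos, allele_h1=h1, allele_h2=h2, phase_err=0.0)
        )
        stats.n_phased += 1
    blocks = [
        HaplotypeBlock(block_id=f"trio_{chrom}", sites=sorted(sites, key=lambda s: s.pos))
        for chrom, sites in per_chrom.items()
    ]
    return blocks, stats


def _vcf_genotypes(path, sample: str):
    """Yield (chrom, pos, (allele, allele)) for one sample of a VCF."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    if sample not in vcf.samples:
        raise ValueError(f"sample {sample!r} not in {path} (has {vcf.samples})")
    idx = vcf.samples.index(sample)
    for variant in vcf:
        if not variant.is_snp or len(variant.ALT) != 1:
            continue
        gt = variant.genotypes[idx]
        if gt[0] < 0 or gt[1] < 0:
            continue
        alleles = [variant.REF] + variant.ALT
        yield variant.CHROM, variant.POS, (alleles[gt[0]], alleles[gt[1]])


def trio_phase_vcf(
    child_vcf,
    parents_vcf,
    child_sample: str,
    parent1_sample: str,
    parent2_sample: str,
) -> tuple[list[HaplotypeBlock], TrioPhaseStats]:
    """Trio-phase donor heterozygous sites from VCF files.

    ``child_vcf`` holds the donor genotypes; ``parents_vcf`` holds both
    parents genotyped at the same loci (it may be the same file).  Output is
    one block per chromosome in donor-coordinate order.
    """
    parent1 = {}
    parent2 = {}
    for chrom, pos, g in _vcf_genotypes(parents_vcf, parent1_sample):
        parent1[(chrom, pos)] = g
    for chrom, pos, g in _vcf_genotypes(parents_vcf, parent2_sample):
        parent2[(chrom, pos)] = g
    child = (
        (chrom, pos, g)
        for chrom, pos, g in _vcf_genotypes(child_vcf, child_sample)
        if g[0] != g[1]
    )
    return trio_phase_records(child, parent1, parent2)
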