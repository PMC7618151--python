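"""Simulation of crossover-informative Hi-C read pairs from a known map.

The generator is the package's validation backbone: given a reference
recombination landscape it emits informative pairs whose crossover
status follows the map (through the Haldane mapping function) with a
controlled status-error rate, using an empirical insert-size
distribution, until a target effective coverage is reached.  Feeding the
simulated pairs back through :class:`~xovermap.model.CrossoverMapModel`
measures how faithfully the inference chain recovers a known truth for a
given coverage, error rate and insert profile.

Also here: miniature SAM + HapCUT2 fixtures with planted crossovers for
end-to-end testing of the informative-pair finder, and the
truth-vs-reconstruction correlation harness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .infopairs import InformativePair, SnpObservation, read_pairs_tsv, with_likelihoods
from .model import RecombinationMap
from .phasing import HaplotypeBlock, PhasedHet, write_hapcut2

logger = logging.getLogger(__name__)

__all__ = [
    "SimParams",
    "sample_insert_distribution",
    "simulate_pairs",
    "evaluate_reconstruction",
    "make_fixture",
    "sawtooth_map",
    "log_uniform_inserts",
]

#: base/phase error probability attached to simulated observations — near
#: zero so the planted status-error rate is the only error source
SIM_QUALITY_ERR = 1e-6

EVAL_SCALES = (2_000, 10_000, 100_000, 1_000_000, 5_000_000)


@dataclass
class SimParams:
    """Controlled conditions of a simulation run.

    ``error_rate`` flips the observed status of each pair (both false
    positives and false negatives); ``target_coverage`` is the mean
    effective coverage (pairs spanning a position, averaged over the
    chromosome) at which simulation stops.
    """

    error_rate: float = 0.01
    target_coverage: float = 1_000.0
    replicates: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate outside [0, 1]")
        if self.target_coverage <= 0:
            raise ValueError("target_coverage must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def sample_insert_distribution(source) -> np.ndarray:
    """Empirical insert-size distribution from a real pairs file.

    ``source`` is a pairs-TSV path, a sequence of
    :class:`InformativePair`, or an array of insert sizes.  Returns the
    array of observed d values; simulation resamples it uniformly, so
    simulated insert sizes match the source distribution exactly in the
    large-sample limit.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        source = read_pairs_tsv(source)
    if len(source) == 0:
        raise ValueError("empty insert-size source")
    if isinstance(source[0], InformativePair):
        d = np.array([p.d for p in source], dtype=float)
    else:
        d = np.asarray(source, dtype=float)
    if np.any(d <= 0):
        raise ValueError("insert sizes must be positive")
    return d


def haldane_p(delta_cM: np.ndarray) -> np.ndarray:
    """Recombination probability for a genetic distance in cM:
    ``p = (1 - exp(-2 d_M)) / 2``, saturating at 1/2."""
    return (1.0 - np.exp(-2.0 * np.asarray(delta_cM, dtype=float) / 100.0)) / 2.0


def simulate_pairs(
    ref: RecombinationMap,
    inserts: np.ndarray,
    params: SimParams,
    rng: np.random.Generator | None = None,
    return_truth: bool = False,
):
    """Simulate informative pairs whose statuses follow a reference map.

    Each pair's left endpoint is uniform on ``[1, L-d]`` with ``d`` drawn
    from the empirical insert distribution (redrawn if ``d >= L``).  The
    true status is C with probability given by the Haldane function of
    the map distance between the endpoints; the observed status is
    flipped with probability ``error_rate``.  Pairs carry near-zero
    base/phase error probabilities.  Simulation stops when mean spanning
    coverage ``sum(d)/L`` reaches ``target_coverage``.

    Returns a list of :class:`InformativePair` (and the true-status bool
    array when ``return_truth``).
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    inserts = np.asarray(inserts, dtype=float)
    start, end = ref.retained_span
    length = float(end - start)
    usable = inserts[inserts < length]
    if len(usable) == 0:
        raise ValueError("no insert size fits inside the chromosome")
    n_target = int(np.ceil(params.target_coverage * length / usable.mean()))
    d = rng.choice(usable, size=n_target, replace=True)
    # trim so realised mean coverage ~ target
    excess = np.cumsum(d) >= params.target_coverage * length
    if np.any(excess):
        d = d[: max(1, int(np.argmax(excess)) + 1)]
    left = start + np.floor(rng.uniform(0.0, length - d)).astype(np.int64)
    right = left + d.astype(np.int64)
    delta_cm = ref.cm_at(right) - ref.cm_at(left)
    p_c = haldane_p(delta_cm)
    true_c = rng.uniform(size=len(d)) < p_c
    flips = rng.uniform(size=len(d)) < params.error_rate
    obs_c = true_c ^ flips
    pairs = []
    for lp, rp, c in zip(left, right, obs_c):
        lobs = SnpObservation(
            pos=int(lp), read_base="N", base_err=SIM_QUALITY_ERR,
            phase_err=SIM_QUALITY_ERR, hap_match=1,
        )
        robs = SnpObservation(
            pos=int(rp), read_base="N", base_err=SIM_QUALITY_ERR,
            phase_err=SIM_QUALITY_ERR, hap_match=2 if c else 1,
        )
        pairs.append(
            with_likelihoods(
                InformativePair(
                    chrom=ref.chrom, left=lobs, right=robs, status="C" if c else "N"
                )
            )
        )
    if return_truth:
        return pairs, true_c
    return pairs


def evaluate_reconstruction(
    ref: RecombinationMap,
    reconstructed: Sequence[RecombinationMap],
    scales: Sequence[int] = EVAL_SCALES,
) -> dict:
    """Truth-vs-reconstruction correlations at several spatial scales.

    For each scale the chromosome (intersection of retained spans) is cut
    into windows of that size; the per-window cM totals of the truth and
    of each replicate are Pearson-correlated.  Scales with fewer than 3
    windows, or zero variance on either side, are reported as None.
    Also reports the relative bias of the mean per-bp rate,
    ``mean_r_hat / mean_r_true - 1``, averaged over replicates.

    Returns ``{"correlations": {scale: {"per_replicate": [...], "mean": x}},
    "mean_rate_bias": b}``.
    """
    lo = max(m.retained_span[0] for m in list(reconstructed) + [ref])
    hi = min(m.retained_span[1] for m in list(reconstructed) + [ref])
    if hi <= lo:
        raise ValueError("reference and reconstructed spans do not overlap")
    out: dict = {"correlations": {}, "mean_rate_bias": None}
    biases = []
    for m in reconstructed:
        truth_cm = float(ref.cm_at(hi) - ref.cm_at(lo))
        est_cm = float(m.cm_at(hi) - m.cm_at(lo))
        if truth_cm > 0:
            biases.append(est_cm / truth_cm - 1.0)
    out["mean_rate_bias"] = float(np.mean(biases)) if biases else None
    for scale in scales:
        # full windows only: a trailing partial bin would fabricate
        # variance on an otherwise constant landscape
        edges = np.arange(lo, hi + 1, scale, dtype=float)
        if len(edges) - 1 < 3:
            out["correlations"][int(scale)] = {"per_replicate": None, "mean": None}
            continue
        truth = np.diff(ref.cm_at(edges))
        per_rep = []

        def _degenerate(x):
            return x.std() <= 1e-9 * max(abs(x).max(), 1e-300)

        for m in reconstructed:
            est = np.diff(m.cm_at(edges))
            if _degenerate(truth) or _degenerate(est):
                per_rep.append(None)
            else:
                per_rep.append(float(np.corrcoef(truth, est)[0, 1]))
        valid = [r for r in per_rep if r is not None]
        out["correlations"][int(scale)] = {
            "per_replicate": per_rep,
            "mean": float(np.mean(valid)) if valid else None,
        }
    return out


# ---------------------------------------------------------------------------
# synthetic inputs


def sawtooth_map(
    chrom: str,
    chrom_len: int,
    mean_rate_cM_per_Mb: float = 3.0,
    n_teeth: int = 5,
    n_intervals: int = 400,
    amplitude_gradient: float = 0.8,
) -> RecombinationMap:
    """A synthetic landscape of repeated 0-to-peak ramps whose tooth
    height grows along the chromosome.

    The ramps put structure at sub-tooth scales while the amplitude
    gradient (tooth height scaling linearly from ``1-g`` to ``1+g`` times
    the mean) puts structure at multi-Mb scales, so truth correlations
    are informative at both fine and coarse resolution.  The mean rate is
    ``mean_rate_cM_per_Mb`` regardless of the gradient.
    """
    bounds = np.linspace(1, chrom_len, n_intervals + 1)
    mids = (bounds[:-1] + bounds[1:]) / 2.0
    x = (mids - 1) / (chrom_len - 1)
    phase = x * n_teeth
    saw = phase - np.floor(phase)
    amp = 1.0 + amplitude_gradient * (2.0 * x - 1.0)
    rate = 2.0 * mean_rate_cM_per_Mb * saw * amp / 1e6  # cM/bp
    rate *= mean_rate_cM_per_Mb / (np.mean(rate) * 1e6)
    return RecombinationMap(chrom, bounds, rate)


def log_uniform_inserts(
    n: int,
    d_min: int = 300,
    d_max: int = 5_000_000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Synthetic Hi-C-like insert sizes, log-uniform between ``d_min``
    and ``d_max`` — heavy representation of both the short inserts that
    calibrate the false-positive correction and the long inserts that
    calibrate the baseline rate."""
    rng = rng if rng is not None else np.random.default_rng(0)
    return np.exp(rng.uniform(np.log(d_min), np.log(d_max), size=n)).astype(np.int64).astype(float)


# ---------------------------------------------------------------------------
# SAM + HapCUT2 fixture with planted crossovers


def make_fixture(
    chrom_len: int,
    n_hets: int,
    n_pairs: int,
    planted_breakpoints: Sequence[int],
    seed: int,
    sam_path,
    hapcut_path,
    chrom: str = "chr1",
    read_len: int = 100,
):
    """Write a miniature aligned gamete Hi-C dataset with known truth.

    Heterozygous A/G sites are placed uniformly; each simulated gamete
    haplotype starts as haplotype 1 and switches at every planted
    breakpoint.  Read pairs are placed uniformly, reads carry the
    gamete's allele at every covered het (quality Q40), and a matching
    single-block HapCUT2 file is written.  Returns a truth list with one
    record per read pair: ``(qname, left_read_start, right_read_start,
    expected_status_or_None)`` where the status is None when the pair
    covers no het on one side (uninformative).
    """
    import pysam

    if n_hets < 2:
        raise ValueError("need at least 2 heterozygous sites")
    for bp in planted_breakpoints:
        if not 1 <= bp <= chrom_len:
            raise ValueError(f"breakpoint {bp} outside chromosome")
    rng = np.random.default_rng(seed)
    het_pos = np.sort(rng.choice(np.arange(read_len + 1, chrom_len - read_len), size=n_hets, replace=False))
    sites = [PhasedHet(chrom=chrom, pos=int(p), allele_h1="A", allele_h2="G", phase_err=0.0) for p in het_pos]
    write_hapcut2([HaplotypeBlock(block_id="b1", sites=sites)], hapcut_path)

    def gamete_hap(pos: np.ndarray) -> np.ndarray:
        """1 or 2: haplotype carried at each position after the planted
        crossovers (switch at every breakpoint, scanning left to right)."""
        switches = np.zeros(np.shape(pos), dtype=int)
        for bp in planted_breakpoints:
            switches += (np.asarray(pos) >= bp).astype(int)
        return 1 + (switches % 2)

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": int(chrom_len)}],
    }
    truth = []
    records = []
    for k in range(n_pairs):
        r1_start = int(rng.integers(1, chrom_len - read_len))  # 1-based
        r2_start = int(rng.integers(r1_start, min(r1_start + chrom_len // 2, chrom_len - read_len)))
        if r2_start <= r1_start:
            r2_start = r1_start + 1
        qname = f"pair_{k}"
        covered = []
        for start in (r1_start, r2_start):
            mask = (het_pos >= start) & (het_pos < start + read_len)
            covered.append(het_pos[mask])
        if len(covered[0]) and len(covered[1]):
            outer_l = int(covered[0].min())
            outer_r = int(covered[1].max())
            if outer_r > outer_l:
                status = "C" if gamete_hap(outer_l) != gamete_hap(outer_r) else "N"
            else:
                status = None
        else:
            status = None
        truth.append((qname, r1_start, r2_start, status))
        for start, is_read1 in ((r1_start, True), (r2_start, False)):
            seq = np.full(read_len, ord("T"), dtype=np.uint8)
            mask = (het_pos >= start) & (het_pos < start + read_len)
            for hp in het_pos[mask]:
                hap = gamete_hap(hp)
                seq[hp - start] = ord("A") if hap == 1 else ord("G")
            a = pysam.AlignedSegment()
            a.query_name = qname
            a.query_sequence = seq.tobytes().decode()
            a.flag = (0x1 | 0x2 | (0x40 if is_read1 else 0x80) | (0x20 if is_read1 else 0x10))
            a.reference_id = 0
            a.reference_start = start - 1  # SAM text stays 1-based
            a.mapping_quality = 60
            a.cigarstring = f"{read_len}M"
            a.next_reference_id = 0
            a.next_reference_start = (r2_start if is_read1 else r1_start) - 1
            a.template_length = (r2_start - r1_start + read_len) * (1 if is_read1 else -1)
            a.query_qualities = pysam.qualitystring_to_array("I" * read_len)  # Q40
            records.append(a)
    records.sort(key=lambda a: a.reference_start)
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
        for a in records:
            out.write(a)
    return truth
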