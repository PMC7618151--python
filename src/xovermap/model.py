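"""Recombination-map inference from crossover-informative Hi-C pairs.

The estimation problem: given informative read pairs classified as
crossover (C) or non-crossover (N) between their two outermost phased
SNPs, recover the per-bp crossover rate landscape of the donor's meioses.
The procedure is

1. remove *imbalanced SNPs* — likely variant-calling/phasing artifacts
   that bound only crossover-indicating pairs;
2. estimate ``r*``, the chromosome-average per-bp crossover rate, from
   long-insert pairs (where true crossovers dominate false positives);
3. estimate the false-positive correction ``f`` from short-insert pairs,
   whose observed crossover mass should be almost entirely error;
4. adjust long non-crossover pairs for the possibility of a masking
   double crossover (Poisson);
5. convert each pair's corrected likelihoods into a posterior crossover
   probability with the uniform-map prior ``pc = r* * d``;
6. spread each posterior uniformly over the pair's insert to obtain an
   initial piecewise-constant map, then sharpen it by EM, redistributing
   each pair's probability mass across the intervals it spans in
   proportion to the current map;
7. trim chromosome edges where effective coverage (the number of pairs
   spanning a position) is too low to be informative.

Uncertainty comes from a nonparametric bootstrap over read pairs.

The user-facing surface is :class:`CrossoverMapModel` (construct from a
pair list or TSV) whose :meth:`~CrossoverMapModel.fit` returns a
:class:`CrossoverMapResults` carrying the fitted :class:`RateModel`, the
:class:`RecombinationMap`, diagnostics, ``summary()``, ``bootstrap()``
and plotting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .infopairs import InformativePair, read_pairs_tsv

logger = logging.getLogger(__name__)

__all__ = [
    "RateModel",
    "RecombinationMap",
    "CoverageProfile",
    "MapWithCI",
    "estimate_baseline_rate",
    "correction_factor",
    "posterior_crossover",
    "double_crossover_adjust",
    "filter_imbalanced_snps",
    "effective_coverage",
    "edge_trim",
    "initial_map",
    "em_refine",
    "map_length_cM",
    "delta_r_regions",
    "CrossoverMapModel",
    "CrossoverMapResults",
    "read_map_tsv",
]

LONG_THRESHOLD_DEFAULT = 1_000_000  # bp; insert above which FP rate is negligible
SHORT_THRESHOLD_DEFAULT = 1_000  # bp; insert below which C calls are mostly error
EM_MAX_ITER_DEFAULT = 2  # sharpening passes; see em_refine on why few
EM_TOL_DEFAULT = 1e-4


# ---------------------------------------------------------------------------
# domain containers


@dataclass
class RateModel:
    """Chromosome-level baseline rate and false-positive correction.

    ``r_star`` is the average per-bp crossover rate (Morgans/bp, i.e.
    expected crossovers per bp per gamete); ``f`` is the per-pair
    false-positive crossover likelihood excess estimated from short
    inserts, interpreted as the dataset's crossover error rate.
    """

    chrom: str
    r_star: float
    f: float
    long_threshold: int = LONG_THRESHOLD_DEFAULT
    short_threshold: int = SHORT_THRESHOLD_DEFAULT

    def __post_init__(self) -> None:
        if self.r_star < 0:
            raise ValueError("r_star must be nonnegative")
        self.f = float(min(max(self.f, 0.0), 1.0 - 1e-12))
        if self.long_threshold <= self.short_threshold:
            raise ValueError("long_threshold must exceed short_threshold")


@dataclass
class RecombinationMap:
    """Piecewise-constant recombination landscape.

    ``boundaries`` (length m+1, sorted, unique, 1-based bp) delimit m
    intervals; ``rate`` (length m) is the rate of each interval in cM/bp.
    ``retained_span`` is the [start, end] kept after edge trimming;
    intervals tile it exactly.
    """

    chrom: str
    boundaries: np.ndarray
    rate: np.ndarray
    retained_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.boundaries.ndim != 1 or self.rate.shape != (len(self.boundaries) - 1,):
            raise ValueError("boundaries must be 1-D with len(rate)+1 entries")
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if np.any(self.rate < 0):
            raise ValueError("rates must be nonnegative")
        if self.retained_span is None:
            self.retained_span = (int(self.boundaries[0]), int(self.boundaries[-1]))

    @property
    def lengths(self) -> np.ndarray:
        return np.diff(self.boundaries)

    @property
    def rate_cM_per_Mb(self) -> np.ndarray:
        return self.rate * 1e6

    def total_cM(self) -> float:
        return float(np.sum(self.rate * self.lengths))

    def cumulative_cM(self) -> np.ndarray:
        """Cumulative genetic position (cM) at each boundary."""
        return np.concatenate([[0.0], np.cumsum(self.rate * self.lengths)])

    def cm_at(self, pos) -> np.ndarray:
        """Genetic position (cM) at physical position(s), linear within
        intervals, clamped outside the retained span."""
        return np.interp(np.asarray(pos, dtype=float), self.boundaries, self.cumulative_cM())

    def binned_cM(self, scale: int) -> tuple[np.ndarray, np.ndarray]:
        """Total cM per window of ``scale`` bp across the retained span."""
        start, end = self.retained_span
        edges = np.arange(start, end + scale, scale, dtype=float)
        edges[-1] = min(edges[-1], end)
        if edges[-1] < end:
            edges = np.append(edges, end)
        cm = self.cm_at(edges)
        return edges, np.diff(cm)

    def to_tsv(self, path, mode: str = "w") -> None:
        cum = self.cumulative_cM()
        with open(path, mode) as fh:
            if mode == "w":
                fh.write("chrom\tstart\tend\trate_cM_per_Mb\tcumulative_cM\n")
            for i in range(len(self.rate)):
                fh.write(
                    f"{self.chrom}\t{int(self.boundaries[i])}\t{int(self.boundaries[i + 1])}\t"
                    f"{self.rate[i] * 1e6:.8g}\t{cum[i + 1]:.8g}\n"
                )


def read_map_tsv(path) -> dict[str, RecombinationMap]:
    """Read the map TSV dialect (chrom, start, end, rate_cM_per_Mb,
    cumulative_cM) back into per-chromosome maps."""
    rows: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("chrom\t") or line.startswith("#"):
                continue
            chrom, start, end, rate_mb, _cum = line.split("\t")[:5]
            rows.setdefault(chrom, []).append((int(start), int(end), float(rate_mb)))
    maps = {}
    for chrom, ivs in rows.items():
        ivs.sort()
        bounds = [ivs[0][0]]
        rates = []
        for start, end, rate_mb in ivs:
            if start != bounds[-1]:
                bounds.append(start)
                rates.append(0.0)
            bounds.append(end)
            rates.append(rate_mb / 1e6)
        maps[chrom] = RecombinationMap(chrom, np.array(bounds, float), np.array(rates, float))
    return maps


@dataclass
class CoverageProfile:
    """Effective coverage: number of informative pairs spanning each
    interval of a piecewise-constant grid."""

    chrom: str
    boundaries: np.ndarray
    count: np.ndarray

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        self.count = np.asarray(self.count, dtype=float)
        if np.any(self.count < 0):
            raise ValueError("coverage counts must be nonnegative")

    def at(self, pos) -> np.ndarray:
        pos = np.asarray(pos, dtype=float)
        idx = np.clip(np.searchsorted(self.boundaries, pos, side="right") - 1, 0, len(self.count) - 1)
        out = self.count[idx]
        out = np.where((pos < self.boundaries[0]) | (pos >= self.boundaries[-1]), 0.0, out)
        return out

    def mean(self) -> float:
        lens = np.diff(self.boundaries)
        total = lens.sum()
        return float(np.sum(self.count * lens) / total) if total > 0 else 0.0

    def median(self) -> float:
        lens = np.diff(self.boundaries)
        order = np.argsort(self.count)
        cdf = np.cumsum(lens[order])
        i = int(np.searchsorted(cdf, cdf[-1] / 2.0))
        return float(self.count[order[min(i, len(order) - 1)]])


@dataclass
class MapWithCI:
    """Bootstrap mean map with a per-interval 95% envelope."""

    mean_map: RecombinationMap
    lo95: np.ndarray
    hi95: np.ndarray
    n_boot: int

    def __post_init__(self) -> None:
        self.lo95 = np.asarray(self.lo95, dtype=float)
        self.hi95 = np.asarray(self.hi95, dtype=float)
        if not (
            np.all(self.lo95 <= self.mean_map.rate + 1e-12)
            and np.all(self.mean_map.rate <= self.hi95 + 1e-12)
        ):
            raise ValueError("envelope must bracket the mean per interval")

    def to_tsv(self, path, mode: str = "w") -> None:
        m = self.mean_map
        cum = m.cumulative_cM()
        with open(path, mode) as fh:
            if mode == "w":
                fh.write("chrom\tstart\tend\trate_cM_per_Mb\tcumulative_cM\tlo95_cM_per_Mb\thi95_cM_per_Mb\n")
            for i in range(len(m.rate)):
                fh.write(
                    f"{m.chrom}\t{int(m.boundaries[i])}\t{int(m.boundaries[i + 1])}\t"
                    f"{m.rate[i] * 1e6:.8g}\t{cum[i + 1]:.8g}\t"
                    f"{self.lo95[i] * 1e6:.8g}\t{self.hi95[i] * 1e6:.8g}\n"
                )


# ---------------------------------------------------------------------------
# flat array view of a pair list (internal)


class _PairArrays:
    """Column view of informative pairs for vectorised estimation."""

    __slots__ = ("chrom", "left", "right", "d", "is_c", "lc", "ln", "n")

    def __init__(self, pairs: Sequence[InformativePair]):
        self.n = len(pairs)
        self.chrom = pairs[0].chrom if pairs else ""
        self.left = np.array([p.left.pos for p in pairs], dtype=np.int64)
        self.right = np.array([p.right.pos for p in pairs], dtype=np.int64)
        self.d = (self.right - self.left).astype(np.float64)
        self.is_c = np.array([p.status == "C" for p in pairs], dtype=bool)
        self.lc = np.array([p.lc for p in pairs], dtype=np.float64)
        self.ln = np.array([p.ln for p in pairs], dtype=np.float64)


# ---------------------------------------------------------------------------
# rate model estimation


def estimate_baseline_rate(
    pairs: Sequence[InformativePair] | _PairArrays,
    long_threshold: int = LONG_THRESHOLD_DEFAULT,
) -> float:
    """Average per-bp crossover rate ``r*`` from long-insert pairs.

    Long inserts (default > 1 Mb) have a highly favourable true:false
    positive ratio, so the crossover-likelihood mass of long C pairs per
    bp surveyed estimates the chromosome-wide rate:
    ``r* = sum(lc over long C pairs) / sum(d over all long pairs)``.
    """
    arr = pairs if isinstance(pairs, _PairArrays) else _PairArrays(pairs)
    long_mask = arr.d > long_threshold
    if not np.any(long_mask):
        raise ValueError(
            f"no pairs with insert > {long_threshold} bp; lower long_threshold "
            "(--FPrateThresholds) for this chromosome"
        )
    denom = float(arr.d[long_mask].sum())
    numer = float(arr.lc[long_mask & arr.is_c].sum())
    return numer / denom


def correction_factor(
    pairs: Sequence[InformativePair] | _PairArrays,
    r_star: float,
    short_threshold: int = SHORT_THRESHOLD_DEFAULT,
) -> float:
    """False-positive correction ``f`` from short-insert pairs.

    Short inserts (default < 1 kb) almost never contain a true crossover,
    so their excess crossover-likelihood mass beyond the baseline
    expectation, per short informative pair, estimates the per-pair
    false-positive rate:
    ``f = (sum lc - r* * sum d) / n_short``, with both sums over short C
    pairs and ``n_short`` counting all short informative pairs.  Clamped
    to [0, 1).
    """
    arr = pairs if isinstance(pairs, _PairArrays) else _PairArrays(pairs)
    short_mask = arr.d < short_threshold
    ns = int(short_mask.sum())
    if ns == 0:
        return 0.0
    sc = short_mask & arr.is_c
    f = (float(arr.lc[sc].sum()) - r_star * float(arr.d[sc].sum())) / ns
    return min(max(f, 0.0), 1.0 - 1e-12)


def double_crossover_adjust(
    pair: InformativePair,
    model: RateModel,
    min_d: int | None = None,
) -> InformativePair:
    """Adjust a long non-crossover pair for a masking double crossover.

    A double crossover within the insert leaves both ends on the same
    haplotype and so masquerades as N.  With expected crossover count
    ``lambda = r* * d`` the Poisson probability of exactly two is
    ``pd = lambda^2 * exp(-lambda) / 2``; for long N pairs the
    conservative convention ``lc=0, ln=1`` becomes ``lc=pd, ln=1-pd``.
    Crossover interference makes nearby doubles unlikely, so short pairs
    are untouched (default threshold 1 Mb).
    """
    if min_d is None:
        min_d = model.long_threshold
    if pair.status != "N" or pair.d <= min_d:
        return pair
    lam = model.r_star * pair.d
    pd = lam * lam * np.exp(-lam) / 2.0
    return replace(pair, lc=float(pd), ln=float(1.0 - pd))


def _double_crossover_adjust_arrays(arr: _PairArrays, r_star: float, min_d: int) -> None:
    mask = (~arr.is_c) & (arr.d > min_d)
    lam = r_star * arr.d[mask]
    pd = lam * lam * np.exp(-lam) / 2.0
    arr.lc[mask] = pd
    arr.ln[mask] = 1.0 - pd


def posterior_crossover(pair: InformativePair, model: RateModel) -> float:
    """Posterior probability that a crossover occurred within the pair.

    Uses the uniform-rate prior ``pc = min(r* * d, 1)`` and the corrected
    likelihoods: for C pairs
    ``P = (lc-f)*pc / [(lc-f)*pc + (ln+f)*(1-pc)]`` with ``lc-f`` floored
    at 0.  N pairs have ``lc=0`` (posterior 0) unless the double-crossover
    adjustment raised ``lc``; the f-correction targets false-positive C
    calls and is not applied to N pairs.
    """
    pc = min(max(model.r_star * pair.d, 0.0), 1.0)
    if pair.status == "C":
        num = max(pair.lc - model.f, 0.0) * pc
        den = num + (pair.ln + model.f) * (1.0 - pc)
    else:
        num = pair.lc * pc
        den = num + pair.ln * (1.0 - pc)
    if den <= 0.0:
        logger.warning("degenerate posterior denominator for pair at %s:%d", pair.chrom, pair.left.pos)
        return 0.0
    return num / den


def _posteriors_arrays(arr: _PairArrays, r_star: float, f: float) -> np.ndarray:
    pc = np.clip(r_star * arr.d, 0.0, 1.0)
    lc_eff = np.where(arr.is_c, np.maximum(arr.lc - f, 0.0), arr.lc)
    ln_eff = np.where(arr.is_c, arr.ln + f, arr.ln)
    num = lc_eff * pc
    den = num + ln_eff * (1.0 - pc)
    with np.errstate(invalid="ignore", divide="ignore"):
        post = np.where(den > 0.0, num / den, 0.0)
    return post


# ---------------------------------------------------------------------------
# imbalanced-SNP filter


def filter_imbalanced_snps(
    pairs: Sequence[InformativePair],
    c_min: int = 2,
    n_max: int = 0,
) -> tuple[list[InformativePair], list[tuple[str, int]]]:
    """Remove imbalanced SNPs and the pairs they bound, iteratively.

    A SNP is *imbalanced* when, among the pairs for which it is an
    outermost SNP, at least ``c_min`` indicate a crossover while at most
    ``n_max`` indicate a non-crossover (defaults 2 and 0).  Such SNPs are
    typically variant-calling or phasing artifacts producing false
    recombination spikes.  Removal can expose new imbalanced SNPs, so the
    rule is applied until stable.
    """
    kept = list(pairs)
    removed_snps: list[tuple[str, int]] = []
    while True:
        c_count: dict[tuple[str, int], int] = {}
        n_count: dict[tuple[str, int], int] = {}
        for p in kept:
            for key in ((p.chrom, p.left.pos), (p.chrom, p.right.pos)):
                if p.status == "C":
                    c_count[key] = c_count.get(key, 0) + 1
                    n_count.setdefault(key, 0)
                else:
                    n_count[key] = n_count.get(key, 0) + 1
                    c_count.setdefault(key, 0)
        bad = {k for k in c_count if c_count[k] >= c_min and n_count[k] <= n_max}
        if not bad:
            break
        removed_snps.extend(sorted(bad))
        kept = [
            p
            for p in kept
            if (p.chrom, p.left.pos) not in bad and (p.chrom, p.right.pos) not in bad
        ]
    return kept, removed_snps


# ---------------------------------------------------------------------------
# coverage, trimming, map construction


def effective_coverage(
    pairs: Sequence[InformativePair] | _PairArrays,
    chrom_len: int | None = None,
) -> CoverageProfile:
    """Piecewise-constant count of informative pairs spanning each point.

    The grid is the union of the pairs' outermost-SNP coordinates; a pair
    covers the half-open interval [left, right).  ``chrom_len`` only
    extends the profile with a trailing zero interval.
    """
    arr = pairs if isinstance(pairs, _PairArrays) else _PairArrays(pairs)
    if arr.n == 0:
        bounds = np.array([1.0, float(chrom_len or 2)])
        return CoverageProfile(arr.chrom, bounds, np.zeros(1))
    bounds = np.unique(np.concatenate([arr.left, arr.right])).astype(float)
    if chrom_len is not None and chrom_len > bounds[-1]:
        bounds = np.append(bounds, float(chrom_len))
    if chrom_len is not None and bounds[0] > 1:
        bounds = np.insert(bounds, 0, 1.0)
    delta = np.zeros(len(bounds))
    li = np.searchsorted(bounds, arr.left)
    ri = np.searchsorted(bounds, arr.right)
    np.add.at(delta, li, 1.0)
    np.add.at(delta, ri, -1.0)
    count = np.cumsum(delta)[:-1]
    count[np.abs(count) < 1e-9] = 0.0
    return CoverageProfile(arr.chrom, bounds, count)


def edge_trim(profile: CoverageProfile, min_cov: float) -> tuple[int, int] | None:
    """Retained [start, end] after trimming low-coverage chromosome edges.

    Scans inward from each end for the first interval with coverage >=
    ``min_cov``; interior dips are never trimmed (they reflect local SNP
    deserts, not the systematic edge effect).  Returns None when coverage
    never reaches the cutoff.
    """
    ok = np.nonzero(profile.count >= min_cov)[0]
    if len(ok) == 0:
        logger.warning("edge_trim: coverage never reaches %g; empty map", min_cov)
        return None
    start = profile.boundaries[ok[0]]
    end = profile.boundaries[ok[-1] + 1]
    return int(start), int(end)


def _grid_for_span(
    profile: CoverageProfile, span: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Grid boundaries and coverage restricted to the retained span."""
    b = profile.boundaries
    i0 = int(np.searchsorted(b, span[0], side="left"))
    i1 = int(np.searchsorted(b, span[1], side="right")) - 1
    bounds = b[i0 : i1 + 1].copy()
    count = profile.count[i0:i1].copy()
    return bounds, count


def _pair_interval_ranges(
    arr_left: np.ndarray, arr_right: np.ndarray, bounds: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Clip each pair's span to the grid and return interval index ranges
    [li, ri): pair covers intervals li..ri-1."""
    left = np.clip(arr_left, bounds[0], bounds[-1])
    right = np.clip(arr_right, bounds[0], bounds[-1])
    li = np.searchsorted(bounds, left)
    ri = np.searchsorted(bounds, right)
    return li, ri


def initial_map(
    pairs: Sequence[InformativePair] | _PairArrays,
    posteriors: np.ndarray,
    profile: CoverageProfile,
    retained_span: tuple[int, int],
) -> RecombinationMap:
    """Initial landscape: each pair's crossover probability spread
    uniformly over its insert, normalised by effective coverage.

    For interval j the per-bp rate is
    ``sum_i P_i / d_i (pairs spanning j) / N_j`` (Morgans/bp), reported in
    cM/bp.  Intervals with zero coverage inside the span get rate 0.
    """
    arr = pairs if isinstance(pairs, _PairArrays) else _PairArrays(pairs)
    posteriors = np.asarray(posteriors, dtype=float)
    bounds, count = _grid_for_span(profile, retained_span)
    m = len(bounds) - 1
    if m <= 0:
        raise ValueError("retained span contains no grid intervals")
    li, ri = _pair_interval_ranges(arr.left, arr.right, bounds)
    active = (posteriors > 0) & (ri > li)
    dens_delta = np.zeros(m + 1)
    w = posteriors[active] / arr.d[active]
    np.add.at(dens_delta, li[active], w)
    np.add.at(dens_delta, ri[active], -w)
    dens = np.maximum(np.cumsum(dens_delta)[:-1], 0.0)  # cancellation guard
    if np.any((count <= 0) & (dens > 0)):
        logger.warning("initial_map: zero effective coverage inside retained span")
    with np.errstate(invalid="ignore", divide="ignore"):
        rate_m_per_bp = np.where(count > 0, dens / count, 0.0)
    return RecombinationMap(arr.chrom, bounds, rate_m_per_bp * 100.0, retained_span)


def em_refine(
    map0: RecombinationMap,
    pairs: Sequence[InformativePair] | _PairArrays,
    posteriors: np.ndarray,
    profile: CoverageProfile,
    max_iter: int = EM_MAX_ITER_DEFAULT,
    tol: float = EM_TOL_DEFAULT,
) -> tuple[RecombinationMap, int]:
    """Sharpen the initial map by expectation-maximisation.

    E-step: each pair's posterior mass ``P_i`` is redistributed over the
    grid intervals inside its span proportionally to the current interval
    masses ``rate_j * len_j`` (uniform fallback when the span's total rate
    is zero).  M-step: ``rate_j = sum_i w_ij / (N_j * len_j)``.  The
    redistributed weights of every pair always sum to ``P_i``, so the
    coverage-weighted total mass is conserved exactly.  Iterates until the
    maximum relative per-interval change drops below ``tol`` or
    ``max_iter`` is reached.

    ``max_iter`` is deliberately small by default.  In bulk gamete Hi-C
    each crossover is observed by a single ligation product, so read
    pairs carry no shared localisation signal within their spans; the
    redistribution likelihood is maximised by piling mass onto
    coincidental span overlaps, and iterating far beyond a couple of
    self-consistency passes trades fine-scale fidelity for spurious
    spikes.  Two passes sharpen genuinely supported features while
    leaving the landscape stable; raise ``max_iter`` only with data where
    crossovers are multiply observed.

    Returns the refined map and the number of iterations performed.
    """
    arr = pairs if isinstance(pairs, _PairArrays) else _PairArrays(pairs)
    posteriors = np.asarray(posteriors, dtype=float)
    bounds = map0.boundaries
    m = len(bounds) - 1
    lens = np.diff(bounds)
    count = profile.at((bounds[:-1] + bounds[1:]) / 2.0)
    li, ri = _pair_interval_ranges(arr.left, arr.right, bounds)
    active = (posteriors > 0) & (ri > li)
    li, ri, P = li[active], ri[active], posteriors[active]
    span_len = bounds[ri] - bounds[li]
    rate = map0.rate / 100.0  # Morgans/bp internally
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mass = rate * lens
        prefix = np.concatenate([[0.0], np.cumsum(mass)])
        S = prefix[ri] - prefix[li]
        pos_S = S > 0
        u_delta = np.zeros(m + 1)
        wS = P[pos_S] / S[pos_S]
        np.add.at(u_delta, li[pos_S], wS)
        np.add.at(u_delta, ri[pos_S], -wS)
        u = np.maximum(np.cumsum(u_delta)[:-1], 0.0)  # cancellation guard
        dens_delta = np.zeros(m + 1)
        if np.any(~pos_S):  # uniform fallback over the clipped span
            wU = P[~pos_S] / span_len[~pos_S]
            np.add.at(dens_delta, li[~pos_S], wU)
            np.add.at(dens_delta, ri[~pos_S], -wU)
        dens_u = np.maximum(np.cumsum(dens_delta)[:-1], 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            new_rate = np.where(count > 0, (rate * u + dens_u) / count, 0.0)
        scale = np.maximum(np.maximum(rate, new_rate), 1e-300)
        rel = np.max(np.abs(new_rate - rate) / scale) if m else 0.0
        rate = new_rate
        if rel < tol:
            break
    else:
        if max_iter > EM_MAX_ITER_DEFAULT:  # expected at the default pass count
            logger.warning("em_refine: no convergence after %d iterations", max_iter)
    return (
        RecombinationMap(map0.chrom, bounds, rate * 100.0, map0.retained_span),
        n_iter,
    )


def map_length_cM(rmap: RecombinationMap) -> tuple[float, float]:
    """Total genetic length as (cM, Morgans)."""
    cm = rmap.total_cM()
    return cm, cm / 100.0


# ---------------------------------------------------------------------------
# map comparison


def _envelope_on_grid(ci: MapWithCI, bounds: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean/lo/hi rates of a bootstrap map looked up on a common grid."""
    src = ci.mean_map.boundaries
    mid = (bounds[:-1] + bounds[1:]) / 2.0
    idx = np.clip(np.searchsorted(src, mid, side="right") - 1, 0, len(ci.mean_map.rate) - 1)
    return ci.mean_map.rate[idx], ci.lo95[idx], ci.hi95[idx]


def delta_r_regions(
    a: MapWithCI,
    b: MapWithCI,
    normalize: bool = False,
) -> tuple[list[tuple[int, int]], int, float]:
    """Intervals where the 95% envelopes of two maps do not intersect.

    These are the regions of significant recombination-rate difference.
    With ``normalize=True`` each map (mean and envelope) is first divided
    by its length-weighted mean rate, so only landscape-shape differences
    remain.  Envelopes are closed intervals: touching bounds intersect.

    Returns (list of (start, end) regions, total bp, fraction of the
    compared span).
    """
    if a.mean_map.chrom != b.mean_map.chrom:
        raise ValueError("maps are on different chromosomes")
    lo = max(a.mean_map.retained_span[0], b.mean_map.retained_span[0])
    hi = min(a.mean_map.retained_span[1], b.mean_map.retained_span[1])
    if hi <= lo:
        logger.warning("delta_r_regions: retained spans do not overlap")
        return [], 0, 0.0
    bounds = np.unique(
        np.concatenate([a.mean_map.boundaries, b.mean_map.boundaries])
    )
    bounds = bounds[(bounds >= lo) & (bounds <= hi)]
    if bounds[0] > lo:
        bounds = np.insert(bounds, 0, lo)
    if bounds[-1] < hi:
        bounds = np.append(bounds, hi)
    mean_a, lo_a, hi_a = _envelope_on_grid(a, bounds)
    mean_b, lo_b, hi_b = _envelope_on_grid(b, bounds)
    if normalize:
        lens = np.diff(bounds)
        for mean, lo_e, hi_e in ((mean_a, lo_a, hi_a), (mean_b, lo_b, hi_b)):
            mu = np.sum(mean * lens) / lens.sum()
            if mu > 0:
                mean /= mu
                lo_e /= mu
                hi_e /= mu
    disjoint = (hi_a < lo_b) | (hi_b < lo_a)
    regions: list[tuple[int, int]] = []
    i = 0
    m = len(disjoint)
    while i < m:
        if disjoint[i]:
            j = i
            while j + 1 < m and disjoint[j + 1]:
                j += 1
            regions.append((int(bounds[i]), int(bounds[j + 1])))
            i = j + 1
        i += 1
    total_bp = int(sum(e - s for s, e in regions))
    return regions, total_bp, total_bp / float(hi - lo)


# ---------------------------------------------------------------------------
# model / results


@dataclass
class FitDiagnostics:
    n_pairs_in: int = 0
    n_pairs_used: int = 0
    n_imbalanced_snps: int = 0
    n_long: int = 0
    n_short: int = 0
    em_iterations: int = 0
    min_cov: float = 0.0


class CrossoverMapModel:
    """Recombination-landscape model for one chromosome's informative
    pairs.

    Parameters
    ----------
    pairs : sequence of InformativePair
        Crossover-informative pairs of a single chromosome (as produced
        by :func:`xovermap.infopairs.find_informative_pairs`).
    chrom_len : int, optional
        Physical chromosome length; only used to pad the coverage
        profile, never to extrapolate rates.
    long_threshold, short_threshold : int
        Insert-size cutoffs (bp) defining the long-insert pairs used for
        the baseline rate and the short-insert pairs used for the
        false-positive correction.
    imbalance_c_min, imbalance_n_max : int
        Imbalanced-SNP filter thresholds.
    double_xover_min_d : int, optional
        Minimum insert size for the double-crossover adjustment
        (defaults to ``long_threshold``).
    min_cov : float, optional
        Edge-trim coverage cutoff; defaults to 10% of the median
        effective coverage.
    em_tol, em_max_iter : EM stopping rule (see :func:`em_refine` on why
        the default pass count is small).
    """

    def __init__(
        self,
        pairs: Sequence[InformativePair],
        chrom_len: int | None = None,
        *,
        long_threshold: int = LONG_THRESHOLD_DEFAULT,
        short_threshold: int = SHORT_THRESHOLD_DEFAULT,
        imbalance_c_min: int = 2,
        imbalance_n_max: int = 0,
        double_xover_min_d: int | None = None,
        min_cov: float | None = None,
        em_tol: float = EM_TOL_DEFAULT,
        em_max_iter: int = EM_MAX_ITER_DEFAULT,
    ):
        pairs = list(pairs)
        if not pairs:
            raise ValueError("no informative pairs supplied")
        chroms = {p.chrom for p in pairs}
        if len(chroms) > 1:
            raise ValueError(f"pairs span multiple chromosomes: {sorted(chroms)}")
        self.pairs = pairs
        self.chrom = pairs[0].chrom
        self.chrom_len = chrom_len
        self.long_threshold = int(long_threshold)
        self.short_threshold = int(short_threshold)
        self.imbalance_c_min = imbalance_c_min
        self.imbalance_n_max = imbalance_n_max
        self.double_xover_min_d = (
            int(double_xover_min_d) if double_xover_min_d is not None else int(long_threshold)
        )
        self.min_cov = min_cov
        self.em_tol = em_tol
        self.em_max_iter = em_max_iter
        self._filtered: list[InformativePair] | None = None

    @classmethod
    def from_pairs_file(cls, path, chrom: str | None = None, **kwargs) -> "CrossoverMapModel":
        """Build a model from the informative-pairs TSV (one chromosome;
        pass ``chrom`` to select when the file holds several)."""
        pairs = read_pairs_tsv(path)
        if chrom is not None:
            pairs = [p for p in pairs if p.chrom == chrom]
        return cls(pairs, **kwargs)

    # -- pipeline ---------------------------------------------------------

    def _balanced_pairs(self) -> tuple[list[InformativePair], list[tuple[str, int]]]:
        if self._filtered is None:
            self._filtered, self._removed_snps = filter_imbalanced_snps(
                self.pairs, self.imbalance_c_min, self.imbalance_n_max
            )
        return self._filtered, self._removed_snps

    def fit(self, pairs: Sequence[InformativePair] | None = None) -> "CrossoverMapResults":
        """Run the full inference chain and return the results object.

        ``pairs`` overrides the (imbalance-filtered) pair list — used by
        the bootstrap to refit resampled data without re-filtering.
        """
        diag = FitDiagnostics(n_pairs_in=len(self.pairs))
        if pairs is None:
            kept, removed = self._balanced_pairs()
            diag.n_imbalanced_snps = len(removed)
        else:
            kept, removed = list(pairs), []
        if not kept:
            raise ValueError("no pairs left after imbalanced-SNP filtering")
        diag.n_pairs_used = len(kept)
        arr = _PairArrays(kept)
        diag.n_long = int((arr.d > self.long_threshold).sum())
        diag.n_short = int((arr.d < self.short_threshold).sum())
        r_star = estimate_baseline_rate(arr, self.long_threshold)
        f = correction_factor(arr, r_star, self.short_threshold)
        rate_model = RateModel(
            self.chrom, r_star, f, self.long_threshold, self.short_threshold
        )
        _double_crossover_adjust_arrays(arr, r_star, self.double_xover_min_d)
        posteriors = _posteriors_arrays(arr, r_star, f)
        profile = effective_coverage(arr, self.chrom_len)
        min_cov = self.min_cov if self.min_cov is not None else 0.1 * profile.median()
        diag.min_cov = float(min_cov)
        span = edge_trim(profile, min_cov)
        if span is None:
            raise ValueError("effective coverage never reaches the edge-trim cutoff")
        map0 = initial_map(arr, posteriors, profile, span)
        refined, n_iter = em_refine(
            map0, arr, posteriors, profile, self.em_max_iter, self.em_tol
        )
        diag.em_iterations = n_iter
        return CrossoverMapResults(
            model=self,
            rate_model=rate_model,
            map=refined,
            initial=map0,
            coverage=profile,
            posteriors=posteriors,
            diagnostics=diag,
            removed_snps=removed,
        )


@dataclass
class CrossoverMapResults:
    """Fitted recombination landscape with diagnostics.

    Attributes
    ----------
    rate_model : RateModel
        Baseline per-bp rate ``r*`` and false-positive correction ``f``.
    map : RecombinationMap
        EM-refined landscape over the retained span (cM/bp intervals).
    initial : RecombinationMap
        The pre-EM landscape (uniform within-insert spreading).
    coverage : CoverageProfile
    posteriors : np.ndarray
        Per-pair posterior crossover probabilities (filter order).
    """

    model: CrossoverMapModel
    rate_model: RateModel
    map: RecombinationMap
    initial: RecombinationMap
    coverage: CoverageProfile
    posteriors: np.ndarray
    diagnostics: FitDiagnostics
    removed_snps: list = field(default_factory=list)

    @property
    def total_cM(self) -> float:
        return self.map.total_cM()

    @property
    def mean_rate_cM_per_Mb(self) -> float:
        span = self.map.retained_span
        return self.total_cM / (span[1] - span[0]) * 1e6

    def summary(self) -> str:
        d = self.diagnostics
        span = self.map.retained_span
        lines = [
            "Crossover map fit",
            "=" * 52,
            f"chromosome            {self.map.chrom}",
            f"informative pairs     {d.n_pairs_in}",
            f"pairs used            {d.n_pairs_used}",
            f"imbalanced SNPs cut   {d.n_imbalanced_snps}",
            f"long pairs (> {self.rate_model.long_threshold/1e6:g} Mb) {d.n_long}",
            f"short pairs (< {self.rate_model.short_threshold/1e3:g} kb) {d.n_short}",
            f"r* (M/bp)             {self.rate_model.r_star:.4g}",
            f"error rate f          {self.rate_model.f:.4%}",
            f"retained span         {span[0]:,} - {span[1]:,}",
            f"mean eff. coverage    {self.coverage.mean():.1f}x",
            f"edge-trim cutoff      {d.min_cov:.1f}x",
            f"EM iterations         {d.em_iterations}",
            f"map length            {self.total_cM:.2f} cM ({self.total_cM/100:.3f} M)",
            f"mean rate             {self.mean_rate_cM_per_Mb:.3f} cM/Mb",
        ]
        return "\n".join(lines)

    def bootstrap(self, n_boot: int = 50, seed: int | None = None) -> MapWithCI:
        """Percentile bootstrap over informative pairs.

        Pairs (post imbalance filter) are resampled with replacement
        ``n_boot`` times; the whole chain from ``r*`` onward is rerun per
        replicate.  Replicate maps are evaluated on the union grid of
        their boundaries restricted to the intersection of retained
        spans; the envelope is the per-interval 2.5/97.5 percentile.
        """
        if n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        rng = np.random.default_rng(seed)
        base, _ = self.model._balanced_pairs()
        maps: list[RecombinationMap] = []
        for _ in range(n_boot):
            idx = rng.integers(0, len(base), size=len(base))
            resample = [base[i] for i in idx]
            maps.append(self.model.fit(pairs=resample).map)
        lo = max(m.retained_span[0] for m in maps)
        hi = min(m.retained_span[1] for m in maps)
        if hi <= lo:
            raise ValueError("bootstrap retained spans do not overlap")
        bounds = np.unique(np.concatenate([m.boundaries for m in maps]))
        bounds = bounds[(bounds >= lo) & (bounds <= hi)]
        mids = (bounds[:-1] + bounds[1:]) / 2.0
        rates = np.empty((n_boot, len(mids)))
        for k, m in enumerate(maps):
            idx = np.clip(
                np.searchsorted(m.boundaries, mids, side="right") - 1, 0, len(m.rate) - 1
            )
            rates[k] = m.rate[idx]
        mean = rates.mean(axis=0)
        lo95 = np.percentile(rates, 2.5, axis=0)
        hi95 = np.percentile(rates, 97.5, axis=0)
        mean_map = RecombinationMap(self.map.chrom, bounds, mean, (int(lo), int(hi)))
        return MapWithCI(mean_map, lo95, hi95, n_boot)

    def plot(self, ax=None, scale: int = 100_000):
        """Plot the landscape (cM/Mb, binned at ``scale`` bp)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        edges, cm = self.map.binned_cM(scale)
        widths = np.diff(edges)
        ax.stairs(cm / widths * 1e6, edges / 1e6)
        ax.set_xlabel(f"{self.map.chrom} position (Mb)")
        ax.set_ylabel("rate (cM/Mb)")
        ax.set_title(f"{self.map.chrom}: {self.total_cM:.1f} cM")
        return ax
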