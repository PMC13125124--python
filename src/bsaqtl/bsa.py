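"""Genotype-count QTL-seq: bulk allele frequencies, delta tracks, sliding
windows, per-chromosome confidence thresholds and region calling.

Unlike read-depth QTL-seq, the per-bulk allele frequency here is a count
over genotyped RILs: the fraction of bulk members carrying the allele
polymorphic to a chosen reference parent (heterozygotes count half).  The
scan contrasts the high- and low-bulk frequencies per locus (delta),
smooths the delta with a wide sliding window, and calls a region where a
run of windows exceeds the chromosome-wise threshold

    upper = |mean(delta)| + t_{conf, n-1} * sd(delta) / sqrt(n)

provided the run is "low noise": at least ``min_run_snps`` member SNPs
individually beyond the threshold and at least ``min_beyond_fraction`` of
all member SNPs beyond it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genofilter import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix
from .pheno import BlupTable

__all__ = [
    "FrequencyTrack",
    "DeltaTrack",
    "WindowTrack",
    "ChromosomeThreshold",
    "CandidateRegion",
    "bulk_frequency",
    "delta_track",
    "sliding_window_mean",
    "chromosome_threshold",
    "call_regions",
    "region_pve",
    "validate_across_populations",
    "scan_chromosome",
]


@dataclass
class FrequencyTrack:
    chrom: str
    pos: np.ndarray  # 1-based, strictly increasing
    freq: np.ndarray  # in [0,1] where unmasked
    mask: np.ndarray  # True = masked (insufficient calls)
    n_calls: np.ndarray
    bulk: str
    reference_parent: str

    def __post_init__(self) -> None:
        if np.any(np.diff(self.pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        ok = ~self.mask
        if ok.any() and (np.nanmin(self.freq[ok]) < 0 or np.nanmax(self.freq[ok]) > 1):
            raise ValueError("frequencies outside [0, 1]")


@dataclass
class DeltaTrack:
    chrom: str
    pos: np.ndarray
    delta: np.ndarray  # high - low, NaN where masked
    mask: np.ndarray

    def __post_init__(self) -> None:
        ok = ~self.mask
        if ok.any() and np.nanmax(np.abs(self.delta[ok])) > 1 + 1e-9:
            raise ValueError("delta outside [-1, 1]")


@dataclass
class WindowTrack:
    chrom: str
    start: np.ndarray  # 1-based inclusive window starts
    end: np.ndarray  # 1-based inclusive window ends (start + width - 1)
    mean: np.ndarray  # NaN for empty windows
    count: np.ndarray
    width_bp: int
    step_bp: int


@dataclass
class ChromosomeThreshold:
    chrom: str
    mean_abs: float  # |mean delta| over unmasked loci
    sd: float
    n: int
    t: float
    confidence: float

    @property
    def upper(self) -> float:
        return self.mean_abs + self.t * self.sd / np.sqrt(self.n)


@dataclass
class CandidateRegion:
    population: str
    trait: str
    chrom: str
    start_bp: int  # first SNP beyond the threshold
    end_bp: int  # last SNP beyond the threshold
    mean_abs_delta: float
    ci: float
    sign: int  # +1 peak / -1 trough of the window means
    n_snps: int
    n_beyond: int
    beyond_fraction: float
    pve: float | None = None
    validated: bool = False
    validated_start_bp: int | None = None
    validated_end_bp: int | None = None

    @property
    def length_bp(self) -> int:
        # end minus start, the reporting convention for region length
        return self.end_bp - self.start_bp

    def overlaps(self, other: "CandidateRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start_bp <= other.end_bp
            and other.start_bp <= self.end_bp
        )


def bulk_frequency(
    G: GenotypeMatrix,
    bulk: list[str],
    reference_parent: str,
    min_calls: int = 15,
    bulk_label: str = "",
) -> dict[str, FrequencyTrack]:
    """Per-chromosome tracks of the non-reference-parent allele frequency
    within a bulk.

    At each locus the frequency is (homozygous-for-the-other-parent count
    + 0.5 * heterozygous count) / non-missing calls; a locus is masked when
    fewer than ``min_calls`` bulk members are genotyped.  Loci should first
    be restricted to the parentally informative set.
    """
    ref_calls = G.calls[:, G.sample_index(reference_parent)]
    if not np.all(np.isin(ref_calls, (HOM_REF, HOM_ALT))):
        raise ValueError(
            "reference parent has missing or heterozygous calls; restrict to "
            "informative loci first"
        )
    bulk_calls = G.calls_for(list(bulk))
    nonmissing = bulk_calls != MISSING
    n_calls = nonmissing.sum(axis=1)
    other_hom = np.where(ref_calls == HOM_REF, HOM_ALT, HOM_REF)
    n_other = (bulk_calls == other_hom[:, None]).sum(axis=1)
    n_het = (bulk_calls == HET).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_calls > 0, (n_other + 0.5 * n_het) / n_calls, np.nan)
    mask = n_calls < min_calls
    freq = np.where(mask, np.nan, freq)

    tracks = {}
    chroms = G.loci["chrom"].to_numpy()
    pos_all = G.loci["pos"].to_numpy()
    for chrom in G.chromosomes():
        sel = chroms == chrom
        tracks[chrom] = FrequencyTrack(
            chrom=chrom,
            pos=pos_all[sel].astype(np.int64),
            freq=freq[sel],
            mask=mask[sel],
            n_calls=n_calls[sel],
            bulk=bulk_label,
            reference_parent=reference_parent,
        )
    return tracks


def delta_track(
    high: FrequencyTrack, low: FrequencyTrack, min_freq: float = 0.3
) -> DeltaTrack:
    """Delta = high-bulk frequency minus low-bulk frequency per locus.

    A locus is masked when either input is masked, or when the frequency is
    <= ``min_freq`` in *both* bulks — where neither bulk carries the
    non-reference allele appreciably there is no contrast to measure,
    whereas a single low-frequency bulk is exactly the signal sought.
    """
    if high.chrom != low.chrom or not np.array_equal(high.pos, low.pos):
        raise ValueError("high and low tracks must share loci")
    if high.reference_parent != low.reference_parent:
        raise ValueError("tracks use different reference parents")
    with np.errstate(invalid="ignore"):
        both_low = (high.freq <= min_freq) & (low.freq <= min_freq)
    mask = high.mask | low.mask | both_low
    delta = np.where(mask, np.nan, high.freq - low.freq)
    return DeltaTrack(chrom=high.chrom, pos=high.pos, delta=delta, mask=mask)


def sliding_window_mean(
    delta: DeltaTrack,
    width_bp: int = 2_000_000,
    step_bp: int = 10_000,
    chrom_length: int | None = None,
) -> WindowTrack:
    """Mean delta in windows [s, s+width-1] for s = 1, 1+step, 1+2*step, ...

    Enumeration continues while the start does not exceed the chromosome
    end (the last SNP position unless ``chrom_length`` is given).  Windows
    with no unmasked member loci carry NaN means.
    """
    if width_bp <= 0 or step_bp <= 0:
        raise ValueError("width and step must be positive")
    end = chrom_length if chrom_length is not None else (int(delta.pos.max()) if delta.pos.size else 0)
    if end <= 0:
        return WindowTrack(
            chrom=delta.chrom,
            start=np.array([], dtype=np.int64),
            end=np.array([], dtype=np.int64),
            mean=np.array([]),
            count=np.array([], dtype=np.int64),
            width_bp=width_bp,
            step_bp=step_bp,
        )
    starts = np.arange(1, end + 1, step_bp, dtype=np.int64)
    ends = starts + width_bp - 1

    valid = ~delta.mask
    vals = np.where(valid, delta.delta, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    ccnt = np.concatenate([[0], np.cumsum(valid.astype(np.int64))])
    i0 = np.searchsorted(delta.pos, starts, side="left")
    i1 = np.searchsorted(delta.pos, ends, side="right")
    count = ccnt[i1] - ccnt[i0]
    total = csum[i1] - csum[i0]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return WindowTrack(
        chrom=delta.chrom, start=starts, end=ends, mean=mean, count=count,
        width_bp=width_bp, step_bp=step_bp,
    )


def chromosome_threshold(delta: DeltaTrack, confidence: float = 0.999) -> ChromosomeThreshold:
    """Chromosome-wise threshold |mean| + t * sd / sqrt(n) over unmasked
    loci, with t the two-sided Student quantile at ``confidence`` and
    df = n - 1.  A locus is "beyond" when |delta| exceeds the threshold."""
    d = delta.delta[~delta.mask]
    n = d.size
    if n < 2:
        raise ValueError(f"chromosome {delta.chrom}: need >= 2 unmasked loci, have {n}")
    t = float(stats.t.ppf(0.5 + confidence / 2.0, df=n - 1))
    return ChromosomeThreshold(
        chrom=delta.chrom,
        mean_abs=float(abs(d.mean())),
        sd=float(d.std(ddof=1)),
        n=n,
        t=t,
        confidence=confidence,
    )


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first, last) index pairs."""
    out = []
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return out
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def call_regions(
    delta: DeltaTrack,
    windows: WindowTrack,
    thr: ChromosomeThreshold,
    min_run_snps: int = 10,
    min_beyond_fraction: float = 0.8,
    max_gap_snps: int = 10,
    population: str = "",
    trait: str = "",
    merge_overlapping: bool = True,
) -> list[CandidateRegion]:
    """Call candidate regions from runs of threshold-exceeding windows.

    Seed intervals are maximal runs of consecutive windows whose |mean|
    exceeds ``thr.upper``.  Because a window is much wider than the step,
    a run's span smears well past the underlying signal, so beyond-
    threshold SNPs inside the span are grouped into clusters: a new
    cluster starts whenever more than ``max_gap_snps`` consecutive
    within-threshold loci intervene.  Each cluster spans its first to last
    beyond-threshold SNP and is kept only when low-noise: at least
    ``min_run_snps`` member SNPs beyond the threshold and a beyond
    fraction >= ``min_beyond_fraction``.  Same-sign overlapping regions
    are merged.
    """
    if delta.chrom != windows.chrom or delta.chrom != thr.chrom:
        raise ValueError("inputs must describe the same chromosome")
    upper = thr.upper
    with np.errstate(invalid="ignore"):
        beyond_w = (windows.count > 0) & (np.abs(windows.mean) > upper)
    valid = ~delta.mask
    beyond_snp = valid & (np.abs(np.where(valid, delta.delta, 0.0)) > upper)

    # rank of each locus among unmasked loci, for gap counting
    valid_rank = np.cumsum(valid) - 1
    regions: list[CandidateRegion] = []
    for a, b in _runs(beyond_w):
        span_lo, span_hi = int(windows.start[a]), int(windows.end[b])
        in_span = (delta.pos >= span_lo) & (delta.pos <= span_hi)
        cand = np.flatnonzero(in_span & beyond_snp)
        if cand.size == 0:
            continue
        # clusters of beyond SNPs separated by > max_gap_snps unmasked loci
        gaps = np.diff(valid_rank[cand])
        cluster_breaks = np.flatnonzero(gaps > max_gap_snps + 1)
        cluster_edges = np.concatenate([[0], cluster_breaks + 1, [cand.size]])
        for ci in range(cluster_edges.size - 1):
            cl = cand[cluster_edges[ci] : cluster_edges[ci + 1]]
            start_bp = int(delta.pos[cl[0]])
            end_bp = int(delta.pos[cl[-1]])
            members = np.flatnonzero((delta.pos >= start_bp) & (delta.pos <= end_bp) & valid)
            n_beyond = int(beyond_snp[members].sum())
            n_snps = int(members.size)
            frac = n_beyond / n_snps if n_snps else 0.0
            if n_beyond < min_run_snps or frac < min_beyond_fraction:
                continue
            sign = 1 if np.nanmean(delta.delta[members]) >= 0 else -1
            regions.append(
                CandidateRegion(
                    population=population,
                    trait=trait,
                    chrom=delta.chrom,
                    start_bp=start_bp,
                    end_bp=end_bp,
                    mean_abs_delta=float(np.nanmean(np.abs(delta.delta[members]))),
                    ci=float(upper),
                    sign=sign,
                    n_snps=n_snps,
                    n_beyond=n_beyond,
                    beyond_fraction=float(frac),
                )
            )
    if merge_overlapping:
        regions = _merge_same_sign(regions, delta, upper)
    return regions


def _merge_same_sign(
    regions: list[CandidateRegion], delta: DeltaTrack, upper: float
) -> list[CandidateRegion]:
    regions = sorted(regions, key=lambda r: (r.sign, r.start_bp))
    merged: list[CandidateRegion] = []
    for r in regions:
        if merged and merged[-1].sign == r.sign and merged[-1].overlaps(r):
            prev = merged.pop()
            start, end = prev.start_bp, max(prev.end_bp, r.end_bp)
            valid = ~delta.mask
            members = np.flatnonzero((delta.pos >= start) & (delta.pos <= end) & valid)
            beyond = np.abs(delta.delta[members]) > upper
            merged.append(
                CandidateRegion(
                    population=r.population,
                    trait=r.trait,
                    chrom=r.chrom,
                    start_bp=start,
                    end_bp=end,
                    mean_abs_delta=float(np.nanmean(np.abs(delta.delta[members]))),
                    ci=upper,
                    sign=r.sign,
                    n_snps=int(members.size),
                    n_beyond=int(beyond.sum()),
                    beyond_fraction=float(beyond.mean()) if members.size else 0.0,
                )
            )
        else:
            merged.append(r)
    return sorted(merged, key=lambda r: r.start_bp)


def region_pve(
    region: CandidateRegion,
    delta: DeltaTrack,
    G: GenotypeMatrix,
    gei_blups: pd.Series,
    reference_parent: str,
    rils: list[str],
) -> float | None:
    """R^2 of the regression of GEI BLUPs on the peak-SNP genotype.

    The peak SNP is the member locus maximising |delta|; its genotype is
    coded as the non-reference-parent allele fraction (0 / 0.5 / 1) across
    all RILs of the population, not only the bulks.  Returns None when the
    peak SNP is monomorphic across the genotyped RILs.
    """
    chroms = G.loci["chrom"].to_numpy()
    pos_all = G.loci["pos"].to_numpy()
    sel = (chroms == region.chrom) & (pos_all >= region.start_bp) & (pos_all <= region.end_bp)
    if not sel.any():
        return None
    track_sel = (delta.pos >= region.start_bp) & (delta.pos <= region.end_bp) & ~delta.mask
    if not track_sel.any():
        return None
    peak_pos = int(delta.pos[track_sel][np.argmax(np.abs(delta.delta[track_sel]))])
    locus = int(np.flatnonzero((chroms == region.chrom) & (pos_all == peak_pos))[0])

    ref_call = G.calls[locus, G.sample_index(reference_parent)]
    calls = np.array([G.calls[locus, G.sample_index(r)] for r in rils], dtype=float)
    ok = calls != MISSING
    # fraction of the non-reference-parent allele: 0, 0.5 or 1
    x = calls / 2.0 if ref_call == HOM_REF else 1.0 - calls / 2.0
    y = gei_blups.reindex(rils).to_numpy(dtype=float)
    ok &= ~np.isnan(y)
    if ok.sum() < 3 or np.std(x[ok]) == 0:
        return None
    res = stats.linregress(x[ok], y[ok])
    return float(res.rvalue**2)


def validate_across_populations(
    regions_a: list[CandidateRegion], regions_b: list[CandidateRegion]
) -> list[CandidateRegion]:
    """Flag regions detected in both populations for the same trait on the
    same chromosome (>= 1 bp overlap) and record the intersected interval
    as the putative-QTL span.  Returns the concatenated, annotated list."""
    for r in regions_a + regions_b:
        r.validated = False
        r.validated_start_bp = None
        r.validated_end_bp = None
    for ra in regions_a:
        for rb in regions_b:
            if ra.trait == rb.trait and ra.overlaps(rb):
                lo = max(ra.start_bp, rb.start_bp)
                hi = min(ra.end_bp, rb.end_bp)
                for r in (ra, rb):
                    r.validated = True
                    r.validated_start_bp = lo if r.validated_start_bp is None else min(r.validated_start_bp, lo)
                    r.validated_end_bp = hi if r.validated_end_bp is None else max(r.validated_end_bp, hi)
    return regions_a + regions_b


def scan_chromosome(
    high: FrequencyTrack,
    low: FrequencyTrack,
    min_freq: float = 0.3,
    width_bp: int = 2_000_000,
    step_bp: int = 10_000,
    confidence: float = 0.999,
    min_run_snps: int = 10,
    min_beyond_fraction: float = 0.8,
    max_gap_snps: int = 10,
    chrom_length: int | None = None,
    population: str = "",
    trait: str = "",
) -> tuple[DeltaTrack, WindowTrack, ChromosomeThreshold | None, list[CandidateRegion]]:
    """Convenience wrapper chaining delta -> windows -> threshold -> calls
    for one chromosome; returns (delta, windows, threshold, regions) with a
    None threshold (and no regions) when too few loci survive masking."""
    delta = delta_track(high, low, min_freq=min_freq)
    windows = sliding_window_mean(delta, width_bp, step_bp, chrom_length)
    if (~delta.mask).sum() < 2:
        return delta, windows, None, []
    thr = chromosome_threshold(delta, confidence)
    regions = call_regions(
        delta, windows, thr, min_run_snps, min_beyond_fraction, max_gap_snps,
        population=population, trait=trait,
    )
    return delta, windows, thr, regions
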