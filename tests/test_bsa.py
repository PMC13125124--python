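"""The delta allele-frequency scan: frequencies, windows, thresholds,
region calling, PVE and cross-population validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from bsaqtl.bsa import (
    CandidateRegion,
    DeltaTrack,
    FrequencyTrack,
    bulk_frequency,
    call_regions,
    chromosome_threshold,
    delta_track,
    region_pve,
    scan_chromosome,
    sliding_window_mean,
    validate_across_populations,
)
from bsaqtl.pheno import BlupTable

from conftest import make_matrix


def _freq_track(pos, freq, mask=None, bulk="high", chrom="Chr01"):
    pos = np.asarray(pos, dtype=np.int64)
    freq = np.asarray(freq, dtype=float)
    mask = np.zeros(pos.size, bool) if mask is None else np.asarray(mask, bool)
    return FrequencyTrack(chrom=chrom, pos=pos, freq=np.where(mask, np.nan, freq),
                          mask=mask, n_calls=np.full(pos.size, 20), bulk=bulk,
                          reference_parent="P1")


def _delta(pos, delta, mask=None, chrom="Chr01"):
    pos = np.asarray(pos, dtype=np.int64)
    delta = np.asarray(delta, dtype=float)
    mask = np.zeros(pos.size, bool) if mask is None else np.asarray(mask, bool)
    return DeltaTrack(chrom=chrom, pos=pos, delta=np.where(mask, np.nan, delta), mask=mask)


# ---------------------------------------------------------------------------
# Bulk allele frequency
# ---------------------------------------------------------------------------

def _bulk_matrix(ril_calls):
    """Parents P1 (hom-ref) and P2 (hom-alt) + the given RIL calls."""
    rows = np.array([[0, 2] + list(ril_calls)], dtype=np.int8)
    samples = ["P1", "P2"] + [f"r{i}" for i in range(len(ril_calls))]
    return make_matrix(rows, samples=samples)


@pytest.mark.parametrize(
    "calls, expected",
    [
        ([0] * 20, 0.0),          # all share the reference-parent allele
        ([2] * 10 + [0] * 10, 0.5),  # equal parental contribution
        ([2] * 20, 1.0),          # all carry the other parent's allele
        ([0] * 19 + [1], 0.025),  # one heterozygote counts half
    ],
)
def test_bulk_frequency_anchor_values(calls, expected):
    G = _bulk_matrix(calls)
    track = bulk_frequency(G, [f"r{i}" for i in range(20)], "P1")["Chr01"]
    assert track.freq[0] == pytest.approx(expected)


def test_bulk_frequency_relative_to_chosen_reference():
    G = _bulk_matrix([2] * 15 + [0] * 5)
    f1 = bulk_frequency(G, [f"r{i}" for i in range(20)], "P1")["Chr01"].freq[0]
    f2 = bulk_frequency(G, [f"r{i}" for i in range(20)], "P2")["Chr01"].freq[0]
    assert f1 == pytest.approx(0.75) and f2 == pytest.approx(0.25)


def test_bulk_frequency_masks_low_call_loci_and_uses_called_denominator():
    G = _bulk_matrix([2] * 8 + [0] * 8 + [-1] * 4)  # 16 of 20 called
    track = bulk_frequency(G, [f"r{i}" for i in range(20)], "P1", min_calls=15)["Chr01"]
    assert not track.mask[0] and track.freq[0] == pytest.approx(0.5)
    track2 = bulk_frequency(G, [f"r{i}" for i in range(20)], "P1", min_calls=17)["Chr01"]
    assert track2.mask[0] and np.isnan(track2.freq[0])


def test_bulk_frequency_requires_clean_reference_parent():
    rows = np.array([[1, 2, 0, 0]], dtype=np.int8)
    G = make_matrix(rows, samples=["P1", "P2", "r0", "r1"])
    with pytest.raises(ValueError, match="reference parent"):
        bulk_frequency(G, ["r0", "r1"], "P1")


# ---------------------------------------------------------------------------
# Delta track
# ---------------------------------------------------------------------------

def test_delta_basic_and_low_frequency_filter():
    pos = [1000, 2000, 3000]
    high = _freq_track(pos, [0.6, 1.0, 0.2])
    low = _freq_track(pos, [0.6, 0.0, 0.1], bulk="low")
    d = delta_track(high, low, min_freq=0.3)
    assert d.delta[0] == pytest.approx(0.0)
    assert d.delta[1] == pytest.approx(1.0) and not d.mask[1]  # extreme contrast kept
    assert d.mask[2]  # both bulks <= 0.3 -> masked


def test_delta_requires_matching_loci():
    high = _freq_track([1000, 2000], [0.5, 0.5])
    low = _freq_track([1000, 3000], [0.5, 0.5], bulk="low")
    with pytest.raises(ValueError, match="share loci"):
        delta_track(high, low)


# ---------------------------------------------------------------------------
# Sliding windows
# ---------------------------------------------------------------------------

def test_window_enumeration_matches_published_convention():
    # width 2 Mbp, step 10 kbp: first window starts at 1, second at 10,001
    d = _delta([5_000_000], [0.4])
    w = sliding_window_mean(d, 2_000_000, 10_000, chrom_length=6_000_000)
    assert w.start[0] == 1 and w.start[1] == 10_001
    assert w.end[0] == 2_000_000  # inclusive endpoint, exact width
    assert np.all(w.end - w.start + 1 == 2_000_000)


def test_single_locus_mean_in_every_containing_window():
    d = _delta([5_000_000], [0.4])
    w = sliding_window_mean(d, 2_000_000, 10_000, chrom_length=8_000_000)
    contains = (w.start <= 5_000_000) & (w.end >= 5_000_000)
    assert np.all(w.mean[contains] == pytest.approx(0.4))
    assert np.all(np.isnan(w.mean[~contains]))
    assert np.all(w.count[~contains] == 0)


def brute_force_windows(pos, delta, mask, width, step, end):
    starts, means, counts = [], [], []
    s = 1
    while s <= end:
        in_w = [(p >= s) and (p <= s + width - 1) and not m for p, m in zip(pos, mask)]
        vals = [d for d, keep in zip(delta, in_w) if keep]
        starts.append(s)
        counts.append(len(vals))
        means.append(np.mean(vals) if vals else np.nan)
        s += step
    return np.array(starts), np.array(means), np.array(counts)


@pytest.mark.parametrize("seed", range(5))
def test_windows_match_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(5, 80)
    pos = np.sort(rng.choice(np.arange(1, 500_000), size=n, replace=False))
    delta = rng.uniform(-1, 1, n)
    mask = rng.random(n) < 0.2
    d = _delta(pos, delta, mask)
    width, step = int(rng.integers(10_000, 120_000)), int(rng.integers(2_000, 30_000))
    w = sliding_window_mean(d, width, step, chrom_length=500_000)
    starts, means, counts = brute_force_windows(pos, delta, mask, width, step, 500_000)
    assert np.array_equal(w.start, starts)
    assert np.array_equal(w.count, counts)
    np.testing.assert_allclose(w.mean, means, rtol=0, atol=1e-12)


def test_empty_chromosome_yields_empty_track():
    d = _delta([], [])
    w = sliding_window_mean(d)
    assert w.start.size == 0


# ---------------------------------------------------------------------------
# Chromosome threshold
# ---------------------------------------------------------------------------

def test_threshold_sigma_zero_equals_abs_mean():
    d = _delta([1, 2, 3, 4], [0.2, 0.2, 0.2, 0.2])
    thr = chromosome_threshold(d)
    assert thr.sd == 0.0 and thr.upper == pytest.approx(0.2)


def test_threshold_t_large_df_matches_normal_quantile():
    d = _delta(np.arange(1, 100_002), np.random.default_rng(0).normal(0, 0.1, 100_001))
    thr = chromosome_threshold(d, confidence=0.999)
    assert thr.t == pytest.approx(stats.norm.ppf(0.9995), abs=1e-3)


def test_threshold_hand_computation():
    vals = np.array([0.1, -0.1, 0.3, -0.3])
    d = _delta([10, 20, 30, 40], vals)
    thr = chromosome_threshold(d, confidence=0.999)
    sd = np.sqrt(((vals - vals.mean()) ** 2).sum() / 3)
    t = stats.t.ppf(0.9995, 3)
    assert thr.mean_abs == pytest.approx(0.0)
    assert thr.sd == pytest.approx(sd)
    assert thr.upper == pytest.approx(0.0 + t * sd / 2.0)


def test_threshold_needs_two_loci():
    with pytest.raises(ValueError, match=">= 2"):
        chromosome_threshold(_delta([1], [0.1]))


# ---------------------------------------------------------------------------
# Region calling
# ---------------------------------------------------------------------------

def _planted_fixture(rng, block_delta=0.5, alternate=False):
    """1,200 loci at 10 kb spacing; loci 500-699 form a planted block."""
    n = 1200
    pos = np.arange(1, n + 1) * 10_000
    delta = rng.normal(0, 0.05, n)
    block = slice(500, 700)
    if alternate:
        delta[block] = np.where(np.arange(500, 700) % 2 == 0, block_delta, 0.0)
    else:
        delta[block] = block_delta
    d = _delta(pos, delta)
    w = sliding_window_mean(d, 2_000_000, 10_000, chrom_length=int(pos[-1]))
    thr = chromosome_threshold(d)
    return d, w, thr, pos, block


def test_flat_track_calls_no_regions():
    rng = np.random.default_rng(1)
    pos = np.arange(1, 501) * 10_000
    d = _delta(pos, np.full(500, 0.01) + rng.normal(0, 0.001, 500))
    w = sliding_window_mean(d, 2_000_000, 10_000, chrom_length=int(pos[-1]))
    thr = chromosome_threshold(d)
    assert call_regions(d, w, thr) == []


def test_planted_block_called_exactly_once():
    rng = np.random.default_rng(2)
    d, w, thr, pos, block = _planted_fixture(rng)
    regions = call_regions(d, w, thr)
    assert len(regions) == 1
    r = regions[0]
    assert pos[block][0] >= r.start_bp - 2_000_000 and pos[block][-1] <= r.end_bp + 2_000_000
    assert r.start_bp >= pos[block.start - 30] and r.end_bp <= pos[min(block.stop + 30, 1199)]
    assert r.sign == 1
    assert r.length_bp == r.end_bp - r.start_bp
    assert r.beyond_fraction >= 0.8 and r.n_beyond >= 10
    assert 0 <= r.mean_abs_delta <= 1


def test_interspersed_block_rejected_as_noise():
    rng = np.random.default_rng(3)
    d, w, thr, pos, block = _planted_fixture(rng, alternate=True)
    regions = call_regions(d, w, thr, min_beyond_fraction=0.8)
    assert regions == []
    # but permissive fraction would call it
    relaxed = call_regions(d, w, thr, min_beyond_fraction=0.4)
    assert len(relaxed) >= 1


def test_region_boundaries_are_first_and_last_beyond_snps():
    rng = np.random.default_rng(4)
    d, w, thr, pos, block = _planted_fixture(rng)
    r = call_regions(d, w, thr)[0]
    beyond = np.abs(d.delta) > thr.upper
    in_span = (pos >= r.start_bp) & (pos <= r.end_bp)
    assert beyond[np.searchsorted(pos, r.start_bp)]
    assert beyond[np.searchsorted(pos, r.end_bp)]


def test_swapping_bulks_is_antisymmetric():
    """Negated delta: same |delta|, thresholds and region boundaries, with
    flipped peak/trough sign."""
    rng = np.random.default_rng(5)
    d, w, thr, pos, block = _planted_fixture(rng)
    d_neg = _delta(pos, -d.delta)
    w_neg = sliding_window_mean(d_neg, 2_000_000, 10_000, chrom_length=int(pos[-1]))
    thr_neg = chromosome_threshold(d_neg)
    assert thr_neg.upper == pytest.approx(thr.upper)
    regs = call_regions(d, w, thr)
    regs_neg = call_regions(d_neg, w_neg, thr_neg)
    assert len(regs) == len(regs_neg) == 1
    assert regs[0].start_bp == regs_neg[0].start_bp
    assert regs[0].end_bp == regs_neg[0].end_bp
    assert regs[0].mean_abs_delta == pytest.approx(regs_neg[0].mean_abs_delta)
    assert regs[0].sign == -regs_neg[0].sign


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_scan_invariants_on_random_tracks(seed):
    rng = np.random.default_rng(seed)
    n = 100
    pos = np.sort(rng.choice(np.arange(1, 10_000_000), size=n, replace=False))
    high = _freq_track(pos, rng.uniform(0, 1, n))
    low = _freq_track(pos, rng.uniform(0, 1, n), bulk="low")
    d, w, thr, regions = scan_chromosome(high, low, width_bp=1_000_000, step_bp=100_000)
    ok = ~d.mask
    if ok.any():
        assert np.nanmax(np.abs(d.delta[ok])) <= 1.0
    if thr is not None:
        assert thr.upper >= thr.mean_abs >= 0
    for r in regions:
        assert r.start_bp <= r.end_bp
        assert r.length_bp == r.end_bp - r.start_bp
        assert 0 <= r.mean_abs_delta <= 1
        assert 0 <= r.beyond_fraction <= 1


# ---------------------------------------------------------------------------
# PVE
# ---------------------------------------------------------------------------

def _pve_setup(y_from_x):
    rng = np.random.default_rng(6)
    n = 60
    calls = rng.choice([0, 2], size=n)
    rows = np.array([[0, 2] + list(calls)], dtype=np.int8)
    rils = [f"r{i}" for i in range(n)]
    G = make_matrix(rows, samples=["P1", "P2"] + rils)
    x = calls / 2.0
    y = y_from_x(x, rng)
    gei = pd.Series(y, index=rils)
    region = CandidateRegion(population="p", trait="y", chrom="Chr01",
                             start_bp=1000, end_bp=1000, mean_abs_delta=0.5,
                             ci=0.1, sign=1, n_snps=1, n_beyond=1, beyond_fraction=1.0)
    d = _delta([1000], [0.5])
    return region, d, G, gei, rils, x, y


def test_pve_perfect_determination_is_one():
    region, d, G, gei, rils, *_ = _pve_setup(lambda x, rng: 2.0 + 3.0 * x)
    assert region_pve(region, d, G, gei, "P1", rils) == pytest.approx(1.0)


def test_pve_equals_squared_pearson_for_single_predictor():
    region, d, G, gei, rils, x, y = _pve_setup(
        lambda x, rng: x + rng.normal(0, 1.0, x.size)
    )
    pve = region_pve(region, d, G, gei, "P1", rils)
    assert pve == pytest.approx(stats.pearsonr(x, y)[0] ** 2)


def test_pve_null_is_small():
    region, d, G, gei, rils, *_ = _pve_setup(lambda x, rng: rng.normal(0, 1.0, x.size))
    assert region_pve(region, d, G, gei, "P1", rils) < 0.1


def test_pve_monomorphic_peak_reported_missing():
    n = 20
    rows = np.array([[0, 2] + [0] * n], dtype=np.int8)
    rils = [f"r{i}" for i in range(n)]
    G = make_matrix(rows, samples=["P1", "P2"] + rils)
    gei = pd.Series(np.random.default_rng(0).normal(size=n), index=rils)
    region = CandidateRegion(population="p", trait="y", chrom="Chr01",
                             start_bp=1000, end_bp=1000, mean_abs_delta=0.5,
                             ci=0.1, sign=1, n_snps=1, n_beyond=1, beyond_fraction=1.0)
    assert region_pve(region, _delta([1000], [0.5]), G, gei, "P1", rils) is None


# ---------------------------------------------------------------------------
# Cross-population validation
# ---------------------------------------------------------------------------

def _region(pop, trait, chrom, start, end):
    return CandidateRegion(population=pop, trait=trait, chrom=chrom, start_bp=start,
                           end_bp=end, mean_abs_delta=0.3, ci=0.1, sign=1,
                           n_snps=50, n_beyond=45, beyond_fraction=0.9)


def test_validation_overlap_intersection():
    a = _region("A", "protein", "Chr01", 10_000_000, 20_000_000)
    b = _region("B", "protein", "Chr01", 15_000_000, 25_000_000)
    out = validate_across_populations([a], [b])
    assert all(r.validated for r in out)
    assert a.validated_start_bp == 15_000_000 and a.validated_end_bp == 20_000_000


def test_validation_requires_same_trait():
    a = _region("A", "protein", "Chr01", 10, 20)
    b = _region("B", "lysine", "Chr01", 10, 20)
    out = validate_across_populations([a], [b])
    assert not any(r.validated for r in out)


def test_validation_disjoint_not_validated():
    a = _region("A", "protein", "Chr01", 10, 20)
    b = _region("B", "protein", "Chr01", 30, 40)
    out = validate_across_populations([a], [b])
    assert not any(r.validated for r in out)
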