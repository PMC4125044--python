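"""Dispersion summaries, Ansari-Bradley and F tests, site occupancy."""
import itertools

import numpy as np
import pytest
from scipy import stats as sstats

from divplane import colocstats
from divplane.localize import LocalizationRecord


def _records(dx_n, dx_z, dx_m=None, length=4.0):
    recs = []
    for i in range(len(dx_n)):
        recs.append(
            LocalizationRecord(
                length=length,
                dx_n=dx_n[i],
                dx_z=dx_z[i],
                dx_matp=np.nan if dx_m is None else dx_m[i],
                nucleoid_class="compact",
                ring_class="central",
                n_nucleoids=1,
                n_rings=1,
                cell_id=i,
            )
        )
    return recs


# -- coloc summary ----------------------------------------------------------

def test_perfect_colocalization_gives_zero_sigma_and_unit_r2():
    rng = np.random.default_rng(0)
    dx = rng.normal(0, 0.15, 200)
    s = colocstats.coloc_summary(_records(dx, dx.copy()))
    assert s.sigma_zn_nm == pytest.approx(0.0, abs=1e-9)
    assert s.r_squared == pytest.approx(1.0, abs=1e-12)


def test_sigma_and_r2_match_closed_form():
    rng = np.random.default_rng(1)
    n = 1000
    dx_n = rng.normal(0, 0.150, n)
    dx_z = dx_n + rng.normal(0, 0.045, n)
    s = colocstats.coloc_summary(_records(dx_n, dx_z))
    assert s.n == n
    assert s.sigma_zn_nm == pytest.approx(45.0, abs=5.0)
    expected_r2 = 1.0 - 45.0**2 / (150.0**2 + 45.0**2)
    assert s.r_squared == pytest.approx(expected_r2, abs=0.02)


def test_independent_displacements_give_nonpositive_r2_in_expectation():
    rng = np.random.default_rng(2)
    r2 = []
    for _ in range(50):
        dx_n = rng.normal(0, 0.15, 300)
        dx_z = rng.normal(0, 0.15, 300)
        r2.append(colocstats.coloc_summary(_records(dx_n, dx_z)).r_squared)
    assert np.mean(r2) < 0.0


def test_summary_invariant_under_origin_shift_and_equivariant_under_mirror():
    rng = np.random.default_rng(3)
    dx_n = rng.normal(0, 0.15, 400)
    dx_z = dx_n + rng.normal(0, 0.05, 400)
    base = colocstats.coloc_summary(_records(dx_n, dx_z))
    mirrored = colocstats.coloc_summary(_records(-dx_n, -dx_z))
    assert mirrored.sigma_zn_nm == pytest.approx(base.sigma_zn_nm)
    assert mirrored.r_squared == pytest.approx(base.r_squared)


def test_small_subset_flagged_low_power():
    rng = np.random.default_rng(4)
    dx = rng.normal(0, 0.1, 5)
    s = colocstats.coloc_summary(_records(dx, dx + 0.01))
    assert s.low_power


def test_sigma_recovery_across_dispersion_regimes():
    """Sample SDs track generative sigma within 15% at n = 500."""
    rng = np.random.default_rng(5)
    for sigma_nm in (40.0, 56.0, 150.0, 344.0):
        dx_n = rng.normal(0, 0.150, 500)
        dx_z = dx_n + rng.normal(0, sigma_nm / 1000.0, 500)
        s = colocstats.coloc_summary(_records(dx_n, dx_z, length=6.0))
        assert s.sigma_zn_nm == pytest.approx(sigma_nm, rel=0.15)


# -- Ansari-Bradley ---------------------------------------------------------

def test_identical_samples_are_not_less_dispersed():
    rng = np.random.default_rng(6)
    x = rng.normal(0, 1, 12)
    res = colocstats.ansari_bradley(x, x.copy())
    assert res.pvalue >= 0.5


def test_statistic_matches_reference_implementation():
    rng = np.random.default_rng(7)
    for _ in range(5):
        a = rng.normal(0, 1, rng.integers(6, 15))
        b = rng.normal(0, 2, rng.integers(6, 15))
        ours = colocstats.ansari_bradley(a, b, center=False)
        ref = sstats.ansari(a, b)
        assert ours.statistic == pytest.approx(ref.statistic)


def test_exact_p_equals_brute_force_enumeration():
    """Full C(12,6) enumeration, written out independently here."""
    rng = np.random.default_rng(8)
    a, b = rng.normal(0, 1, 6), rng.normal(0, 1.8, 6)
    res = colocstats.ansari_bradley(a, b, center=False, exact=True)
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled)
    n = len(pooled)
    scores = np.empty(n)
    for rank, idx in enumerate(order, start=1):
        scores[idx] = min(rank, n + 1 - rank)
    observed = scores[:6].sum()
    hits = sum(
        scores[list(comb)].sum() >= observed - 1e-12
        for comb in itertools.combinations(range(n), 6)
    )
    assert res.pvalue == pytest.approx(hits / 924)


def test_exact_and_normal_p_agree_at_crossover():
    rng = np.random.default_rng(9)
    diffs = []
    for _ in range(20):
        a, b = rng.normal(0, 1, 10), rng.normal(0, 1.5, 10)
        pe = colocstats.ansari_bradley(a, b, exact=True).pvalue
        pn = colocstats.ansari_bradley(a, b, exact=False).pvalue
        diffs.append(abs(pe - pn))
    assert np.mean(diffs) < 0.01
    assert max(diffs) < 0.03


def test_less_dispersed_sample_rejects():
    rng = np.random.default_rng(10)
    a = rng.normal(0, 0.4, 60)
    b = rng.normal(0, 1.0, 60)
    assert colocstats.ansari_bradley(a, b).pvalue < 0.01
    assert colocstats.ansari_bradley(
        b, a, alternative="greater_dispersed"
    ).pvalue < 0.01


def test_degenerate_identical_values_give_p_one():
    res = colocstats.ansari_bradley([1.0] * 6, [1.0] * 6)
    assert res.degenerate
    assert res.pvalue == 1.0


def test_type_one_error_near_nominal():
    rng = np.random.default_rng(11)
    n_rej = 0
    n_sim = 2000
    for _ in range(n_sim):
        x, y = rng.normal(0, 1, 40), rng.normal(0, 1, 40)
        if colocstats.ansari_bradley(x, y).pvalue < 0.05:
            n_rej += 1
    rate = n_rej / n_sim
    assert 0.03 <= rate <= 0.07  # 2000-rep screen; full check at 10^4 reps


# -- F test -----------------------------------------------------------------

def test_f_statistic_unity_on_identical_samples():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    res = colocstats.variance_f_test(x, x.copy())
    assert res.statistic == pytest.approx(1.0)


def test_f_test_matches_f_distribution():
    rng = np.random.default_rng(12)
    a, b = rng.normal(0, 1, 30), rng.normal(0, 1, 25)
    res = colocstats.variance_f_test(a, b, alternative="greater")
    expected = sstats.f(29, 24).sf(a.var(ddof=1) / b.var(ddof=1))
    assert res.pvalue == pytest.approx(expected)


def test_f_test_power_at_variance_ratio_four():
    rng = np.random.default_rng(13)
    hits = 0
    for _ in range(200):
        a = rng.normal(0, 2, 100)
        b = rng.normal(0, 1, 100)
        if colocstats.variance_f_test(a, b, alternative="greater").pvalue < 1e-3:
            hits += 1
    assert hits >= 198


def test_zero_denominator_variance_flagged():
    res = colocstats.variance_f_test([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
    assert res.degenerate
    assert np.isinf(res.statistic)
    assert res.pvalue == 0.0


# -- site occupancy ---------------------------------------------------------

def _multi_record(centers, rings, cell_id=0, length=8.0):
    return LocalizationRecord(
        length=length,
        n_nucleoids=len(centers),
        nucleoid_centers=list(centers),
        ring_centers=list(rings),
        n_rings=len(rings),
        cell_id=cell_id,
    )


def test_full_n_occupancy_and_empty_o():
    recs = [
        _multi_record([-1.6, 1.6], [-1.6, 1.6], cell_id=i) for i in range(30)
    ]
    table = colocstats.site_occupancy(recs)
    assert table.frequency["N"] == 1.0
    assert table.frequency["O"] == 0.0


def test_zero_tolerance_empties_occupancy():
    recs = [
        _multi_record([-1.6, 1.6], [-1.58, 1.62], cell_id=i)
        for i in range(20)
    ]
    table = colocstats.site_occupancy(recs, tolerance=1e-9)
    assert table.frequency["N"] == 0.0
    assert table.frequency["O"] == 0.0


def test_overlapping_nucleoids_excluded():
    recs = [_multi_record([-0.2, 0.2], [0.0])] * 5 + [
        _multi_record([-1.6, 1.6], [-1.6], cell_id=9)
    ]
    table = colocstats.site_occupancy(recs)
    assert table.n_excluded == 5
    assert table.n_cells == 1


def test_replicate_sds_reported():
    rng = np.random.default_rng(14)
    recs = []
    for i in range(150):
        rings = []
        if rng.random() < 0.98:
            rings.append(-1.6 + rng.normal(0, 0.03))
        if rng.random() < 0.59:
            rings.append(0.0 + rng.normal(0, 0.03))
        if rng.random() < 0.98:
            rings.append(1.6 + rng.normal(0, 0.03))
        recs.append(_multi_record([-1.6, 1.6], rings, cell_id=i))
    table = colocstats.site_occupancy(recs, n_replicates=3)
    assert len(table.replicate_frequencies["N"]) == 3
    assert abs(table.frequency["N"] - 0.98) <= 3 * np.sqrt(
        0.98 * 0.02 / 300
    )
    assert abs(table.frequency["O"] - 0.59) <= 3 * np.sqrt(
        0.59 * 0.41 / 150
    )
    assert np.isfinite(table.sd["N"]) and np.isfinite(table.sd["O"])
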