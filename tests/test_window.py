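"""Windowed DMR statistics: site tests, summaries, donor stratification."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycometh.simulate import (
    WgbsSimConfig,
    default_islet_donors,
    simulate_wgbs_counts,
)
from glycometh.window import (
    extract_window,
    parse_window,
    site_test,
    stratify,
    summarize_window,
)


def exhaustive_mw_p(a, b):
    """Exact two-sided Mann-Whitney p by enumerating every group labeling.

    For each C(n1+n2, n1) assignment of the pooled values to the first
    group, compute the U statistic; the two-sided p is the fraction of
    assignments at least as extreme (in either tail) as observed.
    """
    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)

    def u_stat(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y)

    u_obs = u_stat(a, b)
    n2 = len(b)
    center = n1 * n2 / 2
    dev_obs = abs(u_obs - center)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if abs(u_stat(ga, gb) - center) >= dev_obs:
            count += 1
        total += 1
    return count / total


def test_site_test_two_vs_two_most_extreme():
    """Control {1,2} vs case {3,4}: 6 labelings, the observed split is one
    of the two most extreme -> two-sided p = 2/6."""
    p, tied = site_test([1, 2], [3, 4])
    assert p == pytest.approx(1 / 3)
    assert not tied


def test_site_test_identical_groups():
    p, tied = site_test([5.0, 5.0], [5.0, 5.0, 5.0])
    assert p == 1.0
    assert tied


def test_site_test_16v2_matches_exhaustive_enumeration():
    """The 16-vs-2 islet design: exact null over C(18,2) = 153 labelings."""
    rng = np.random.default_rng(0)
    ctrl = rng.normal(70, 5, size=16)
    case = rng.normal(55, 5, size=2)
    p, _ = site_test(ctrl, case)
    assert p == pytest.approx(exhaustive_mw_p(ctrl, case))
    assert p == pytest.approx(2 / 153)      # cases below every control


@given(st.data())
@settings(max_examples=40, deadline=None)
def test_site_test_matches_enumeration_small_groups(data):
    """Exact agreement with exhaustive permutation for tie-free data with
    up to 10 total donors in any group split."""
    n1 = data.draw(st.integers(1, 5))
    n2 = data.draw(st.integers(1, 5))
    vals = data.draw(st.lists(st.floats(0, 100, allow_nan=False),
                              min_size=n1 + n2, max_size=n1 + n2,
                              unique=True))
    p, tied = site_test(vals[:n1], vals[n1:])
    assert not tied
    assert p == pytest.approx(exhaustive_mw_p(vals[:n1], vals[n1:]))


def _matrix(control_cols, case_cols, rows):
    donors = list(control_cols) + list(case_cols)
    idx = pd.MultiIndex.from_tuples([(100 + i, "+") for i in range(len(rows))],
                                    names=["pos", "strand"])
    return pd.DataFrame(rows, index=idx, columns=donors)


def test_summarize_window_counts_and_change():
    rng = np.random.default_rng(1)
    controls = [f"c{i}" for i in range(6)]
    cases = [f"t{i}" for i in range(6)]
    rows = []
    for _ in range(10):
        rows.append(np.concatenate([rng.normal(70, 1, 6), rng.normal(50, 1, 6)]))
    for _ in range(5):
        rows.append(np.concatenate([rng.normal(50, 1, 6), rng.normal(70, 1, 6)]))
    mat = _matrix(controls, cases, rows)
    s = summarize_window(mat, (controls, cases), seed=0)
    assert s.n_sites == 15
    assert s.increased_dmps == 10
    assert s.decreased_dmps == 5
    assert s.increased_dmps + s.decreased_dmps + s.ties == s.n_sites
    assert s.sdmp_count <= s.n_sites
    assert s.sdmp_count == 15            # 20-point separation at sd 1
    expected = (10 * 20 + 5 * (-20)) / 15
    assert s.mean_change_sdmp == pytest.approx(expected, abs=1.5)


def test_summarize_window_sign_flip():
    """Swapping the two groups negates changes and swaps the direction
    tallies; p-values are unchanged."""
    rng = np.random.default_rng(2)
    controls = [f"c{i}" for i in range(5)]
    cases = [f"t{i}" for i in range(4)]
    rows = [np.concatenate([rng.normal(60, 5, 5), rng.normal(55, 5, 4)])
            for _ in range(12)]
    mat = _matrix(controls, cases, rows)
    fwd = summarize_window(mat, (controls, cases), seed=0)
    rev = summarize_window(mat, (cases, controls), seed=0)
    assert rev.increased_dmps == fwd.decreased_dmps
    assert rev.decreased_dmps == fwd.increased_dmps
    assert np.allclose(rev.per_site["p"], fwd.per_site["p"])
    assert np.allclose(rev.per_site["change"], -fwd.per_site["change"])
    if fwd.sdmp_count:
        assert rev.mean_change_sdmp == pytest.approx(-fwd.mean_change_sdmp)


def test_summarize_window_invariant_to_orderings():
    rng = np.random.default_rng(3)
    controls = [f"c{i}" for i in range(5)]
    cases = [f"t{i}" for i in range(3)]
    rows = [np.concatenate([rng.normal(60, 8, 5), rng.normal(50, 8, 3)])
            for _ in range(9)]
    mat = _matrix(controls, cases, rows)
    base = summarize_window(mat, (controls, cases), seed=4)
    shuffled = mat.iloc[::-1]                      # site order reversed
    s2 = summarize_window(shuffled, (controls, cases), seed=4)
    assert s2.sdmp_count == base.sdmp_count
    assert s2.increased_dmps == base.increased_dmps
    if base.sdmp_count:
        assert s2.mean_change_sdmp == pytest.approx(base.mean_change_sdmp)


def test_summarize_window_single_nonsignificant_site():
    mat = _matrix(["c0", "c1"], ["t0", "t1"],
                  [np.array([60.0, 61.0, 60.5, 59.5])])
    s = summarize_window(mat, (["c0", "c1"], ["t0", "t1"]), seed=0)
    assert s.sdmp_count == 0
    assert math.isnan(s.mean_change_sdmp)
    assert math.isnan(s.ci_low)


def test_summarize_window_missing_cells_use_available_donors():
    rng = np.random.default_rng(5)
    controls, cases = ["c0", "c1", "c2"], ["t0", "t1"]
    rows = [np.concatenate([rng.normal(70, 2, 3), rng.normal(50, 2, 2)])
            for _ in range(4)]
    mat = _matrix(controls, cases, rows)
    mat.iloc[0, 0] = np.nan                        # one missing control value
    mat.iloc[1, 3] = np.nan
    mat.iloc[1, 4] = np.nan                        # site 1 loses all cases
    s = summarize_window(mat, (controls, cases), seed=0)
    assert s.n_sites == 3                          # site 1 excluded entirely


def test_extract_window_both_strands_and_reliability(islet_wgbs_study):
    config, tables, donors, truth = islet_wgbs_study
    first = int(truth["pos"].iloc[0])
    mat = extract_window(tables, config.chrom, first, first + 1)
    assert set(mat.index) == {(first, "+"), (first + 1, "-")}
    # percent scale
    assert np.nanmax(mat.to_numpy()) <= 100.0
    # only reliable calls (eff_ct > 10) enter the matrix
    donor0 = donors["donor_id"].iloc[0]
    raw = tables[donor0]
    low = raw[raw["eff_ct"] <= 10]
    full = extract_window(tables, config.chrom, config.start, config.end)
    for _, row in low.iterrows():
        key = (row["pos"], row["strand"])
        if key in full.index:
            assert np.isnan(full.loc[key, donor0])


def test_extract_window_degenerate_single_position(islet_wgbs_study):
    config, tables, _, truth = islet_wgbs_study
    pos = int(truth["pos"].iloc[3])
    mat = extract_window(tables, config.chrom, pos, pos)
    assert all(ix[0] == pos for ix in mat.index)


def test_extract_window_rejects_bad_bounds(islet_wgbs_study):
    config, tables, _, _ = islet_wgbs_study
    with pytest.raises(ValueError, match="exceeds end"):
        extract_window(tables, config.chrom, 100, 50)
    with pytest.raises(ValueError, match="no reliable calls"):
        extract_window(tables, "chrNOPE", 1, 100)


def test_stratify_islet_cohort():
    donors = default_islet_donors()
    ctrl, case = stratify(donors, "t2d")
    assert (len(ctrl), len(case)) == (16, 2)
    young, old = stratify(donors, "age")
    assert (len(young), len(old)) == (5, 13)
    males, females = stratify(donors, "sex")
    assert (len(males), len(females)) == (8, 10)
    m_ctrl, m_case = stratify(donors, "t2d_sex_matched")
    assert (len(m_ctrl), len(m_case)) == (6, 2)
    assert set(m_case).issubset(set(males))


def test_stratify_age_boundary_goes_to_old():
    donors = pd.DataFrame({"donor_id": ["a", "b"], "age": [40, 39],
                           "sex": ["male", "male"], "t2d": [False, False]})
    young, old = stratify(donors, "age")
    assert young == ["b"] and old == ["a"]


def test_stratify_sex_matched_mixed_cases_error():
    donors = pd.DataFrame({"donor_id": ["a", "b", "c"],
                           "age": [50, 60, 55],
                           "sex": ["male", "female", "male"],
                           "t2d": [True, True, False]})
    with pytest.raises(ValueError, match="mixed sex"):
        stratify(donors, "t2d_sex_matched")


def test_parse_window_forms():
    assert parse_window("chr17:55479635-55489635") == ("chr17", 55479635, 55489635)
    assert parse_window("chr17:55484635+-5000") == ("chr17", 55479635, 55489635)
    with pytest.raises(ValueError):
        parse_window("chr17")


def test_planted_islet_contrast_recovered(islet_wgbs_study):
    """A uniform 16-point control-minus-case difference is recovered by the
    window's mean change over all sites; the sDMP-conditional mean is
    reported alongside and is no smaller."""
    config, tables, donors, _ = islet_wgbs_study
    controls, cases = stratify(donors, "t2d")
    mat = extract_window(tables, config.chrom, config.start, config.end)
    s = summarize_window(mat, (controls, cases), seed=1)
    assert s.mean_change_all == pytest.approx(16.0, abs=3.0)
    assert s.sdmp_count > 0
    assert s.mean_change_sdmp >= s.mean_change_all - 1.0
    assert s.ci_low <= s.ci_high


def test_null_window_sdmp_rate_near_alpha():
    """With no planted difference and balanced groups the sDMP rate sits
    near the nominal 5% level."""
    rates = []
    donors = pd.DataFrame({
        "donor_id": [f"d{i:02d}" for i in range(18)],
        "age": [50] * 18,
        "sex": ["male"] * 18,
        "t2d": [False] * 9 + [True] * 9,
    })
    for seed in range(6):
        cfg = WgbsSimConfig(start=55479635, end=55482635, planted_delta=0.0,
                            donors=donors, seed=seed)
        tables, meta, _ = simulate_wgbs_counts(cfg)
        controls, cases = stratify(meta, "t2d")
        mat = extract_window(tables, cfg.chrom, cfg.start, cfg.end)
        s = summarize_window(mat, (controls, cases), seed=seed, n_boot=50)
        rates.append(s.sdmp_count / s.n_sites)
    assert np.mean(rates) == pytest.approx(0.05, abs=0.02)
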