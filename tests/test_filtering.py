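"""Zygosity calling and the site/sample filter chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvpopgen.config import Config
from pvpopgen.dataset import AMBIGUOUS, HET, HOM_ALT, HOM_REF, MISSING
from pvpopgen.filtering import (apply_sample_filter, apply_site_filters,
                                call_genotype_state, call_genotype_states,
                                filter_dataset)

from conftest import make_dataset


@pytest.mark.parametrize("fraction,expected", [
    (0.10, HOM_REF),
    (0.249, HOM_REF),
    (0.90, HOM_ALT),
    (0.751, HOM_ALT),
    (0.50, HET),
    (0.40, HET),
    (0.60, HET),
    (0.30, AMBIGUOUS),
    (0.25, AMBIGUOUS),     # boundary: homozygous intervals are strict
    (0.75, AMBIGUOUS),
    (0.65, AMBIGUOUS),
    (float("nan"), MISSING),
])
def test_zygosity_rule(fraction, expected):
    assert call_genotype_state(fraction) == expected


def test_zygosity_rejects_out_of_range():
    with pytest.raises(ValueError):
        call_genotype_state(1.2)


@given(st.floats(min_value=0.0, max_value=1.0))
@settings(deadline=None, max_examples=200)
def test_zygosity_partitions_unit_interval(f):
    """Every fraction in [0,1] receives exactly one defined state."""
    state = call_genotype_state(f)
    assert state in (HOM_REF, HOM_ALT, HET, AMBIGUOUS)
    # interval membership is mutually consistent with the rule
    if f < 0.25:
        assert state == HOM_REF
    elif f > 0.75:
        assert state == HOM_ALT
    elif 0.40 <= f <= 0.60:
        assert state == HET
    else:
        assert state == AMBIGUOUS


def test_adjacent_run_removed_entirely():
    """Two SNPs at consecutive positions are both discarded."""
    depth = np.full((4, 6), 20)
    frac = np.tile([0.0, 0.5, 1.0, 0.5], (6, 1)).T
    ds = make_dataset(depth, frac)
    ds.loci.loc[2, "position"] = 100
    ds.loci.loc[3, "position"] = 101
    out, report = apply_site_filters(ds)
    assert report.n_adjacent_removed == 2
    assert out.n_loci == 4
    assert 100 not in out.loci["position"].values
    assert 101 not in out.loci["position"].values


def test_maf_filter_removes_rare_alternate():
    depth = np.full((12, 2), 30)
    frac = np.zeros((12, 2))
    frac[0, 0] = 0.5            # alt frequency 0.042 < 0.05 at site 0
    frac[:3, 1] = 1.0           # alt frequency 0.25 at site 1
    ds = make_dataset(depth, frac)
    out, report = apply_site_filters(ds)
    assert report.n_maf_removed == 1
    assert out.n_loci == 1
    assert out.loci["position"].iloc[0] == 20


def test_depth_masking_and_missingness():
    """Calls below depth 3 become missing; sites >= 20% missing are dropped."""
    depth = np.full((10, 3), 30)
    depth[:3, 0] = 2            # 30% of calls at site 0 under-covered
    frac = np.tile([0.5, 0.5, 0.4], (10, 1))
    ds = make_dataset(depth, frac)
    out, report = apply_site_filters(ds)
    assert report.n_depth_masked_calls == 3
    assert report.n_missingness_removed == 1
    assert out.n_loci == 2


def test_report_counts_match_brute_force():
    """Each rule's casualty count matches independently re-applying that
    rule to the dataset as it stood when the rule ran."""
    rng = np.random.default_rng(0)
    n, m = 10, 10
    depth = rng.integers(0, 40, size=(n, m))
    frac = rng.random((n, m))
    ds = make_dataset(depth, frac)
    ds.loci.loc[4, "position"] = 200
    ds.loci.loc[5, "position"] = 201
    cfg = Config()
    out, report = apply_site_filters(ds, cfg)

    # brute force, in the documented order
    alive = np.ones(m, bool)
    pos = ds.loci["position"].to_numpy()
    adjacent = np.zeros(m, bool)
    for a in range(m):
        for b in range(m):
            if a != b and abs(pos[a] - pos[b]) == 1:
                adjacent[a] = True
    assert report.n_adjacent_removed == int(adjacent.sum())
    alive &= ~adjacent

    d = np.where((ds.depth < cfg.min_depth), 0, ds.depth)
    f = np.where(d == 0, np.nan, ds.alt_fraction)
    called = np.zeros((n, m), bool)
    dos = np.full((n, m), np.nan)
    for i in range(n):
        for j in range(m):
            s = call_genotype_state(f[i, j] if d[i, j] > 0 else float("nan"), cfg)
            called[i, j] = s in (HOM_REF, HET, HOM_ALT)
            dos[i, j] = {HOM_REF: 0.0, HET: 0.5, HOM_ALT: 1.0}.get(s, np.nan)
    too_missing = ((~called).sum(axis=0) / n) >= cfg.max_site_missing
    assert report.n_missingness_removed == int((too_missing & alive).sum())
    alive &= ~too_missing
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dos, axis=0)
    bad = alive & ((freq < cfg.maf_lo) | (freq > cfg.maf_hi) | np.isnan(freq))
    assert report.n_maf_removed == int(bad.sum())
    alive &= ~bad
    assert report.n_retained == int(alive.sum()) == out.n_loci


def test_sample_filter_boundary():
    """0% missing retained; >30% missing removed; planted dropout found."""
    n, m = 4, 10
    depth = np.full((n, m), 30)
    depth[1, :4] = 0            # 40% missing -> removed
    depth[2, :3] = 0            # 30% missing -> retained (strict >)
    frac = np.full((n, m), 0.5)
    ds = make_dataset(depth, frac)
    ds = call_genotype_states(ds)
    out, report = apply_sample_filter(ds)
    assert report.n_samples_removed == 1
    assert report.removed_samples == ["S1"]
    assert list(out.samples.index) == ["S0", "S2", "S3"]


def test_all_samples_removed_is_an_error():
    depth = np.zeros((3, 5), int)
    depth[:, 0] = 30
    frac = np.full((3, 5), 0.5)
    ds = make_dataset(depth, frac)
    ds = call_genotype_states(ds)
    with pytest.raises(ValueError, match="missingness"):
        apply_sample_filter(ds)


def test_site_filters_idempotent():
    rng = np.random.default_rng(3)
    depth = rng.integers(0, 40, size=(12, 15))
    frac = rng.random((12, 15))
    ds = make_dataset(depth, frac)
    once, r1 = apply_site_filters(ds)
    twice, r2 = apply_site_filters(once)
    assert r2.n_retained == r1.n_retained
    assert np.array_equal(once.depth, twice.depth)
    pd.testing.assert_frame_equal(once.loci, twice.loci)


def test_planted_dropout_sample_removed(small_sim):
    ds, _, _ = small_sim
    ds = ds.copy()
    drop = ds.sample_ids[7]
    idx = list(ds.samples.index).index(drop)
    ds.depth[idx, : int(0.4 * ds.n_loci)] = 0
    ds.alt_fraction[idx, : int(0.4 * ds.n_loci)] = np.nan
    ds.alt2_fraction[idx, : int(0.4 * ds.n_loci)] = np.nan
    _, report = filter_dataset(ds)
    assert drop in report.removed_samples
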