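"""Quantification: assignment, rarefaction, ALR, loads, gmAFD, BF ratios."""

import math

import numpy as np
import pandas as pd
import pytest

from mimicspike.quantify import (AmbiguousAssignmentError, CountTable,
                                 LoadEstimate, QuantError, SampleSpike,
                                 SpikeConfig, alr_transform, assign_features,
                                 bf_ratio, differential_load, estimate_load,
                                 gmafd, rarefy)
from mimicspike.simulate import SimScenario, simulate_counts
from oracles import random_dna


def make_table(data, seqs=None):
    return CountTable(pd.DataFrame(data), seqs)


def test_count_table_rejects_negative_and_fractional():
    with pytest.raises(QuantError):
        make_table({"s1": [-1, 2]})
    with pytest.raises(QuantError):
        CountTable(pd.DataFrame({"s1": [0.5, 1.0]}))


# -------------------------------------------------------------- assignment

@pytest.fixture(scope="module")
def mimic_panel(rng=None):
    rng = np.random.default_rng(2)
    return {f"m{i}": random_dna(rng, 250) for i in range(3)}


def test_assignment_exact_and_near_matches(mimic_panel):
    rng = np.random.default_rng(3)
    exact = mimic_panel["m0"]
    mut = list(mimic_panel["m1"])
    mut[100] = "A" if mut[100] != "A" else "C"  # one mismatch, identity 0.996
    seqs = {"f_exact": exact, "f_mut": "".join(mut), "f_env": random_dna(rng, 250)}
    table = make_table({"s1": [10, 20, 30]}, seqs)
    table.counts.index = list(seqs)
    assign = assign_features(table, mimic_panel)
    assert assign.feature_assignments["f_exact"] == "m0"
    assert assign.feature_assignments["f_mut"] == "m1"
    assert assign.feature_assignments["f_env"] == "environmental"
    # multiple features per mimic are summed; partition is exact
    assert assign.mimic_counts["s1"].sum() + assign.env_counts["s1"] == 60


def test_assignment_ambiguity_is_an_error(mimic_panel):
    dup_panel = dict(mimic_panel)
    dup_panel["m_dup"] = mimic_panel["m0"]
    table = make_table({"s1": [5]}, {"f": mimic_panel["m0"]})
    table.counts.index = ["f"]
    with pytest.raises(AmbiguousAssignmentError):
        assign_features(table, dup_panel)


def test_partition_invariant_on_simulated_data():
    table, truth = simulate_counts(SimScenario(n_samples=3, depth=50_000, seed=4))
    panel = {m: table.feature_seqs[m] for m in truth.mimic_copies.index}
    assign = assign_features(table, panel)
    total = assign.mimic_counts.sum(axis=0) + assign.env_counts
    assert (total == table.counts.sum(axis=0)).all()


# -------------------------------------------------------------- rarefaction

def test_rarefy_full_depth_is_identity_and_seeded():
    table = make_table({"s1": [100, 200, 300], "s2": [10, 20, 30]})
    same = rarefy(table, 60, seed=1)
    assert (same.counts["s2"] == table.counts["s2"]).all()
    r1 = rarefy(table, 50, seed=9)
    r2 = rarefy(table, 50, seed=9)
    assert r1.counts.equals(r2.counts)
    assert (r1.counts.sum(axis=0) == 50).all()


def test_rarefy_depth_error_names_sample():
    table = make_table({"ok": [100, 100], "small": [5, 5]})
    with pytest.raises(QuantError, match="small"):
        rarefy(table, 50, seed=0)


def test_rarefy_preserves_expected_proportions():
    """Hypergeometric expectation: mean draw = depth * proportion."""
    counts = np.array([120_000, 50_000, 20_000, 9_000, 1_000])
    table = make_table({"s1": counts})
    depth = 40_000
    reps = 300
    acc = np.zeros(len(counts))
    for seed in range(reps):
        acc += rarefy(table, depth, seed=seed).counts["s1"].to_numpy()
    mean = acc / reps
    expected = depth * counts / counts.sum()
    # MC tolerance: 5 SE of the replicate mean (hypergeometric variance bound)
    se = np.sqrt(expected * (1 - counts / counts.sum())) / np.sqrt(reps)
    assert (np.abs(mean - expected) <= 5 * np.maximum(se, 1.0)).all()


# -------------------------------------------------------------- ALR / loads

def test_alr_examples():
    assert alr_transform(1000, 10) == pytest.approx(2.0)
    assert alr_transform(7, 7) == 0.0
    with pytest.raises(QuantError):
        alr_transform(100, 0)
    assert alr_transform(100, 0, pseudocount=0.5) == pytest.approx(
        math.log10(100.5 / 0.5))


def _assignment(env, mimic, samples):
    mimics = pd.DataFrame({s: [m] for s, m in zip(samples, mimic)}, index=["mx"])
    envs = pd.Series(dict(zip(samples, env)))
    return type("A", (), {"mimic_counts": mimics, "env_counts": envs,
                          "total_counts": envs + mimics.sum(axis=0)})()


def test_estimate_load_arithmetic():
    assign = _assignment([5000], [500], ["s1"])
    spike = SpikeConfig({"s1": SampleSpike({"mx": 1e4}, sample_amount=50.0,
                                           unit="mg")})
    (load,) = estimate_load(assign, spike, reference="mx")
    assert load.absolute_load == pytest.approx(1e5)
    assert load.normalized_load == pytest.approx(2e3)  # copies per mg
    assert load.alr == pytest.approx(1.0)


def test_estimate_load_flags_low_spike_reads():
    assign = _assignment([5000, 5000], [500, 10], ["a", "b"])
    spike = SpikeConfig({s: SampleSpike({"mx": 1e4}) for s in ("a", "b")})
    loads = estimate_load(assign, spike, reference="mx", min_mimic_reads=50)
    by = {l.sample: l for l in loads}
    assert by["a"].passed_qc and not by["b"].passed_qc
    assert "low_spike_reads" in by["b"].flags
    assert math.isnan(by["b"].absolute_load)


def test_noiseless_tenfold_alr_difference_is_exact():
    """Two samples, same environmental pool, 10x spike difference."""
    assign = _assignment([100_000, 100_000], [10_000, 1_000], ["hi", "lo"])
    spike = SpikeConfig({"hi": SampleSpike({"mx": 1e5}),
                         "lo": SampleSpike({"mx": 1e4})})
    loads = estimate_load(assign, spike, reference="mx")
    alr = {l.sample: l.alr for l in loads}
    assert alr["lo"] - alr["hi"] == 1.0  # exactly log10(10)
    # equal true loads: differential of 0 once spike levels are accounted for
    d = differential_load(loads)
    assert (d["delta_log10_load"] == 0.0).all()


def test_differential_load_antisymmetry_and_reference_check():
    assign = _assignment([8000, 2000], [400, 100], ["a", "b"])
    spike = SpikeConfig({"a": SampleSpike({"mx": 1e4}),
                         "b": SampleSpike({"mx": 2e4})})
    loads = estimate_load(assign, spike, reference="mx")
    d = differential_load(loads).set_index(["sample_a", "sample_b"])
    assert d.at[("a", "b"), "delta_log10_load"] == \
        -d.at[("b", "a"), "delta_log10_load"]
    other = LoadEstimate("a", "other", 1, 1, 1.0, 0.0, 1.0, 1.0, "sample")
    with pytest.raises(QuantError):
        differential_load([loads[0], other])


# -------------------------------------------------------------- gmAFD

def test_gmafd_examples_and_properties():
    assert gmafd([3.0, 5.0], [3.0, 5.0]) == 1.0
    assert gmafd([2.0, 0.5], [1.0, 1.0]) == pytest.approx(2.0)
    # exp((ln 1.2 + ln 1.5 + ln 3)/3)
    assert gmafd([1.2, 1 / 1.5, 3.0], [1.0, 1.0, 1.0]) == pytest.approx(
        math.exp((math.log(1.2) + math.log(1.5) + math.log(3.0)) / 3), rel=1e-12)
    m, e = [1.7, 0.3, 2.2], [1.1, 0.9, 2.0]
    assert gmafd(m, e) == pytest.approx(gmafd(e, m))
    # log10 and ln formulations agree
    log10_version = 10 ** np.mean(np.abs(np.log10(np.array(m) / np.array(e))))
    assert gmafd(m, e) == pytest.approx(log10_version)
    with pytest.raises(QuantError):
        gmafd([1.0, -2.0], [1.0, 1.0])


# -------------------------------------------------------------- BF ratio

def _load(sample, env, mimic, copies):
    alr = math.log10(env / mimic)
    absolute = 10 ** alr * copies
    return LoadEstimate(sample, "mx", env, mimic, copies, alr, absolute,
                        absolute, "sample")


def test_bf_ratio_cancellation_with_single_cross_domain_mimic():
    bact = _load("s", 8000, 200, 1e4)
    fung = _load("s", 1000, 500, 1e4)
    # copies cancel: (8000/200) / (1000/500) = 20
    assert bf_ratio(bact, fung) == pytest.approx(20.0)
    assert bf_ratio(fung, fung) == 1.0
    with pytest.raises(QuantError):
        bf_ratio(bact, _load("other", 1, 1, 1))


def test_per_mimic_and_aggregate_loads_agree_for_equimolar_mix():
    table, truth = simulate_counts(SimScenario(n_samples=2, depth=200_000, seed=6))
    panel = {m: table.feature_seqs[m] for m in truth.mimic_copies.index}
    assign = assign_features(table, panel)
    agg = estimate_load(assign, truth.spike, reference="aggregate")
    one = estimate_load(assign, truth.spike, reference="mimic01")
    for a, o in zip(agg, one):
        assert a.absolute_load == pytest.approx(o.absolute_load, rel=0.15)
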