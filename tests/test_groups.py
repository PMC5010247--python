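"""Group comparison statistics against enumeration and hand oracles."""

import itertools

import numpy as np
import pytest

from mutseg.consequence import ConsequenceClass, ProteinConsequence
from mutseg.groups import (
    GroupLabel,
    assign_groups,
    derive_signature,
    DifferentialResult,
    logrank_test,
    median_fold_change,
    rank_sum_test,
    sign_concordance,
    survival_by_group,
)
from mutseg.io import ClinicalRecord


def _pc(cls, frame=0):
    return ProteinConsequence(cls, frame, "p.?")


def test_assign_groups_labels():
    cons = {
        "a": _pc(ConsequenceClass.frameshift_extension, 1),
        "b": _pc(ConsequenceClass.frameshift_extension, -1),
        "c": _pc(ConsequenceClass.frameshift_truncation, 1),
        "d": _pc(ConsequenceClass.frameshift_truncation, -1),
        "e": _pc(ConsequenceClass.missense),
        "f": _pc(ConsequenceClass.no_stop, 1),
    }
    ga = assign_groups(cons)
    assert ga.labels["a"] == GroupLabel.ext_plus1
    assert ga.labels["b"] == GroupLabel.ext_minus1
    assert ga.labels["c"] == GroupLabel.trunc_plus1
    assert ga.labels["d"] == GroupLabel.trunc_minus1
    assert ga.labels["e"] == GroupLabel.other_mutant
    assert ga.labels["f"] == GroupLabel.other_mutant
    assert ga.case_samples == ["a"]
    assert set(ga.control_samples) == {"b", "c", "d", "e", "f"}


def test_assign_groups_matches_simulator_truth(sim_default):
    _, cohort, truth = sim_default
    from mutseg.consequence import classify_consequence
    from mutseg.io import single_mutation_patients
    from mutseg.transcripts import synthetic_gata3_transcript

    t = synthetic_gata3_transcript()
    singles = single_mutation_patients(cohort.mutations, "GATA3")
    ga = assign_groups({s: classify_consequence(t, m) for s, m in singles.items()})
    for s, label in ga.labels.items():
        assert label.value == truth.group_labels[s]


def enumeration_pvalue(x, y):
    """Exact two-sided rank-sum p by full enumeration of labelings."""
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = rankdata(pooled)
    obs = ranks[:n].sum()
    mu = n * (n + m + 1) / 2
    stats = []
    for idx in itertools.combinations(range(n + m), n):
        stats.append(ranks[list(idx)].sum())
    stats = np.array(stats)
    p = np.mean(np.abs(stats - mu) >= abs(obs - mu) - 1e-12)
    return p


def test_rank_sum_exact_small_sample():
    stat, p = rank_sum_test([1, 2], [3, 4])
    assert np.isclose(p, 1 / 3)
    _, p2 = rank_sum_test([3, 4], [1, 2])
    assert np.isclose(p, p2)  # symmetric


def test_rank_sum_identical_groups_p_one():
    _, p = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p == 1.0


def test_rank_sum_empty_raises():
    with pytest.raises(ValueError):
        rank_sum_test([], [1.0])


def test_rank_sum_approximation_close_to_enumeration(rng):
    """Normal approximation within 0.02 of the exact enumeration at n=10."""
    for _ in range(10):
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        p_exact = enumeration_pvalue(x, y)
        _, p_approx = rank_sum_test(x, y, exact_max_n=0)  # force approximation
        assert abs(p_approx - p_exact) <= 0.02


def test_rank_sum_exact_matches_enumeration(rng):
    for _ in range(10):
        x = rng.normal(size=4)
        y = rng.normal(size=5)
        _, p = rank_sum_test(x, y)
        assert np.isclose(p, enumeration_pvalue(x, y))


def test_rank_sum_null_uniformity(rng):
    """Under label permutation of null data, p-values are ~uniform."""
    from scipy.stats import kstest

    ps = []
    for _ in range(1000):
        z = rng.normal(size=24)
        ps.append(rank_sum_test(z[:12], z[12:])[1])
    assert kstest(ps, "uniform").pvalue > 0.001


def test_median_fold_change():
    assert median_fold_change([4, 4, 4], [2, 2, 2]) == (2.0, "up")
    assert median_fold_change([2, 2], [2, 2]) == (1.0, "flat")
    fc, d = median_fold_change([1, 1], [4, 4])
    assert fc == 0.25 and d == "down"
    assert median_fold_change([0.0], [0.0]) == (1.0, "flat")


def test_median_fold_change_recovers_known_ratio(rng):
    """Log-normal groups with true median ratio r: FC within 10% at n=200."""
    r = 2.5
    x = np.exp(rng.normal(np.log(r), 0.5, size=200))
    y = np.exp(rng.normal(0.0, 0.5, size=200))
    fc, d = median_fold_change(x, y)
    assert d == "up"
    assert abs(fc - r) / r < 0.10


def _dr(gene, p, fc=2.0, direction="up"):
    return DifferentialResult(
        gene=gene, median_case=fc, median_control=1.0,
        fold_change=fc, direction=direction, p_value=p,
    )


def test_derive_signature_ranking_and_stability():
    results = [_dr("g3", 0.03), _dr("g1", 0.01), _dr("g2", 0.01, fc=4.0)]
    sig = derive_signature(results, k=2)
    assert sig.genes == ["g2", "g1"]  # tie on p broken by |log FC|
    # invariant to input order
    sig2 = derive_signature(results[::-1], k=2)
    assert sig2.genes == sig.genes
    # k larger than available -> everything
    assert len(derive_signature(results, k=10).genes) == 3
    with pytest.raises(ValueError):
        derive_signature(results, k=0)


def test_derive_signature_finds_planted_genes(rng):
    """Planted case/control-shifted genes land in the top-k for k = 2x."""
    planted = [f"P{i}" for i in range(5)]
    nulls = [f"N{i}" for i in range(45)]
    results = []
    for g in planted + nulls:
        shift = 1.5 if g in planted else 0.0
        x = rng.normal(shift, 1, 30)
        y = rng.normal(0, 1, 30)
        _, p = rank_sum_test(x, y)
        fc, d = median_fold_change(x - x.min() + 1, y - y.min() + 1)
        results.append(_dr(g, p, fc, d))
    sig = derive_signature(results, k=10)
    assert set(planted) <= set(sig.genes)


def test_sign_concordance():
    a = [_dr("g1", 0.01), _dr("g2", 0.01, fc=0.5, direction="down"),
         _dr("g3", 0.01)]
    b = [_dr("g1", 0.2), _dr("g2", 0.2, fc=0.5, direction="down"),
         _dr("g4", 0.2)]
    assert sign_concordance(a, a) == (3, 3)
    assert sign_concordance(a, b) == (2, 2)
    b_flip = [_dr("g1", 0.2, fc=0.5, direction="down"), b[1]]
    assert sign_concordance(a, b_flip) == (2, 1)
    # flat counts as discordant unless both flat
    c = [_dr("g1", 0.5, fc=1.0, direction="flat")]
    assert sign_concordance(a, c) == (1, 0)
    assert sign_concordance(c, c) == (1, 1)


def test_sign_concordance_paired_simulation(rng):
    """Two cohorts simulated with identical effect signs agree everywhere."""
    genes = [f"G{i}" for i in range(20)]
    signs = rng.choice([1.5, -1.5], size=20)
    out = []
    for _ in range(2):
        res = []
        for g, s in zip(genes, signs):
            x = rng.normal(5 + s, 0.3, 50)
            y = rng.normal(5, 0.3, 50)
            fc, d = median_fold_change(x, y)
            res.append(_dr(g, 0.01, fc, d))
        out.append(res)
    n_shared, n_conc = sign_concordance(*out)
    assert (n_shared, n_conc) == (20, 20)


def logrank_hand_oracle(times, events, groups):
    """Hand hypergeometric O/E/V sums at each distinct event time."""
    labels = sorted(set(groups))
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    groups = np.asarray(groups)
    O = E = V = 0.0
    for t in sorted(set(times[events])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == labels[0])).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & (groups == labels[0])).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


def test_logrank_identical_groups():
    times = [1.0, 2.0, 3.0] * 2
    events = [True] * 6
    groups = ["A"] * 3 + ["B"] * 3
    res = logrank_test(times, events, groups)
    assert np.isclose(res.logrank_chi2, 0.0, atol=1e-10)
    assert np.isclose(res.p_value, 1.0)


def test_logrank_matches_hand_oracle():
    times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    events = [True] * 6
    groups = ["A", "A", "A", "B", "B", "B"]
    res = logrank_test(times, events, groups)
    expected = logrank_hand_oracle(times, events, groups)
    assert np.isclose(res.logrank_chi2, expected, rtol=1e-6)
    assert res.n_events == {"A": 3, "B": 3}


def test_logrank_group_validation():
    with pytest.raises(ValueError):
        logrank_test([1.0, 2.0], [True, True], ["A", "A"])
    with pytest.raises(ValueError):
        logrank_test([1.0, 2.0], [False, False], ["A", "B"])


def test_km_equals_empirical_survivor_without_censoring():
    times = [1.0, 2.0, 2.0, 3.0, 5.0]
    events = [True] * 5
    res = logrank_test(times + [9.0], events + [True],
                       ["A"] * 5 + ["B"])
    km = res.km_curves["A"].set_index("time")["survival"]
    n = 5
    for t in sorted(set(times)):
        empirical = np.mean(np.asarray(times) > t)
        assert np.isclose(km.loc[t], empirical)


def test_logrank_null_rejection_rate():
    """HR = 1 exponential survival rejects at ~5% when thresholded at 0.05."""
    rng = np.random.default_rng(17)
    rejections = 0
    n_rep = 400
    for _ in range(n_rep):
        times = rng.exponential(50, size=60)
        cens = rng.exponential(120, size=60)
        obs = np.minimum(times, cens)
        events = times <= cens
        groups = np.array(["A"] * 30 + ["B"] * 30)
        res = logrank_test(obs, events, groups)
        rejections += res.p_value < 0.05
    rate = rejections / n_rep
    assert 0.02 <= rate <= 0.08


def test_logrank_power_at_hazard_ratio_three():
    """HR = 3 with ~60% events at n=50/arm: p < 0.05 in >=80% of replicates."""
    rng = np.random.default_rng(23)
    hits = 0
    n_rep = 60
    for _ in range(n_rep):
        t_a = rng.exponential(1 / 0.06, size=50)  # case: hazard 3x
        t_b = rng.exponential(1 / 0.02, size=50)
        cens = rng.exponential(60, size=100)
        times = np.concatenate([t_a, t_b])
        obs = np.minimum(times, cens)
        events = times <= cens
        groups = np.array(["case"] * 50 + ["ctrl"] * 50)
        res = logrank_test(obs, events, groups)
        hits += res.p_value < 0.05
    assert hits / n_rep >= 0.8


def test_survival_by_group_routes_labels():
    from mutseg.groups import GroupAssignment

    ga = GroupAssignment(
        labels={
            "a": GroupLabel.ext_plus1, "b": GroupLabel.ext_plus1,
            "c": GroupLabel.trunc_plus1, "d": GroupLabel.other_mutant,
        }
    )
    clinical = [
        ClinicalRecord("a", 5.0, True), ClinicalRecord("b", 8.0, True),
        ClinicalRecord("c", 30.0, False), ClinicalRecord("d", 40.0, True),
        ClinicalRecord("zz", 1.0, True),  # unlabelled: excluded
    ]
    res = survival_by_group(clinical, ga)
    assert res.n_subjects == {"ext_plus1": 2, "other": 2}
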