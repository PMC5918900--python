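"""Heritability index, null model, exact expectation and the SES t test."""

import itertools

import numpy as np
import pytest
from scipy import stats

from clonalherit.heritability import (EcotypePresence, NullModelConfig,
                                      build_presence, compute_ses,
                                      exact_null_expectation, heritability_index,
                                      null_distribution, run_heritability,
                                      summarize_ecotype, EcotypeHeritability)
from clonalherit.dataset import subset_dataset

TAGS = [("D1", 1), ("D2", 1), ("D1", 2), ("D2", 2)]


def make_ep(mother, daughters, pool, ecotype=1):
    return EcotypePresence(ecotype, frozenset(mother),
                           [frozenset(d) for d in daughters],
                           TAGS[:len(daughters)], frozenset(pool))


# -- independent oracle: exhaustive enumeration of the null model ------------

def enumerate_null(ep: EcotypePresence, k: int):
    """Exact pmf of the null heritability index by enumerating every equally
    likely combination of daughter communities (uniform subsets of the pool)."""
    pool = sorted(ep.pool)
    per_daughter = [list(itertools.combinations(pool, min(r, len(pool))))
                    for r in ep.daughter_richness]
    pmf: dict[int, float] = {}
    total = np.prod([len(c) for c in per_daughter])
    for combo in itertools.product(*per_daughter):
        i = sum(1 for o in ep.mother_set
                if sum(o in set(d) for d in combo) >= k)
        pmf[i] = pmf.get(i, 0.0) + 1.0 / total
    return pmf


def test_heritability_index_direct_counts():
    ep = make_ep({"A", "B", "C"}, [{"A", "B"}, {"A"}, {"B"}, set()], {"A", "B", "C"})
    assert heritability_index(ep, 2) == 2
    assert heritability_index(ep, 1) == 2
    assert heritability_index(ep, 3) == 0
    empty = make_ep(set(), [{"A"}, {"B"}], {"A", "B"})
    assert heritability_index(empty, 2) == 0
    with pytest.raises(ValueError):
        heritability_index(make_ep({"A"}, [{"A"}], {"A"}), 2)


def test_index_monotone_in_k():
    rng = np.random.default_rng(0)
    for _ in range(20):
        pool = list(range(8))
        mother = set(rng.choice(8, 5, replace=False).tolist())
        daughters = [set(rng.choice(8, rng.integers(0, 8), replace=False).tolist())
                     for _ in range(4)]
        ep = make_ep(mother, daughters, pool)
        vals = [heritability_index(ep, k) for k in (1, 2, 3, 4)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


def test_build_presence_pools_and_sets(toy_network):
    roots = subset_dataset(toy_network, {"role": ["mother_root", "daughter_root"]})
    eps = build_presence(roots, "ecotype")
    assert len(eps) == 1
    ep = eps[0]
    assert ep.mother_set == {"o1", "o2", "o3", "o4"}
    assert ep.daughter_sets[0] == {"o1", "o2"}     # d11: stolon 1, D1
    assert ep.pool == ep.mother_set
    assert heritability_index(ep, 2) == 2          # o1 and o2 in >=2 daughters


def test_regional_pool_is_union_of_mothers(study):
    ds, truth = study
    roots = subset_dataset(ds, {"marker": "fungi_18S",
                                "role": ["mother_root", "daughter_root"]})
    eps = build_presence(roots, "regional")
    union = set().union(*(ep.mother_set for ep in eps))
    assert all(ep.pool == union for ep in eps)
    # brute-force recomputation of presence sets from the counts matrix
    for ep in eps:
        sid = f"F_E{ep.ecotype:02d}_M"
        brute = {o for o in roots.counts.columns if roots.counts.loc[sid, o] > 0}
        assert ep.mother_set == brute


def test_exact_expectation_closed_forms():
    # k=1, one daughter of richness r: expectation m*r/N
    ep = make_ep({"A", "B"}, [{"A"}], {"A", "B", "C", "D"})
    assert exact_null_expectation(ep, 1) == pytest.approx(2 * 1 / 4)
    # all daughters sample the whole pool: expectation = |mother_set|
    full = make_ep({"A", "B"}, [{"A", "B", "C"}] * 4, {"A", "B", "C"})
    for k in (1, 2, 3, 4):
        assert exact_null_expectation(full, k) == pytest.approx(2)


def test_exact_expectation_matches_enumeration():
    pool = ["a", "b", "c"]
    ep = make_ep(pool, [{"a"}, {"b"}, {"a", "c"}, set()], pool)
    pmf = enumerate_null(ep, 2)
    mean_enum = sum(v * p for v, p in pmf.items())
    assert exact_null_expectation(ep, 2) == pytest.approx(mean_enum)


def test_null_distribution_bounds_and_reproducibility():
    rng = np.random.default_rng(3)
    pool = list(range(10))
    ep = make_ep(set(rng.choice(10, 6, replace=False).tolist()),
                 [set(rng.choice(10, r, replace=False).tolist()) for r in (4, 3, 5, 2)],
                 pool)
    cfg = NullModelConfig(n_iter=2000, k_min_daughters=2, seed=42)
    d1 = null_distribution(ep, cfg)
    d2 = null_distribution(ep, cfg)
    assert np.array_equal(d1, d2)                       # bit-reproducible
    assert d1.min() >= 0 and d1.max() <= len(ep.mother_set)


def test_null_monotone_in_k_iterationwise():
    ep = make_ep(set(range(4)), [set(range(r)) for r in (2, 2, 3, 1)], set(range(6)))
    draws = {k: null_distribution(ep, NullModelConfig(500, k, seed=9)) for k in (1, 2, 3)}
    assert np.all(draws[1] >= draws[2]) and np.all(draws[2] >= draws[3])


def test_degenerate_saturated_null_excluded():
    pool = {"A", "B", "C"}
    ep = make_ep({"A", "B"}, [pool] * 4, pool)
    rec = summarize_ecotype(ep, NullModelConfig(200, 2, "ecotype", 1))
    assert rec.excluded and rec.sigma_null == 0.0 and rec.i_null == pytest.approx(2.0)


def test_monte_carlo_mean_matches_exact():
    rng = np.random.default_rng(11)
    for _ in range(5):
        n = int(rng.integers(3, 7))
        pool = list(range(n))
        mother = set(rng.choice(n, rng.integers(1, n + 1), replace=False).tolist())
        daughters = [set(rng.choice(n, rng.integers(0, n + 1), replace=False).tolist())
                     for _ in range(4)]
        ep = make_ep(mother, daughters, pool)
        draws = null_distribution(ep, NullModelConfig(9999, 2, seed=int(rng.integers(2**31))))
        exact = exact_null_expectation(ep, 2)
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - exact) <= max(3 * se, 1e-9)


def test_ses_t_test_reference_values():
    recs = [EcotypeHeritability(i, 0, 0.0, 1.0, s) for i, s in enumerate([1.0, 2.0, 3.0])]
    res = compute_ses(recs)
    assert res.t == pytest.approx(3.4641016, rel=1e-6)
    assert res.df == 2
    assert res.p_one_sided == pytest.approx(stats.t.sf(3.4641016, 2), rel=1e-6)
    assert 0.03 < res.p_one_sided < 0.04


def test_ses_zero_variance_raises():
    recs = [EcotypeHeritability(i, 5, 5.0, 1.0, 0.0) for i in range(4)]
    with pytest.raises(ValueError, match="zero variance"):
        compute_ses(recs)


def test_excluded_ecotypes_reduce_df(study):
    ds, _ = study
    roots = subset_dataset(ds, {"marker": "fungi_18S",
                                "role": ["mother_root", "daughter_root"]})
    res = run_heritability(roots, NullModelConfig(299, 2, "regional", 5))
    n_ok = sum(not r.excluded for r in res.per_ecotype)
    assert res.df == n_ok - 1
    assert len(res.per_ecotype) == 10


def test_seeded_runs_bit_reproducible(study):
    ds, _ = study
    roots = subset_dataset(ds, {"marker": "fungi_18S",
                                "role": ["mother_root", "daughter_root"]})
    cfg = NullModelConfig(199, 2, "regional", 77)
    r1 = run_heritability(roots, cfg)
    r2 = run_heritability(roots, cfg)
    assert r1.t == r2.t
    assert [a.ses for a in r1.per_ecotype] == [a.ses for a in r2.per_ecotype]
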