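"""Generator contracts: provenance of every OTU, calibration, determinism."""

import numpy as np
import pandas as pd
import pytest

from clonalherit.dataset import subset_dataset
from clonalherit.heritability import NullModelConfig, build_presence, heritability_index
from clonalherit.preprocess import remove_control_otus
from clonalherit.simulate import (MarkerConfig, SyntheticConfig, default_markers,
                                  make_fixture, simulate_dataset, simulate_read_sets,
                                  tiny_config)


def fungi_only(seed=0, **overrides):
    mc = default_markers()["fungi_18S"]
    for k, v in overrides.items():
        setattr(mc, k, v)
    return SyntheticConfig(markers={"fungi_18S": mc}, seed=seed)


def test_zero_transmission_means_empty_daughters():
    cfg = fungi_only(seed=1, transmission={ph: 0.0 for ph in
                                           default_markers()["fungi_18S"].transmission})
    ds, truth = simulate_dataset(cfg)
    daughters = subset_dataset(ds, {"role": "daughter_root"}, allow_empty=True,
                               drop_empty_otus=False)
    assert daughters.counts.to_numpy().sum() == 0


def test_zero_occupancy_makes_controls_empty_and_decontamination_noop():
    cfg = fungi_only(seed=2, control_occupancy=0.0, contaminant_root_rate=0.0)
    ds, _ = simulate_dataset(cfg)
    ctrl = subset_dataset(ds, {"role": "control_substrate"}, allow_empty=True,
                          drop_empty_otus=False)
    assert ctrl.counts.to_numpy().sum() == 0
    cleaned = remove_control_otus(ds)
    roots = subset_dataset(ds, {"role": ["mother_root", "daughter_root"]})
    assert set(cleaned.counts.columns) == set(roots.counts.columns)


def test_daughter_otus_are_transmitted_or_contaminant(study):
    ds, truth = study
    for marker in ("fungi_18S", "bacteria_16S"):
        cont = set(truth.contaminants[marker])
        for eco, per_daughter in truth.transmitted[marker].items():
            for sid, transmitted in per_daughter.items():
                observed = set(ds.counts.columns[ds.counts.loc[sid] > 0])
                assert observed <= set(transmitted) | cont
                mother = set(truth.mother_sets[marker][eco])
                assert set(transmitted) - cont <= mother  # no spontaneous taxa


def test_same_seed_byte_identical(tmp_path):
    a, _ = simulate_dataset(SyntheticConfig(seed=31))
    b, _ = simulate_dataset(SyntheticConfig(seed=31))
    pd.testing.assert_frame_equal(a.counts, b.counts)
    make_fixture("tiny", tmp_path / "x", seed=5)
    make_fixture("tiny", tmp_path / "y", seed=5)
    assert (tmp_path / "x/tiny_counts.tsv").read_bytes() == \
           (tmp_path / "y/tiny_counts.tsv").read_bytes()


def test_tiny_fixture_heritability_hand_checkable(tiny):
    ds, truth = tiny
    roots = subset_dataset(ds, {"role": ["mother_root", "daughter_root"]})
    eps = build_presence(roots, "ecotype")
    for ep in eps:
        # brute-force recount straight from the counts matrix
        brute = 0
        for otu in ep.mother_set:
            n_daughters = sum(otu in d for d in ep.daughter_sets)
            brute += n_daughters >= 2
        assert heritability_index(ep, 2) == brute


def test_study_like_calibration(study):
    ds, truth = study
    rt_mothers = subset_dataset(ds, {"marker": "fungi_18S", "role": "mother_root"})
    mean_rich = (rt_mothers.counts > 0).sum(axis=1).mean()
    assert abs(mean_rich - 40) <= 8          # configured 40, within 20%
    bac_m = subset_dataset(ds, {"marker": "bacteria_16S", "role": "mother_root"})
    assert abs((bac_m.counts > 0).sum(axis=1).mean() - 800) <= 160


def test_expected_daughter_richness_tracks_truth():
    """Mean realized transmitted-set size matches cohort * retention decay
    within Monte-Carlo error over replicate datasets."""
    cfg = fungi_only(seed=3)
    diffs, var_sum, n = 0.0, 0.0, 0
    for rep in range(15):
        ds, truth = simulate_dataset(cfg, seed=200 + rep)
        for eco, per_daughter in truth.transmitted["fungi_18S"].items():
            for sid, transmitted in per_daughter.items():
                meta = ds.sample_meta(sid)
                exp = truth.expected_daughter_richness("fungi_18S", eco,
                                                       meta.position, meta.stolon)
                diffs += len(transmitted) - exp
                var_sum += max(exp, 1.0)     # Binomial variance bound n*p*(1-p) <= n*p
                n += 1
    se = np.sqrt(var_sum) / n
    assert abs(diffs / n) <= 3 * se


def test_ses_monotone_in_cohort_sharing():
    """Estimated SES grows with the fraction of transmission that goes through
    the shared cohort (replicate-averaged, 3-point grid)."""
    from clonalherit.heritability import run_heritability
    means = []
    for sharing in (0.2, 0.6, 1.0):
        ses = []
        for rep in range(8):
            cfg = fungi_only(seed=7000 + rep, sharing=sharing)
            ds, _ = simulate_dataset(cfg)
            roots = subset_dataset(ds, {"role": ["mother_root", "daughter_root"]})
            res = run_heritability(roots, NullModelConfig(299, 2, "regional", 7000 + rep))
            ses.append(res.ses_values.mean())
        means.append(np.mean(ses))
    assert means[0] < means[1] < means[2]


def test_simulated_read_sets_hit_configured_overlap():
    from clonalherit.overlap import shared_read_fraction
    mothers, daughters, realized = simulate_read_sets(shared_fraction=0.34, seed=6)
    assert shared_read_fraction(mothers, daughters) == pytest.approx(realized)
    assert realized == pytest.approx(34.0, abs=0.1)


def test_inconsistent_config_rejected():
    with pytest.raises(ValueError):
        SyntheticConfig(cohort_mode="bogus")
    with pytest.raises(ValueError):
        fungi_only(transmission={"Ascomycota": 1.5})
    with pytest.raises(ValueError):
        make_fixture("nope")
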