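"""Generators: determinism, planted truth, and closed-form convergence."""

import dataclasses
import io

import numpy as np
import pytest

from cfmeth.formats import write_pat
from cfmeth.simulate import (
    CohortSimConfig,
    MixtureSimConfig,
    ReferenceSimConfig,
    scaled_reference_config,
    simulate_cohort,
    simulate_mixture,
    simulate_reference_set,
    spike_in_series,
    uxm_probabilities,
)
from cfmeth.stats import spearman
from cfmeth.uxm import ClassifierParams, classify_fragment, tally_uxm


def _pat_bytes(records, tmp_path, name):
    path = tmp_path / name
    write_pat(records, path)
    return path.read_bytes()


def test_reference_generation_is_deterministic(tmp_path):
    cfg = scaled_reference_config(seed=99)
    a = simulate_reference_set(cfg)
    b = simulate_reference_set(cfg)
    for ct in a.cell_types:
        for i in range(cfg.samples_per_type):
            assert _pat_bytes(a.fragments[ct][i], tmp_path, f"a_{ct}_{i}.pat") == _pat_bytes(
                b.fragments[ct][i], tmp_path, f"b_{ct}_{i}.pat"
            )
    np.testing.assert_array_equal(a.theta, b.theta)


def test_noise_free_hypo_marker_fragments_all_classify_u():
    cfg = scaled_reference_config(seed=5, bisulfite_error=0.0)
    ref = simulate_reference_set(cfg)
    hypo = [m for m in ref.truth_markers if m.direction == "hypo"][0]
    recs = ref.pooled_fragments(hypo.group)
    in_block = [
        r for r in recs if hypo.block.start_cpg <= r.start_cpg < hypo.block.end_cpg
    ]
    # marker_low = 0.05: at epsilon 0 a latently methylated fragment is all-C,
    # everything else all-T -> classes are pure U or pure M, mostly U
    classes = [classify_fragment(r, hypo.block) for r in in_block]
    assert set(classes) <= {"U", "M"}
    assert np.mean([c == "U" for c in classes]) > 0.8


def test_planted_marker_count_and_direction_mix():
    cfg = scaled_reference_config(seed=2)
    ref = simulate_reference_set(cfg)
    assert len(ref.truth_markers) == cfg.n_cell_types * cfg.planted_markers_per_type
    per_group = {ct: 0 for ct in ref.cell_types}
    for m in ref.truth_markers:
        per_group[m.group] += 1
    assert set(per_group.values()) == {cfg.planted_markers_per_type}


def test_too_many_planted_markers_rejected():
    with pytest.raises(ValueError, match="exceed"):
        ReferenceSimConfig(n_cell_types=4, n_blocks=100, planted_markers_per_type=50)


def test_mixture_empty_and_determinism(small_reference):
    assert simulate_mixture(small_reference, MixtureSimConfig((1.0, 0, 0, 0), 0)) == []
    cfg = MixtureSimConfig((0.5, 0.5, 0, 0), 5000, seed=4)
    assert simulate_mixture(small_reference, cfg) == simulate_mixture(small_reference, cfg)


def test_mixture_source_composition_matches_proportions(small_reference):
    """Fragment-count conservation and truth composition of a mixture."""
    mix = simulate_mixture(small_reference, MixtureSimConfig((0.7, 0.3, 0, 0), 20_000, seed=6))
    assert sum(r.count for r in mix) == 20_000
    # type-0 hypo markers should look mostly U, type-2 markers uninvolved
    tallies = tally_uxm(mix, [m.block for m in small_reference.truth_markers])
    u_share = tallies[:, 0].sum() / tallies.sum()
    assert 0 < u_share < 1


def test_spike_series_truth_metadata(small_reference):
    mixes = spike_in_series(
        small_reference, small_reference.cell_types[0], small_reference.cell_types[1],
        levels=(0.0, 0.01), replicates=3, depth_per_block=20, seed=9,
    )
    assert [m.level for m in mixes] == [0.0, 0.0, 0.0, 0.01, 0.01, 0.01]
    assert [m.replicate for m in mixes] == [0, 1, 2, 0, 1, 2]
    again = spike_in_series(
        small_reference, small_reference.cell_types[0], small_reference.cell_types[1],
        levels=(0.0, 0.01), replicates=3, depth_per_block=20, seed=9,
    )
    assert [m.records for m in again] == [m.records for m in mixes]


def test_uxm_probabilities_closed_form_matches_simulation():
    theta, eps = 0.9, 0.05
    cfg = ReferenceSimConfig(
        n_cell_types=1, samples_per_type=1, n_blocks=1, planted_markers_per_type=1,
        marker_low=theta, marker_high=theta, bisulfite_error=eps,
        fragments_per_block=200_000, cpgs_per_fragment=(5, 5),
        cell_type_names=("x",), seed=17,
    )
    ref = simulate_reference_set(cfg)
    tallies = tally_uxm(ref.fragments["x"][0], ref.blocks)[0]
    emp = tallies / tallies.sum()
    p = uxm_probabilities(theta, eps, 5)
    sem = np.sqrt(np.asarray(p) * (1 - np.asarray(p)) / tallies.sum())
    assert np.all(np.abs(emp - p) < 4 * sem + 1e-9)


def test_uxm_probabilities_rejects_below_rlen():
    with pytest.raises(ValueError):
        uxm_probabilities(0.5, 0.03, 2)


# -- cohort -----------------------------------------------------------------


def test_cohort_fractions_sum_to_one_and_schema():
    table = simulate_cohort(CohortSimConfig(seed=3))
    sums = table.groupby(["patient_id", "timepoint"])["fraction"].sum()
    np.testing.assert_allclose(sums, 1.0, atol=1e-9)
    assert set(table["timepoint"]) == {"PRE", "POD0", "POD7", "POD30"}
    outcomes = table.groupby("patient_id")["outcome"].first()
    assert (outcomes != "no_injury").sum() == 11  # 55% of 20 patients


def test_cohort_zero_noise_reproduces_trajectory_means():
    cfg = CohortSimConfig(noise_sigma=0.0, conc_sigma=0.0, enzyme_sigma=0.0, seed=0)
    table = simulate_cohort(cfg)
    hep = table[(table.cell_type == "hepatocyte") & (table.timepoint == "POD7")]
    for _, row in hep.iterrows():
        arm = "no_injury" if row.outcome == "no_injury" else "injury"
        assert row.fraction == pytest.approx(cfg.hepatocyte_means[arm]["POD7"])


def test_cohort_enzyme_link_induces_strong_correlation():
    table = simulate_cohort(CohortSimConfig(seed=12))
    sub = table[(table.cell_type == "hepatocyte") & (table.timepoint == "POD0")]
    res = spearman(sub["AST"].to_numpy(), sub["geq_per_ml"].to_numpy())
    assert res.statistic > 0.7


def test_cohort_injury_effect_direction_across_seeds():
    wins = 0
    n_seeds = 25
    for s in range(n_seeds):
        table = simulate_cohort(CohortSimConfig(seed=1000 + s))
        hep = table[table.cell_type == "hepatocyte"]
        wide = hep.pivot_table(index="patient_id", columns="timepoint", values="fraction")
        combined = (wide["POD7"] + wide["POD30"]) / 2
        outcome = hep.groupby("patient_id")["outcome"].first()
        injured = outcome != "no_injury"
        if combined[injured].mean() > combined[~injured].mean():
            wins += 1
    assert wins >= 0.95 * n_seeds
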