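"""Clonal growth simulation, label induction, clone statistics, case logic."""

from fractions import Fraction
from itertools import product

import numpy as np
import pytest

from syncytia.clonal_dynamics import (
    EventSchedule,
    Population,
    canonical_schedule,
    classify_induction_case,
    compute_clone_stats,
    count_overlap_events,
    induce_labels,
    simulate_population,
)


def test_zero_rates_give_static_founders():
    sched = EventSchedule(horizon=96, endo_rate=0.0, mitosis_rate=0.0,
                          fusion_rate=0.0, n_units=10)
    pop = simulate_population(sched, seed=1)
    assert len(pop.units) == 10
    assert all(len(u.nuclei) == 1 and len(u.nuclei[0].copies) == 1 for u in pop.units)
    assert all(not u.fused_with for u in pop.units)
    assert pop.events == []


def test_mitosis_only_branching_mean():
    """Mean unit size after a mitosis window matches the branching-process
    expectation e^(rate*window) within 3 SE over 200 seeds."""
    rate, window = 0.04, 32
    sizes = []
    for seed in range(200):
        sched = EventSchedule(horizon=40, endo_window=(0, 0), endo_rate=0.0,
                              mitosis_window=(0, window), mitosis_rate=rate,
                              fusion_rate=0.0, n_units=8)
        pop = simulate_population(sched, seed=seed)
        sizes.extend(len(u.nuclei) for u in pop.units)
    sizes = np.asarray(sizes, dtype=float)
    expect = np.exp(rate * window)
    se = sizes.std(ddof=1) / np.sqrt(len(sizes))
    assert abs(sizes.mean() - expect) <= 3 * se


def test_simulation_determinism():
    sched = canonical_schedule(fusion_rate=0.003)
    a = simulate_population(sched, seed=9)
    b = simulate_population(sched, seed=9)
    assert [(e.time, e.kind, e.unit) for e in a.events] == [
        (e.time, e.kind, e.unit) for e in b.events
    ]
    assert [len(u.nuclei) for u in a.units] == [len(u.nuclei) for u in b.units]


def test_zero_efficiency_leaves_all_copies_uncoloured():
    pop = simulate_population(canonical_schedule(), seed=2)
    lab = induce_labels(pop, 0, efficiency=0.0, seed=3)
    assert all(c is None for c in lab.colour_of.values())
    with pytest.raises(ValueError, match="no labelled clones"):
        compute_clone_stats(lab)


def test_full_efficiency_single_copy_gives_single_colour_clones():
    """Induction before any proliferative event: every clone carries exactly
    one colour (the early-induction outcome)."""
    pop = simulate_population(canonical_schedule(), seed=4)
    stats = compute_clone_stats(induce_labels(pop, 0, efficiency=1.0, seed=5))
    assert stats.n_clones == 16
    assert np.all(stats.colours_per_clone == 1)
    assert stats.multicoloured_fraction == 0.0


@pytest.mark.parametrize("m", [1, 2, 3, 4])
def test_single_colour_probability_matches_enumeration(m):
    """P(all copies same colour | m copies) = 4^(1-m): exact by enumeration,
    and matched by simulation within 3 SE at 10,000 draws."""
    total = Fraction(0)
    for combo in product(range(4), repeat=m):
        if len(set(combo)) == 1:
            total += Fraction(1)
    exact = total / Fraction(4**m)
    assert exact == Fraction(4) ** (1 - m)

    pop = Population.from_copy_counts([m] * 10_000)
    lab = induce_labels(pop, 0, efficiency=1.0, seed=m * 11)
    single = np.mean([
        len(lab.nucleus_colours(u.nuclei[0])) == 1 for u in pop.units
    ])
    p = float(exact)
    se = np.sqrt(p * (1 - p) / 10_000) or 1e-9
    assert abs(single - p) <= 3 * se


def test_colour_marginals_uniform():
    """Each recombined copy draws its colour uniformly over the four."""
    from scipy.stats import chisquare

    pop = Population.from_copy_counts([1] * 100_000)
    lab = induce_labels(pop, 0, efficiency=1.0, seed=17)
    colours = [c for c in lab.colour_of.values() if c is not None]
    counts = np.bincount(colours, minlength=5)[1:]
    assert chisquare(counts).pvalue > 0.001


def test_later_copies_inherit_parental_colour():
    """Copies created by endoreplication after induction carry the colour of
    the copy they were replicated from."""
    sched = EventSchedule(horizon=20, endo_window=(10, 20), endo_rate=0.3,
                          mitosis_window=(0, 0), mitosis_rate=0.0, n_units=30)
    pop = simulate_population(sched, seed=6)
    lab = induce_labels(pop, 5, efficiency=1.0, seed=7)  # before endoreplication
    for unit in pop.units:
        for nuc in unit.nuclei:
            # every copy in a nucleus descends from one induced root copy
            assert len(lab.nucleus_colours(nuc)) == 1


def test_stats_recount_oracle():
    """Clone statistics equal a direct recount from units and colours."""
    sched = canonical_schedule(fusion_rate=0.002)
    pop = simulate_population(sched, seed=8)
    lab = induce_labels(pop, 48, efficiency=0.9, seed=9)
    stats = compute_clone_stats(lab)
    combos = []
    labelled_nuclei = 0
    for unit in pop.units:
        seen = {}
        for nuc in unit.nuclei:
            combo = lab.nucleus_colours(nuc)
            if not combo:
                continue
            labelled_nuclei += 1
            seen.setdefault(combo, 0)
            seen[combo] += 1
        combos.extend(seen.values())
    assert stats.n_clones == len(combos)
    assert int(stats.clone_sizes.sum()) == labelled_nuclei
    assert stats.fusion_events == sum(1 for e in pop.events if e.kind == "fusion")
    assert stats.events_per_clone == pytest.approx(stats.fusion_events / stats.n_clones)


def test_case_classification_canonical_windows():
    """Induction before / between / after the endoreplication-then-mitosis
    windows classifies as cases 1 / 2 / 4."""
    sched = canonical_schedule()
    pop = simulate_population(sched, seed=10)
    base = compute_clone_stats(induce_labels(pop, 0, seed=11))
    got = {
        t: classify_induction_case(
            compute_clone_stats(induce_labels(pop, t, seed=11 + t)), base
        )
        for t in (8, 48, 88)
    }
    assert got == {8: 1, 48: 2, 88: 4}


def test_case3_detected_for_mitosis_first_schedule():
    """The mitosis-before-endoreplication schedule the data argue against is
    still classifiable: induction between its windows gives case 3."""
    sched = EventSchedule(horizon=96, mitosis_window=(16, 48), mitosis_rate=0.04,
                          endo_window=(48, 80), endo_rate=0.05, n_units=16)
    pop = simulate_population(sched, seed=12)
    base = compute_clone_stats(induce_labels(pop, 0, seed=13))
    stats = compute_clone_stats(induce_labels(pop, 48, seed=14))
    assert classify_induction_case(stats, base) == 3


def test_events_per_clone_invariant_under_colour_relabelling():
    sched = canonical_schedule(fusion_rate=0.004)
    pop = simulate_population(sched, seed=15)
    lab = induce_labels(pop, 0, efficiency=1.0, seed=16)
    stats = compute_clone_stats(lab)
    perm = {None: None, 1: 3, 2: 4, 3: 1, 4: 2}
    lab_perm = induce_labels(pop, 0, efficiency=1.0, seed=16)
    lab_perm.colour_of = {c: perm[v] for c, v in lab.colour_of.items()}
    stats_perm = compute_clone_stats(lab_perm)
    assert stats_perm.n_clones == stats.n_clones
    assert stats_perm.events_per_clone == stats.events_per_clone
    np.testing.assert_array_equal(
        np.sort(stats_perm.clone_sizes), np.sort(stats.clone_sizes)
    )


def test_overlap_events_match_log_filter_oracle():
    """Detectable fusions = logged fusions whose partners differed in colour
    combination; same-colour fusions are undetectable."""
    sched = canonical_schedule(fusion_rate=0.01)
    pop = simulate_population(sched, seed=18)
    lab = induce_labels(pop, 0, mode="CAAX", efficiency=1.0, seed=19)
    overlap = count_overlap_events(lab)
    oracle_det = oracle_undet = 0
    for e in pop.events:
        if e.kind != "fusion":
            continue
        ca = lab.copies_colours(e.copies_a)
        cb = lab.copies_colours(e.copies_b)
        if ca != cb:
            oracle_det += 1
        else:
            oracle_undet += 1
    assert (overlap.detectable, overlap.undetectable) == (oracle_det, oracle_undet)
    assert overlap.total == sum(1 for e in pop.events if e.kind == "fusion")


def test_no_fusion_means_no_overlaps():
    pop = simulate_population(canonical_schedule(), seed=20)
    lab = induce_labels(pop, 0, mode="CAAX", seed=21)
    assert count_overlap_events(lab).total == 0
    with pytest.raises(ValueError, match="NLS"):
        count_overlap_events(induce_labels(pop, 0, mode="NLS", seed=21))


def test_schedule_validation():
    with pytest.raises(ValueError, match="window"):
        EventSchedule(horizon=50, endo_window=(10, 60))
    with pytest.raises(ValueError, match="horizon"):
        induce_labels(simulate_population(canonical_schedule(), seed=0), 200)
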