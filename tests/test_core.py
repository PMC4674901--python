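"""Unit and property tests of the fractionation simulator."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fractionator import (
    GenomeState,
    GeometricDeletionModel,
    Trajectory,
    apply_deletion_event,
    extract_runs,
    run_composition,
    sample_deletion_length,
    simulate_fractionation,
)
from fractionator.core import CheckpointRecord


# ---------------------------------------------------------------- geometric law


def test_mu_below_one_rejected():
    with pytest.raises(ValueError):
        GeometricDeletionModel(0.99)


def test_mu_one_is_degenerate():
    model = GeometricDeletionModel(1.0)
    rng = np.random.default_rng(0)
    assert all(sample_deletion_length(model, rng) == 1 for _ in range(1000))
    assert model.pmf(1) == 1.0 and model.pmf(2) == 0.0


def test_geometric_moments_mu2():
    """mu = 2: P(X=1) = 0.5 and mean 2, each within 3 SEs over 1e5 draws."""
    model = GeometricDeletionModel(2.0)
    rng = np.random.default_rng(42)
    n = 100_000
    draws = np.array([model.sample(rng) for _ in range(n)])
    se_p = math.sqrt(0.5 * 0.5 / n)
    assert abs((draws == 1).mean() - 0.5) < 3 * se_p
    se_mean = math.sqrt(2.0) / math.sqrt(n)  # SD of geometric(2) = sqrt(mu^2 - mu)
    assert abs(draws.mean() - 2.0) < 3 * se_mean


@given(a=st.integers(1, 50), mu=st.floats(1.0, 10.0, allow_nan=False))
@settings(derandomize=True, max_examples=50)
def test_pmf_normalised_head(a, mu):
    model = GeometricDeletionModel(mu)
    assert 0.0 <= model.pmf(a) <= 1.0
    head = sum(model.pmf(k) for k in range(1, 200))
    assert head <= 1.0 + 1e-12


# ------------------------------------------------------------- deletion events


def _state(n, singles, topology="circular"):
    cs = np.ones(n, dtype=bool)
    cs[list(singles)] = False
    return GenomeState(cs, topology)


def test_event_on_all_double_genome_has_no_overlap():
    state = GenomeState.all_double(10)
    _, ev = apply_deletion_event(state, 4, 3)
    assert ev.converted == [4, 5, 6]
    assert ev.overlapped_runs == 0
    assert state.deleted_count == 3


def test_event_skips_existing_single_gene():
    # gene 4 already single: quota-2 event at 3 converts 3 and 5, merging into one run
    state = _state(10, [4])
    _, ev = apply_deletion_event(state, 3, 2)
    assert ev.converted == [3, 5]
    assert ev.overlapped_runs == 1
    assert extract_runs(state).single_runs == Counter({3: 1})


def test_event_absorbs_two_runs():
    # singles at 1 and 3; event of 3 from 0 converts 0, 2, 4 -> one run of 5
    state = _state(6, [1, 3])
    _, ev = apply_deletion_event(state, 0, 3)
    assert ev.converted == [0, 2, 4]
    assert ev.overlapped_runs == 2
    tally = extract_runs(state)
    assert tally.single_runs == Counter({5: 1})
    assert tally.double_runs == Counter({1: 1})


def test_event_contract_violations():
    state = _state(6, [2])
    with pytest.raises(ValueError):
        apply_deletion_event(state, 2, 1)  # start not double-copy
    all_single = GenomeState(np.zeros(4, dtype=bool))
    with pytest.raises(ValueError):
        apply_deletion_event(all_single, 0, 1)


def test_linear_event_truncated_at_chromosome_end():
    state = _state(5, [], topology="linear")
    _, ev = apply_deletion_event(state, 3, 4)
    assert ev.converted == [3, 4]  # scan cannot wrap


def _reference_apply(cs, start, a, circular):
    """Independent re-derivation of the skipping rule.

    Scan order is the position sequence from `start`; the first min(a, #doubles
    in scan order) doubles are converted.  A pre-existing single run is
    overlapped iff one of its members precedes the last converted position in
    scan order.
    """
    n = len(cs)
    order = [(start + k) % n for k in range(n)] if circular else list(range(start, n))
    idx = {p: i for i, p in enumerate(order)}
    doubles = [p for p in order if cs[p]]
    conv = doubles[: min(a, len(doubles))]
    # pre-existing maximal single runs as position sets
    runs = []
    seen = set()
    singles = {p for p in range(n) if not cs[p]}
    for p in singles:
        if p in seen:
            continue
        s = p
        if circular:
            while (s - 1) % n in singles and (s - 1) % n != p:
                s = (s - 1) % n
        else:
            while s - 1 in singles:
                s -= 1
        run = set()
        cur = s
        while cur in singles and len(run) < n:
            run.add(cur)
            seen.add(cur)
            cur = (cur + 1) % n if circular else cur + 1
        runs.append(run)
    last = idx[conv[-1]]
    q = sum(1 for run in runs if any(m in idx and idx[m] < last for m in run))
    return conv, q


@given(
    n=st.integers(4, 24),
    data=st.data(),
    a=st.integers(1, 30),
    circular=st.booleans(),
)
@settings(derandomize=True, max_examples=200)
def test_event_matches_independent_reference(n, data, a, circular):
    singles = data.draw(
        st.sets(st.integers(0, n - 1), max_size=n - 1), label="singles"
    )
    doubles = sorted(set(range(n)) - singles)
    start = data.draw(st.sampled_from(doubles), label="start")
    cs = np.ones(n, dtype=bool)
    cs[list(singles)] = False
    ref_conv, ref_q = _reference_apply(cs.copy(), start, a, circular)
    state = GenomeState(cs.copy(), "circular" if circular else "linear")
    _, ev = apply_deletion_event(state, start, a)
    assert ev.converted == ref_conv
    assert ev.overlapped_runs == ref_q
    # skipping never resurrects a single-copy gene
    assert not state.copy_state[list(singles)].any()


# ------------------------------------------------------------------- run tallies


def test_extract_runs_all_double():
    tally = extract_runs(GenomeState.all_double(12))
    assert tally.single_runs == Counter()
    assert tally.double_runs == Counter({12: 1})


def test_extract_runs_circular():
    tally = extract_runs(_state(12, [2, 3, 4, 8]))
    assert tally.single_runs == Counter({3: 1, 1: 1})
    assert tally.double_runs == Counter({3: 1, 5: 1})
    tally.validate()


def test_extract_runs_circular_wraparound():
    # singles 11, 0, 1 form one run across the origin
    tally = extract_runs(_state(12, [11, 0, 1]))
    assert tally.single_runs == Counter({3: 1})
    assert tally.double_runs == Counter({9: 1})


def test_extract_runs_linear():
    tally = extract_runs(_state(5, [0, 1, 4], topology="linear"))
    assert tally.single_runs == Counter({2: 1, 1: 1})
    assert tally.double_runs == Counter({2: 1})


@given(n=st.integers(4, 40), data=st.data())
@settings(derandomize=True, max_examples=100)
def test_circular_run_counts_balance(n, data):
    """On a circle with both states present, #single runs == #double runs,
    and run lengths conserve the genome size."""
    singles = data.draw(st.sets(st.integers(0, n - 1), min_size=1, max_size=n - 1))
    tally = extract_runs(_state(n, singles))
    tally.validate()
    assert tally.total_runs("single") == tally.total_runs("double")


# ------------------------------------------------------------------ trajectories


def test_gene_by_gene_trajectory_has_unit_events():
    traj = simulate_fractionation(
        40, GeometricDeletionModel(1.0), [0.5], seed=3, keep_events=True
    )
    assert len(traj.events) == 20
    assert all(ev.requested_length == 1 for ev in traj.events)
    assert all(ev.overlapped_runs == 0 for ev in traj.events)


def test_single_deletion_checkpoint():
    traj = simulate_fractionation(4, GeometricDeletionModel(1.5), [0.25], seed=0)
    rec = traj.checkpoints[0]
    assert rec.deleted_count == 1
    assert rec.tally.single_runs == Counter({1: 1})


def test_checkpoints_hit_targets_exactly_and_conserve_genes():
    omts = [0.1, 0.3, 0.5, 0.7, 0.9]
    traj = simulate_fractionation(137, GeometricDeletionModel(2.2), omts, seed=11)
    for omt, rec in zip(omts, traj.checkpoints):
        assert rec.deleted_count == round(omt * 137)
        rec.tally.validate()


def test_trajectory_determinism():
    kwargs = dict(
        n_genes=120,
        model=GeometricDeletionModel(1.7),
        checkpoints=[0.2, 0.6],
        seed=99,
        keep_events=True,
    )
    t1 = simulate_fractionation(**kwargs)
    t2 = simulate_fractionation(**kwargs)
    for r1, r2 in zip(t1.checkpoints, t2.checkpoints):
        assert np.array_equal(r1.copy_state, r2.copy_state)
    assert [e.converted for e in t1.events] == [e.converted for e in t2.events]


def test_invalid_simulation_parameters():
    model = GeometricDeletionModel(1.5)
    with pytest.raises(ValueError):
        simulate_fractionation(100, model, [0.0])
    with pytest.raises(ValueError):
        simulate_fractionation(100, model, [1.0])
    with pytest.raises(ValueError):
        simulate_fractionation(100, model, [0.5, 0.3])
    with pytest.raises(ValueError):
        simulate_fractionation(1, model, [0.5])


def test_double_run_mean_decreases_with_fractionation():
    """nu_t, the mean double-copy run length, shrinks as deletion proceeds."""
    omts = [0.2, 0.5, 0.8]
    means = np.zeros(len(omts))
    for s in range(40):
        traj = simulate_fractionation(300, GeometricDeletionModel(1.5), omts, seed=1000 + s)
        means += [rec.tally.mean_length("double") for rec in traj.checkpoints]
    means /= 40
    assert means[0] > means[1] > means[2]


def test_mu1_matches_uniform_subset_enumeration_small():
    """Gene-by-gene deletion at N=6, 2 deleted: run tallies equal the exact
    law of a uniform 2-subset of a 6-cycle (adjacent pair prob 6/15)."""
    R = 30_000
    rng = np.random.default_rng(7)
    adjacent = 0
    for _ in range(R):
        traj = simulate_fractionation(6, GeometricDeletionModel(1.0), [2 / 6], seed=rng)
        if traj.checkpoints[0].tally.single_runs == Counter({2: 1}):
            adjacent += 1
    p = 6 / 15
    se = math.sqrt(p * (1 - p) / R)
    assert abs(adjacent / R - p) < 3 * se


# --------------------------------------------------------------- run composition


def test_composition_gene_by_gene():
    traj = simulate_fractionation(
        60, GeometricDeletionModel(1.0), [0.5], seed=5, keep_events=True
    )
    comp = run_composition(traj, 0.5)
    assert (comp["n_events"] == comp["run_length"]).all()
    assert (comp["mean_event_length"] == 1.0).all()


def test_composition_single_unoverlapped_event():
    state = GenomeState.all_double(12)
    state, ev = apply_deletion_event(state, 2, 4)
    traj = Trajectory(12, 4.0, "circular", None, events=[ev])
    traj.checkpoints.append(
        CheckpointRecord(4 / 12, 4, extract_runs(state), state.copy_state.copy(), 1)
    )
    comp = run_composition(traj, 4 / 12)
    assert comp.to_dict("records") == [
        {"run_length": 4, "n_events": 1, "mean_event_length": 4.0}
    ]


def test_composition_requires_event_log():
    traj = simulate_fractionation(20, GeometricDeletionModel(1.0), [0.5], seed=1)
    with pytest.raises(ValueError):
        run_composition(traj, 0.5)
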