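"""Discrete simulator of post-WGD fractionation by geometric-length deletion events.

After a whole genome doubling (WGD) every gene is present in two copies.
Fractionation removes one copy of each duplicate pair over time.  The model
simulated here deletes, at each step, a geometrically distributed number of
consecutive double-copy genes (mean ``mu``) starting from a uniformly chosen
double-copy gene; genes that are already single-copy are *skipped*, so a
deletion event can extend or merge pre-existing single-copy runs.  With
``mu = 1`` the process degenerates to gene-by-gene loss (the "functional"
model); ``mu > 1`` is the segmental-excision ("structural") model.

Positions are 0-based throughout the in-memory API; the TSV interchange
format in :mod:`fractionator.io` is 1-based.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "GeometricDeletionModel",
    "GenomeState",
    "DeletionEvent",
    "RunLengthTally",
    "CheckpointRecord",
    "Trajectory",
    "sample_deletion_length",
    "apply_deletion_event",
    "extract_runs",
    "simulate_fractionation",
    "run_composition",
]

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator, None]

TOPOLOGIES = ("circular", "linear")


def _as_rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class GeometricDeletionModel:
    """Deletion-event length law: geometric on {1, 2, ...} with mean ``mu``.

    ``P(X = a) = (1/mu) (1 - 1/mu)^(a-1)``.  ``mu = 1`` puts all mass on
    ``X = 1`` (gene-by-gene deletion).
    """

    mu: float

    def __post_init__(self) -> None:
        if not (self.mu >= 1.0) or not math.isfinite(self.mu):
            raise ValueError(f"mean deletion length mu must be >= 1, got {self.mu}")

    def pmf(self, a: int) -> float:
        if a < 1:
            return 0.0
        if self.mu == 1.0:
            return 1.0 if a == 1 else 0.0
        p = 1.0 / self.mu
        return p * (1.0 - p) ** (a - 1)

    def sample(self, rng: np.random.Generator) -> int:
        """Draw one event length by inversion (exact at ``mu = 1``)."""
        if self.mu == 1.0:
            return 1
        u = rng.random()
        # X = ceil(log(1-U) / log(1-p)), U in [0, 1)
        a = math.ceil(math.log1p(-u) / math.log1p(-1.0 / self.mu))
        return a if a >= 1 else 1


def sample_deletion_length(model: GeometricDeletionModel, rng: SeedLike) -> int:
    """Sample one deletion-event length from ``model``'s geometric law."""
    return model.sample(_as_rng(rng))


class GenomeState:
    """Per-position copy status of the N duplicated genes.

    ``copy_state`` is a boolean array, True = double-copy.  The initial
    post-WGD genome is all-double.
    """

    __slots__ = ("copy_state", "topology")

    def __init__(self, copy_state: np.ndarray, topology: str = "circular"):
        cs = np.asarray(copy_state, dtype=bool)
        if cs.ndim != 1 or cs.size < 2:
            raise ValueError("genome must be a 1-D sequence of at least 2 genes")
        if topology not in TOPOLOGIES:
            raise ValueError(f"topology must be one of {TOPOLOGIES}, got {topology!r}")
        self.copy_state = cs
        self.topology = topology

    @classmethod
    def all_double(cls, n_genes: int, topology: str = "circular") -> "GenomeState":
        if n_genes < 2:
            raise ValueError(f"n_genes must be >= 2, got {n_genes}")
        return cls(np.ones(n_genes, dtype=bool), topology)

    @property
    def n_genes(self) -> int:
        return self.copy_state.size

    @property
    def deleted_count(self) -> int:
        return int(self.copy_state.size - np.count_nonzero(self.copy_state))

    @property
    def theta(self) -> float:
        """Proportion of genes still double-copy."""
        return 1.0 - self.deleted_count / self.n_genes

    def copy(self) -> "GenomeState":
        return GenomeState(self.copy_state.copy(), self.topology)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"GenomeState(n_genes={self.n_genes}, deleted={self.deleted_count}, "
            f"topology={self.topology!r})"
        )


@dataclass
class DeletionEvent:
    """One applied deletion event.

    ``requested_length`` is the quota of double-copy genes the event set out
    to convert (after any checkpoint truncation); ``converted`` lists the
    positions flipped double -> single, in scan order; ``overlapped_runs`` is
    the number of distinct pre-existing single-copy runs the scan skipped
    through (the event's q).
    """

    start: int
    requested_length: int
    converted: list
    overlapped_runs: int


def apply_deletion_event(state: GenomeState, start: int, a: int):
    """Apply one deletion event of quota ``a`` starting at ``start``.

    Scans in increasing position order (wrapping if circular), converting
    double-copy genes to single-copy and skipping single-copy genes, until
    ``a`` genes have been converted or no further double-copy gene is
    reachable.  Mutates ``state`` in place and returns
    ``(state, DeletionEvent)``.
    """
    cs = state.copy_state
    n = cs.size
    if not (0 <= start < n):
        raise ValueError(f"start {start} out of range for N={n}")
    if a < 1:
        raise ValueError(f"event length must be >= 1, got {a}")
    n_double = int(np.count_nonzero(cs))
    if n_double == 0:
        raise ValueError("no double-copy genes left to delete")
    if not cs[start]:
        raise ValueError(f"start position {start} is not double-copy")

    circular = state.topology == "circular"
    quota = min(a, n_double)
    converted: list = []
    q = 0
    prev_was_gap = False
    pos = start
    while len(converted) < quota:
        if pos >= n:
            if circular:
                pos -= n
            else:
                break  # ran off the linear end
        if cs[pos]:
            cs[pos] = False
            converted.append(pos)
            if prev_was_gap:
                q += 1
            prev_was_gap = False
        else:
            prev_was_gap = True
        pos += 1
    return state, DeletionEvent(start, a, converted, q)


@dataclass
class RunLengthTally:
    """Counts of maximal single-copy and double-copy runs by length.

    ``single_runs`` estimates the single-copy run-length distribution psi_t,
    ``double_runs`` the double-copy distribution rho_t (whose mean is nu_t).
    """

    single_runs: Counter
    double_runs: Counter
    n_genes: int
    deleted_count: int

    def validate(self) -> None:
        s = sum(l * c for l, c in self.single_runs.items())
        d = sum(l * c for l, c in self.double_runs.items())
        if s != self.deleted_count:
            raise AssertionError(f"single-run genes {s} != deleted_count {self.deleted_count}")
        if s + d != self.n_genes:
            raise AssertionError(f"run genes {s + d} != N {self.n_genes}")

    def runs(self, run_type: str) -> Counter:
        if run_type == "single":
            return self.single_runs
        if run_type == "double":
            return self.double_runs
        raise ValueError(f"run_type must be 'single' or 'double', got {run_type!r}")

    def total_runs(self, run_type: str) -> int:
        return sum(self.runs(run_type).values())

    def mean_length(self, run_type: str) -> float:
        """Mean run length; for 'double' this estimates nu_t."""
        runs = self.runs(run_type)
        n = sum(runs.values())
        if n == 0:
            raise ValueError(f"no {run_type}-copy runs in tally")
        return sum(l * c for l, c in runs.items()) / n

    def lengths_counts(self, run_type: str):
        """Sorted (lengths, counts) arrays for the requested run type."""
        runs = self.runs(run_type)
        if not runs:
            return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
        lengths = np.array(sorted(runs), dtype=np.int64)
        counts = np.array([runs[l] for l in lengths], dtype=np.int64)
        return lengths, counts

    def cumulative(self, run_type: str):
        """Empirical cumulative: proportion of runs of length <= l.

        Returns ``(lengths, cum_probs)`` on the observed support.
        """
        lengths, counts = self.lengths_counts(run_type)
        if lengths.size == 0:
            raise ValueError(f"no {run_type}-copy runs in tally")
        cum = np.cumsum(counts) / counts.sum()
        return lengths, cum


def _run_lengths(cs: np.ndarray, circular: bool):
    """Decompose a boolean track into maximal runs: yields (is_double, length)."""
    n = cs.size
    if cs.all() or not cs.any():
        return [(bool(cs[0]), n)]
    if circular:
        # rotate so index 0 starts a new run
        change = np.flatnonzero(cs != np.roll(cs, 1))
        cs = np.roll(cs, -change[0])
    boundaries = np.flatnonzero(cs[1:] != cs[:-1]) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n]))
    return [(bool(cs[s]), int(e - s)) for s, e in zip(starts, ends)]


def extract_runs(state: GenomeState) -> RunLengthTally:
    """Tally maximal single- and double-copy runs of a genome state."""
    single: Counter = Counter()
    double: Counter = Counter()
    for is_double, length in _run_lengths(state.copy_state, state.topology == "circular"):
        (double if is_double else single)[length] += 1
    return RunLengthTally(single, double, state.n_genes, state.deleted_count)


@dataclass
class CheckpointRecord:
    """Snapshot of the process when the deleted proportion first reaches a target."""

    one_minus_theta: float
    deleted_count: int
    tally: RunLengthTally
    copy_state: np.ndarray
    n_events: int


@dataclass
class Trajectory:
    """One realisation of the fractionation process with per-checkpoint tallies."""

    n_genes: int
    mu: float
    topology: str
    seed: object
    checkpoints: list = field(default_factory=list)
    events: Optional[list] = None

    def checkpoint(self, one_minus_theta: float) -> CheckpointRecord:
        for rec in self.checkpoints:
            if abs(rec.one_minus_theta - one_minus_theta) < 1e-9:
                return rec
        raise KeyError(f"no checkpoint at 1-theta = {one_minus_theta}")


def _validate_checkpoints(n_genes: int, proportions: Sequence[float]) -> list:
    if len(proportions) == 0:
        raise ValueError("at least one checkpoint is required")
    prev = 0.0
    targets = []
    for p in proportions:
        if not (0.0 < p < 1.0):
            raise ValueError(f"checkpoint 1-theta must lie in (0, 1), got {p}")
        if p <= prev:
            raise ValueError("checkpoints must be strictly increasing")
        prev = p
        t = int(round(p * n_genes))
        if t < 1 or t > n_genes - 1:
            raise ValueError(
                f"checkpoint 1-theta={p} rounds to {t} deleted genes for N={n_genes}; "
                "must leave at least one gene in each copy state"
            )
        targets.append(t)
    if any(b <= a for a, b in zip(targets, targets[1:])):
        raise ValueError("checkpoints round to non-increasing deletion targets")
    return targets


def simulate_fractionation(
    n_genes: int,
    model: GeometricDeletionModel,
    checkpoints: Sequence[float],
    topology: str = "circular",
    seed: SeedLike = None,
    keep_events: bool = False,
    exact_checkpoints: bool = True,
) -> Trajectory:
    """Run the fractionation process, recording run tallies at each checkpoint.

    Each step draws a start gene uniformly among the current double-copy genes
    and an event length from ``model``; the event converts that many
    double-copy genes scanning rightward, skipping single-copy genes.  With
    ``exact_checkpoints`` (default) the event reaching a checkpoint target is
    truncated so ``deleted_count`` equals ``round((1-theta) * N)`` exactly;
    otherwise the first event crossing the target ends the stage (first-
    crossing convention).

    Identical ``(n_genes, model, checkpoints, topology, seed)`` give an
    identical trajectory.
    """
    if topology not in TOPOLOGIES:
        raise ValueError(f"topology must be one of {TOPOLOGIES}, got {topology!r}")
    targets = _validate_checkpoints(n_genes, checkpoints)
    rng = _as_rng(seed)
    state = GenomeState.all_double(n_genes, topology)
    cs = state.copy_state
    circular = topology == "circular"
    n = n_genes

    traj = Trajectory(
        n_genes=n_genes,
        mu=model.mu,
        topology=topology,
        seed=seed if not isinstance(seed, np.random.Generator) else None,
        events=[] if keep_events else None,
    )

    mu = model.mu
    log_q = math.log1p(-1.0 / mu) if mu > 1.0 else None
    deleted = 0
    n_events = 0
    rand = rng.random  # local alias: hot loop

    for omt, target in zip(checkpoints, targets):
        while deleted < target:
            # uniform start among double-copy genes, by rejection
            while True:
                start = int(rand() * n)
                if cs[start]:
                    break
            if log_q is None:
                a = 1
            else:
                a = math.ceil(math.log1p(-rand()) / log_q)
                if a < 1:
                    a = 1
            if exact_checkpoints and a > target - deleted:
                a = target - deleted
            # inline scan (same semantics as apply_deletion_event)
            quota = min(a, n - deleted)
            converted = [] if keep_events else None
            n_conv = 0
            q = 0
            prev_was_gap = False
            pos = start
            while n_conv < quota:
                if pos >= n:
                    if circular:
                        pos -= n
                    else:
                        break
                if cs[pos]:
                    cs[pos] = False
                    n_conv += 1
                    if converted is not None:
                        converted.append(pos)
                    if prev_was_gap:
                        q += 1
                    prev_was_gap = False
                else:
                    prev_was_gap = True
                pos += 1
            deleted += n_conv
            n_events += 1
            if keep_events:
                traj.events.append(DeletionEvent(start, quota, converted, q))
        tally = extract_runs(state)
        traj.checkpoints.append(
            CheckpointRecord(
                one_minus_theta=float(omt),
                deleted_count=deleted,
                tally=tally,
                copy_state=cs.copy(),
                n_events=n_events,
            )
        )
    return traj


def run_composition(trajectory: Trajectory, one_minus_theta: float) -> pd.DataFrame:
    """Decompose each single-copy run at a checkpoint into its deletion events.

    Returns a DataFrame with one row per maximal single-copy run:
    ``run_length``, ``n_events`` (distinct deletion events that contributed
    converted genes to the run) and ``mean_event_length`` (mean quota of those
    events).  Long runs built from many overlapping events tend to be made of
    longer individual events — the non-independence that prevents run lengths
    from being negative-binomial sums of i.i.d. geometrics.
    """
    if trajectory.events is None:
        raise ValueError("trajectory has no event log; rerun with keep_events=True")
    rec = trajectory.checkpoint(one_minus_theta)
    n = trajectory.n_genes
    owner = np.full(n, -1, dtype=np.int64)  # position -> event index
    for i, ev in enumerate(trajectory.events[: rec.n_events]):
        for p in ev.converted:
            owner[p] = i

    rows = []
    pos0 = 0
    cs = rec.copy_state
    circular = trajectory.topology == "circular"
    offset = 0
    runs = _run_lengths(cs, circular)
    if circular and not (cs.all() or not cs.any()):
        change = np.flatnonzero(cs != np.roll(cs, 1))
        offset = int(change[0])
    for is_double, length in runs:
        if not is_double:
            positions = [(offset + pos0 + k) % n for k in range(length)]
            ev_ids = {int(owner[p]) for p in positions}
            ev_ids.discard(-1)
            lengths = [trajectory.events[i].requested_length for i in ev_ids]
            rows.append(
                {
                    "run_length": length,
                    "n_events": len(ev_ids),
                    "mean_event_length": float(np.mean(lengths)),
                }
            )
        pos0 += length
    return pd.DataFrame(rows, columns=["run_length", "n_events", "mean_event_length"])
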