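"""Discrimination between gene-by-gene (mu = 1) and segmental (mu > 1) fractionation.

The procedure: simulate the deletion process over a grid of (mu, N, 1-theta),
pool run-length counts into empirical reference cumulatives F (single-copy
runs) and G (double-copy runs), then assign an observed genome to the mu
"bin" whose reference cumulative minimises the Kolmogorov-Smirnov distance to
the sample's run-length cumulative.  Error rates of this binning estimator
are assessed by classifying freshly simulated trajectories of known mu.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    GeometricDeletionModel,
    RunLengthTally,
    simulate_fractionation,
)

__all__ = [
    "DEFAULT_MU_GRID",
    "ReferenceCumulativeLibrary",
    "ClassificationResult",
    "ErrorAssessment",
    "build_reference",
    "ks_distance",
    "classify_sample",
    "assess_discrimination",
    "compare_run_types",
]

logger = logging.getLogger("fractionator")

DEFAULT_MU_GRID: Tuple[float, ...] = tuple(round(1.0 + 0.1 * i, 1) for i in range(15))
DEFAULT_OMT_GRID: Tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 10))

RUN_TYPES = ("single", "double")


def _key(mu: float, n_genes: int, omt: float) -> Tuple[float, int, float]:
    return (round(float(mu), 6), int(n_genes), round(float(omt), 6))


@dataclass
class ReferenceCumulativeLibrary:
    """Empirical reference cumulatives of run lengths on a (mu, N, 1-theta) grid.

    ``cumulatives[run_type][(mu, N, 1-theta)]`` is a 1-D array c where
    ``c[l-1]`` is the proportion of runs of length <= l, for l up to the
    largest observed length.  Built by pooling run counts over replicate
    trajectories (run-weighted averaging); per-trial averaging of relative
    frequencies is available via ``pooling="per_trial"``.
    """

    mus: Tuple[float, ...]
    n_genes_list: Tuple[int, ...]
    one_minus_thetas: Tuple[float, ...]
    replicates: int
    seed: object
    topology: str = "circular"
    pooling: str = "pooled"
    cumulatives: Dict[str, Dict[Tuple[float, int, float], np.ndarray]] = field(
        default_factory=lambda: {"single": {}, "double": {}}
    )
    run_totals: Dict[str, Dict[Tuple[float, int, float], float]] = field(
        default_factory=lambda: {"single": {}, "double": {}}
    )

    def cumulative(self, run_type: str, mu: float, n_genes: int, omt: float) -> np.ndarray:
        if run_type not in RUN_TYPES:
            raise ValueError(f"run_type must be one of {RUN_TYPES}, got {run_type!r}")
        key = _key(mu, n_genes, omt)
        try:
            return self.cumulatives[run_type][key]
        except KeyError:
            raise KeyError(
                f"library has no cell (mu={key[0]}, N={key[1]}, 1-theta={key[2]}) "
                f"for run_type={run_type!r}"
            ) from None

    def has_cell(self, run_type: str, mu: float, n_genes: int, omt: float) -> bool:
        return _key(mu, n_genes, omt) in self.cumulatives.get(run_type, {})

    def to_frame(self, run_type: str) -> pd.DataFrame:
        """Long-format table: mu, n_genes, one_minus_theta, length, cum_prob."""
        rows = []
        for (mu, n, omt), cum in sorted(self.cumulatives[run_type].items()):
            for i, c in enumerate(cum):
                rows.append((mu, n, omt, i + 1, float(c)))
        return pd.DataFrame(
            rows, columns=["mu", "n_genes", "one_minus_theta", "length", "cum_prob"]
        )


def _counts_to_cum(counts: np.ndarray) -> np.ndarray:
    total = counts.sum()
    if total == 0:
        raise RuntimeError("reference cell has zero runs")
    cum = np.cumsum(counts) / total
    cum[-1] = 1.0
    return cum


def build_reference(
    mus: Sequence[float] = DEFAULT_MU_GRID,
    n_genes_list: Sequence[int] = (900,),
    one_minus_thetas: Sequence[float] = DEFAULT_OMT_GRID,
    replicates: int = 300,
    run_type: str = "both",
    topology: str = "circular",
    seed: object = 0,
    pooling: str = "pooled",
) -> ReferenceCumulativeLibrary:
    """Simulate the grid and build reference run-length cumulatives.

    For each (mu, N), ``replicates`` trajectories are run with checkpoints at
    every requested 1-theta; run counts are pooled across replicates per cell
    and normalised into a cumulative.  Deterministic given ``seed``.
    ``run_type`` selects which cumulatives to retain ("single", "double" or
    "both"; both come from the same simulations).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if run_type not in RUN_TYPES + ("both",):
        raise ValueError(f"run_type must be 'single', 'double' or 'both', got {run_type!r}")
    if pooling not in ("pooled", "per_trial"):
        raise ValueError(f"pooling must be 'pooled' or 'per_trial', got {pooling!r}")
    wanted = RUN_TYPES if run_type == "both" else (run_type,)
    omts = tuple(float(x) for x in one_minus_thetas)

    lib = ReferenceCumulativeLibrary(
        mus=tuple(float(m) for m in mus),
        n_genes_list=tuple(int(n) for n in n_genes_list),
        one_minus_thetas=omts,
        replicates=int(replicates),
        seed=seed,
        topology=topology,
        pooling=pooling,
    )
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = iter(root.spawn(len(lib.mus) * len(lib.n_genes_list)))
    for mu in lib.mus:
        model = GeometricDeletionModel(mu)
        for n in lib.n_genes_list:
            cell_seed = next(children)
            streams = cell_seed.spawn(replicates)
            # accumulate counts per (omt, run_type) up to N
            acc = {
                rt: {omt: np.zeros(n, dtype=np.float64) for omt in omts} for rt in wanted
            }
            for rep in range(replicates):
                traj = simulate_fractionation(n, model, omts, topology, seed=streams[rep])
                for rec in traj.checkpoints:
                    for rt in wanted:
                        lengths, counts = rec.tally.lengths_counts(rt)
                        if pooling == "pooled":
                            np.add.at(acc[rt][rec.one_minus_theta], lengths - 1, counts)
                        else:
                            total = counts.sum()
                            np.add.at(
                                acc[rt][rec.one_minus_theta],
                                lengths - 1,
                                counts / total,
                            )
            for rt in wanted:
                for omt in omts:
                    counts = acc[rt][omt]
                    nz = np.flatnonzero(counts)
                    if nz.size == 0:
                        raise RuntimeError(
                            f"no {rt}-copy runs observed for cell "
                            f"(mu={mu}, N={n}, 1-theta={omt})"
                        )
                    trimmed = counts[: nz[-1] + 1]
                    total = float(trimmed.sum())
                    if pooling == "pooled" and total < 30:
                        logger.warning(
                            "reference cell (mu=%s, N=%s, 1-theta=%s, %s) pooled only "
                            "%d runs; its cumulative is noisy",
                            mu, n, omt, rt, int(total),
                        )
                    lib.cumulatives[rt][_key(mu, n, omt)] = _counts_to_cum(trimmed)
                    lib.run_totals[rt][_key(mu, n, omt)] = total
    return lib


def ks_distance(sample_tally: RunLengthTally, reference_cum: np.ndarray, run_type: str) -> float:
    """Kolmogorov-Smirnov distance between a sample run-length cumulative and a
    reference cumulative on integer support.

    Both cumulatives are step functions in l; D is the maximum absolute
    difference over the union of supports (beyond the longer support both
    equal 1).
    """
    lengths, counts = sample_tally.lengths_counts(run_type)
    if lengths.size == 0:
        raise ValueError(f"sample has no {run_type}-copy runs; KS distance undefined")
    l_max = int(max(lengths[-1], reference_cum.size))
    sample_cum = np.zeros(l_max)
    sample_cum[lengths - 1] = counts
    sample_cum = np.cumsum(sample_cum) / counts.sum()
    ref = np.ones(l_max)
    ref[: reference_cum.size] = reference_cum
    return float(np.abs(sample_cum - ref).max())


@dataclass
class ClassificationResult:
    """KS distances over candidate mu bins and the argmin estimate mu_hat."""

    sample_id: object
    distances: "pd.Series"  # indexed by candidate mu
    mu_hat: float
    tie: bool
    run_type: str
    n_genes: int
    one_minus_theta: float


def classify_sample(
    sample_tally: RunLengthTally,
    library: ReferenceCumulativeLibrary,
    n_genes: int,
    one_minus_theta: float,
    run_type: str = "single",
    sample_id: object = None,
    rel_tol: float = 1e-12,
) -> ClassificationResult:
    """Assign a sample to the mu bin minimising the KS distance.

    Ties (distances equal to within ``rel_tol``) are broken toward the
    smallest mu — conservative in favour of the gene-by-gene model.
    """
    dists = {}
    for mu in library.mus:
        if not library.has_cell(run_type, mu, n_genes, one_minus_theta):
            raise KeyError(
                f"library missing cell (mu={mu}, N={n_genes}, 1-theta={one_minus_theta}) "
                f"for run_type={run_type!r}"
            )
        ref = library.cumulative(run_type, mu, n_genes, one_minus_theta)
        dists[mu] = ks_distance(sample_tally, ref, run_type)
    ser = pd.Series(dists).sort_index()
    d_min = ser.min()
    winners = ser.index[ser <= d_min + rel_tol]
    return ClassificationResult(
        sample_id=sample_id,
        distances=ser,
        mu_hat=float(winners[0]),
        tie=len(winners) > 1,
        run_type=run_type,
        n_genes=int(n_genes),
        one_minus_theta=float(one_minus_theta),
    )


@dataclass
class ErrorAssessment:
    """Frequencies of mu_hat over a grid of true (mu, N, 1-theta) cells.

    ``table`` is a DataFrame indexed by (true_mu, n_genes, one_minus_theta)
    with one column per mu_hat bin; rows sum to 1.  ``freq_mu1()`` extracts
    the frequency of mu_hat = 1.0, the quantity tracking the type-I error of
    the gene-by-gene null when true_mu = 1.
    """

    table: pd.DataFrame
    samples_per_cell: int
    run_type: str
    seed: object

    def freq_mu1(self) -> pd.Series:
        return self.table[1.0]


def assess_discrimination(
    true_mus: Sequence[float],
    n_genes_list: Sequence[int],
    one_minus_thetas: Sequence[float],
    samples_per_cell: int,
    library: ReferenceCumulativeLibrary,
    seed: object = 1,
    run_type: str = "single",
    topology: str = "circular",
) -> ErrorAssessment:
    """Classify freshly simulated trajectories and tabulate mu_hat frequencies.

    For each (true mu, N), ``samples_per_cell`` independent trajectories are
    simulated with checkpoints at every requested 1-theta; each trajectory is
    classified at every checkpoint (checkpoints of one trajectory are
    correlated, as in a genome observed at successive stages).  ``seed``
    should be independent of the library's seed.
    """
    omts = tuple(float(x) for x in one_minus_thetas)
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = iter(root.spawn(len(tuple(true_mus)) * len(tuple(n_genes_list))))
    counts: Dict[Tuple[float, int, float], "pd.Series"] = {}
    bins = list(library.mus)
    for mu in true_mus:
        model = GeometricDeletionModel(float(mu))
        for n in n_genes_list:
            cell_seed = next(children)
            streams = cell_seed.spawn(samples_per_cell)
            tallies = {omt: pd.Series(0, index=bins, dtype=float) for omt in omts}
            for i in range(samples_per_cell):
                traj = simulate_fractionation(int(n), model, omts, topology, seed=streams[i])
                for rec in traj.checkpoints:
                    res = classify_sample(
                        rec.tally, library, int(n), rec.one_minus_theta, run_type, sample_id=i
                    )
                    tallies[rec.one_minus_theta][res.mu_hat] += 1
            for omt in omts:
                counts[(float(mu), int(n), omt)] = tallies[omt] / samples_per_cell
    table = pd.DataFrame(counts).T
    table.index.names = ["true_mu", "n_genes", "one_minus_theta"]
    table.columns.name = "mu_hat"
    return ErrorAssessment(
        table=table, samples_per_cell=int(samples_per_cell), run_type=run_type, seed=seed
    )


def compare_run_types(
    assessment_single: ErrorAssessment, assessment_double: ErrorAssessment
) -> pd.DataFrame:
    """Per-cell difference in frequency of mu_hat = 1 (double minus single).

    Positive entries mean classification from double-copy runs infers the
    gene-by-gene model more often than classification from single-copy runs.
    """
    if not assessment_single.table.index.equals(assessment_double.table.index):
        raise ValueError("assessments were made on different grids")
    if assessment_single.samples_per_cell != assessment_double.samples_per_cell:
        raise ValueError("assessments used different sample counts")
    diff = assessment_double.freq_mu1() - assessment_single.freq_mu1()
    out = diff.to_frame("freq_mu1_double_minus_single")
    out["freq_mu1_single"] = assessment_single.freq_mu1()
    out["freq_mu1_double"] = assessment_double.freq_mu1()
    return out
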