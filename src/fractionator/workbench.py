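"""Study orchestration: reference building + error assessment in one run.

Reproduces the discrimination-study outputs — mu_hat histograms at a fixed
deleted proportion, frequency-of-mu_hat=1 curves against 1-theta, and the
single- vs double-copy comparison — on a configurable (desk-scale by
default) grid, writing TSVs plus a JSON manifest sufficient to reproduce
the run bit-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import GenomeState
from .discrimination import (
    DEFAULT_MU_GRID,
    DEFAULT_OMT_GRID,
    assess_discrimination,
    build_reference,
    compare_run_types,
)
from .io import write_library, write_manifest, write_track
from .overlap import OverlapParams, p0_discrete_closed, p0_discrete_sum

__all__ = ["StudyConfig", "run_figure_study", "generate_fixture"]

logger = logging.getLogger("fractionator")

FIXTURE_KINDS = ("tiny_state", "toy_tally", "analytic_grid")


@dataclass
class StudyConfig:
    """Parameters of a discrimination study; defaults are desk-scale."""

    ref_mus: Tuple[float, ...] = DEFAULT_MU_GRID
    true_mus: Tuple[float, ...] = (1.0, 1.2, 1.5, 1.9)
    n_genes_list: Tuple[int, ...] = (200, 900)
    one_minus_thetas: Tuple[float, ...] = DEFAULT_OMT_GRID
    replicates: int = 300
    samples: int = 300
    topology: str = "circular"
    seed: int = 0
    histogram_omt: float = 0.2
    run_types: Tuple[str, ...] = ("single", "double")
    out_dir: Optional[str] = None
    plot: bool = False

    def validate(self) -> None:
        grid = set(DEFAULT_OMT_GRID)
        bad = [x for x in self.one_minus_thetas if round(x, 6) not in {round(g, 6) for g in grid}]
        if bad:
            raise ValueError(
                f"1-theta values {bad} outside the supported grid 0.1..0.9 step 0.1"
            )
        if self.histogram_omt not in self.one_minus_thetas:
            raise ValueError("histogram_omt must be one of the configured 1-theta values")
        unknown = set(self.true_mus) - set(self.ref_mus)
        if unknown:
            raise ValueError(f"true mu values {sorted(unknown)} missing from reference grid")
        for rt in self.run_types:
            if rt not in ("single", "double"):
                raise ValueError(f"unknown run type {rt!r}")
        if self.replicates < 1 or self.samples < 1:
            raise ValueError("replicates and samples must be >= 1")


def run_figure_study(config: StudyConfig):
    """Build the reference library, assess discrimination, write study TSVs.

    Returns ``(library, {run_type: ErrorAssessment}, comparison_frame)``.
    When ``config.out_dir`` is set, writes:

    - ``library/``          serialized reference cumulatives
    - ``histograms.tsv``    mu_hat distribution per (true mu, N) at
                            ``histogram_omt`` deleted fraction
    - ``freq_mu1_<rt>.tsv`` frequency of mu_hat = 1 vs 1-theta per cell
    - ``run_type_comparison.tsv``  double-minus-single differences
    - ``manifest.json``
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    lib_seed, assess_seed = root.spawn(2)
    logger.info(
        "building reference library: %d mu x %s N, %d replicates",
        len(config.ref_mus),
        list(config.n_genes_list),
        config.replicates,
    )
    library = build_reference(
        mus=config.ref_mus,
        n_genes_list=config.n_genes_list,
        one_minus_thetas=config.one_minus_thetas,
        replicates=config.replicates,
        run_type="both",
        topology=config.topology,
        seed=lib_seed,
    )
    assessments = {}
    for rt in config.run_types:
        logger.info("assessing discrimination on %s-copy runs", rt)
        # same assess_seed for every run type: identical trajectories, so the
        # single/double comparison is paired
        assessments[rt] = assess_discrimination(
            true_mus=config.true_mus,
            n_genes_list=config.n_genes_list,
            one_minus_thetas=config.one_minus_thetas,
            samples_per_cell=config.samples,
            library=library,
            seed=assess_seed,
            run_type=rt,
            topology=config.topology,
        )
    comparison = None
    if {"single", "double"} <= set(config.run_types):
        comparison = compare_run_types(assessments["single"], assessments["double"])

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_library(library, out / "library")
        first_rt = config.run_types[0]
        hist = (
            assessments[first_rt]
            .table.xs(config.histogram_omt, level="one_minus_theta")
            .reset_index()
        )
        hist.to_csv(out / "histograms.tsv", sep="\t", index=False)
        for rt, assessment in assessments.items():
            assessment.freq_mu1().reset_index().rename(columns={1.0: "freq_mu1"}).to_csv(
                out / f"freq_mu1_{rt}.tsv", sep="\t", index=False
            )
        if comparison is not None:
            comparison.reset_index().to_csv(
                out / "run_type_comparison.tsv", sep="\t", index=False
            )
        if config.plot:
            _plot_study(assessments, out)
        write_manifest(out / "manifest.json", asdict(config))
    return library, assessments, comparison


def _plot_study(assessments, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for rt, assessment in assessments.items():
        fig, ax = plt.subplots(figsize=(6, 4))
        freq = assessment.freq_mu1()
        for (mu, n), grp in freq.groupby(level=["true_mu", "n_genes"]):
            omts = grp.index.get_level_values("one_minus_theta")
            ax.plot(omts, grp.values, marker="o", label=f"mu={mu}, N={n}")
        ax.set_xlabel("deleted proportion 1-theta")
        ax.set_ylabel("frequency of mu_hat = 1")
        ax.set_ylim(-0.02, 1.02)
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / f"freq_mu1_{rt}.png", dpi=150)
        plt.close(fig)


def generate_fixture(kind: str, seed: int = 0, out_dir: str = ".") -> Path:
    """Write a small deterministic input file used by tests and demos.

    kinds: ``tiny_state`` (N = 12 circular track with single-copy genes at
    1-based positions 3, 4, 5, 9), ``toy_tally`` (two single runs of lengths
    1 and 3), ``analytic_grid`` (p0 by summation vs closed form over a
    mu x nu grid).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if kind == "tiny_state":
        cs = np.ones(12, dtype=bool)
        cs[[2, 3, 4, 8]] = False  # 0-based
        path = out / "tiny_state.tsv"
        write_track(GenomeState(cs, "circular"), path)
    elif kind == "toy_tally":
        path = out / "toy_tally.tsv"
        pd.DataFrame(
            {
                "one_minus_theta": [0.4, 0.4, 0.4, 0.4],
                "run_type": ["single", "single", "double", "double"],
                "length": [1, 3, 2, 4],
                "count": [1, 1, 1, 1],
            }
        ).to_csv(path, sep="\t", index=False)
    elif kind == "analytic_grid":
        rows = []
        for mu in (1.0, 1.1, 1.5, 2.0, 2.4):
            for nu in (2.0, 5.0, 10.0, 100.0, 1000.0):
                params = OverlapParams(mu, nu)
                rows.append(
                    (mu, nu, p0_discrete_sum(params, 1e-12), p0_discrete_closed(params))
                )
        path = out / "analytic_grid.tsv"
        pd.DataFrame(rows, columns=["mu", "nu", "p0_sum", "p0_closed"]).to_csv(
            path, sep="\t", index=False, float_format="%.12g"
        )
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    return path
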