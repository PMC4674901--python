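"""TSV/JSON interchange: copy-state tracks, trajectory summaries, libraries.

All positions in on-disk tracks are 1-based; the in-memory API is 0-based.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import GenomeState, RunLengthTally, Trajectory
from .discrimination import ReferenceCumulativeLibrary

__all__ = [
    "read_track",
    "write_track",
    "track_frame",
    "write_trajectory_summary",
    "read_tally",
    "write_library",
    "read_library",
    "write_manifest",
]

PathLike = Union[str, Path]


def track_frame(state: GenomeState, gene_ids=None) -> pd.DataFrame:
    """Copy-state track as a DataFrame: position (1-based), gene_id, copies."""
    n = state.n_genes
    df = pd.DataFrame(
        {
            "position": np.arange(1, n + 1),
            "gene_id": gene_ids if gene_ids is not None else [f"g{i}" for i in range(1, n + 1)],
            "copies": np.where(state.copy_state, 2, 1),
        }
    )
    return df


def write_track(state: GenomeState, path: PathLike, gene_ids=None) -> None:
    track_frame(state, gene_ids).to_csv(path, sep="\t", index=False)


def read_track(path: PathLike, topology: str = "circular") -> GenomeState:
    """Read a copy-state track TSV (columns position, [gene_id,] copies)."""
    df = pd.read_csv(path, sep="\t")
    required = {"position", "copies"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"track file {path} is missing columns {sorted(missing)}")
    df = df.sort_values("position")
    n = len(df)
    if not np.array_equal(df["position"].to_numpy(), np.arange(1, n + 1)):
        raise ValueError(f"track positions must be exactly 1..{n} with no gaps")
    copies = df["copies"].to_numpy()
    if not np.isin(copies, (1, 2)).all():
        raise ValueError("track 'copies' column must contain only 1 or 2")
    return GenomeState(copies == 2, topology)


def write_trajectory_summary(traj: Trajectory, path: PathLike) -> None:
    """Long-format run tallies: one_minus_theta, run_type, length, count."""
    rows = []
    for rec in traj.checkpoints:
        for run_type in ("single", "double"):
            for length, count in sorted(rec.tally.runs(run_type).items()):
                rows.append((rec.one_minus_theta, run_type, length, count))
    pd.DataFrame(
        rows, columns=["one_minus_theta", "run_type", "length", "count"]
    ).to_csv(path, sep="\t", index=False)


def read_tally(
    path: PathLike, one_minus_theta: float, n_genes: int
) -> RunLengthTally:
    """Rebuild a RunLengthTally from a trajectory-summary TSV at one checkpoint."""
    from collections import Counter

    df = pd.read_csv(path, sep="\t")
    sel = df[np.isclose(df["one_minus_theta"], one_minus_theta)]
    if sel.empty:
        raise ValueError(f"no rows at 1-theta = {one_minus_theta} in {path}")
    single = Counter(
        dict(zip(sel[sel.run_type == "single"].length, sel[sel.run_type == "single"]["count"]))
    )
    double = Counter(
        dict(zip(sel[sel.run_type == "double"].length, sel[sel.run_type == "double"]["count"]))
    )
    deleted = int(sum(l * c for l, c in single.items()))
    return RunLengthTally(single, double, int(n_genes), deleted)


def _seed_repr(seed) -> Optional[int]:
    if isinstance(seed, (int, np.integer)):
        return int(seed)
    if isinstance(seed, np.random.SeedSequence):
        ent = seed.entropy
        return int(ent) if isinstance(ent, (int, np.integer)) else None
    return None


def write_library(lib: ReferenceCumulativeLibrary, outdir: PathLike) -> None:
    """Serialise a reference library: one TSV per run type + JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_types = [rt for rt, d in lib.cumulatives.items() if d]
    for rt in run_types:
        lib.to_frame(rt).to_csv(outdir / f"reference_{rt}.tsv", sep="\t", index=False)
    sidecar = {
        "mus": list(lib.mus),
        "n_genes_list": list(lib.n_genes_list),
        "one_minus_thetas": list(lib.one_minus_thetas),
        "replicates": lib.replicates,
        "seed": _seed_repr(lib.seed),
        "topology": lib.topology,
        "pooling": lib.pooling,
        "run_types": run_types,
    }
    (outdir / "library.json").write_text(json.dumps(sidecar, indent=2) + "\n")


def read_library(outdir: PathLike) -> ReferenceCumulativeLibrary:
    outdir = Path(outdir)
    sidecar = json.loads((outdir / "library.json").read_text())
    lib = ReferenceCumulativeLibrary(
        mus=tuple(sidecar["mus"]),
        n_genes_list=tuple(sidecar["n_genes_list"]),
        one_minus_thetas=tuple(sidecar["one_minus_thetas"]),
        replicates=sidecar["replicates"],
        seed=sidecar["seed"],
        topology=sidecar["topology"],
        pooling=sidecar["pooling"],
    )
    from .discrimination import _key

    for rt in sidecar["run_types"]:
        df = pd.read_csv(outdir / f"reference_{rt}.tsv", sep="\t")
        for (mu, n, omt), grp in df.groupby(["mu", "n_genes", "one_minus_theta"]):
            grp = grp.sort_values("length")
            lmax = int(grp["length"].max())
            cum = np.ones(lmax)
            cum[grp["length"].to_numpy() - 1] = grp["cum_prob"].to_numpy()
            lib.cumulatives[rt][_key(mu, int(n), omt)] = cum
    return lib


def write_manifest(path: PathLike, params: dict) -> None:
    """Record the full parameter set (plus package version) next to outputs."""
    from . import __version__

    payload = dict(params)
    payload["package"] = "fractionator"
    payload["version"] = __version__
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
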