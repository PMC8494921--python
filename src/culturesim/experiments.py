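"""Parameter-sweep driver, replicate aggregation, output and plotting.

A sweep is a cartesian grid over payoff-bias levels, learner types, and
either population sizes (unstructured, the "size" sweep) or neighbourhood
sigmas at fixed N=200 (the "structure" sweep).  Each grid cell is run for
``n_replicates`` independent simulations whose seeds derive deterministically
from ``(base_seed, cell_index, replicate_index)``, so any cell — or any
single replicate — can be reproduced in isolation and the result does not
depend on execution order.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core import LEARNER_TYPES, SimulationConfig, run_simulation

__all__ = [
    "SweepGrid",
    "SweepResult",
    "build_sweep",
    "replicate_seed",
    "run_cell",
    "run_sweep",
    "write_results",
    "read_results",
    "plot_trajectories",
]

logger = logging.getLogger(__name__)

DEFAULT_BIAS_LEVELS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
DEFAULT_SIZES = (10, 20, 100, 200)
DEFAULT_SIGMAS = (1.0, 3.0, 5.0, 7.0)
STRUCTURED_POPULATION_SIZE = 200

RESULT_COLUMNS = [
    "sweep_kind",
    "payoff_bias",
    "learner_type",
    "population_size",
    "sigma",
    "time_step",
    "mean_diversity",
    "se_diversity",
    "mean_payoff",
    "se_payoff",
    "n_replicates",
]


@dataclass(frozen=True)
class SweepGrid:
    """A cartesian parameter grid plus replication and seeding settings.

    ``kind`` is "size" (unstructured; ``levels`` are population sizes) or
    "structure" (ring neighbourhoods at N=200; ``levels`` are sigmas).
    """

    kind: str
    payoff_bias_levels: tuple[float, ...] = DEFAULT_BIAS_LEVELS
    learner_types: tuple[str, ...] = LEARNER_TYPES
    levels: tuple[float, ...] = ()
    n_replicates: int = 10_000
    n_steps: int = 200
    error_rate: float = 0.02
    pool_size: int = 100
    payoff_rate: float = 1.0
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("size", "structure"):
            raise ValueError("kind must be 'size' or 'structure'")
        for name in ("payoff_bias_levels", "learner_types", "levels"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def n_cells(self) -> int:
        return (
            len(self.payoff_bias_levels) * len(self.learner_types) * len(self.levels)
        )

    def cells(self) -> Iterator[tuple[int, dict]]:
        """Yield (cell_index, cell parameters) in a fixed deterministic order."""
        combos = itertools.product(
            self.payoff_bias_levels, self.learner_types, self.levels
        )
        for index, (b, t, level) in enumerate(combos):
            if self.kind == "size":
                cell = {
                    "payoff_bias": b,
                    "learner_type": t,
                    "population_size": int(level),
                    "sigma": None,
                }
            else:
                cell = {
                    "payoff_bias": b,
                    "learner_type": t,
                    "population_size": STRUCTURED_POPULATION_SIZE,
                    "sigma": float(level),
                }
            yield index, cell

    def cell_config(self, cell: dict, seed: int) -> SimulationConfig:
        return SimulationConfig(
            payoff_bias=cell["payoff_bias"],
            learner_type=cell["learner_type"],
            error_rate=self.error_rate,
            pool_size=self.pool_size,
            population_size=cell["population_size"],
            structure_sigma=cell["sigma"],
            n_steps=self.n_steps,
            payoff_rate=self.payoff_rate,
            seed=seed,
        )


def build_sweep(kind: str, **overrides) -> SweepGrid:
    """Build a sweep grid with the study defaults where not overridden.

    The default "size" sweep is 6 bias levels x 3 learner types x 4
    population sizes (72 cells); the default "structure" sweep swaps the
    sizes for sigmas 1, 3, 5, 7 at N=200 (also 72 cells).
    """
    if kind not in ("size", "structure"):
        raise ValueError("kind must be 'size' or 'structure'")
    if "levels" not in overrides:
        overrides["levels"] = DEFAULT_SIZES if kind == "size" else DEFAULT_SIGMAS
    for name in ("payoff_bias_levels", "learner_types", "levels"):
        if name in overrides:
            overrides[name] = tuple(overrides[name])
    return SweepGrid(kind=kind, **overrides)


def replicate_seed(base_seed: int, cell_index: int, replicate_index: int) -> int:
    """Deterministic per-replicate seed from (base_seed, cell, replicate)."""
    ss = np.random.SeedSequence((int(base_seed), int(cell_index), int(replicate_index)))
    return int(ss.generate_state(1)[0] % (2**31))


def _aggregate(diversity: np.ndarray, payoff: np.ndarray) -> dict[str, np.ndarray]:
    # rows = replicates, columns = time steps 0..n_steps
    n = diversity.shape[0]
    ddof = 1 if n > 1 else 0
    scale = np.sqrt(n)
    return {
        "mean_diversity": diversity.mean(axis=0),
        "se_diversity": diversity.std(axis=0, ddof=ddof) / scale,
        "mean_payoff": payoff.mean(axis=0),
        "se_payoff": payoff.std(axis=0, ddof=ddof) / scale,
    }


def run_cell(grid: SweepGrid, cell_index: int, cell: dict) -> pd.DataFrame:
    """Run all replicates of one grid cell and aggregate per-step statistics."""
    n_records = grid.n_steps + 1
    diversity = np.empty((grid.n_replicates, n_records))
    payoff = np.empty((grid.n_replicates, n_records))
    for rep in range(grid.n_replicates):
        seed = replicate_seed(grid.base_seed, cell_index, rep)
        trajectory = run_simulation(grid.cell_config(cell, seed))
        diversity[rep] = trajectory.diversity
        payoff[rep] = trajectory.mean_payoff
    stats = _aggregate(diversity, payoff)
    frame = pd.DataFrame(
        {
            "sweep_kind": grid.kind,
            "payoff_bias": cell["payoff_bias"],
            "learner_type": cell["learner_type"],
            "population_size": cell["population_size"],
            "sigma": np.nan if cell["sigma"] is None else cell["sigma"],
            "time_step": np.arange(n_records),
            **stats,
            "n_replicates": grid.n_replicates,
        }
    )
    return frame[RESULT_COLUMNS]


@dataclass
class SweepResult:
    """Replicate-averaged trajectories for every cell of a sweep.

    ``data`` is tidy: one row per (cell, time_step) with per-step replicate
    means and standard errors of diversity and mean payoff.  ``meta`` carries
    full provenance (grid parameters, base seed, engine version).
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)


def run_sweep(grid: SweepGrid, progress: bool = False) -> SweepResult:
    """Run every cell of the grid; deterministic given ``base_seed``."""
    logger.info(
        "sweep start: kind=%s cells=%d replicates=%d steps=%d base_seed=%d",
        grid.kind, grid.n_cells, grid.n_replicates, grid.n_steps, grid.base_seed,
    )
    frames = []
    for cell_index, cell in grid.cells():
        logger.info("cell %d/%d: %s", cell_index + 1, grid.n_cells, cell)
        frames.append(run_cell(grid, cell_index, cell))
        if progress:  # pragma: no cover - cosmetic
            print(f"cell {cell_index + 1}/{grid.n_cells} done", flush=True)
    data = pd.concat(frames, ignore_index=True)
    meta = {
        "engine_version": __version__,
        "grid": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(grid).items()
        },
        "seed_rule": "numpy SeedSequence((base_seed, cell_index, replicate_index)) mod 2^31",
    }
    return SweepResult(data=data, meta=meta)


def write_results(result: SweepResult, out_path: str | Path) -> tuple[Path, Path]:
    """Write the tidy CSV and its JSON metadata sidecar.

    ``out_path`` is the CSV path; the sidecar replaces its suffix with
    ``.meta.json``.  Floats are written in round-trip precision so reading
    the CSV back reproduces the in-memory aggregates exactly.
    """
    csv_path = Path(out_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    result.data.to_csv(csv_path, index=False)
    meta_path = csv_path.with_suffix(".meta.json")
    meta_path.write_text(json.dumps(result.meta, indent=2) + "\n")
    return csv_path, meta_path


def read_results(csv_path: str | Path) -> SweepResult:
    """Read a written sweep back (CSV + sidecar if present)."""
    csv_path = Path(csv_path)
    data = pd.read_csv(csv_path)
    meta_path = csv_path.with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return SweepResult(data=data, meta=meta)


def _panel_levels(data: pd.DataFrame) -> tuple[str, list]:
    if data["sigma"].notna().any():
        return "sigma", sorted(data["sigma"].dropna().unique())
    return "population_size", sorted(data["population_size"].unique())


def plot_trajectories(
    result: SweepResult, out_path: str | Path, formats: Sequence[str] = ("png",)
) -> list[Path]:
    """Plot replicate-mean trajectories, one panel grid per quantity.

    Panels are laid out sizes-or-sigmas (rows) x payoff-bias levels
    (columns), one line per learner type; produces one figure for diversity
    and one for mean payoff.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = result.data
    if data.empty:
        raise ValueError("result is empty")
    level_col, levels = _panel_levels(data)
    bias_levels = sorted(data["payoff_bias"].unique())
    types = [t for t in LEARNER_TYPES if t in set(data["learner_type"])]
    colors = {"copier": "tab:blue", "innovator": "tab:orange", "maintainer": "tab:green"}

    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    written = []
    for column, label in (
        ("mean_diversity", "Gini-Simpson diversity"),
        ("mean_payoff", "mean variant payoff"),
    ):
        nrows, ncols = len(levels), len(bias_levels)
        fig, axes = plt.subplots(
            nrows, ncols, figsize=(2.2 * ncols + 1, 1.8 * nrows + 1),
            sharex=True, sharey=(column == "mean_diversity"), squeeze=False,
        )
        for i, level in enumerate(levels):
            for j, b in enumerate(bias_levels):
                ax = axes[i][j]
                mask = (data[level_col] == level) & (data["payoff_bias"] == b)
                for t in types:
                    sub = data[mask & (data["learner_type"] == t)]
                    ax.plot(sub["time_step"], sub[column],
                            color=colors.get(t), label=t, lw=1)
                if i == 0:
                    ax.set_title(f"b = {b:g}", fontsize=9)
                if j == 0:
                    name = "sigma" if level_col == "sigma" else "N"
                    ax.set_ylabel(f"{name} = {level:g}", fontsize=9)
        axes[0][-1].legend(fontsize=7, frameon=False)
        fig.supxlabel("time step")
        fig.supylabel(label)
        fig.tight_layout()
        for fmt in formats:
            path = out_path.with_name(f"{out_path.stem}_{column}.{fmt}")
            fig.savefig(path, dpi=150)
            written.append(path)
        plt.close(fig)
    return written
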