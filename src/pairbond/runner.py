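"""Replicate execution, the crossed experimental design, metrics and file output.

A replicate is fully determined by (config, seed): it founds a population,
runs the configured number of iterations, and returns a
:class:`RunSummary` with a (thinned) per-iteration metrics table, the
final-population genotype table, and run-level courtship statistics.

`run_crossed_design` evaluates a grid of named configurations with
deterministic per-(cell, replicate) child seeds and optional incremental
CSV output so interrupted sweeps can resume.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import SimConfig
from .core import EMOTIONS, TRAIT_NAMES
from .dynamics import MetricsRecord, Population, run_iteration

__all__ = [
    "RunSummary",
    "run_replicate",
    "run_crossed_design",
    "mutual_cooperation_rate",
    "courtship_statistics",
    "child_seed",
    "paper_grid",
    "GENOTYPE_COLUMNS",
]

logger = logging.getLogger("pairbond")

METRIC_COLUMNS = [
    "iteration",
    "mutual_cooperation_rate",
    "n_bonded_pairs",
    "n_new_pairings",
    "n_divorces",
    "n_deceptions",
    "mean_courtship_rounds",
    "mean_lifetime_payoff",
]

GENOTYPE_COLUMNS = ["agent_id"] + [
    f"G_{e}{t}" for e in EMOTIONS for t in TRAIT_NAMES
] + ["lifetime_payoff"]


@dataclass
class RunSummary:
    """Everything one replicate produced."""

    config: SimConfig
    seed: int
    metrics: pd.DataFrame
    genotypes: pd.DataFrame
    mean_courtship_rounds_per_pairing: float
    total_new_pairings: int = 0
    total_courtship_interactions: int = 0

    def final_epoch_cooperation(self, fraction: float = 0.1) -> float:
        """Mean mutual-cooperation rate over the last `fraction` of recorded rows."""
        if self.metrics.empty:
            return 0.0
        tail = max(1, int(round(fraction * len(self.metrics))))
        return float(self.metrics["mutual_cooperation_rate"].iloc[-tail:].mean())

    def to_dir(self, path: str | Path) -> Path:
        """Write metrics.csv, genotypes.csv and manifest.json under `path`."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(path / "metrics.csv", index=False)
        self.genotypes.to_csv(path / "genotypes.csv", index=False)
        manifest = {
            "config": self.config.to_dict(),
            "seed": self.seed,
            "mean_courtship_rounds_per_pairing": self.mean_courtship_rounds_per_pairing,
            "total_new_pairings": self.total_new_pairings,
            "total_courtship_interactions": self.total_courtship_interactions,
            "package": "pairbond 0.1.0",
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return path


def mutual_cooperation_rate(actions_a: Sequence[bool], actions_b: Sequence[bool]) -> float:
    """Fraction of bonded rounds where both actual actions were cooperate.

    Inputs are parallel cooperation flags for one iteration's bonded rounds.
    An iteration with no bonded rounds contributes 0 (a population that
    never bonds is non-cooperative).
    """
    a = np.asarray(actions_a, dtype=bool)
    b = np.asarray(actions_b, dtype=bool)
    if a.size == 0:
        return 0.0
    return float((a & b).mean())


def genotype_table(pop: Population) -> pd.DataFrame:
    """Final-population genotype dump: one row per agent, 24 named traits."""
    flat = pop.geno.reshape(pop.n, 24)
    df = pd.DataFrame(flat, columns=GENOTYPE_COLUMNS[1:-1])
    df.insert(0, "agent_id", np.arange(pop.n))
    df["lifetime_payoff"] = pop.payoff
    return df


def run_replicate(cfg: SimConfig, seed: int | None = None,
                  progress_every: int = 0) -> RunSummary:
    """Run one replicate; identical (config, seed) gives identical output."""
    cfg.validate()
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    pop = Population.founders(cfg, rng)
    logger.info("replicate start: seed=%d N=%d iterations=%d", seed, cfg.N, cfg.iterations)

    records: list[MetricsRecord] = []
    total_pairings = 0
    total_courtships = 0
    for it in range(cfg.iterations):
        rec = run_iteration(pop, cfg, rng)
        total_pairings += rec.n_new_pairings
        total_courtships += int(round(rec.mean_courtship_rounds * rec.n_new_pairings))
        if it % cfg.thin == 0 or it == cfg.iterations - 1:
            records.append(rec)
        if progress_every and it % progress_every == 0:
            logger.info("iteration %d/%d coop=%.3f", it, cfg.iterations,
                        rec.mutual_cooperation_rate)

    metrics = pd.DataFrame([vars(r) for r in records], columns=METRIC_COLUMNS)
    mean_rounds = total_courtships / total_pairings if total_pairings else 0.0
    logger.info("replicate end: seed=%d", seed)
    return RunSummary(
        config=cfg,
        seed=seed,
        metrics=metrics,
        genotypes=genotype_table(pop),
        mean_courtship_rounds_per_pairing=mean_rounds,
        total_new_pairings=total_pairings,
        total_courtship_interactions=total_courtships,
    )


def child_seed(base_seed: int, cell_id: str, replicate: int) -> int:
    """Deterministic, collision-resistant seed for one (cell, replicate)."""
    key = f"{base_seed}|{cell_id}|{replicate}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def run_crossed_design(grid: Mapping[str, SimConfig], replicates: int,
                       base_seed: int = 0, out_dir: str | Path | None = None,
                       final_epoch_fraction: float = 0.1) -> pd.DataFrame:
    """Run every (cell, replicate) of a named configuration grid.

    Returns one row per run with summary statistics.  With `out_dir`, each
    row is written incrementally to ``sweep.csv`` and already-present rows
    are skipped, so interrupted sweeps resume.
    """
    cells = list(grid.items())
    ids = [c for c, _ in cells]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate cell ids in grid")

    out_path = Path(out_dir) / "sweep.csv" if out_dir is not None else None
    done: set[tuple[str, int]] = set()
    rows: list[dict] = []
    if out_path is not None and out_path.exists():
        prev = pd.read_csv(out_path)
        rows = prev.to_dict("records")
        done = {(r["cell"], int(r["replicate"])) for r in rows}

    for cell_id, cfg in cells:
        for rep in range(replicates):
            if (cell_id, rep) in done:
                continue
            seed = child_seed(base_seed, cell_id, rep)
            summary = run_replicate(cfg, seed=seed)
            row = {
                "cell": cell_id,
                "replicate": rep,
                "seed": seed,
                "final_epoch_cooperation": summary.final_epoch_cooperation(final_epoch_fraction),
                "mean_courtship_rounds_per_pairing": summary.mean_courtship_rounds_per_pairing,
                "mean_lifetime_payoff": float(summary.metrics["mean_lifetime_payoff"].iloc[-1])
                if not summary.metrics.empty else 0.0,
            }
            rows.append(row)
            if out_path is not None:
                out_path.parent.mkdir(parents=True, exist_ok=True)
                pd.DataFrame(rows).to_csv(out_path, index=False)
    return pd.DataFrame(rows)


def courtship_statistics(run_means: Iterable[float]) -> dict:
    """Top-quartile average and maximum of run-level mean courtship rounds.

    Each element of `run_means` is one run's mean number of courtship
    interactions per new pairing.  The top quartile is the ceil(n/4)
    largest run means.
    """
    means = np.asarray(sorted(run_means, reverse=True), dtype=float)
    if means.size == 0:
        raise ValueError("courtship_statistics requires at least one run")
    k = int(np.ceil(means.size / 4))
    return {
        "top_quartile_average": float(means[:k].mean()),
        "max_average": float(means[0]),
    }


def paper_grid(base: SimConfig | None = None) -> dict[str, SimConfig]:
    """The full crossed design: noise levels x noise types x costs x toggles.

    Enumerates xi in {0, 0.04, 0.08, 0.12, 0.16, 0.20} for perceptual and
    action noise, c_cou in {0, 0.4, 0.8}, c_div in {0, 4, 16}, c_dec in
    {0, 0.4, 0.8, 1.2, 1.6}, crossed with the bookkeeping/courtship/deceit
    toggles (costs of disabled mechanisms fixed at their first level to
    avoid redundant cells).
    """
    from .interactions import NoiseSpec

    if base is None:
        base = SimConfig()
    grid: dict[str, SimConfig] = {}
    for kind in ("perceptual", "action"):
        for xi in (0.0, 0.04, 0.08, 0.12, 0.16, 0.20):
            for book in (True, False):
                for court in (True, False):
                    for deceit in (True, False):
                        for c_cou in (0.0, 0.4, 0.8) if court else (0.0,):
                            for c_dec in (0.0, 0.4, 0.8, 1.2, 1.6) if deceit else (0.0,):
                                for c_div in (0.0, 4.0, 16.0):
                                    cid = (f"{kind}-xi{xi:g}-book{int(book)}-court{int(court)}"
                                           f"-dec{int(deceit)}-ccou{c_cou:g}-cdec{c_dec:g}-cdiv{c_div:g}")
                                    grid[cid] = base.replace(
                                        noise=NoiseSpec(kind=kind, xi=xi),
                                        enable_bookkeeping=book,
                                        enable_courtship=court,
                                        enable_deceit=deceit,
                                        c_cou=c_cou, c_dec=c_dec, c_div=c_div,
                                    )
    return grid
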