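"""Parameter sweeps and named experiment presets.

Each preset enumerates the grid of one of the standard experimental designs
(haploid/diploid, uniform or two-clone start, with or without drift, binary
or continuous fitness) as a list of :class:`TrialConfig` cells.  Presets ship
with desk-scale trial counts; pass ``trials``/``replicates`` to restore the
full 80 x 100 protocol.  Per-cell RNG streams derive deterministically from
the master seed and the cell index, so partial re-runs reproduce bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .landscape import FitnessSpec
from .reproduction import NO_DRIFT, TWO_TYPES
from .selection import TrialConfig, run_experiment, run_replicates

logger = logging.getLogger(__name__)

# the nine mixability ratios of the standard panel grid: 0.9 / f for the
# fitness-1 fractions f = 0.89 ... 0.81 of the binary design
D_GRID = [round(0.9 / f, 4) for f in
          (0.89, 0.88, 0.87, 0.86, 0.85, 0.84, 0.83, 0.82, 0.81)]
D_ANCHORS = [1.0112, 1.0588, 1.1111]
R_GRID = [round(0.05 * k, 2) for k in range(11)]
L_GRID_HAPLOID = list(range(2, 21, 2))
L_GRID_DIPLOID = list(range(2, 17, 2))
N_GRID = [250, 500, 1000, 2000, 4000]
SIGMA_GRID = [0.05, 0.15, 0.25, 0.35, 0.45]


@dataclass
class SweepConfig:
    name: str
    cells: list[TrialConfig]
    trials: int = 25
    replicates: int = 1
    seed: int = 0


def _cells(base: TrialConfig, **grids) -> list[TrialConfig]:
    keys = list(grids)
    cells = [base]
    for key in keys:
        new = []
        for cell in cells:
            for value in grids[key]:
                if key == "sigma":
                    new.append(
                        replace(cell, fitness=replace(cell.fitness, sd=value))
                    )
                elif key == "frac_j":
                    new.append(
                        replace(
                            cell,
                            binary_frac_j=value,
                            d=round(cell.binary_frac_i / value, 4),
                        )
                    )
                else:
                    new.append(replace(cell, **{key: value}))
        cells = new
    return cells


def _preset_fig1() -> list[TrialConfig]:
    base = TrialConfig(ploidy=1, N=2000, alleles_per_locus=2)
    return _cells(base, d=D_GRID, num_loci=L_GRID_HAPLOID)


def _preset_fig2() -> list[TrialConfig]:
    base = TrialConfig(
        ploidy=1, N=2000, alleles_per_locus=2, scheme=TWO_TYPES, drift=NO_DRIFT
    )
    return _cells(base, d=D_GRID, num_loci=L_GRID_HAPLOID)


def _preset_fig3() -> list[TrialConfig]:
    base = TrialConfig(ploidy=1, N=2000, num_loci=12, start="clones",
                       scheme="clones_only")
    return _cells(base, d=D_GRID, r=R_GRID)


def _preset_fig4() -> list[TrialConfig]:
    base = TrialConfig(ploidy=1, num_loci=12, start="clones", scheme="clones_only")
    return _cells(base, d=D_ANCHORS, r=[0.0, 0.5], N=N_GRID)


def _preset_fig5() -> list[TrialConfig]:
    base = TrialConfig(ploidy=2, N=2000, alleles_per_locus=2)
    return _cells(base, d=D_GRID, num_loci=L_GRID_DIPLOID)


def _preset_fig6() -> list[TrialConfig]:
    base = TrialConfig(
        ploidy=2, N=2000, num_loci=8, start="clones", scheme="clones_only",
        generations=2,
    )
    return _cells(base, d=D_GRID, r=R_GRID)


def _preset_fig7() -> list[TrialConfig]:
    base = TrialConfig(ploidy=1, N=2000, scheme=TWO_TYPES)
    return _cells(base, d=D_GRID, num_loci=L_GRID_HAPLOID)


def _preset_fig8() -> list[TrialConfig]:
    base = TrialConfig(ploidy=1, N=2000, all_loci=True)
    return _cells(base, d=D_GRID, num_loci=L_GRID_HAPLOID)


def _preset_fig9() -> list[TrialConfig]:
    base = TrialConfig(ploidy=1, N=2000, num_loci=12, start="clones",
                       scheme="clones_only")
    return _cells(base, d=D_ANCHORS, r=[0.0, 0.5], sigma=SIGMA_GRID)


def _preset_fig11() -> list[TrialConfig]:
    base = TrialConfig(ploidy=2, N=2000, scheme=TWO_TYPES, drift=NO_DRIFT)
    return _cells(base, d=D_GRID, num_loci=L_GRID_DIPLOID)


def _preset_fig15() -> list[TrialConfig]:
    base = TrialConfig(
        ploidy=1, N=2000, fitness=FitnessSpec(mode="binary", mean=0.9, sd=0.0),
        binary_frac_i=0.9,
    )
    return _cells(base, frac_j=[0.89, 0.87, 0.85, 0.83, 0.81],
                  num_loci=[12, 14, 16, 18, 20])


def _preset_fig18() -> list[TrialConfig]:
    base = TrialConfig(
        ploidy=1, N=2000, num_loci=12, start="clones", scheme="clones_only",
        fitness=FitnessSpec(mode="binary", mean=0.9, sd=0.0), binary_frac_i=0.9,
    )
    return _cells(base, frac_j=[0.89, 0.85, 0.81], r=R_GRID)


def _preset_fig19() -> list[TrialConfig]:
    base = TrialConfig(
        ploidy=2, N=2000, fitness=FitnessSpec(mode="binary", mean=0.9, sd=0.0),
        binary_frac_i=0.9,
    )
    return _cells(base, frac_j=[0.89, 0.85, 0.81], num_loci=[9, 11, 13, 15])


def _preset_fig20() -> list[TrialConfig]:
    base = TrialConfig(
        ploidy=2, N=2000, num_loci=8, start="clones", scheme="clones_only",
        generations=2,
        fitness=FitnessSpec(mode="binary", mean=0.9, sd=0.0), binary_frac_i=0.9,
    )
    return _cells(base, frac_j=[0.89, 0.85, 0.81], r=R_GRID)


PRESETS = {
    "fig1": _preset_fig1,
    "fig2": _preset_fig2,
    "fig3": _preset_fig3,
    "fig4": _preset_fig4,
    "fig5": _preset_fig5,
    "fig6": _preset_fig6,
    "fig7": _preset_fig7,
    "fig8": _preset_fig8,
    "fig9": _preset_fig9,
    "fig11": _preset_fig11,
    "fig15": _preset_fig15,
    "fig18": _preset_fig18,
    "fig19": _preset_fig19,
    "fig20": _preset_fig20,
}


def preset_sweep(
    name: str, trials: int = 25, replicates: int = 1, seed: int = 0
) -> SweepConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return SweepConfig(
        name=name, cells=PRESETS[name](), trials=trials, replicates=replicates,
        seed=seed,
    )


def cell_rng_seed(master_seed: int, cell_index: int) -> np.random.SeedSequence:
    """Deterministic per-cell stream: master seed plus cell coordinates."""
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(cell_index,))


def run_sweep(cfg: SweepConfig) -> pd.DataFrame:
    """One result row per grid cell; infeasible cells report their error
    instead of aborting the sweep."""
    records = []
    for k, cell in enumerate(cfg.cells):
        ss = cell_rng_seed(cfg.seed, k)
        try:
            if cfg.replicates >= 2:
                res = run_replicates(cell, cfg.replicates, cfg.trials, ss)
            else:
                res = run_experiment(cell, cfg.trials, np.random.default_rng(ss))
            rec = res.to_record()
            rec["error"] = ""
        except Exception as exc:  # infeasible cell (e.g. binary fill at small L)
            logger.warning("cell %d of sweep %s failed: %s", k, cfg.name, exc)
            rec = {"P": np.nan, "g": np.nan, "error": str(exc)}
        rec["cell"] = k
        rec["preset"] = cfg.name
        rec["seed"] = cfg.seed
        records.append(rec)
        logger.info(
            "sweep %s cell %d/%d: P=%s g=%s",
            cfg.name, k + 1, len(cfg.cells), rec.get("P"), rec.get("g"),
        )
    return pd.DataFrame.from_records(records)
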