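"""Per-marker-set regressions and the fixed-size resampling comparison.

Marker sets of different sizes capture different amounts of variance
partly because of their size; to compare categories on an equal
footing, each set is also refit on a fixed number of markers (default
500) drawn at random without replacement, the draw repeated (default
500 times) and the per-replicate R^2 summarised as mean +/- SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import SET_MAFS, SET_REGIONS
from .model import MCMCConfig, WGRPrior, default_prior, gibbs_fit

__all__ = [
    "SubsetResult",
    "draw_replicate_indices",
    "run_per_set",
    "resample_fixed_size",
    "report_tables",
]

logger = logging.getLogger(__name__)


@dataclass
class SubsetResult:
    """Resampling summary for one marker set."""

    set_name: str
    n_markers: int
    n_resample: int
    n_reps: int
    r2_reps: np.ndarray
    seed: int

    @property
    def r2_mean(self) -> float:
        return float(np.mean(self.r2_reps))

    @property
    def r2_sd(self) -> float:
        return float(np.std(self.r2_reps, ddof=1)) if self.n_reps > 1 else 0.0


def draw_replicate_indices(indices, size: int, rep: int, master_seed: int):
    """Without-replacement draw for replicate ``rep``.

    The sub-stream is keyed on (master_seed, rep) so replicates are
    reproducible and independent of execution order.
    """
    indices = np.asarray(indices)
    if size > indices.size:
        raise ValueError(f"subset size {size} exceeds set size {indices.size}")
    rng = np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(101, rep)))
    return np.sort(rng.choice(indices, size, replace=False))


def _fit_r2(y, Z, Xc, prior, mcmc) -> float:
    post = gibbs_fit(y, Z, Xc, prior=prior, mcmc=mcmc)
    return post.r_squared


def run_per_set(y, Z, Xc, marker_sets: dict, prior: WGRPrior | None = None,
                mcmc: MCMCConfig | None = None, seed: int = 0,
                partition_r2: float = 0.5) -> pd.DataFrame:
    """Full-set R^2 for every marker set plus the covariates-only baseline.

    Each fit shares y and Z; when ``prior`` is None a default prior is
    derived per set from its own marker-variance total.  Rows:
    ``baseline`` (L=0) then one per set.
    """
    if isinstance(marker_sets, dict):
        items = list(marker_sets.items())
    else:
        items = [(s.name, s) for s in marker_sets]
    names = [n for n, _ in items]
    if len(set(names)) != len(names):
        raise ValueError("duplicate marker-set names")
    mcmc = mcmc or MCMCConfig()
    rows = []
    base = MCMCConfig(n_iter=mcmc.n_iter, burn_in=mcmc.burn_in, thin=mcmc.thin,
                      seed=_subseed(seed, 0))
    r2_base = _fit_r2(y, Z, None, prior, base)
    rows.append({"set_name": "baseline", "n_markers": 0, "r2_full": r2_base})
    for k, (name, ms) in enumerate(items, start=1):
        idx = np.asarray(ms.indices, dtype=int)
        if idx.size == 0:
            logger.warning("marker set %s is empty; skipped", name)
            continue
        sub = np.ascontiguousarray(Xc[:, idx])
        p = prior or default_prior(float(np.var(y, ddof=1)), sub, partition_r2)
        cfg = MCMCConfig(n_iter=mcmc.n_iter, burn_in=mcmc.burn_in,
                         thin=mcmc.thin, seed=_subseed(seed, k))
        rows.append({"set_name": name, "n_markers": int(idx.size),
                     "r2_full": _fit_r2(y, Z, sub, p, cfg)})
    return pd.DataFrame(rows)


def _subseed(master: int, k: int) -> int:
    return int(np.random.SeedSequence(master, spawn_key=(7, k))
               .generate_state(1)[0] % (2 ** 31))


def resample_fixed_size(y, Z, Xc, marker_set, size: int = 500, reps: int = 500,
                        prior: WGRPrior | None = None,
                        mcmc: MCMCConfig | None = None, seed: int = 0,
                        partition_r2: float = 0.5) -> SubsetResult:
    """Fit ``reps`` models on random ``size``-marker subsets of one set."""
    idx = np.asarray(marker_set.indices, dtype=int)
    if idx.size < size:
        raise ValueError(
            f"set '{marker_set.name}' has {idx.size} markers, fewer than the "
            f"requested subset size {size}")
    mcmc = mcmc or MCMCConfig(n_iter=5_000, burn_in=1_000)
    r2 = np.empty(reps)
    for rep in range(reps):
        sub_idx = draw_replicate_indices(idx, size, rep, seed)
        sub = np.ascontiguousarray(Xc[:, sub_idx])
        p = prior or default_prior(float(np.var(y, ddof=1)), sub, partition_r2)
        cfg = MCMCConfig(n_iter=mcmc.n_iter, burn_in=mcmc.burn_in,
                         thin=mcmc.thin, seed=_subseed(seed, 10_000 + rep))
        r2[rep] = _fit_r2(y, Z, sub, p, cfg)
    return SubsetResult(set_name=marker_set.name, n_markers=int(idx.size),
                        n_resample=size, n_reps=reps, r2_reps=r2, seed=seed)


def report_tables(counts: pd.DataFrame | None = None,
                  per_set: pd.DataFrame | None = None,
                  resampled: dict | None = None):
    """Assemble the three 3x4 report grids.

    * counts grid with integer percents of the grand total,
    * full-set R^2 grid,
    * resampled "mean +/- SD" grid (3 decimals).

    Missing cells render as NA.  Returns a dict of DataFrames.
    """
    out = {}
    if counts is not None:
        from .classify import cross_tab
        _, formatted = cross_tab(None, counts=counts)
        out["counts"] = formatted
    if per_set is not None:
        grid = pd.DataFrame("NA", index=SET_REGIONS, columns=SET_MAFS)
        lut = dict(zip(per_set["set_name"], per_set["r2_full"]))
        for r in SET_REGIONS:
            for m in SET_MAFS:
                v = lut.get(f"{r}_{m}")
                if v is not None:
                    grid.loc[r, m] = f"{v:.3f}"
        out["r2_full"] = grid
    if resampled is not None:
        grid = pd.DataFrame("NA", index=SET_REGIONS, columns=SET_MAFS)
        for name, res in resampled.items():
            r, _, m = name.partition("_")
            if r in SET_REGIONS and m in SET_MAFS:
                grid.loc[r, m] = f"{res.r2_mean:.3f} ± {res.r2_sd:.3f}"
        out["r2_resampled"] = grid
    return out
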