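"""Simulation experiments on competing pre-miRNA species.

The core construct is an eight-species panel built on the fitted wild-type
rates: for each of the four reaction rates there is one species with that
rate raised 10-fold ("hi") and one raised 20-fold ("2hi"), all other rates
at wild-type. Running the panel against a shared Dicer pool over a range of
pool sizes exposes which kinetic features confer a competitive advantage
when the enzyme is scarce; the no-competition control runs each species
alone with the full pool.

Steady-state read-outs are summarized as fold changes relative to a named
reference condition (typically the abundant-Dicer 8 nM condition, or the
all-species-at-1-nM baseline for perturbation experiments). Perturbation
experiments overexpress (5 nM) or knock out (0 nM) one species at a time at
1.55 nM Dicer — a pool size chosen well inside the competitive regime — and
report every species' fold change versus the unperturbed baseline.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kinetics import (
    RateSet,
    SpeciesSpec,
    SystemConfig,
    SteadyState,
    WT_RATES,
    run_to_steady_state,
)

__all__ = [
    "PANEL_LABELS",
    "PERTURBATION_D0",
    "competition_panel",
    "steady_mature",
    "single_species_sweep",
    "dicer_sweep",
    "fold_change",
    "premirna_dicer_sweep",
    "min_dicer_for_fold_change",
    "perturbation_row",
    "perturbation_matrix",
]

#: Fixed panel order: one rate scaled per species, 10x then 20x.
PANEL_LABELS = ("ka_hi", "ka_2hi", "kb_hi", "kb_2hi", "kc_hi", "kc_2hi", "kd_hi", "kd_2hi")

#: Dicer pool for the overexpression/knockout experiments (nM): a condition
#: with notable competition for the default panel.
PERTURBATION_D0 = 1.55

_PANEL_SCALING = {
    "ka_hi": ("k_a", 10.0),
    "ka_2hi": ("k_a", 20.0),
    "kb_hi": ("k_b", 10.0),
    "kb_2hi": ("k_b", 20.0),
    "kc_hi": ("k_c", 10.0),
    "kc_2hi": ("k_c", 20.0),
    "kd_hi": ("k_d", 10.0),
    "kd_2hi": ("k_d", 20.0),
}


def competition_panel(
    P0: float = 1.0,
    D0: float = 8.0,
    *,
    shared_dicer: bool = True,
    base: RateSet = WT_RATES,
) -> SystemConfig:
    """The eight-species panel: each rate raised 10x or 20x over ``base``."""
    species = tuple(
        SpeciesSpec(label=label, P0=P0, rates=base.scaled(*_PANEL_SCALING[label]))
        for label in PANEL_LABELS
    )
    return SystemConfig(species=species, D0=D0, shared_dicer=shared_dicer)


def steady_mature(config: SystemConfig, **opts) -> pd.Series:
    """Steady-state mature miRNA per species, as a label-indexed Series."""
    return run_to_steady_state(config, **opts).mature_series()


def single_species_sweep(
    rate_name: str,
    *,
    scales: Sequence[float] | None = None,
    co_name: str = "D0",
    co_values: Sequence[float] | None = None,
    base: RateSet = WT_RATES,
    P0: float = 1.0,
    D0: float = 5.0,
    **opts,
) -> pd.DataFrame:
    """Steady mature miRNA of a single species over a (rate scale x condition) grid.

    One reaction rate is scaled multiplicatively (default 1e-2..1e2, log
    grid) while either the Dicer pool (``co_name='D0'``, default 0.01-15 nM)
    or the initial pre-miRNA (``co_name='P0'``, 0-5 nM) is varied.
    Returns a tidy frame with columns ``scale``, ``co_name``, ``M``.
    """
    if rate_name not in ("k_a", "k_b", "k_c", "k_d"):
        raise ValueError(f"invalid rate name {rate_name!r}")
    if co_name not in ("D0", "P0"):
        raise ValueError(f"co_name must be 'D0' or 'P0', got {co_name!r}")
    if scales is None:
        scales = np.geomspace(1e-2, 1e2, 25)
    if co_values is None:
        co_values = np.linspace(0.01, 15.0, 40) if co_name == "D0" else np.linspace(0.0, 5.0, 21)
    rows = []
    for scale in scales:
        rates = base.scaled(rate_name, scale)
        for co in co_values:
            p0 = co if co_name == "P0" else P0
            d0 = co if co_name == "D0" else D0
            if p0 == 0.0:
                M = 0.0
            else:
                config = SystemConfig(
                    species=(SpeciesSpec(label="s", P0=p0, rates=rates),), D0=d0
                )
                M = run_to_steady_state(config, **opts).M[0]
            rows.append({"scale": scale, co_name: co, "M": float(M)})
    return pd.DataFrame(rows)


def dicer_sweep(
    panel: SystemConfig,
    D_grid: Sequence[float] | None = None,
    *,
    shared_dicer: bool | None = None,
    **opts,
) -> pd.DataFrame:
    """Steady mature miRNA per panel species over a grid of Dicer pool sizes.

    Returns a tidy frame with columns ``D0``, ``species``, ``M``.
    """
    if D_grid is None:
        D_grid = np.linspace(0.01, 8.0, 40)
    if shared_dicer is None:
        shared_dicer = panel.shared_dicer
    rows = []
    for d0 in D_grid:
        config = replace(panel, D0=float(d0), shared_dicer=shared_dicer)
        ss = run_to_steady_state(config, **opts)
        for label, m in zip(ss.labels, ss.M):
            rows.append({"D0": float(d0), "species": label, "M": float(m)})
    return pd.DataFrame(rows)


def fold_change(
    result: pd.DataFrame,
    reference: Mapping[str, float],
    *,
    value_col: str = "M",
) -> pd.DataFrame:
    """Per-species ratio of ``value_col`` to its value at a reference grid point.

    ``reference`` maps grid-column names to the reference coordinates, e.g.
    ``{"D0": 8.0}``. A zero reference with a non-zero numerator yields a
    missing value (NaN), never infinity.
    """
    mask = np.ones(len(result), dtype=bool)
    for col, val in reference.items():
        mask &= np.isclose(result[col].to_numpy(), val)
    ref = result[mask]
    if ref.empty:
        raise ValueError(f"reference point {dict(reference)} not on the grid")
    ref_by_species = ref.set_index("species")[value_col]
    out = result.copy()
    ref_vals = out["species"].map(ref_by_species).to_numpy(dtype=float)
    num = out[value_col].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = num / ref_vals
    fc[(ref_vals == 0.0) & (num != 0.0)] = np.nan
    fc[(ref_vals == 0.0) & (num == 0.0)] = np.nan
    out["fold_change"] = fc
    return out


def premirna_dicer_sweep(
    panel: SystemConfig,
    P0_grid: Sequence[float] | None = None,
    D_grid: Sequence[float] | None = None,
    *,
    reference: tuple[float, float] = (5.0, 15.0),
    **opts,
) -> pd.DataFrame:
    """Joint sweep of uniform per-species pre-miRNA and Dicer pool.

    Every species' initial concentration is set to the same ``P0`` at each
    grid point. Fold change is referenced to ``reference = (P0, D0)``
    (default 5 nM per species, 15 nM Dicer). Returns a tidy frame with
    columns ``P0``, ``D0``, ``species``, ``M``, ``fold_change``.
    """
    if P0_grid is None:
        P0_grid = np.linspace(0.0, 5.0, 21)
    if D_grid is None:
        D_grid = np.linspace(0.01, 15.0, 40)
    P0_grid = sorted(set(float(p) for p in P0_grid) | {float(reference[0])})
    D_grid = sorted(set(float(d) for d in D_grid) | {float(reference[1])})
    rows = []
    for p0 in P0_grid:
        for d0 in D_grid:
            if p0 == 0.0:
                for label in panel.labels:
                    rows.append({"P0": p0, "D0": d0, "species": label, "M": 0.0})
                continue
            config = replace(
                panel,
                species=tuple(replace(s, P0=p0) for s in panel.species),
                D0=d0,
            )
            ss = run_to_steady_state(config, **opts)
            for label, m in zip(ss.labels, ss.M):
                rows.append({"P0": p0, "D0": d0, "species": label, "M": float(m)})
    result = pd.DataFrame(rows)
    return fold_change(result, {"P0": reference[0], "D0": reference[1]})


def min_dicer_for_fold_change(
    panel: SystemConfig,
    *,
    threshold: float = 0.5,
    shared_dicer: bool | None = None,
    D_lo: float = 0.01,
    D_hi: float = 8.0,
    reference_D0: float = 8.0,
    n_grid: int = 9,
    xtol: float = 1e-3,
    **opts,
) -> pd.Series:
    """Smallest Dicer pool at which each species reaches a fold-change threshold.

    Fold change is referenced to the abundant-Dicer condition
    (``reference_D0``, default 8 nM). A coarse grid scan brackets the
    crossing per species, then bisection refines it to ``xtol`` nM. Species
    that never reach the threshold on [D_lo, D_hi] get NaN.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    if shared_dicer is None:
        shared_dicer = panel.shared_dicer

    def mature_at(d0: float) -> pd.Series:
        return steady_mature(replace(panel, D0=d0, shared_dicer=shared_dicer), **opts)

    ref = mature_at(reference_D0)
    grid = np.linspace(D_lo, D_hi, n_grid)
    fc_grid = pd.DataFrame({d0: mature_at(float(d0)) / ref for d0 in grid}).T

    out = {}
    for label in panel.labels:
        fc = fc_grid[label].to_numpy()
        if fc[0] >= threshold:
            out[label] = float(grid[0])
            continue
        above = np.nonzero(fc >= threshold)[0]
        if above.size == 0:
            out[label] = math.nan
            continue
        hi_idx = above[0]
        lo, hi = float(grid[hi_idx - 1]), float(grid[hi_idx])
        while hi - lo > xtol:
            mid = 0.5 * (lo + hi)
            if mature_at(mid)[label] / ref[label] >= threshold:
                hi = mid
            else:
                lo = mid
        out[label] = hi
    return pd.Series(out, name="min_D0")


def perturbation_row(
    panel: SystemConfig,
    perturbed_label: str,
    level: float,
    *,
    D0: float = PERTURBATION_D0,
    shared_dicer: bool | None = None,
    baseline: SteadyState | None = None,
    **opts,
) -> pd.Series:
    """Fold change of every species after setting one species' P0 to ``level``.

    Baseline is the unperturbed panel (all species at their configured P0,
    by default 1 nM) at the same Dicer pool and competition setting. A
    knocked-out species (level 0) has fold change exactly 0 by definition:
    no substrate, no mature product.
    """
    if shared_dicer is None:
        shared_dicer = panel.shared_dicer
    base_cfg = replace(panel, D0=D0, shared_dicer=shared_dicer)
    if baseline is None:
        baseline = run_to_steady_state(base_cfg, **opts)
    perturbed_cfg = base_cfg.with_P0(perturbed_label, level)
    perturbed = run_to_steady_state(perturbed_cfg, **opts)
    base_m = baseline.mature_series()
    pert_m = perturbed.mature_series()
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = pert_m / base_m
    fc[(base_m == 0.0)] = np.nan
    fc.name = perturbed_label
    return fc


def perturbation_matrix(
    panel: SystemConfig,
    level: float,
    *,
    D0: float = PERTURBATION_D0,
    shared_dicer: bool | None = None,
    **opts,
) -> pd.DataFrame:
    """8x8 perturbation matrix: rows = perturbed species, columns = fold change.

    ``level=5.0`` is overexpression, ``level=0.0`` knockout. All rows share
    one baseline run at the same conditions.
    """
    if shared_dicer is None:
        shared_dicer = panel.shared_dicer
    base_cfg = replace(panel, D0=D0, shared_dicer=shared_dicer)
    baseline = run_to_steady_state(base_cfg, **opts)
    rows = [
        perturbation_row(
            panel, label, level, D0=D0, shared_dicer=shared_dicer, baseline=baseline, **opts
        )
        for label in panel.labels
    ]
    return pd.DataFrame(rows)
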