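"""Competition panel, sweeps, fold changes and perturbation experiments."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from mircompete import (
    PANEL_LABELS,
    WT_RATES,
    closed_form_diced_fraction,
    dicer_sweep,
    fold_change,
    min_dicer_for_fold_change,
    perturbation_matrix,
    perturbation_row,
    premirna_dicer_sweep,
    single_species_sweep,
    stall_demand,
    steady_mature,
)

D_GRID_SMALL = [0.5, 1.55, 4.0, 8.0]


# --- panel construction ------------------------------------------------------

def test_panel_scales_exactly_one_rate_per_species(panel):
    assert panel.labels == PANEL_LABELS
    factors = {"hi": 10.0, "2hi": 20.0}
    for sp in panel.species:
        rate_key, suffix = sp.label.split("_")
        rate_name = {"ka": "k_a", "kb": "k_b", "kc": "k_c", "kd": "k_d"}[rate_key]
        for name in ("k_a", "k_b", "k_c", "k_d"):
            expected = getattr(WT_RATES, name) * (factors[suffix] if name == rate_name else 1.0)
            assert getattr(sp.rates, name) == pytest.approx(expected)
        assert sp.P0 == 1.0


# --- single-species sweep ----------------------------------------------------

def test_single_species_sweep_matches_oracle():
    df = single_species_sweep("k_a", scales=[1.0, 100.0], co_values=[5.0])
    base = df.query("scale == 1.0")["M"].item()
    assert base == pytest.approx(closed_form_diced_fraction(WT_RATES), abs=1e-4)
    boosted = df.query("scale == 100.0")["M"].item()
    q100 = closed_form_diced_fraction(WT_RATES.scaled("k_a", 100.0))
    assert boosted == pytest.approx(q100, abs=1e-4)


def test_single_species_sweep_p0_axis_zero_is_zero():
    df = single_species_sweep("k_c", scales=[1.0], co_name="P0", co_values=[0.0, 1.0])
    assert df.query("P0 == 0.0")["M"].item() == 0.0
    assert df.query("P0 == 1.0")["M"].item() > 0.0


def test_single_species_sweep_rejects_bad_inputs():
    with pytest.raises(ValueError, match="rate name"):
        single_species_sweep("k_x", scales=[1.0], co_values=[5.0])
    with pytest.raises(ValueError, match="co_name"):
        single_species_sweep("k_a", co_name="X0", scales=[1.0], co_values=[5.0])


# --- dicer sweep and competition ordering ------------------------------------

def test_abundant_dicer_reaches_isolated_closed_form(panel):
    """At 8 nM the stall demand (~5 nM) is covered: every species attains q_i."""
    assert stall_demand(panel) < 8.0
    shared = steady_mature(replace(panel, D0=8.0, shared_dicer=True))
    for sp in panel.species:
        q_i = closed_form_diced_fraction(sp.rates)
        assert shared[sp.label] == pytest.approx(q_i * sp.P0, abs=1e-3)


def test_competition_never_helps(panel):
    """Shared-pool steady M <= isolated steady M per species, every Dicer level."""
    for d0 in D_GRID_SMALL:
        shared = steady_mature(replace(panel, D0=d0, shared_dicer=True))
        isolated = steady_mature(replace(panel, D0=d0, shared_dicer=False))
        assert np.all(shared.to_numpy() <= isolated.to_numpy() + 1e-6)
    # and the two coincide when Dicer is abundant
    assert np.allclose(shared.to_numpy(), isolated.to_numpy(), atol=1e-3)


def test_isolated_sweep_equals_independent_single_runs(panel):
    iso = dicer_sweep(panel, [1.0], shared_dicer=False)
    for sp in panel.species:
        alone = steady_mature(replace(panel.isolated(sp.label), D0=1.0))
        got = iso.query("species == @sp.label")["M"].item()
        assert got == pytest.approx(alone[sp.label], abs=1e-9)


def test_scarce_dicer_suppresses_everyone(panel):
    scarce = steady_mature(replace(panel, D0=0.01, shared_dicer=True))
    iso = steady_mature(replace(panel, D0=0.01, shared_dicer=False))
    assert np.all(scarce.to_numpy() <= iso.to_numpy() + 1e-9)
    assert scarce.sum() <= 0.011  # at most the Dicer supply can mature (plus tol)


# --- fold change -------------------------------------------------------------

def test_fold_change_reference_and_ratios():
    df = pd.DataFrame(
        {
            "D0": [8.0, 8.0, 2.0, 2.0],
            "species": ["a", "b", "a", "b"],
            "M": [0.4, 0.2, 0.2, 0.0],
        }
    )
    out = fold_change(df, {"D0": 8.0})
    assert out.query("D0 == 8.0")["fold_change"].tolist() == [1.0, 1.0]
    assert out.query("D0 == 2.0 and species == 'a'")["fold_change"].item() == 0.5
    assert out.query("D0 == 2.0 and species == 'b'")["fold_change"].item() == 0.0


def test_fold_change_zero_reference_is_missing_not_inf():
    df = pd.DataFrame(
        {"D0": [8.0, 2.0], "species": ["a", "a"], "M": [0.0, 0.3]}
    )
    out = fold_change(df, {"D0": 8.0})
    assert np.isnan(out.query("D0 == 2.0")["fold_change"].item())


def test_fold_change_requires_on_grid_reference():
    df = pd.DataFrame({"D0": [8.0], "species": ["a"], "M": [0.1]})
    with pytest.raises(ValueError, match="reference"):
        fold_change(df, {"D0": 5.0})


# --- joint pre-miRNA / Dicer sweep -------------------------------------------

def test_premirna_dicer_sweep_reference_and_monotonicity(panel):
    df = premirna_dicer_sweep(
        panel, P0_grid=[0.0, 1.0, 5.0], D_grid=[1.0, 5.0, 15.0]
    )
    at_ref = df.query("P0 == 5.0 and D0 == 15.0")
    assert np.allclose(at_ref["fold_change"], 1.0)
    assert np.all(df.query("P0 == 0.0")["fold_change"] == 0.0)
    # more Dicer at fixed P0 never hurts any species
    for label in panel.labels:
        sub = df.query("P0 == 1.0 and species == @label").sort_values("D0")
        assert np.all(np.diff(sub["M"]) >= -1e-6)


# --- minimum Dicer for a fold-change threshold --------------------------------

def test_min_dicer_threshold(panel):
    """Competition raises (never lowers) the Dicer needed for half recovery."""
    small = replace(panel, species=panel.species[:3])  # ka_hi, ka_2hi, kb_hi
    shared = min_dicer_for_fold_change(
        small, threshold=0.5, shared_dicer=True, n_grid=5, xtol=0.01
    )
    iso = min_dicer_for_fold_change(
        small, threshold=0.5, shared_dicer=False, n_grid=5, xtol=0.01
    )
    assert np.all(iso.to_numpy() <= shared.to_numpy() + 0.02)
    assert np.all(shared.to_numpy() > 0.0)


def test_min_dicer_rejects_bad_threshold(panel):
    with pytest.raises(ValueError):
        min_dicer_for_fold_change(panel, threshold=0.0)


# --- perturbation experiments -------------------------------------------------

def test_sham_perturbation_row_is_all_ones(panel):
    row = perturbation_row(panel, "kc_hi", 1.0)
    assert np.allclose(row.to_numpy(), 1.0, atol=1e-6)


def test_knockout_matrix_diagonal_zero_offdiag_nonneg(panel):
    ko = perturbation_matrix(panel, 0.0)
    assert np.all(np.diag(ko.to_numpy()) == 0.0)
    off = ko.to_numpy()[~np.eye(8, dtype=bool)]
    assert np.all(off >= 0.0)


def test_overexpression_matrix_diagonal_above_one(panel):
    oe = perturbation_matrix(panel, 5.0)
    assert np.all(np.diag(oe.to_numpy()) > 1.0)


def test_knockout_leaves_isolated_others_unchanged(panel):
    """Without a shared pool, removing one species cannot touch the rest."""
    base = steady_mature(replace(panel, D0=1.55, shared_dicer=False))
    ko = steady_mature(
        replace(panel.with_P0("kc_2hi", 0.0), D0=1.55, shared_dicer=False)
    )
    others = [l for l in panel.labels if l != "kc_2hi"]
    assert np.allclose(base[others], ko[others], atol=1e-12)


def test_knockout_frees_dicer_for_others_in_shared_pool(panel):
    """With competition, knocking a species out weakly helps every other one."""
    base = steady_mature(replace(panel, D0=1.55, shared_dicer=True))
    ko = steady_mature(
        replace(panel.with_P0("kc_2hi", 0.0), D0=1.55, shared_dicer=True)
    )
    others = [l for l in panel.labels if l != "kc_2hi"]
    assert np.all(ko[others].to_numpy() >= base[others].to_numpy() - 1e-6)
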