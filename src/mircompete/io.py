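"""File adapters: tidy TSV, YAML configs, and FASTA + dot-bracket hairpins.

These are the package's on-disk interfaces. Time series are TSV with
columns ``time_min, diced_fraction``; hairpins either a combined TSV
(``id, sequence, structure, arm5_start, arm5_end, arm3_start, arm3_end``)
or a FASTA file with a Vienna-style sidecar of dot-bracket strings;
expression tables are TSV with ``id`` plus one column per condition.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .bpp import BppCurve, HairpinRecord, parse_hairpin
from .fitting import FitResult, TimeSeriesData
from .kinetics import RateSet, SpeciesSpec, SteadyState, SystemConfig, Trajectory
from .stats import ExpressionTable

__all__ = [
    "read_timeseries_tsv",
    "write_timeseries_tsv",
    "read_hairpins_tsv",
    "write_hairpins_tsv",
    "read_hairpins_fasta",
    "read_expression_tsv",
    "write_trajectory_tsv",
    "write_steady_state_json",
    "write_fit_result_json",
    "write_bpp_curves_tsv",
    "write_association_json",
    "load_system_config",
]


def read_timeseries_tsv(path, *, P0: float, D0: float, label: str = "") -> TimeSeriesData:
    df = pd.read_csv(path, sep="\t")
    return TimeSeriesData(
        times_min=df["time_min"].to_numpy(),
        diced_fraction=df["diced_fraction"].to_numpy(),
        P0=P0,
        D0=D0,
        label=label or Path(path).stem,
    )


def write_timeseries_tsv(data: TimeSeriesData, path) -> None:
    pd.DataFrame(
        {"time_min": data.times_min, "diced_fraction": data.diced_fraction}
    ).to_csv(path, sep="\t", index=False)


_HAIRPIN_COLS = ["id", "sequence", "structure", "arm5_start", "arm5_end", "arm3_start", "arm3_end"]


def read_hairpins_tsv(path) -> list[HairpinRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_HAIRPIN_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"hairpin TSV missing columns {sorted(missing)}")
    return [
        parse_hairpin(
            row.id,
            row.sequence,
            row.structure,
            (row.arm5_start, row.arm5_end),
            (row.arm3_start, row.arm3_end),
        )
        for row in df.itertuples(index=False)
    ]


def write_hairpins_tsv(records: Iterable[HairpinRecord], path) -> None:
    rows = [
        {
            "id": h.id,
            "sequence": h.sequence,
            "structure": h.structure,
            "arm5_start": h.arm5[0],
            "arm5_end": h.arm5[1],
            "arm3_start": h.arm3[0],
            "arm3_end": h.arm3[1],
        }
        for h in records
    ]
    pd.DataFrame(rows, columns=_HAIRPIN_COLS).to_csv(path, sep="\t", index=False)


def read_hairpins_fasta(fasta_path, structure_path, arms: dict) -> list[HairpinRecord]:
    """FASTA sequences plus a sidecar of dot-bracket lines in the same order.

    ``arms`` maps record id to ``(arm5, arm3)`` interval pairs, which FASTA
    cannot carry.
    """
    seqs: dict[str, str] = {}
    order: list[str] = []
    current = None
    for line in Path(fasta_path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            current = line[1:].split()[0]
            order.append(current)
            seqs[current] = ""
        elif current is not None:
            seqs[current] += line
    structures = [s.strip() for s in Path(structure_path).read_text().splitlines() if s.strip()]
    if len(structures) != len(order):
        raise ValueError(
            f"{len(order)} FASTA records but {len(structures)} structure lines"
        )
    records = []
    for rid, struct in zip(order, structures):
        arm5, arm3 = arms[rid]
        records.append(parse_hairpin(rid, seqs[rid], struct, arm5, arm3))
    return records


def read_expression_tsv(path) -> ExpressionTable:
    return ExpressionTable(pd.read_csv(path, sep="\t"))


def write_trajectory_tsv(traj: Trajectory, path) -> None:
    traj.to_frame().to_csv(path, sep="\t", index=False)


def write_steady_state_json(ss: SteadyState, path) -> None:
    payload = {
        "labels": list(ss.labels),
        "P": [float(v) for v in ss.P],
        "PD": [float(v) for v in ss.PD],
        "S": [float(v) for v in ss.S],
        "M": [float(v) for v in ss.M],
        "D": float(ss.D) if hasattr(ss.D, "__float__") else [float(v) for v in ss.D],
        "converged": bool(ss.converged),
        "t_end_s": float(ss.t_end),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_fit_result_json(result: FitResult, path) -> None:
    payload = {
        "rates": asdict(result.rates),
        "sse": result.sse,
        "kb_over_ka": result.kb_over_ka,
        "plateau": result.plateau,
        "n_evaluations": result.n_evaluations,
        "converged": result.converged,
        "seed": result.seed,
        "sse_trace": result.sse_trace,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_bpp_curves_tsv(curves: Iterable[BppCurve], path) -> None:
    """Tidy per-position curve table: columns id, position, bpp, filled."""
    frames = [
        pd.DataFrame(
            {"id": c.id, "position": c.positions, "bpp": c.bpp, "filled": c.filled}
        )
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_association_json(results: dict, comparison, path) -> None:
    """Association summaries plus the slope comparison, as one JSON object.

    ``results`` maps condition name to an AssociationResult; ``comparison``
    is a SlopeComparison (or None).
    """
    payload = {name: asdict(res) for name, res in results.items()}
    if comparison is not None:
        payload["slope_comparison"] = asdict(comparison)
    Path(path).write_text(json.dumps(payload, indent=2))


def load_system_config(path) -> tuple[SystemConfig, dict]:
    """Load a simulation config from YAML/JSON.

    Schema::

        species:
          - {label: wt, P0_nM: 1.0, ka: 0.0053, kb: 0.134, kc: 0.0122, kd: 10439.0}
        D0_nM: 5.0
        shared_dicer: true
        t_end_min: 60          # optional
        solver: {rtol: 1e-8, atol: 1e-10, steady_tol: 1e-9}   # optional

    Returns the config plus the leftover options (time horizon in seconds
    under ``t_end_s``, solver settings under ``solver``).
    """
    raw = yaml.safe_load(Path(path).read_text())
    species = tuple(
        SpeciesSpec(
            label=str(s["label"]),
            P0=float(s["P0_nM"]),
            rates=RateSet(
                k_a=float(s["ka"]), k_b=float(s["kb"]), k_c=float(s["kc"]), k_d=float(s["kd"])
            ),
        )
        for s in raw["species"]
    )
    config = SystemConfig(
        species=species,
        D0=float(raw["D0_nM"]),
        shared_dicer=bool(raw.get("shared_dicer", True)),
    )
    opts = {"solver": raw.get("solver", {})}
    if "t_end_min" in raw:
        opts["t_end_s"] = float(raw["t_end_min"]) * 60.0
    return config, opts
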