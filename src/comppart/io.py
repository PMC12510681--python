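"""Reading, writing and reporting for long-format mixture experiment tables.

The on-disk schema is one CSV row per (mixture, species):

    mixture_id, species_id, ry_expected, yield_observed, mono_full_yield,
    mono_partial_yield, density_full, density_total_mixture,
    ability (optional), age_or_time (optional)

Lines starting with '#' are comments. Two fixture datasets ship with the
package: ``trees`` (20 simulated aspen-spruce mixtures across four stand
ages, stand volume in m3/ha) and ``grassland`` (15 two-species grassland pot
mixtures, aboveground biomass in g/pot).
"""

from __future__ import annotations

import importlib.resources
import json
import logging
import math
from pathlib import Path
from typing import Mapping

import pandas as pd

from .additive import additive_partition
from .competitive import partition_community
from .config import RunConfig
from .core import (
    ComppartError,
    Diagnostic,
    MixtureCommunity,
    MixtureDataset,
    MixtureObservation,
    SpeciesReference,
    validate_dataset,
)

__all__ = [
    "REQUIRED_COLUMNS",
    "read_dataset",
    "dataset_from_frame",
    "dataset_to_frame",
    "write_dataset",
    "load_fixture",
    "fixture_path",
    "run_partition",
    "community_table",
    "species_table",
]

logger = logging.getLogger("comppart")

REQUIRED_COLUMNS = (
    "mixture_id",
    "species_id",
    "ry_expected",
    "yield_observed",
    "mono_full_yield",
    "density_full",
    "density_total_mixture",
)
OPTIONAL_COLUMNS = ("mono_partial_yield", "ability", "age_or_time")


def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def dataset_from_frame(
    frame: pd.DataFrame,
    yield_units: str = "yield",
    density_units: str = "individuals",
) -> MixtureDataset:
    """Build a dataset from a long-format DataFrame (one row per mixture-species)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ComppartError(f"missing required column(s): {', '.join(missing)}")
    for col in OPTIONAL_COLUMNS:
        if col not in frame.columns:
            frame = frame.assign(**{col: None})
    numeric = [c for c in REQUIRED_COLUMNS if c not in ("mixture_id", "species_id")]
    numeric += ["mono_partial_yield", "ability"]
    for col in numeric:
        try:
            frame[col] = pd.to_numeric(frame[col])
        except (ValueError, TypeError) as err:
            bad = frame[pd.to_numeric(frame[col], errors="coerce").isna() & frame[col].notna()]
            row = int(bad.index[0]) + 2 if len(bad) else "?"
            raise ComppartError(
                f"non-numeric value in column {col!r} (file row {row}): {err}"
            ) from None

    communities: list[MixtureCommunity] = []
    for mid, grp in frame.groupby("mixture_id", sort=False):
        refs: dict[str, SpeciesReference] = {}
        obs: list[MixtureObservation] = []
        d_total = float(grp["density_total_mixture"].iloc[0])
        age = grp["age_or_time"].iloc[0]
        age = None if (age is None or (isinstance(age, float) and math.isnan(age))) else str(age)
        for _, row in grp.iterrows():
            sid = str(row["species_id"])
            refs[sid] = SpeciesReference(
                sid,
                float(row["mono_full_yield"]),
                float(row["density_full"]),
                ability=_opt(row["ability"]),
            )
            obs.append(
                MixtureObservation(
                    sid,
                    float(row["ry_expected"]),
                    float(row["yield_observed"]),
                    mono_partial_yield=_opt(row["mono_partial_yield"]),
                )
            )
        communities.append(
            MixtureCommunity(str(mid), d_total, tuple(obs), refs, age_or_time=age)
        )
    return MixtureDataset(communities, yield_units, density_units)


def read_dataset(
    path: str | Path,
    config: RunConfig | None = None,
    yield_units: str = "yield",
    density_units: str = "individuals",
) -> MixtureDataset:
    """Read and validate a long-format CSV; warnings are logged, errors raised."""
    config = config or RunConfig()
    path = Path(path)
    if not path.exists():
        raise ComppartError(f"input file not found: {path}")
    frame = pd.read_csv(path, comment="#")
    dataset = dataset_from_frame(frame, yield_units, density_units)
    diags = validate_dataset(dataset, ry_sum_tol=config.ry_sum_tolerance)
    _report_diagnostics(diags, str(path))
    return dataset


def _report_diagnostics(diags: list[Diagnostic], source: str) -> None:
    errors = [d for d in diags if d.severity == "error"]
    for d in diags:
        if d.severity == "warning":
            logger.warning("%s: %s", source, d)
    if errors:
        msgs = "; ".join(str(d) for d in errors)
        raise ComppartError(f"{source}: invalid dataset: {msgs}")


def dataset_to_frame(dataset: MixtureDataset) -> pd.DataFrame:
    """Long-format DataFrame with the on-disk schema (inverse of read)."""
    rows = []
    for com in dataset:
        for obs in com.observations:
            ref = com.reference(obs.species_id)
            rows.append(
                {
                    "mixture_id": com.mixture_id,
                    "species_id": obs.species_id,
                    "ry_expected": obs.ry_expected,
                    "yield_observed": obs.yield_observed,
                    "mono_full_yield": ref.mono_full_yield,
                    "mono_partial_yield": obs.mono_partial_yield,
                    "density_full": ref.density_full,
                    "density_total_mixture": com.density_total,
                    "ability": ref.ability,
                    "age_or_time": com.age_or_time,
                }
            )
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS[:5]) + ["mono_partial_yield"] + list(REQUIRED_COLUMNS[5:]) + ["ability", "age_or_time"])


def write_dataset(dataset: MixtureDataset, path: str | Path) -> None:
    dataset_to_frame(dataset).to_csv(path, index=False)


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture ('trees' or 'grassland')."""
    if name not in ("trees", "grassland"):
        raise ComppartError(f"unknown fixture {name!r}; choose 'trees' or 'grassland'")
    return Path(str(importlib.resources.files("comppart") / "data" / f"{name}.csv"))


def load_fixture(name: str, config: RunConfig | None = None) -> MixtureDataset:
    """Load a packaged fixture dataset by name."""
    units = {"trees": ("m3/ha", "stems/ha"), "grassland": ("g/pot", "stems/pot")}[
        name if name in ("trees", "grassland") else "trees"
    ]
    return read_dataset(fixture_path(name), config, *units)


def community_table(dataset: MixtureDataset, config: RunConfig | None = None) -> pd.DataFrame:
    """Community-level report: one row per mixture plus an 'Average' row.

    Columns depend on config.model: the competitive components (positive,
    competitive, negative, their combined competitive+negative column, BPM)
    and/or the additive components (CE, SE); net is always present.
    """
    config = config or RunConfig()
    rows = []
    for com in dataset:
        row: dict[str, object] = {"mixture_id": com.mixture_id}
        if config.model in ("competitive", "both"):
            part = partition_community(com, config)
            row.update(
                net=part.net,
                positive=part.positive_effect,
                competitive=part.competitive_effect,
                negative=part.negative_effect,
                comp_neg=part.combined_comp_neg,
                bpm=part.bpm,
                pair_label=part.pair_label,
            )
        if config.model in ("additive", "both"):
            add = additive_partition(com)
            row.update(net=add.net, ce=add.complementarity, se=add.selection)
        rows.append(row)
    table = pd.DataFrame(rows)
    mean_row = {"mixture_id": "Average"}
    for col in table.columns:
        if col not in ("mixture_id", "pair_label"):
            mean_row[col] = table[col].mean()
    table = pd.concat([table, pd.DataFrame([mean_row])], ignore_index=True)
    if config.round_digits is not None:
        num = table.select_dtypes("number").columns
        table[num] = table[num].round(config.round_digits)
    return table


def species_table(dataset: MixtureDataset, config: RunConfig | None = None) -> pd.DataFrame:
    """Species-level report: expectations, responses and interaction classes."""
    config = config or RunConfig()
    rows = []
    for com in dataset:
        comp = (
            partition_community(com, config)
            if config.model in ("competitive", "both")
            else None
        )
        add = additive_partition(com) if config.model in ("additive", "both") else None
        by_sid = {s.species_id: s for s in comp.species} if comp else {}
        for obs in com.observations:
            row: dict[str, object] = {
                "mixture_id": com.mixture_id,
                "species_id": obs.species_id,
                "y_obs": obs.yield_observed,
            }
            if comp:
                sp = by_sid[obs.species_id]
                row.update(
                    y_ne=sp.y_ne,
                    y_ce=sp.y_ce,
                    mg=sp.mg,
                    rc=sp.rc,
                    deviation=sp.deviation,
                    interaction_class=sp.interaction_class,
                )
            if add:
                row.update(
                    delta_ry=add.delta_ry[obs.species_id],
                    ry_observed=add.ry_observed[obs.species_id],
                )
            rows.append(row)
    table = pd.DataFrame(rows)
    if config.round_digits is not None:
        num = table.select_dtypes("number").columns
        table[num] = table[num].round(config.round_digits)
    return table


def run_partition(
    dataset: MixtureDataset,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the selected model(s) over a dataset and optionally write reports.

    Returns {'community': ..., 'species': ...}; with out_dir set, writes
    community.csv and species.csv (or .json) there.
    """
    config = config or RunConfig()
    diags = validate_dataset(dataset, ry_sum_tol=config.ry_sum_tolerance)
    _report_diagnostics(diags, "dataset")
    tables = {
        "community": community_table(dataset, config),
        "species": species_table(dataset, config),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in tables.items():
            if config.output_format == "json":
                (out / f"{name}.json").write_text(
                    json.dumps(table.to_dict(orient="records"), indent=1, default=str)
                )
            else:
                table.to_csv(out / f"{name}.csv", index=False)
    return tables
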