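"""File formats and experiment configuration.

Data files are plain CSV: column 1 the titrate concentration, columns
2+ replicate observations; optional ``total_<component>`` columns
override fixed totals per row (2D titrations).  Concentrations are
interpreted in the single unit declared in the experiment config — no
internal unit conversion ever happens.

The experiment config is a YAML file tying together the reactions file,
the data file, parameter roles (fit/fixed) with values or guesses, the
data-function spec and analysis options.  ``generate_config`` writes a
commented template for a parsed system so a user only fills in roles
and values.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import FitProblem, TitrationDataset
from .model import (
    EquilibriumModel,
    anisotropy_data_function,
    build_model,
    compile_data_function,
)
from .reactions import ReactionSystem, parse_reactions

__all__ = [
    "read_titration_csv",
    "write_titration_csv",
    "ExperimentConfig",
    "generate_config",
    "load_config",
]

logger = logging.getLogger(__name__)


def read_titration_csv(
    path, titrate: str = "titrate", fixed_totals: dict[str, float] | None = None
) -> TitrationDataset:
    """Read a titration table.

    The header row is auto-detected (a non-numeric first cell) and
    skipped.  Rows are sorted by concentration with a warning if the
    file was unsorted; a negative concentration is an error naming the
    row.  ``total_<X>`` columns become per-row overrides of the fixed
    totals.
    """
    path = Path(path)
    rows: list[tuple[int, list[str]]] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            row = [c.strip() for c in row]
            if not row or all(c == "" for c in row):
                continue
            if row[0].startswith("#"):
                continue
            rows.append((lineno, row))
    if not rows:
        raise ValueError(f"{path}: empty data file")
    header = None
    try:
        float(rows[0][1][0])
    except ValueError:
        header = rows[0][1]
        rows = rows[1:]
        if not rows:
            raise ValueError(f"{path}: no data rows below the header")
    override_cols: dict[int, str] = {}
    if header:
        if header[0]:
            titrate = header[0] if header[0] != "titrate" else titrate
        for j, name in enumerate(header[1:], start=1):
            if name.startswith("total_"):
                override_cols[j] = name[len("total_"):]

    def cell(value, lineno, j):
        if value == "":
            return None
        try:
            return float(value)
        except ValueError:
            raise ValueError(
                f"{path}: non-numeric value {value!r} at row {lineno}, "
                f"column {j + 1}"
            ) from None

    concs, observations, overrides = [], [], []
    any_override = False
    for lineno, row in rows:
        conc = cell(row[0], lineno, 0)
        if conc is None:
            continue
        if conc < 0:
            raise ValueError(f"{path}: negative concentration at row {lineno}")
        reps, over = [], {}
        for j in range(1, len(row)):
            v = cell(row[j], lineno, j)
            if v is None:
                continue
            if j in override_cols:
                over[override_cols[j]] = v
                any_override = True
            else:
                reps.append(v)
        if not reps:
            raise ValueError(f"{path}: row {lineno} has no observations")
        concs.append(conc)
        observations.append(np.array(reps))
        overrides.append(over or None)
    if not concs:
        raise ValueError(f"{path}: no data rows")
    concs = np.array(concs)
    order = np.argsort(concs, kind="stable")
    if not np.all(order == np.arange(len(concs))):
        logger.warning("%s: concentrations were unsorted; sorting", path)
    return TitrationDataset(
        titrate=titrate,
        concentrations=concs[order],
        observations=[observations[i] for i in order],
        fixed_totals=dict(fixed_totals or {}),
        point_totals=[overrides[i] for i in order] if any_override else None,
    )


def write_titration_csv(path, dataset: TitrationDataset) -> None:
    n_rep = max(len(o) for o in dataset.observations)
    cols = {dataset.titrate: dataset.concentrations}
    for k in range(n_rep):
        cols[f"rep{k + 1}"] = [
            o[k] if k < len(o) else np.nan for o in dataset.observations
        ]
    if dataset.point_totals is not None:
        keys = sorted({k for pt in dataset.point_totals if pt for k in pt})
        for key in keys:
            cols[f"total_{key}"] = [
                (pt or {}).get(key, dataset.fixed_totals.get(key, np.nan))
                for pt in dataset.point_totals
            ]
    pd.DataFrame(cols).to_csv(path, index=False)


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one fit, in one declared unit."""

    reactions_file: str
    data_file: str
    titrate: str
    unit: str = "M"
    fixed_totals: dict[str, float] = field(default_factory=dict)
    parameters: dict[str, dict] = field(default_factory=dict)  # name -> {role, value}
    data_function: dict = field(default_factory=dict)  # {type|expression, ...}
    analysis: dict = field(default_factory=dict)
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "reactions_file": self.reactions_file,
            "data_file": self.data_file,
            "titrate": self.titrate,
            "unit": self.unit,
            "fixed_totals": dict(self.fixed_totals),
            "parameters": {k: dict(v) for k, v in self.parameters.items()},
            "data_function": dict(self.data_function),
            "analysis": dict(self.analysis),
            "seed": self.seed,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    # -- assembly into library objects -------------------------------------
    def load_system(self, base_dir=".") -> ReactionSystem:
        text = Path(base_dir, self.reactions_file).read_text()
        return parse_reactions(text)

    def build_model(self, base_dir=".") -> EquilibriumModel:
        system = self.load_system(base_dir)
        spec = dict(self.data_function)
        kind = spec.pop("type", "expression")
        if kind == "anisotropy":
            df = anisotropy_data_function(
                system, labeled=spec["labeled"],
                bound_species=tuple(spec["bound_species"]) if "bound_species" in spec else None,
            )
        elif kind == "expression":
            df = compile_data_function(
                system, spec["expression"],
                scalars=tuple(spec.get("scalars", ())),
                label=spec.get("label", "signal"),
            )
        else:
            raise ValueError(f"unknown data function type {kind!r}")
        model = build_model(system, df)
        declared = set(self.parameters)
        needed = set(model.parameters)
        unknown = declared - needed
        if unknown:
            raise ValueError(
                f"config names parameters absent from the system: {sorted(unknown)}"
            )
        return model

    def build_problem(self, base_dir=".") -> FitProblem:
        model = self.build_model(base_dir)
        dataset = read_titration_csv(
            Path(base_dir, self.data_file),
            titrate=self.titrate,
            fixed_totals=self.fixed_totals,
        )
        free, fixed = {}, {}
        for name, entry in self.parameters.items():
            role = entry.get("role", "fit")
            value = float(entry["value"])
            (free if role == "fit" else fixed)[name] = value
        return FitProblem(
            model=model, dataset=dataset,
            free_parameters=free, fixed_parameters=fixed,
        )


def generate_config(
    system: ReactionSystem,
    reactions_file: str = "reactions.txt",
    data_file: str = "data.csv",
    titrate: str | None = None,
    path=None,
) -> ExperimentConfig:
    """Template config for a parsed system: every parameter listed with
    a fit-role placeholder, the first component as default titrate and
    the others as fixed totals."""
    titrate = titrate or system.components[0]
    if titrate not in system.components:
        raise ValueError(f"titrate {titrate!r} is not a component")
    cfg = ExperimentConfig(
        reactions_file=reactions_file,
        data_file=data_file,
        titrate=titrate,
        fixed_totals={c: 0.0 for c in system.components if c != titrate},
        parameters={p: {"role": "fit", "value": 1e-6} for p in system.parameters},
        data_function={"type": "anisotropy", "labeled": next(
            (c for c in system.components if c != titrate), titrate
        )},
        seed=0,
    )
    if path is not None:
        cfg.save(path)
    return cfg


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: not a mapping")
    known = {
        "reactions_file", "data_file", "titrate", "unit", "fixed_totals",
        "parameters", "data_function", "analysis", "seed",
    }
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return ExperimentConfig(**data)
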