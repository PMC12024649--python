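"""Table and config I/O: CSV readers/writers and YAML model serialization.

All tabular interchange is tidy CSV (UTF-8, header row, '.' decimal); model
specifications are single YAML documents with a versioned schema tag.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .assays import PlateTimeSeries
from .bulkfit import InductionCurve
from .lineage import CellRecord
from .models import (
    AutoactivatorParams,
    CLine,
    ConstantProduction,
    LacParams,
    ModelSpec,
    ProteaseSwitchParams,
    RLine,
    TwoComponentParams,
)

logger = logging.getLogger(__name__)

MODEL_SCHEMA = "gcswitch-model/1"

TRACE_COLUMNS = ["cell_id", "parent_id", "time_h", "length_um", "fluor_total"]
PLATE_COLUMNS = ["well", "time_h", "od600", "signal"]


class SchemaError(ValueError):
    """Input table/config does not match the expected schema."""


# ---------------------------------------------------------------------------
# model YAML
# ---------------------------------------------------------------------------

_REGULATION_TAGS = {"constant": ConstantProduction, "c_line": CLine, "r_line": RLine}


def model_to_dict(spec: ModelSpec) -> dict:
    params = dataclasses.asdict(spec.params)
    if spec.kind == "lac":
        reg = spec.params.regulation
        tag = {ConstantProduction: "constant", CLine: "c_line", RLine: "r_line"}[type(reg)]
        params["regulation"] = {"mode": tag, **dataclasses.asdict(reg)}
    return {
        "schema": MODEL_SCHEMA,
        "kind": spec.kind,
        "modulation": spec.modulation,
        "params": params,
    }


def model_from_dict(doc: dict) -> ModelSpec:
    if doc.get("schema") != MODEL_SCHEMA:
        raise SchemaError(f"expected schema {MODEL_SCHEMA!r}, got {doc.get('schema')!r}")
    kind = doc["kind"]
    params = dict(doc["params"])
    if kind == "autoactivator":
        p = AutoactivatorParams(**params)
    elif kind == "protease":
        params["auto"] = AutoactivatorParams(**params["auto"])
        p = ProteaseSwitchParams(**params)
    elif kind == "two_component":
        params["auto"] = AutoactivatorParams(**params["auto"])
        p = TwoComponentParams(**params)
    elif kind == "lac":
        reg = dict(params.pop("regulation"))
        cls = _REGULATION_TAGS[reg.pop("mode")]
        params["regulation"] = cls(**reg)
        p = LacParams(**params)
    else:
        raise SchemaError(f"unknown model kind {kind!r}")
    return ModelSpec(kind=kind, params=p, modulation=doc.get("modulation", "nutrient"))


def save_model_yaml(spec: ModelSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(model_to_dict(spec), sort_keys=False))


def load_model_yaml(path) -> ModelSpec:
    return model_from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# single-cell trace tables
# ---------------------------------------------------------------------------

def write_trace_table(cells: Sequence[CellRecord], path) -> None:
    rows = []
    for c in cells:
        for t, ln, fl in zip(c.time, c.length, c.fluor):
            rows.append(
                {
                    "cell_id": c.cell_id,
                    "parent_id": c.parent_id if c.parent_id is not None else "",
                    "time_h": t,
                    "length_um": ln,
                    "fluor_total": fl,
                }
            )
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(path, index=False)


def read_trace_table(path) -> tuple[list[CellRecord], list[str]]:
    """Load cell records grouped and time-sorted; returns (cells, orphans).

    ``orphans`` lists parent ids referenced but absent from the table; the
    affected records are still loaded (with the dangling reference kept).
    """
    df = pd.read_csv(path, dtype={"cell_id": str, "parent_id": str})
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trace table is missing column(s): {', '.join(missing)}")
    df["parent_id"] = df["parent_id"].fillna("")
    children: dict[str, list[str]] = {}
    order: list[str] = []
    groups = {}
    for cid, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("time_h")
        if grp["time_h"].duplicated().any():
            raise SchemaError(f"cell {cid!r} has duplicate frame times")
        groups[cid] = grp
        order.append(cid)
        pid = grp["parent_id"].iloc[0]
        if pid:
            children.setdefault(pid, []).append(cid)
    cells = []
    orphans = []
    for cid in order:
        grp = groups[cid]
        pid = grp["parent_id"].iloc[0] or None
        if pid is not None and pid not in groups:
            orphans.append(pid)
        cells.append(
            CellRecord(
                cell_id=cid,
                parent_id=pid,
                time=grp["time_h"].to_numpy(),
                length=grp["length_um"].to_numpy(),
                fluor=grp["fluor_total"].to_numpy(),
                daughters=tuple(children.get(cid, ())),
            )
        )
    orphans = sorted(set(orphans))
    if orphans:
        logger.warning("trace table references %d unknown parent id(s): %s",
                       len(orphans), ", ".join(orphans))
    return cells, orphans


# ---------------------------------------------------------------------------
# plate tables
# ---------------------------------------------------------------------------

def write_plate_table(series: Sequence[PlateTimeSeries], path) -> None:
    frames = []
    for s in series:
        df = pd.DataFrame(
            {"well": s.meta.get("well", ""), "time_h": s.time,
             "od600": s.od600, "signal": s.signal}
        )
        for key, val in s.meta.items():
            if key != "well":
                df[key] = val
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_plate_table(path) -> list[PlateTimeSeries]:
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"plate table is missing column(s): {', '.join(missing)}")
    meta_cols = [c for c in df.columns if c not in ("time_h", "od600", "signal")]
    out = []
    for well, grp in df.groupby("well", sort=False):
        grp = grp.sort_values("time_h")
        meta = {c: grp[c].iloc[0] for c in meta_cols}
        out.append(
            PlateTimeSeries(
                time=grp["time_h"].to_numpy(),
                od600=grp["od600"].to_numpy(),
                signal=grp["signal"].to_numpy(),
                meta=meta,
            )
        )
    return out


# ---------------------------------------------------------------------------
# induction curves
# ---------------------------------------------------------------------------

def write_induction_curve(curve: InductionCurve, path) -> None:
    pd.DataFrame(
        {"conc_uM": curve.conc, "activity": curve.activity, "sigma": curve.sigma}
    ).to_csv(path, index=False)


def read_induction_curve(path) -> InductionCurve:
    df = pd.read_csv(path)
    missing = [c for c in ("conc_uM", "activity", "sigma") if c not in df.columns]
    if missing:
        raise SchemaError(f"induction curve is missing column(s): {', '.join(missing)}")
    df = df.sort_values("conc_uM")
    return InductionCurve(
        conc=df["conc_uM"].to_numpy(),
        activity=df["activity"].to_numpy(),
        sigma=df["sigma"].to_numpy(),
    )
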