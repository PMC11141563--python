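"""Reading and writing measurement tables, profiles, configs and reports.

The measurement table is a CSV with columns ``station,d,S,C,label`` (one
row per station, consistent units).  Rows with both ``S`` and ``C``
present are slab boundaries; rows carrying only ``d`` are interior
subslab stations.  A body is reconstructed from such a table alone:
consecutive boundaries delimit slabs, the interior rows between them fix
the subslab count, and a boundary with ``d = 0`` marks a cone apex.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .comparators import TwoViewProfile
from .core import BodyMeasurement, CrossSection, Slab
from .exceptions import ValidationError

__all__ = [
    "read_measurements",
    "write_measurements",
    "body_from_table",
    "table_from_body",
    "read_profile",
    "write_profile",
    "load_config",
    "write_report",
]

MEASUREMENT_COLUMNS = ["station", "d", "S", "C", "label"]


def read_measurements(path) -> pd.DataFrame:
    """Read a ``station,d,S,C[,label]`` CSV into a sorted table."""
    df = pd.read_csv(path)
    missing = {"station", "d"} - set(df.columns)
    if missing:
        raise ValidationError(f"measurement table lacks columns {sorted(missing)}")
    for col in ("S", "C"):
        if col not in df.columns:
            df[col] = np.nan
    if "label" not in df.columns:
        df["label"] = ""
    return df[MEASUREMENT_COLUMNS].sort_values("station", ignore_index=True)


def write_measurements(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def _section_from_row(row) -> CrossSection:
    has_S = pd.notna(row.S)
    has_C = pd.notna(row.C)
    return CrossSection(
        station=float(row.station),
        d=float(row.d),
        S=float(row.S) if has_S else None,
        C=float(row.C) if has_C else None,
        label="" if pd.isna(row.label) else str(row.label),
    )


def body_from_table(
    df: pd.DataFrame, modes: list[str] | None = None, name: str = ""
) -> BodyMeasurement:
    """Build a :class:`BodyMeasurement` from a measurement table.

    Slab boundaries are the rows where ``S`` and ``C`` are both present,
    or where ``d = 0`` (a cone apex needs neither).  Interior rows between
    two boundaries must be equally spaced; their count fixes the subslab
    number ``n``.  ``modes`` optionally overrides the per-slab mode
    (default: cone where exactly one end has ``d = 0``, else frustum).
    """
    df = df.sort_values("station", ignore_index=True)
    is_boundary = (df["S"].notna() & df["C"].notna()) | (df["d"] == 0)
    idx = np.flatnonzero(is_boundary.to_numpy())
    if idx.size < 2:
        raise ValidationError("need at least two boundary rows (with S and C)")
    slabs = []
    sections = {i: _section_from_row(df.iloc[i]) for i in idx}
    for s_i, (i0, i1) in enumerate(zip(idx, idx[1:])):
        ant, post = sections[i0], sections[i1]
        interior = df.iloc[i0 + 1:i1]
        n = len(interior) + 1
        expected = np.linspace(ant.station, post.station, n + 1)[1:-1]
        if len(interior) and not np.allclose(
            interior["station"].to_numpy(), expected,
            rtol=0, atol=1e-6 * (post.station - ant.station),
        ):
            raise ValidationError(
                f"interior stations of slab {s_i} are not equally spaced"
            )
        if modes is not None:
            mode = modes[s_i]
        else:
            mode = "cone" if (ant.d == 0) != (post.d == 0) else "frustum"
        slabs.append(
            Slab(
                anterior=ant,
                posterior=post,
                n=n,
                interior_d=tuple(float(v) for v in interior["d"]),
                mode=mode,
            )
        )
    return BodyMeasurement(slabs=slabs, name=name)


def table_from_body(body: BodyMeasurement) -> pd.DataFrame:
    """Flatten a body back into a measurement table (main body only)."""
    rows = []

    def add_section(sec: CrossSection) -> None:
        rows.append(
            {"station": sec.station, "d": sec.d,
             "S": np.nan if sec.S is None else sec.S,
             "C": np.nan if sec.C is None else sec.C,
             "label": sec.label}
        )

    for i, slab in enumerate(body.slabs):
        if i == 0:
            add_section(slab.anterior)
        stations = np.linspace(slab.anterior.station, slab.posterior.station,
                               slab.n + 1)[1:-1]
        for st, d in zip(stations, slab.interior_d):
            rows.append({"station": st, "d": d, "S": np.nan, "C": np.nan, "label": ""})
        add_section(slab.posterior)
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def read_profile(path) -> TwoViewProfile:
    """Read a two-view profile CSV ``station,half_height,half_width``."""
    df = pd.read_csv(path)
    missing = {"station", "half_height", "half_width"} - set(df.columns)
    if missing:
        raise ValidationError(f"profile table lacks columns {sorted(missing)}")
    df = df.sort_values("station", ignore_index=True)
    return TwoViewProfile(
        stations=df["station"].to_numpy(float),
        half_height=df["half_height"].to_numpy(float),
        half_width=df["half_width"].to_numpy(float),
    )


def write_profile(profile: TwoViewProfile, path) -> None:
    pd.DataFrame(
        {
            "station": profile.stations,
            "half_height": profile.half_height,
            "half_width": profile.half_width,
        }
    ).to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a declarative YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {path} must be a mapping")
    return cfg


def write_report(report: dict, path) -> None:
    """Write a JSON report (numbers coerced to plain floats)."""

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, default=default) + "\n")
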