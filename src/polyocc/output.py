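"""Structured result output: TSV and JSON with parameter provenance.

TSV files carry a header row and full-precision scientific notation
(12 significant digits) so five-significant-figure window edges remain
auditable; a ``<name>.params.json`` sidecar records the resolved parameters.
JSON output mirrors the columns as arrays and embeds the provenance block
directly. Identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .model import OccupancyCurve, OccupancyWindow, windows_to_frame

__all__ = ["curve_to_frame", "write_results"]

_FLOAT_FMT = "%.12e"


def curve_to_frame(
    curve: OccupancyCurve, companion: OccupancyCurve | None = None
) -> pd.DataFrame:
    """One row per grid point. With a companion curve of the other mode on the
    same grid, emit both occupancy columns side by side."""
    cols: dict[str, Any] = {"c_total_molar": curve.c_total}
    pair = {curve.mode.value: curve}
    if companion is not None:
        if companion.c_total.shape != curve.c_total.shape or not np.allclose(
            companion.c_total, curve.c_total
        ):
            raise ValueError("companion curve must share the concentration grid")
        pair[companion.mode.value] = companion
    if len(pair) == 2:
        cols["theta_on_only"] = pair["on_only"].theta
        cols["theta_on_off"] = pair["on_off"].theta
        cols["c_eff_molar"] = pair["on_off"].c_eff
    else:
        cols[f"theta_{curve.mode.value}"] = curve.theta
        cols["c_eff_molar"] = curve.c_eff
    return pd.DataFrame(cols)


def _to_frame(result) -> pd.DataFrame:
    if isinstance(result, pd.DataFrame):
        return result
    if isinstance(result, OccupancyCurve):
        return curve_to_frame(result)
    if isinstance(result, OccupancyWindow):
        return windows_to_frame([result])
    if isinstance(result, (list, tuple)) and all(
        isinstance(r, OccupancyWindow) for r in result
    ):
        return windows_to_frame(result)
    raise TypeError(f"cannot tabulate result of type {type(result).__name__}")


def write_results(
    result,
    path: "str | Path",
    fmt: str = "tsv",
    provenance: Mapping[str, Any] | None = None,
) -> Path:
    """Write a curve, window set, or table to ``path`` as TSV or JSON.

    TSV gets a ``<path>.params.json`` provenance sidecar (when provenance is
    supplied); JSON embeds provenance under the ``"provenance"`` key.
    """
    path = Path(path)
    frame = _to_frame(result)
    if fmt == "tsv":
        frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
        if provenance is not None:
            sidecar = path.with_suffix(path.suffix + ".params.json")
            sidecar.write_text(json.dumps(dict(provenance), indent=2, sort_keys=True))
    elif fmt == "json":
        payload: dict[str, Any] = {
            col: frame[col].tolist() for col in frame.columns
        }
        if provenance is not None:
            payload["provenance"] = dict(provenance)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    else:
        raise ValueError(f"unknown output format {fmt!r} (expected 'tsv' or 'json')")
    return path
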