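"""Model and curve persistence.

Models are stored as version-tagged JSON (format ``riskaudit-model``,
version ``"1"``); floats round-trip exactly through Python's shortest-repr
JSON encoding.  Component curves export to CSV with one row per (feature,
bin); unbounded outer bin edges are written as the sentinels ``-inf`` /
``+inf`` and each feature's finite data range is recorded in ``#`` header
comments so a re-imported curve preserves bin-representative positions.
"""

from __future__ import annotations

import io as _io
import json
import warnings

import numpy as np
import pandas as pd

from .data import DatasetSchema
from .gam import AdditiveRiskResults, BagModel, ComponentFunction, FitConfig

MODEL_FORMAT = "riskaudit-model"
MODEL_VERSION = "1"

CURVE_COLUMNS = ["feature", "bin_left", "bin_right", "value",
                 "ci_lower", "ci_upper", "bin_count"]


class ModelFormatError(ValueError):
    """Unknown or corrupted model/curve file."""


def _farray(obj, name: str) -> np.ndarray:
    try:
        arr = np.asarray(obj, dtype=float)
    except (TypeError, ValueError) as exc:
        raise ModelFormatError(f"corrupted numeric field {name!r}: {obj!r}") from exc
    if not np.isfinite(arr).all():
        raise ModelFormatError(f"non-finite entries in numeric field {name!r}")
    return arr


def _component_to_dict(c: ComponentFunction) -> dict:
    return {
        "feature": c.feature,
        "kind": c.kind,
        "thresholds": c.thresholds.tolist(),
        "values": c.values.tolist(),
        "bin_counts": c.bin_counts.tolist(),
        "support": list(c.support),
        "ci_lower": None if c.ci_lower is None else c.ci_lower.tolist(),
        "ci_upper": None if c.ci_upper is None else c.ci_upper.tolist(),
        "missing_bin_value": c.missing_bin_value,
        "missing_count": c.missing_count,
        "categories": c.categories,
    }


def _component_from_dict(d: dict) -> ComponentFunction:
    name = d["feature"]
    return ComponentFunction(
        feature=name,
        kind=d["kind"],
        thresholds=_farray(d["thresholds"], f"{name}.thresholds"),
        values=_farray(d["values"], f"{name}.values"),
        bin_counts=np.asarray(d["bin_counts"], dtype=np.int64),
        support=tuple(_farray(d["support"], f"{name}.support").tolist()),
        ci_lower=None if d.get("ci_lower") is None else _farray(d["ci_lower"], f"{name}.ci_lower"),
        ci_upper=None if d.get("ci_upper") is None else _farray(d["ci_upper"], f"{name}.ci_upper"),
        missing_bin_value=d.get("missing_bin_value"),
        missing_count=int(d.get("missing_count", 0)),
        categories=d.get("categories"),
    )


def serialize_model(results: AdditiveRiskResults, path) -> None:
    """Write a fitted model to *path* as version-tagged JSON."""
    if not np.isfinite(results.intercept):
        raise ModelFormatError("model intercept is not finite")
    doc = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "schema": results.schema.to_dict(),
        "intercept": results.intercept,
        "components": [_component_to_dict(c) for c in results.components],
        "fit_config": results.fit_config.to_dict(),
        "n_obs": results.n_obs,
        "rounds_used": list(results.rounds_used),
        "bags": None if results.bag_models is None else [
            {"intercept": b.intercept,
             "components": [_component_to_dict(c) for c in b.components]}
            for b in results.bag_models
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def deserialize_model(path) -> AdditiveRiskResults:
    """Read a model written by :func:`serialize_model`; round-trip is exact."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("format") != MODEL_FORMAT:
        raise ModelFormatError(f"not a {MODEL_FORMAT} file: {path}")
    if doc.get("version") != MODEL_VERSION:
        raise ModelFormatError(
            f"unknown model schema version {doc.get('version')!r} (expected {MODEL_VERSION!r})")
    try:
        intercept = float(doc["intercept"])
    except (TypeError, ValueError) as exc:
        raise ModelFormatError(f"corrupted numeric field 'intercept': {doc.get('intercept')!r}") from exc
    bags = None
    if doc.get("bags") is not None:
        bags = [BagModel(intercept=float(b["intercept"]),
                         components=[_component_from_dict(c) for c in b["components"]])
                for b in doc["bags"]]
    return AdditiveRiskResults(
        schema=DatasetSchema.from_dict(doc["schema"]),
        intercept=intercept,
        components=[_component_from_dict(c) for c in doc["components"]],
        fit_config=FitConfig.from_dict(doc["fit_config"]),
        bag_models=bags,
        n_obs=int(doc.get("n_obs", 0)),
        rounds_used=list(doc.get("rounds_used", [])),
    )


# ---------------------------------------------------------------------------
# curve tables
# ---------------------------------------------------------------------------

def export_component_curves(results: AdditiveRiskResults, path) -> None:
    """Export fitted curves to CSV, one row per (feature, bin).

    Columns: feature, bin_left, bin_right, value, ci_lower, ci_upper,
    bin_count.  Outer unbounded edges are the sentinels ``-inf``/``+inf``;
    each feature's observed data range is kept in ``# support`` header lines.
    """
    if not results.components:
        raise RuntimeError("model has no components to export")
    rows = []
    header = ["# riskaudit-curves version=1",
              "# bin_left/bin_right: -inf/+inf mark unbounded outer bins"]
    for c in results.components:
        header.append(f"# support feature={c.feature} min={c.support[0]!r} max={c.support[1]!r}")
        edges = c.bin_edges()
        for b in range(c.n_bins):
            rows.append({
                "feature": c.feature,
                "bin_left": edges[b],
                "bin_right": edges[b + 1],
                "value": c.values[b],
                "ci_lower": np.nan if c.ci_lower is None else c.ci_lower[b],
                "ci_upper": np.nan if c.ci_upper is None else c.ci_upper[b],
                "bin_count": int(c.bin_counts[b]),
            })
    df = pd.DataFrame(rows, columns=CURVE_COLUMNS)
    buf = _io.StringIO()
    df.to_csv(buf, index=False, float_format="%.17g")  # round-trip exact
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(header) + "\n")
        fh.write(buf.getvalue())


def import_component_curves(path) -> list[ComponentFunction]:
    """Re-import a curve table exported by :func:`export_component_curves`.

    Returns components suitable for shape-only auditing (and, together with a
    patient table, for likelihood-based discontinuity testing).
    """
    support = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# support feature="):
                body = line[len("# support "):].strip()
                parts = dict(p.split("=", 1) for p in body.split(" "))
                support[parts["feature"]] = (float(parts["min"]), float(parts["max"]))
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing_cols = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ModelFormatError(f"curve table missing columns: {missing_cols}")
    comps = []
    for feat, grp in df.groupby("feature", sort=False):
        grp = grp.reset_index(drop=True)
        left = grp["bin_left"].astype(float).to_numpy()
        right = grp["bin_right"].astype(float).to_numpy()
        if not np.isneginf(left[0]) or not np.isposinf(right[-1]):
            raise ModelFormatError(f"curve table for {feat!r} lacks unbounded outer bins")
        if not np.allclose(left[1:], right[:-1], equal_nan=False):
            raise ModelFormatError(f"curve table for {feat!r} has non-contiguous bins")
        thresholds = right[:-1]
        values = grp["value"].to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ModelFormatError(f"corrupted numeric field 'value' for feature {feat!r}")
        ci_lo = grp["ci_lower"].to_numpy(dtype=float)
        ci_hi = grp["ci_upper"].to_numpy(dtype=float)
        sup = support.get(feat)
        if sup is None:
            fin = thresholds[np.isfinite(thresholds)]
            sup = (float(fin.min()), float(fin.max())) if fin.size else (0.0, 1.0)
            warnings.warn(f"no support header for {feat!r}; using threshold range",
                          stacklevel=2)
        comps.append(ComponentFunction(
            feature=str(feat), kind="continuous", thresholds=thresholds,
            values=values, bin_counts=grp["bin_count"].to_numpy(dtype=np.int64),
            support=sup,
            ci_lower=None if np.isnan(ci_lo).all() else ci_lo,
            ci_upper=None if np.isnan(ci_hi).all() else ci_hi,
        ))
    return comps
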