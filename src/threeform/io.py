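"""File formats: design specs (YAML/JSON), data tables (CSV), exports.

CSV convention: UTF-8, comma-separated, header row of item identifiers
required; an empty cell means missing, and a configurable sentinel string
("NA" by default also accepted on read).  Write-then-read round-trips are
lossless, including the missingness mask.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .design import BlockAllocation, DesignSpec, FormSet, ItemPool, Scale
from .exceptions import InvalidSpecError, SchemaError


def load_design_spec(path: str | Path) -> tuple[ItemPool, DesignSpec]:
    """Parse a YAML/JSON design spec into a validated pool and spec.

    Recognized keys: ``scales`` (name -> ordered item list), ``singletons``,
    ``forced_x``, ``p_x``, ``method``, ``threshold``, ``require_x_coverage``,
    ``max_retries``, ``seed``.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise InvalidSpecError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise InvalidSpecError(f"{path}: design spec must be a mapping")
    scales_raw = raw.get("scales", {})
    if not isinstance(scales_raw, dict):
        raise InvalidSpecError(f"{path}: 'scales' must map names to item lists")
    scales = [Scale(str(name), [str(it) for it in items]) for name, items in scales_raw.items()]
    pool = ItemPool(
        scales=scales,
        singletons=[str(s) for s in raw.get("singletons", [])],
        forced_x=[str(s) for s in raw.get("forced_x", [])],
    )
    spec = DesignSpec(
        p_x=int(raw.get("p_x", 0)),
        small_scale_threshold=int(raw.get("threshold", 12)),
        method=raw.get("method", "ria"),
        require_x_coverage=bool(raw.get("require_x_coverage", False)),
        max_retries=int(raw.get("max_retries", 100)),
        seed=raw.get("seed"),
    )
    return pool, spec


def read_data_csv(path: str | Path, na_sentinel: str = "NA") -> pd.DataFrame:
    """Read a participant-by-item table; empty cells and the sentinel are missing."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split(",")
    seen: set[str] = set()
    dupes = [h for h in header if h in seen or seen.add(h)]
    if dupes:
        raise SchemaError(f"{path}: duplicate column headers {dupes}")
    try:
        df = pd.read_csv(
            path,
            keep_default_na=False,
            na_values=["", na_sentinel],
            skipinitialspace=False,
        )
    except pd.errors.ParserError as exc:
        raise SchemaError(f"{path}: malformed CSV ({exc})") from exc
    return df.apply(pd.to_numeric, errors="coerce").astype(float)


def write_data_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a table with empty cells for missing values."""
    table.to_csv(path, index=False, na_rep="")


def write_forms_csv(formset: FormSet, allocation: BlockAllocation, out_dir: str | Path) -> list[Path]:
    """One CSV per form (position, item_id, block) plus a combined block file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for label, items in formset.forms.items():
        df = pd.DataFrame(
            {
                "position": range(1, len(items) + 1),
                "item_id": items,
                "block": [allocation.assignment[it] for it in items],
            }
        )
        p = out_dir / f"form_{label}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    blocks = pd.DataFrame(
        {
            "item_id": list(allocation.assignment),
            "block": list(allocation.assignment.values()),
            "provenance": [allocation.provenance.get(it, "") for it in allocation.assignment],
        }
    )
    p = out_dir / "blocks.csv"
    blocks.to_csv(p, index=False)
    written.append(p)
    return written


def config_hash(obj: Any) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode("utf-8")
    return hashlib.sha256(payload).hexdigest()[:12]


def write_run_metadata(out_path: str | Path, seed: int | None, config: Any) -> Path:
    """Sidecar ``<out>.meta.json`` recording the seed and config hash."""
    meta_path = Path(str(out_path) + ".meta.json")
    meta_path.write_text(
        json.dumps(
            {"seed": seed, "config_hash": config_hash(config), "config": config},
            indent=2,
            default=str,
        ),
        encoding="utf-8",
    )
    return meta_path
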