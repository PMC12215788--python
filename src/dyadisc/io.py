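"""TSV interchange with schema validation.

All tabular interchange is tab-separated text with a header row. Each
table kind declares its required columns here; readers fail with the
offending column named rather than propagating a malformed frame.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from dyadisc.exceptions import SchemaError
from dyadisc.isc import ISC_COLUMNS, TimeSeriesPanel

SCHEMAS: dict[str, list[str]] = {
    "panel": ["subject", "video", "region", "timepoint", "value"],
    "ratings": ["subject", "video", "rating"],
    "attributes": ["subject", "age", "gender", "country"],
    "design": [
        "subject_a",
        "subject_b",
        "video",
        "sharing_category",
        "age_similarity",
        "gender_match",
        "country_match",
    ],
    "isc": ISC_COLUMNS,
    "study2": ["participant", "article", "sharing", "similarity", "interest", "valence"],
    "study3": ["participant", "condition", "sharing", "interest", "baseline_sharing"],
}


def write_tsv(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_tsv(path: str | Path, kind: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    frame = pd.read_csv(path, sep="\t")
    if kind is not None:
        check_schema(frame, kind, source=str(path))
    return frame


def check_schema(frame: pd.DataFrame, kind: str, source: str = "<frame>") -> None:
    if kind not in SCHEMAS:
        raise KeyError(f"unknown schema kind {kind!r}")
    missing = [c for c in SCHEMAS[kind] if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{source}: {kind} table missing column(s) {missing}"
        )


def write_panel(panel: TimeSeriesPanel, path: str | Path) -> Path:
    return write_tsv(panel.to_long_frame(), path)


def read_panel(path: str | Path) -> TimeSeriesPanel:
    frame = read_tsv(path, kind="panel")
    return TimeSeriesPanel.from_long_frame(frame)
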