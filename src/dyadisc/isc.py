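"""Dyadic inter-subject correlations (ISCs).

For every unordered pair of subjects (dyad) that watched the same video, the
Pearson correlation between their regional mean time series is computed per
brain region, Fisher z-transformed, and finally z-scored within each region
across all dyad x video observations of that region.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from dyadisc.exceptions import SchemaError, UndefinedCorrelationError

#: Columns of the long-format ISC table.
ISC_COLUMNS = ["subject_a", "subject_b", "video", "region", "r", "z", "z_norm"]


class TimeSeriesPanel:
    """Neural response values indexed by (subject, video, region, timepoint).

    A subject may lack a video entirely (partial data), but whenever two
    subjects share a video they must hold the same regions with series of
    equal length; series must be finite throughout.
    """

    def __init__(self) -> None:
        # (subject, video) -> {region -> 1-D float array}
        self._entries: dict[tuple[str, str], dict[str, np.ndarray]] = {}

    # -- construction ------------------------------------------------------

    def add_cell(
        self, subject: str, video: str, series_by_region: Mapping[str, np.ndarray]
    ) -> None:
        """Insert all regional series for one subject x video cell."""
        cell = {}
        for region, series in series_by_region.items():
            arr = np.asarray(series, dtype=float)
            if arr.ndim != 1 or arr.size < 3:
                raise SchemaError(
                    f"series for ({subject}, {video}, {region}) must be 1-D "
                    f"with >= 3 timepoints"
                )
            if not np.all(np.isfinite(arr)):
                raise SchemaError(
                    f"series for ({subject}, {video}, {region}) contains "
                    f"non-finite values"
                )
            cell[region] = arr
        self._entries[(subject, video)] = cell

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame) -> "TimeSeriesPanel":
        """Build a panel from a long table (subject, video, region, timepoint, value)."""
        required = {"subject", "video", "region", "timepoint", "value"}
        missing = required - set(frame.columns)
        if missing:
            raise SchemaError(f"panel table missing columns: {sorted(missing)}")
        panel = cls()
        for (subject, video), cell in frame.groupby(["subject", "video"], sort=True):
            series_by_region = {}
            for region, block in cell.groupby("region", sort=True):
                block = block.sort_values("timepoint")
                series_by_region[str(region)] = block["value"].to_numpy(dtype=float)
            panel.add_cell(str(subject), str(video), series_by_region)
        return panel

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for (subject, video), cell in sorted(self._entries.items()):
            for region in sorted(cell):
                series = cell[region]
                rows.append(
                    pd.DataFrame(
                        {
                            "subject": subject,
                            "video": video,
                            "region": region,
                            "timepoint": np.arange(series.size),
                            "value": series,
                        }
                    )
                )
        if not rows:
            return pd.DataFrame(
                columns=["subject", "video", "region", "timepoint", "value"]
            )
        return pd.concat(rows, ignore_index=True)

    # -- inspection --------------------------------------------------------

    @property
    def subjects(self) -> list[str]:
        return sorted({s for s, _ in self._entries})

    @property
    def videos(self) -> list[str]:
        return sorted({v for _, v in self._entries})

    def subjects_with_video(self, video: str) -> list[str]:
        return sorted(s for s, v in self._entries if v == video)

    def has_cell(self, subject: str, video: str) -> bool:
        return (subject, video) in self._entries

    def cell(self, subject: str, video: str) -> dict[str, np.ndarray]:
        return self._entries[(subject, video)]

    def regions(self) -> list[str]:
        out: set[str] = set()
        for cell in self._entries.values():
            out.update(cell)
        return sorted(out)

    def validate(self) -> None:
        """Check the cross-subject alignment invariants for every video."""
        for video in self.videos:
            holders = self.subjects_with_video(video)
            ref_subject = holders[0]
            ref_regions = sorted(self._entries[(ref_subject, video)])
            ref_len = {
                r: s.size for r, s in self._entries[(ref_subject, video)].items()
            }
            for subject in holders[1:]:
                cell = self._entries[(subject, video)]
                if sorted(cell) != ref_regions:
                    raise SchemaError(
                        f"video {video!r}: subjects {ref_subject!r} and "
                        f"{subject!r} hold different region sets"
                    )
                for region, series in cell.items():
                    if series.size != ref_len[region]:
                        raise SchemaError(
                            f"video {video!r}, region {region!r}: series length "
                            f"{series.size} for subject {subject!r} differs from "
                            f"{ref_len[region]}"
                        )


def pearson_corr(x: Iterable[float], y: Iterable[float]) -> float:
    """Sample Pearson correlation of two equal-length series.

    Raises on length mismatch, fewer than 3 points, or zero variance in
    either input (an undefined correlation is an error, never silently 0).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise SchemaError(
            f"series length mismatch: {xa.shape} vs {ya.shape}"
        )
    if xa.size < 3:
        raise SchemaError("series must have at least 3 timepoints")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined for zero-variance series"
        )
    r = float(np.corrcoef(xa, ya)[0, 1])
    # guard rounding slightly outside [-1, 1]
    return float(np.clip(r, -1.0, 1.0))


def fisher_z(r) -> float | np.ndarray:
    """Fisher z-transform atanh(r); odd and strictly increasing on (-1, 1).

    Values with |r| >= 1 are refused: callers must clamp explicitly (see
    ``clamp_correlations``) rather than let infinities propagate.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1.0):
        raise ValueError(
            "fisher_z requires |r| < 1; clamp explicitly with "
            "clamp_correlations() if perfect correlations are expected"
        )
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def clamp_correlations(r, eps: float = 1e-7):
    """Clamp correlations into [-(1-eps), 1-eps] so fisher_z stays finite."""
    return np.clip(np.asarray(r, dtype=float), -1.0 + eps, 1.0 - eps)


def compute_dyadic_isc(
    panel: TimeSeriesPanel, clamp: bool = False
) -> pd.DataFrame:
    """Compute one ISC record per (unordered dyad, video, region).

    A record exists only when both dyad members hold the video; with n_v
    subjects holding video v the output has sum_v C(n_v, 2) * n_regions rows.
    Subject pairs are stored with subject_a < subject_b lexicographically so
    each dyad appears exactly once. ``z_norm`` is left NaN here; fill it with
    :func:`normalize_within_region`.
    """
    panel.validate()
    frames = []
    for video in panel.videos:
        holders = panel.subjects_with_video(video)
        if len(holders) < 2:
            continue
        regions = sorted(panel.cell(holders[0], video))
        pairs = list(combinations(range(len(holders)), 2))
        ia = np.array([p[0] for p in pairs])
        ib = np.array([p[1] for p in pairs])
        for region in regions:
            mat = np.vstack([panel.cell(s, video)[region] for s in holders])
            sd = mat.std(axis=1)
            if np.any(sd == 0):
                bad = holders[int(np.argmax(sd == 0))]
                raise UndefinedCorrelationError(
                    f"zero-variance series for subject {bad!r}, video "
                    f"{video!r}, region {region!r}"
                )
            corr = np.corrcoef(mat)
            r = np.clip(corr[ia, ib], -1.0, 1.0)
            frames.append(
                pd.DataFrame(
                    {
                        "subject_a": [holders[i] for i in ia],
                        "subject_b": [holders[j] for j in ib],
                        "video": video,
                        "region": region,
                        "r": r,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=ISC_COLUMNS)
    records = pd.concat(frames, ignore_index=True)
    r = records["r"].to_numpy()
    if clamp:
        r = clamp_correlations(r)
    records["z"] = fisher_z(r)
    records["z_norm"] = np.nan
    return records


def normalize_within_region(records: pd.DataFrame) -> pd.DataFrame:
    """Z-score the Fisher-transformed values within each region.

    Uses the sample standard deviation (ddof=1). Each region needs at least
    two records with nonzero spread; offenders are named in the error.
    """
    if "z" not in records.columns or "region" not in records.columns:
        raise SchemaError("records must carry 'region' and 'z' columns")
    out = records.copy()
    grouped = out.groupby("region")["z"]
    counts = grouped.transform("size")
    if (counts < 2).any():
        bad = sorted(out.loc[counts < 2, "region"].unique())
        raise SchemaError(f"regions with fewer than 2 records: {bad}")
    mean = grouped.transform("mean")
    sd = grouped.transform("std")  # ddof=1
    if (sd == 0).any():
        bad = sorted(out.loc[sd == 0, "region"].unique())
        raise SchemaError(f"regions with zero spread in z: {bad}")
    out["z_norm"] = (out["z"] - mean) / sd
    return out
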