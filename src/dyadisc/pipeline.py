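"""Pipeline orchestration: simulate -> isc -> design -> fit -> report.

Each stage reads and writes TSV files under a run directory, so any stage
can be re-run in isolation and a rerun with the same config and seed
produces byte-identical outputs. A JSON manifest collects seeds, row
counts, convergence information and timings per stage.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from dyadisc import __version__
from dyadisc.behavioral import fit_study2, fit_study3, study3_contrasts
from dyadisc.design import build_dyad_design
from dyadisc.exceptions import ConfigurationError, SchemaError
from dyadisc.io import read_panel, read_tsv, write_panel, write_tsv
from dyadisc.isc import compute_dyadic_isc, normalize_within_region
from dyadisc.lmm import ModelSpec, region_wise_analysis
from dyadisc.synthetic import (
    BehavioralSimConfig,
    NeuralSimConfig,
    simulate_neural_panel,
    simulate_study2_table,
    simulate_study3_table,
)

ALL_STAGES = ("simulate", "isc", "design", "fit-neural", "fit-study2", "fit-study3", "report")

CONTRAST_SETS = {
    "hh-ll": (("HH", "LL"),),
    "hh-lh": (("HH", "LH"),),
    "lh-ll": (("LH", "LL"),),
    "all": (("HH", "LL"), ("HH", "LH"), ("LH", "LL")),
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str = "runs/test"
    seed: int = 0
    preset: str = "test"  # or "full"
    stages: tuple[str, ...] = ALL_STAGES
    contrasts: str = "hh-ll"
    correction: str = "holm"  # holm | bh | none
    alpha: float = 0.05
    clamp_correlations: bool = False
    neural: dict = field(default_factory=dict)  # NeuralSimConfig overrides
    behavioral: dict = field(default_factory=dict)  # BehavioralSimConfig overrides

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        if self.preset not in ("test", "full"):
            raise ConfigurationError(f"preset must be 'test' or 'full', got {self.preset!r}")
        if self.contrasts not in CONTRAST_SETS:
            raise ConfigurationError(f"contrasts must be one of {sorted(CONTRAST_SETS)}")
        if self.correction not in ("holm", "bh", "none"):
            raise ConfigurationError(f"correction must be holm|bh|none, got {self.correction!r}")

    def neural_config(self) -> NeuralSimConfig:
        if self.preset == "full":
            return NeuralSimConfig.full_scale(seed=self.seed, **self.neural)
        return NeuralSimConfig(seed=self.seed, **self.neural)

    def behavioral_config(self) -> BehavioralSimConfig:
        return BehavioralSimConfig(seed=self.seed, **self.behavioral)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _paths(outdir: Path) -> dict[str, Path]:
    return {
        "panel": outdir / "panel.tsv",
        "ratings": outdir / "ratings.tsv",
        "attributes": outdir / "attributes.tsv",
        "isc": outdir / "isc.tsv",
        "design": outdir / "design.tsv",
        "neural_results": outdir / "neural_results.tsv",
        "study2": outdir / "study2.tsv",
        "study2_results": outdir / "study2_results.tsv",
        "study3": outdir / "study3.tsv",
        "study3_results": outdir / "study3_results.tsv",
        "manifest": outdir / "manifest.json",
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages in order and write the run manifest.

    Returns the manifest dict. Raises (with the stage and offending file or
    region named) on any structural error; partial outputs of completed
    stages remain on disk so the run can resume.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = _paths(outdir)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "preset": config.preset,
        "config": {**asdict(config), "stages": list(config.stages)},
        "stages": {},
    }

    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        info: dict = {}
        if stage == "simulate":
            panel, ratings, attrs = simulate_neural_panel(config.neural_config())
            write_panel(panel, paths["panel"])
            write_tsv(ratings, paths["ratings"])
            write_tsv(attrs, paths["attributes"])
            bc = config.behavioral_config()
            write_tsv(simulate_study2_table(bc), paths["study2"])
            write_tsv(simulate_study3_table(bc), paths["study3"])
            info = {
                "subjects": len(attrs),
                "ratings_rows": len(ratings),
                "videos": len(panel.videos),
                "regions": len(panel.regions()),
            }
        elif stage == "isc":
            panel = read_panel(paths["panel"])
            isc = normalize_within_region(
                compute_dyadic_isc(panel, clamp=config.clamp_correlations)
            )
            write_tsv(isc, paths["isc"])
            info = {"isc_rows": len(isc), "regions": int(isc["region"].nunique())}
        elif stage == "design":
            ratings = read_tsv(paths["ratings"], kind="ratings")
            attrs = read_tsv(paths["attributes"], kind="attributes")
            design = build_dyad_design(ratings, attrs)
            write_tsv(design, paths["design"])
            info = {
                "design_rows": len(design),
                "category_counts": design["sharing_category"].value_counts().to_dict(),
            }
        elif stage == "fit-neural":
            isc = read_tsv(paths["isc"], kind="isc")
            design = read_tsv(paths["design"], kind="design")
            results = region_wise_analysis(
                isc,
                design,
                ModelSpec(),
                contrasts=CONTRAST_SETS[config.contrasts],
                correction=config.correction,
                alpha=config.alpha,
            )
            write_tsv(results, paths["neural_results"])
            info = {
                "regions": int(results["region"].nunique()),
                "non_converged": int((~results["converged"]).sum()),
                "significant": int(results["significant"].sum()),
            }
        elif stage == "fit-study2":
            table = read_tsv(paths["study2"], kind="study2")
            rows = []
            for adjusted in (False, True):
                fit, slope = fit_study2(table, adjusted=adjusted)
                row = slope.as_dict()
                row["model"] = "adjusted" if adjusted else "unadjusted"
                rows.append(row)
            write_tsv(pd.DataFrame(rows), paths["study2_results"])
            info = {"models": 2, "observations": len(table)}
        elif stage == "fit-study3":
            table = read_tsv(paths["study3"], kind="study3")
            frames = []
            for controlled in (False, True):
                fit = fit_study3(table, controlled=controlled)
                res = study3_contrasts(fit, which="all")
                res["model"] = "controlled" if controlled else "uncontrolled"
                frames.append(res)
            write_tsv(pd.concat(frames, ignore_index=True), paths["study3_results"])
            info = {"models": 2, "participants": len(table)}
        elif stage == "report":
            counts = {}
            for name in ("isc", "design", "neural_results", "study2_results", "study3_results"):
                if paths[name].exists():
                    counts[name] = len(read_tsv(paths[name]))
            info = {"row_counts": counts}
        manifest["stages"][stage] = {
            **info,
            "elapsed_s": round(time.perf_counter() - t0, 3),
        }

    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------


def validate_inputs(paths: dict[str, str | Path]) -> pd.DataFrame:
    """Per-file schema and invariant checks plus cross-file consistency.

    ``paths`` maps table kinds (panel, ratings, attributes, ...) to files.
    Returns a table with one pass/fail line per check.
    """
    lines: list[tuple[str, str, bool, str]] = []

    def record(source: str, check: str, passed: bool, detail: str = "") -> None:
        lines.append((source, check, passed, detail))

    tables: dict[str, pd.DataFrame] = {}
    for kind, path in paths.items():
        try:
            tables[kind] = read_tsv(path, kind=kind)
            record(str(path), f"{kind} schema", True)
        except (SchemaError, FileNotFoundError, KeyError) as exc:
            record(str(path), f"{kind} schema", False, str(exc))

    if "ratings" in tables:
        ratings = tables["ratings"]
        ok = ratings["rating"].isin([1, 2, 3, 4, 5]).all()
        bad = sorted(ratings.loc[~ratings["rating"].isin([1, 2, 3, 4, 5]), "rating"].unique())
        record(str(paths["ratings"]), "ratings in 1..5", bool(ok), f"offending values: {bad}" if bad else "")
        dup = ratings.duplicated(["subject", "video"]).any()
        record(str(paths["ratings"]), "one rating per subject x video", not dup)
    if "attributes" in tables:
        attrs = tables["attributes"]
        record(str(paths["attributes"]), "unique subjects", not attrs["subject"].duplicated().any())
        record(str(paths["attributes"]), "positive ages", bool((attrs["age"] > 0).all()))
    if "panel" in tables:
        panel_frame = tables["panel"]
        try:
            from dyadisc.isc import TimeSeriesPanel

            TimeSeriesPanel.from_long_frame(panel_frame).validate()
            record(str(paths["panel"]), "panel alignment", True)
        except SchemaError as exc:
            record(str(paths["panel"]), "panel alignment", False, str(exc))
    if "panel" in tables and "ratings" in tables:
        panel_subjects = set(tables["panel"]["subject"])
        rating_subjects = set(tables["ratings"]["subject"])
        orphans = sorted(rating_subjects - panel_subjects)
        record(
            str(paths["ratings"]),
            "rating subjects present in panel",
            not orphans,
            f"missing from panel: {orphans}" if orphans else "",
        )
    if "ratings" in tables and "attributes" in tables:
        missing = sorted(set(tables["ratings"]["subject"]) - set(tables["attributes"]["subject"]))
        record(
            str(paths["ratings"]),
            "rating subjects have attributes",
            not missing,
            f"missing attributes: {missing}" if missing else "",
        )
    return pd.DataFrame(lines, columns=["file", "check", "passed", "detail"])
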