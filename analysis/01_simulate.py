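"""Generate the synthetic study data (neural panel + behavioral tables).

Writes the test-preset run inputs under results/run/: a 20-subject x
4-video x 10-region neural panel with three signal regions in which
high-sharing dyads are more neurally similar by construction, the 1-5
sharing ratings and demographics, and the two behavioral tables
(100 participants x 5 articles; 300 participants in 4 conditions).
"""

from pathlib import Path

from dyadisc.pipeline import RunConfig, run_pipeline

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "run"


def main() -> None:
    config = RunConfig(outdir=str(OUTDIR), seed=2026, stages=("simulate",))
    manifest = run_pipeline(config)
    info = manifest["stages"]["simulate"]
    print(
        f"simulated {info['subjects']} subjects x {info['videos']} videos x "
        f"{info['regions']} regions -> {OUTDIR}"
    )
    print(f"ratings rows: {info['ratings_rows']}")


if __name__ == "__main__":
    main()
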