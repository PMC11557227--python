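"""Shared configuration for the numbered analysis drivers.

The study conditions: a ~1.5 km^2 triangular receiver grid at 150 m
spacing, two sub-colony sites of three pairs each, tags beaconing every
5 s with 5 dB RSS noise, localized in 15 s windows with 100 resampling
replicates.  Large intermediates (detections, truth tracks, fix tables)
go to ``scratch/``; summary tables go to ``results/analysis/``.
"""

from pathlib import Path

from pairtrack.pipeline import PipelineConfig

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results" / "analysis"

CONFIG = PipelineConfig(seed=42)


def ensure_dirs() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
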