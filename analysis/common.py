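"""Shared scenario for the synthetic-experiment analyses (scripts 02-05).

Three observers spanning the sparse-to-dense mosaic range, the five nominal
durations, five runs of 23 trials per condition, and a 30% artifact rate —
a scaled-down cohort with the full condition structure.
"""

from pathlib import Path

from conedrift import synth

RESULTS = Path(__file__).resolve().parents[1] / "results"
SYNTH_DIR = RESULTS / "synthetic"
# bulky per-trial tables go to scratch (regenerable from the seed)
SCRATCH_DIR = Path(__file__).resolve().parents[1] / "scratch" / "synthetic"

SCENARIO = synth.ScenarioConfig(
    n_observers=3,
    mosaic_radius_deg=0.35,
    seed=20260,
)
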