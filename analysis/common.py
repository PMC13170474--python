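"""Shared configuration for the numbered analysis scripts.

One desk-scale study: 17 subjects per anesthetic group, three phases per
subject, 16-channel 60-s recordings at 250 Hz. Everything derives from one
seed so the whole analysis is reproducible end to end.
"""

from pathlib import Path

from doceeg import pipeline

RESULTS = Path(__file__).resolve().parent.parent / "results"
# bulky intermediates (per-subject EEG fixtures, per-channel timecourses)
# live under scratch/; results/ holds the compact summary tables
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"
FIXTURES = SCRATCH / "synthetic"

CONFIG = pipeline.RunConfig(
    mode="files",
    seed=7,
    n_per_group=17,
    n_channels=16,
    duration=60.0,
    fs=250.0,
    n_perm=500,
    data_dir=str(FIXTURES),
    cohort_csv=str(FIXTURES / "cohort.csv"),
    output_dir=str(RESULTS),
)
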