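"""Shared paths and the study configuration used by the analysis scripts.

Bulky epoch data lives under ``scratch/``; small tables and reports go to
``results/``.  The cohort size (3 x 20) and reduced EEG montage keep a full
desk run under a couple of minutes while exercising every stage.
"""

from pathlib import Path

from tdcsdose import synth

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "analysis"
COHORT_DIR = SCRATCH / "cohort"

SEED = 2026


def study_config() -> synth.CohortConfig:
    return synth.CohortConfig(
        n_per_group=20,
        seed=SEED,
        include_eeg=True,
        eeg_n_trials=8,
        eeg_channels=tuple(synth.DEFAULT_EEG_CHANNELS[7:24]),
        tep_dose_shift_uv=1.5,   # planted negative 45-ms dose response
    )
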