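"""Preregistered inference: staged H1 decision tree, H2 and H3 models,
Bayes factors, and the sensation confound model."""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import COHORT_DIR, RESULTS

from tdcsdose import synth
from tdcsdose.pipeline import _jsonify, _report_text, RunConfig, analyze_cohort


def main() -> None:
    cohort = synth.read_cohort(COHORT_DIR)
    behavior_df = pd.read_csv(RESULTS / "behavior_outcomes.csv")
    behavior_df["exclusion_reasons"] = behavior_df.get("exclusion_reasons", "")
    mep_df = pd.read_csv(RESULTS / "mep_summary.csv")
    results = analyze_cohort(cohort.manifest, behavior_df, mep_df)
    (RESULTS / "inference.json").write_text(
        json.dumps(_jsonify(results), indent=2))
    cfg = RunConfig(seed=cohort.config.seed, cohort=cohort.config)
    report = _report_text(results, cfg)
    (RESULTS / "inference_report.txt").write_text(report)
    print(report)


if __name__ == "__main__":
    main()
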