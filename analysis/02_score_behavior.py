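"""Score the motor-sequence task: NCS per trial, outcomes, exclusions."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import COHORT_DIR, RESULTS

import numpy as np

from tdcsdose import behavior, synth


def main() -> None:
    cohort = synth.read_cohort(COHORT_DIR)
    scored = behavior.score_cohort_behavior(cohort.keypress_logs)
    scored.to_csv(RESULTS / "behavior_outcomes.csv", index=False)
    m = cohort.manifest.merge(scored, on="subject_id")
    print(f"scored {len(scored)} subjects; excluded: {int(scored['excluded'].sum())}")
    print("mean NCS by arm:")
    print(m.groupby("group_mA")["mean_ncs"].agg(["mean", "std"]).round(3).to_string())
    r = np.corrcoef(m["typing_wpm"], m["mean_ncs"])[0, 1]
    print(f"corr(typing speed, mean NCS) = {r:.3f} (generator: 0.62)")


if __name__ == "__main__":
    main()
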