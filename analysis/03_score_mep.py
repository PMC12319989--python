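"""Detect MEPs in the EMG epochs, reject log-power outliers, take medians."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import COHORT_DIR, RESULTS

from tdcsdose import mep, synth


def main() -> None:
    cohort = synth.read_cohort(COHORT_DIR)
    df = mep.score_cohort_mep(cohort.emg)
    df.to_csv(RESULTS / "mep_summary.csv", index=False)
    post = df[df["timepoint"] == "post"]
    defined = post["ratio_defined"].sum()
    print(f"MEP summaries for {post.shape[0]} subjects; "
          f"ratios defined (>=30 MEPs both timepoints): {int(defined)}")
    print(f"median detected per recording: {df['n_detected'].median():.0f} of "
          f"{cohort.config.mep_n_trials}")
    print(f"median post/pre ratio = {post['ratio'].median():.3f} "
          f"(generator drift: {cohort.config.mep_ratio_offset})")


if __name__ == "__main__":
    main()
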