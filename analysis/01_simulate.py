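"""Generate the synthetic study: clinical cohort + EEG per subject/phase.

Writes scratch/synthetic/cohort.csv and one TSV recording (with JSON
sidecar) per subject and phase; a copy of the cohort table also goes to
results/cohort.csv. Column dictionary for cohort.csv:

  subject_id       stable identifier, e.g. esk01 / pro01
  group            esketamine | propofol
  age              years
  sex              M | F
  etiology         TBI | CVD
  duration_months  disease duration (lognormal)
  baseline_state   UWS | MCS- | MCS+
  crsr_baseline    CRS-R total score, integer 0-23
  surgical_time    minutes
  recovery_time    minutes to spontaneous-respiration recovery
  norepinephrine   yes | no (intraoperative vasopressor use)
  improved         3-month upward move on the UWS<MCS-<MCS+<EMCS ladder
  state_3mo        state at 3 months
"""

import dataclasses

from common import CONFIG, FIXTURES, RESULTS

from doceeg import pipeline
from doceeg.recording import save_recording


def main() -> None:
    FIXTURES.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.replace(CONFIG, mode="synthetic")
    cohort, recordings = pipeline.generate_dataset(cfg)
    cohort.to_csv(FIXTURES / "cohort.csv", index=False)
    cohort.to_csv(RESULTS / "cohort.csv", index=False)
    for (sid, phase), rec in recordings.items():
        save_recording(rec, FIXTURES / f"{sid}_{phase}.tsv")
    props = cohort.groupby("group")["improved"].mean()
    print(f"wrote {len(cohort)} subjects x 3 phases to {FIXTURES}")
    print(f"3-month improvement: esketamine {props['esketamine']:.0%}, "
          f"propofol {props['propofol']:.0%}")
    print(f"mean recovery time: "
          f"esketamine {cohort[cohort.group == 'esketamine'].recovery_time.mean():.1f} min, "
          f"propofol {cohort[cohort.group == 'propofol'].recovery_time.mean():.1f} min")


if __name__ == "__main__":
    main()
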