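"""Clinical outcomes: cohort summary table, adjusted models, EEG-augmented LRT.

Produces the two-group baseline/outcome table (routed tests with effect
sizes), the adjusted logistic model for 3-month improvement and linear
model for respiratory-recovery time (age, etiology, baseline CRS-R as
confounders), and the exploratory logistic model augmented with
maintenance PE and recovery gamma wPLI, compared by likelihood ratio.
Requires results from 03 (PE) and 04 (wPLI).
"""

import json

import pandas as pd

from common import CONFIG, RESULTS

from doceeg import inference


def main() -> None:
    cohort = pd.read_csv(CONFIG.cohort_csv)
    table = inference.table_one(cohort)
    table.to_csv(RESULTS / "table_one.csv", index=False)
    print(table[["variable", "esketamine", "propofol", "p"]]
          .round(3).to_string(index=False))

    logit = inference.fit_logistic(cohort)
    linear = inference.fit_linear(cohort)
    row = logit.params.loc["group_esketamine"]
    print(f"\nadjusted OR (esketamine vs propofol): {row['or']:.2f} "
          f"[{row['or_low']:.2f}, {row['or_high']:.2f}]")
    lrow = linear.params.loc["group_esketamine"]
    print(f"adjusted recovery-time effect: {lrow['coef']:.2f} min "
          f"[{lrow['ci_low']:.2f}, {lrow['ci_high']:.2f}]")

    # EEG-augmented exploratory model
    pe = pd.read_csv(RESULTS / "pe_subject_means.csv")
    pe_maint = pe[pe["phase"] == "maintenance"] \
        .set_index("subject_id")["pe_mean"]
    wpli = pd.read_csv(RESULTS / "wpli_profiles.csv")
    gamma_rec = wpli[(wpli["phase"] == "recovery")
                     & (wpli["band"] == "gamma")] \
        .set_index("subject_id")["wpli"]
    aug = cohort.copy()
    aug["pe_maintenance"] = aug["subject_id"].map(pe_maint)
    aug["gamma_wpli_recovery"] = aug["subject_id"].map(gamma_rec)
    full = inference.fit_logistic(
        aug, extra_covariates=("pe_maintenance", "gamma_wpli_recovery"))
    reduced = inference.fit_logistic(aug)
    if full.converged and reduced.converged:
        lrt = inference.likelihood_ratio(full, reduced)
        print(f"LRT for adding EEG covariates: chi2={lrt.statistic:.2f}, "
              f"df={int(lrt.effect_size)}, p={lrt.p_raw:.3f}")
        lrt_out = {"chi2": lrt.statistic, "df": lrt.effect_size, "p": lrt.p_raw}
    else:
        print("EEG-augmented model did not converge at this cohort size")
        lrt_out = None

    out = {
        "logistic": {k: (None if pd.isna(v) else float(v))
                     for k, v in logit.params.loc["group_esketamine"].items()},
        "linear": {k: float(v)
                   for k, v in linear.params.loc["group_esketamine"].items()},
        "lrt": lrt_out,
    }
    (RESULTS / "outcome_models.json").write_text(json.dumps(out, indent=1))


if __name__ == "__main__":
    main()
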