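"""Evaluate the nomogram: averaged C-index, 3-year time-dependent ROC,
calibration, decision curve and Youden-cutoff classification.

Reads the fitted model and cohort from results/; writes the evaluation
bundle (JSON + CSV tables) under results/evaluation/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from collasig.competing import FineGrayModel, predict_cif
from collasig.evaluation import (
    averaged_c_index,
    binary_status_at,
    calibration_curve,
    classification_report,
    decision_curve,
    time_dependent_roc,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = pd.read_csv(ROOT / "study" / "cohort.csv").merge(
        pd.read_csv(ROOT / "signatures.csv"), on="patient_id"
    )
    model = FineGrayModel.from_json(ROOT / "fine_gray_model.json")
    time = cohort["time_yr"].to_numpy()
    event = cohort["event"].to_numpy()
    pred = np.array(
        [
            predict_cif(
                model,
                {v: cohort.iloc[i][v] for v in model.variable_terms},
                3.0,
            )
            for i in range(len(cohort))
        ]
    )

    out = ROOT / "evaluation"
    out.mkdir(exist_ok=True)
    c, c_ci = averaged_c_index(pred, time, event, n_boot=200, seed=2024)
    roc = time_dependent_roc(pred, time, event, t_star=3.0)
    cal = calibration_curve(pred, time, event, t_star=3.0, n_bins=4)
    cal.to_csv(out / "calibration.csv", index=False)
    labels, determinate = binary_status_at(time, event, 3.0)
    dc = decision_curve(pred[determinate], labels[determinate])
    dc.to_csv(out / "decision_curve.csv", index=False)
    rep = classification_report(pred[determinate], labels[determinate])
    pd.DataFrame(
        {"threshold": roc.thresholds, "tpr": roc.tpr, "fpr": roc.fpr}
    ).to_csv(out / "roc_curve.csv", index=False)

    summary = {
        "averaged_c_index": c,
        "c_index_ci": list(c_ci),
        "auroc_3yr": roc.auroc,
        "auroc_ci": list(roc.ci),
        "youden_cutoff": rep.cutoff,
        "classification": rep.as_dict(),
        "net_benefit_span": [
            float(dc["threshold"].iloc[0]),
            float(
                dc.loc[dc["net_benefit"] >
                       np.maximum(dc["treat_all"], 0), "threshold"].max()
            ) if (dc["net_benefit"] >
                  np.maximum(dc["treat_all"], 0)).any() else None,
        ],
    }
    (out / "evaluation.json").write_text(json.dumps(summary, indent=2))

    print(f"averaged C-index: {c:.3f} (95% CI {c_ci[0]:.3f}-{c_ci[1]:.3f})")
    print(
        f"3-year AUROC: {roc.auroc:.3f} "
        f"(DeLong CI {roc.ci[0]:.3f}-{roc.ci[1]:.3f}), "
        f"{roc.n_cases} cases / {roc.n_controls} controls"
    )
    print(
        "classification at Youden cutoff "
        f"{rep.cutoff:.3f}: sens={rep.sensitivity:.3f}, "
        f"spec={rep.specificity:.3f}, acc={rep.accuracy:.3f}, "
        f"ppv={rep.ppv:.3f}, npv={rep.npv:.3f}"
    )
    print(f"calibration bins:\n{cal.to_string(index=False)}")


if __name__ == "__main__":
    main()
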