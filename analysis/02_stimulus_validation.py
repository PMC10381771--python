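"""Norming analytics: hit rates, proportion index, confusions, selection.

Converts every stimulus's hit rate to the chance-corrected proportion
index (joint response space for concealed stimuli), pools confusion
matrices per modality, summarizes the 1-5 rating scales, and applies the
selection thresholds (pi > 0.50, moderate intensity, at-least-moderate
believability -- believability waived for concealed displays).

Reads:  results/data/        Writes: results/validation/
"""

import json
from pathlib import Path

import pandas as pd

from emometrics.data import read_item_bank, read_responses
from emometrics.validation import (
    SelectionCriteria,
    StimulusStats,
    confusion_matrix,
    select_stimuli,
    stimulus_pi,
    summarize_ratings,
)

DATA, OUT = Path("results/data"), Path("results/validation")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    bank = read_item_bank(DATA / "bank.json")
    table = read_responses(DATA / "responses.csv", stimulus_index=bank.stimuli)
    ratings = summarize_ratings(table)
    ratings.per_stimulus.to_csv(OUT / "ratings_per_stimulus.csv")
    ratings.per_modality.to_csv(OUT / "ratings_per_modality.csv")

    stats, rows = [], []
    for sid, stim in sorted(bank.stimuli.items()):
        per = ratings.per_stimulus
        pi = stimulus_pi(table, sid, n_options=bank.keys[sid].n_options)
        mi = float(per.loc[sid, "intensity_mean"]) if sid in per.index else None
        mb = float(per.loc[sid, "believability_mean"]) if sid in per.index else None
        stats.append(StimulusStats(sid, stim.modality, pi, mi, mb))
        rows.append({"stimulus_id": sid, "modality": stim.modality, "pi": pi,
                     "mean_intensity": mi, "mean_believability": mb})
    report = pd.DataFrame(rows).set_index("stimulus_id")
    report.to_csv(OUT / "stimulus_report.csv")

    sel = select_stimuli(stats, SelectionCriteria())
    (OUT / "selection.json").write_text(
        json.dumps({"accepted": sel.accepted, "rejected": sel.rejected,
                    "reasons": sel.reasons}, indent=1)
    )
    for mod in sorted({s.modality for s in bank.stimuli.values()}):
        cm = confusion_matrix(table, mod)
        cm.pi_frame().to_csv(OUT / f"confusion_{mod}_pi.csv")
        cm.raw_frame().to_csv(OUT / f"confusion_{mod}_raw.csv")

    by_mod = report.groupby("modality")["pi"].agg(["mean", "std"])
    print("mean pi by modality (joint-k for concealed):")
    print(by_mod.round(3).to_string())
    print(f"accepted {len(sel.accepted)} / {len(stats)} stimuli under default criteria")


if __name__ == "__main__":
    main()
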