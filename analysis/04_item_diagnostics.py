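"""Item diagnostics, reliability, culling, and balanced final selection.

Per item: prior-weighted scalar information, factor loading, summed-score
fit chi-square with the chi-square/df >= 3 poor-fit rule.  Per modality:
Cronbach's alpha, McDonald's omega, the two-of-three culling rule
(misfit / loading < 0.30 / below-pool-mean information), and a greedy
information-maximizing final selection balanced over valence-activation
quadrant x actor gender x actor race.

Reads:  results/data, results/calibration     Writes: results/diagnostics/
"""

import json
from pathlib import Path

import pandas as pd

from emometrics.data import MISSING, GradedMatrix, read_item_bank
from emometrics.diagnostics import (
    compute_diagnostics,
    cull_items,
    reliability,
    select_balanced_final,
)
from emometrics.grm import read_grm_fit
from emometrics.simulate import VALENCE_ACTIVATION

DATA, CAL, OUT = Path("results/data"), Path("results/calibration"), Path("results/diagnostics")


def load_matrix() -> GradedMatrix:
    import numpy as np

    df = pd.read_csv(CAL / "graded_matrix.csv", index_col=0)
    arr = df.to_numpy(dtype=float)
    scores = np.where(np.isnan(arr), MISSING, arr).astype(int)
    return GradedMatrix(
        participant_ids=[str(i) for i in df.index],
        item_ids=list(df.columns),
        scores=scores,
        m_per_item=scores.max(axis=0) + 1,
    )


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    bank = read_item_bank(DATA / "bank.json")
    matrix = load_matrix()
    for mod in ("nonverbal", "verbal", "concealed"):
        fit = read_grm_fit(CAL / f"fit_{mod}.json")
        sub = matrix.subset_items(fit.item_ids)
        diags = compute_diagnostics(sub, fit)
        table = pd.DataFrame(
            [
                {
                    "Item Name": d.item_id,
                    "Item Information": d.scalar_information,
                    "Factor Loadings": d.loading,
                    "chisq": d.fit_chisq,
                    "d.f.": d.fit_df,
                    "p": d.fit_p,
                    "chisq/d.f.": d.chisq_df_ratio,
                }
                for d in diags
            ]
        ).set_index("Item Name")
        table.to_csv(OUT / f"items_{mod}.csv")
        cull = cull_items(diags)
        rel = reliability(sub, fit)
        by_id = {d.item_id: d for d in diags}
        meta = pd.DataFrame(
            [
                {
                    "item_id": iid,
                    "scalar_information": by_id[iid].scalar_information,
                    "valence_activation": VALENCE_ACTIVATION.get(
                        bank.stimuli[iid].target_emotion
                        or bank.stimuli[iid].displayed_emotion,
                        "other",
                    ),
                    "actor_gender": bank.stimuli[iid].actor_gender,
                    "actor_race": bank.stimuli[iid].actor_race,
                }
                for iid in cull.retained
            ]
        ).set_index("item_id")
        n_final = max(2, int(0.6 * len(cull.retained)))
        balanced = select_balanced_final(meta, None, n_final=n_final)
        (OUT / f"summary_{mod}.json").write_text(
            json.dumps(
                {
                    "alpha": rel.alpha,
                    "omega": rel.omega,
                    "n_candidates": len(diags),
                    "retained_after_cull": cull.retained,
                    "culled": cull.reasons,
                    "final_selection": balanced.selected,
                },
                indent=1,
            )
        )
        print(
            f"{mod}: {len(diags)} candidates -> {len(cull.retained)} retained "
            f"-> {len(balanced.selected)} selected; alpha={rel.alpha:.2f}, "
            f"omega={rel.omega:.2f}"
        )


if __name__ == "__main__":
    main()
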