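"""Simulate the synthetic norming cohort every later step consumes.

Generates a demographically crossed respondent pool (4 race groups x 2
genders, 50 per cell at this desk scale), a 64-item bank (31 nonverbal,
20 verbal, 13 concealed), sparse random assignment of 16/12/4 items per
respondent, latent-trait-driven choices, and 1-5 rating scales -- with the
generating item parameters saved as ground truth.

Writes: results/data/{responses.csv, bank.json, truth.json, theta.csv}
"""

import json
from pathlib import Path

import pandas as pd

from emometrics.data import write_item_bank, write_responses
from emometrics.simulate import SimulationSpec, simulate_study

OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = SimulationSpec(n_per_cell=50)  # default structure, desk-scale n
    study = simulate_study(spec)
    write_responses(study.table, OUT / "responses.csv")
    write_item_bank(study.bank, OUT / "bank.json")
    (OUT / "truth.json").write_text(
        json.dumps(
            {
                sid: {"a": p.a, "b": list(map(float, p.b)), "m": p.m}
                for sid, p in study.true_params.items()
            },
            indent=1,
        )
    )
    pd.DataFrame(
        {"participant_id": study.true_scores.participant_ids, "theta": study.theta}
    ).to_csv(OUT / "theta.csv", index=False)
    n_part = len(study.table.participants())
    print(f"simulated {n_part} respondents, {len(study.bank)} stimuli, "
          f"{len(study.table)} judgements (seed {spec.seed})")


if __name__ == "__main__":
    main()
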