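"""Simulate the study cohort: a 2,000-person two-day recall survey.

Generates a synthetic NHANES-like cohort (episodic dairy, skewed intakes,
weekend/sequence effects, lognormal survey weights, ~50% supplement users),
applies the standard exclusions (pregnancy/lactation, breast-milk consumers,
unreliable recalls), and writes the retained recall file that the later
stages consume.
"""

import sys
from pathlib import Path

import numpy as np

from dairyshift.data_model import apply_exclusions
from dairyshift.io import write_recalls
from dairyshift.synthetic import CohortConfig, generate_cohort

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20100


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = CohortConfig(n_participants=2000, seed=SEED)
    participants, days = generate_cohort(cfg)
    kept, removed = apply_exclusions(participants)
    kept_ids = {p.id for p in kept}
    days = [d for d in days if d.participant_id in kept_ids]
    write_recalls(kept, days, OUT / "cohort.csv")

    w = np.array([p.sample_weight for p in kept])
    dairy = np.array([d.dairy_total for d in days])
    print(f"generated {len(participants)} participants, retained {len(kept)} "
          f"after exclusions {removed}")
    print(f"zero-dairy days: {100 * np.mean(dairy == 0):.1f} % "
          f"(episodic consumption)")
    print(f"mean dairy: {dairy.mean():.2f} cup-eq/day; "
          f"weight dispersion cv={w.std() / w.mean():.2f}")
    print(f"wrote {OUT / 'cohort.csv'}")


if __name__ == "__main__":
    main()
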