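"""Paired-posterior probabilities of change between periods.

Reads the posterior draws written by stages 03–05 and reports, for every
comparable quantity, P(2005–2012 value > 1990–2002 value): each prey's
contribution per predator (forage fish matched across its two period
labels), each predator's SEA_B, and the six community metrics. Writes
results/probabilities.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from isoshift.community import METRIC_NAMES
from isoshift.compare import probability_greater
from isoshift.simulate import (
    FORAGE_FISH_SOURCE,
    PERIOD_EARLY,
    PERIOD_LATE,
    PREDATOR_SOURCE_SETS,
)


def _slug(species: str, period: str) -> str:
    return f"{species}_{period}".replace(" ", "_").replace("/", "-").replace("–", "-")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    res = args.results
    out: dict[str, dict] = {"mixing": {}, "sea_b": {}, "community": {}}

    for species, labels in PREDATOR_SOURCE_SETS.items():
        early = pd.read_csv(res / "mixing" / f"draws_{_slug(species, PERIOD_EARLY)}.csv")
        late = pd.read_csv(res / "mixing" / f"draws_{_slug(species, PERIOD_LATE)}.csv")
        out["mixing"][species] = {}
        for label in labels:
            col_a = FORAGE_FISH_SOURCE[PERIOD_EARLY] if label == "forage fish" else label
            col_b = FORAGE_FISH_SOURCE[PERIOD_LATE] if label == "forage fish" else label
            dp = probability_greater(
                late[col_b].to_numpy(), early[col_a].to_numpy(), f"{species}:{label}"
            )
            out["mixing"][species][label] = dp.probability
            print(f"diet  {species:18s} {label:18s} P(late>early) = {dp.probability:.2f}")
        a = pd.read_csv(res / "ellipse" / f"draws_{_slug(species, PERIOD_EARLY)}.csv")
        b = pd.read_csv(res / "ellipse" / f"draws_{_slug(species, PERIOD_LATE)}.csv")
        dp = probability_greater(b["sea_b"].to_numpy(), a["sea_b"].to_numpy(), species)
        out["sea_b"][species] = dp.probability
        print(f"SEA_B {species:18s} {'':18s} P(late>early) = {dp.probability:.2f}")

    ca = pd.read_csv(res / "community" / f"draws_{PERIOD_EARLY.replace('–', '-')}.csv")
    cb = pd.read_csv(res / "community" / f"draws_{PERIOD_LATE.replace('–', '-')}.csv")
    for metric in METRIC_NAMES:
        dp = probability_greater(cb[metric].to_numpy(), ca[metric].to_numpy(), metric)
        out["community"][metric] = dp.probability
        print(f"comm  {metric:18s} {'':18s} P(late>early) = {dp.probability:.2f}")

    path = res / "probabilities.json"
    path.write_text(json.dumps(out, indent=2, ensure_ascii=False) + "\n", encoding="utf-8")
    print(f"probabilities -> {path}")


if __name__ == "__main__":
    main()
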