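"""Mixing-polygon outlier screen for every predator group.

For each species and period, simulates 1500 source polygons (vertices
drawn from the DTDF-corrected source distributions) and reports each
consumer's inclusion probability. Consumers below 0.05 are flagged as
statistical outliers. Groups that sit largely outside their polygon (the
halibut groups do: their d13C lies below every corrected source, which the
mixing model's residual term must absorb) are reported but not destroyed.
"""

import argparse
from pathlib import Path

from isoshift.data import BUILTIN_DTDFS, group_from_samples, read_isotope_csv
from isoshift.mixing import MixingProblem
from isoshift.pipeline import read_source_csv
from isoshift.polygon import filter_outliers, simulate_polygons, PolygonScreenError
from isoshift.simulate import FORAGE_FISH_SOURCE, PREDATOR_SOURCE_SETS, PREDATOR_TABLE


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/screen"))
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    samples = read_isotope_csv(args.data / "consumers.csv")
    sources = read_source_csv(args.data / "sources.csv")
    taxa = {sp: tax for (sp, _), (_, _, _, tax) in PREDATOR_TABLE.items()}

    by_key: dict[tuple[str, str], list] = {}
    for s in samples:
        by_key.setdefault((s.species, s.period), []).append(s)

    for i, ((species, period), ss) in enumerate(sorted(by_key.items())):
        group = group_from_samples(ss, BUILTIN_DTDFS[taxa[species]])
        by_name = {s.name: s for s in sources[period]}
        srcs = tuple(
            by_name[FORAGE_FISH_SOURCE[period] if lbl == "forage fish" else lbl]
            for lbl in PREDATOR_SOURCE_SETS[species]
        )
        res = simulate_polygons(
            MixingProblem(group, srcs, group.dtdf), 1500, seed=args.seed + i
        )
        try:
            _, report = filter_outliers(res, 0.05)
        except PolygonScreenError:
            _, report = filter_outliers(res, 0.0)
            report["kept"] = res.probabilities >= 0.05
        removed = int((~report["kept"]).sum())
        slug = f"{species}_{period}".replace(" ", "_").replace("/", "-").replace("–", "-")
        report.to_csv(args.out / f"screen_{slug}.csv", index=False)
        print(
            f"{species:18s} [{period}]: {removed}/{len(report)} flagged "
            f"(min inclusion {res.probabilities.min():.2f})"
        )
    print(f"reports -> {args.out}")


if __name__ == "__main__":
    main()
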