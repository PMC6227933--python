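"""Fit the Bayesian mixing model for every predator group.

Estimates posterior diet proportions (squid / shrimp / forage fish, plus
Greenland halibut as prey for the marine mammals) per species per period,
and writes the retained draws and whole-percent summaries under
results/mixing/. The default chain is scaled down but retains 2000 draws,
the published posterior size; --full runs the published 500k/300k/100
settings (minutes per group).
"""

import argparse
from pathlib import Path

import pandas as pd

from isoshift.data import BUILTIN_DTDFS, group_from_samples, read_isotope_csv
from isoshift.mixing import (
    DEFAULT_MIXING_SETTINGS,
    McmcSettings,
    MixingProblem,
    fit_mixing_model,
    posterior_summary,
)
from isoshift.pipeline import read_source_csv
from isoshift.simulate import FORAGE_FISH_SOURCE, PREDATOR_SOURCE_SETS, PREDATOR_TABLE


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/mixing"))
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--full", action="store_true", help="published chain settings")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    base = (
        DEFAULT_MIXING_SETTINGS
        if args.full
        else McmcSettings(iterations=100_000, burn_in=40_000, thin=30)
    )
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
        settings = McmcSettings(base.iterations, base.burn_in, base.thin, args.seed + i)
        post = fit_mixing_model(MixingProblem(group, srcs, group.dtdf), settings)
        summ = posterior_summary(post, digits=0)
        slug = f"{species}_{period}".replace(" ", "_").replace("/", "-").replace("–", "-")
        pd.DataFrame(post.draws, columns=post.source_names).to_csv(
            args.out / f"draws_{slug}.csv", index=False
        )
        summ.to_csv(args.out / f"summary_{slug}.csv", index=False)
        pretty = "; ".join(
            f"{r.source} {r.median_pct} ({r.lo_pct}–{r.hi_pct})" for r in summ.itertuples()
        )
        print(f"{species:18s} [{period}]: {pretty}")
    print(f"draws and summaries -> {args.out}")


if __name__ == "__main__":
    main()
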