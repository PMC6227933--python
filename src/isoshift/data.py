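"""Core data model for paired carbon/nitrogen stable-isotope measurements.

Everything downstream works on three kinds of objects: individual consumer
measurements (:class:`IsotopeSample`), prey end-members summarized as
bivariate means and standard deviations (:class:`SourceDistribution`), and
diet-to-tissue discrimination factors (:class:`DiscriminationFactor`) that
shift prey values onto the consumer-tissue scale.

Isotope values are per-mil (permil) delta values: d13C relative to PDB
carbonate and d15N relative to atmospheric N2. All values are assumed
lipid-corrected as given; no lipid-normalization arithmetic is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IsotopeSample",
    "SourceDistribution",
    "DiscriminationFactor",
    "ConsumerGroup",
    "GroupSummary",
    "IsotopeDataError",
    "FormatError",
    "ParseError",
    "InsufficientDataError",
    "BUILTIN_DTDFS",
    "PHOCID_DTDF",
    "CETACEAN_DTDF",
    "FISH_DTDF",
    "delta_from_ratio",
    "read_isotope_csv",
    "write_isotope_csv",
    "summarize_group",
    "source_from_samples",
    "group_from_samples",
]


class IsotopeDataError(Exception):
    """Base class for data-layer errors."""


class FormatError(IsotopeDataError):
    """A file does not have the expected structure (e.g. missing column)."""


class ParseError(IsotopeDataError):
    """A cell could not be interpreted as a number."""


class InsufficientDataError(IsotopeDataError):
    """Too few samples for the requested statistic or fit."""


@dataclass(frozen=True)
class IsotopeSample:
    """One individual's paired d13C/d15N measurement with its labels.

    Period labels are opaque strings ("1990–2002" is configuration, not
    something the pipeline parses years out of).
    """

    species: str
    period: str
    d13c: float
    d15n: float

    def __post_init__(self) -> None:
        if not self.species or not self.period:
            raise ValueError("species and period labels must be non-empty")
        if not (np.isfinite(self.d13c) and np.isfinite(self.d15n)):
            raise ValueError("isotope values must be finite")


@dataclass(frozen=True)
class SourceDistribution:
    """A prey end-member: per-isotope mean and SD (permil) plus sample size.

    ``mean`` and ``sd`` are length-2 in (d13C, d15N) order. A zero SD is
    accepted (point source) but clamped to 1e-6 permil inside likelihoods.
    """

    name: str
    mean: tuple[float, float]
    sd: tuple[float, float]
    n: int = 0

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("source name must be non-empty")
        m = np.asarray(self.mean, dtype=float)
        s = np.asarray(self.sd, dtype=float)
        if m.shape != (2,) or s.shape != (2,):
            raise ValueError("mean and sd must be 2-vectors (d13C, d15N)")
        if np.any(s < 0):
            raise ValueError("source sd must be non-negative")
        object.__setattr__(self, "mean", (float(m[0]), float(m[1])))
        object.__setattr__(self, "sd", (float(s[0]), float(s[1])))

    @property
    def mean_arr(self) -> np.ndarray:
        return np.asarray(self.mean, dtype=float)

    @property
    def sd_arr(self) -> np.ndarray:
        return np.asarray(self.sd, dtype=float)


@dataclass(frozen=True)
class DiscriminationFactor:
    """Diet-to-tissue discrimination: (Delta13C, Delta15N) mean and SD."""

    taxon: str
    mean: tuple[float, float]
    sd: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        m = np.asarray(self.mean, dtype=float)
        s = np.asarray(self.sd, dtype=float)
        if m.shape != (2,) or s.shape != (2,):
            raise ValueError("mean and sd must be 2-vectors")
        if np.any(s < 0):
            raise ValueError("DTDF sd must be non-negative")
        object.__setattr__(self, "mean", (float(m[0]), float(m[1])))
        object.__setattr__(self, "sd", (float(s[0]), float(s[1])))

    @property
    def mean_arr(self) -> np.ndarray:
        return np.asarray(self.mean, dtype=float)

    @property
    def sd_arr(self) -> np.ndarray:
        return np.asarray(self.sd, dtype=float)


#: Muscle-tissue discrimination factors for the consumer taxa handled here.
#: Phocid and cetacean values are literature constants for seal and whale
#: muscle; the fish value comes from meta-analytic regressions of fish muscle
#: versus diet. All carry a 0.2 permil SD on both isotopes.
PHOCID_DTDF = DiscriminationFactor("phocid", (1.3, 2.4), (0.2, 0.2))
CETACEAN_DTDF = DiscriminationFactor("cetacean", (1.3, 1.2), (0.2, 0.2))
FISH_DTDF = DiscriminationFactor("fish", (1.2, 2.1), (0.2, 0.2))

BUILTIN_DTDFS: dict[str, DiscriminationFactor] = {
    "phocid": PHOCID_DTDF,
    "cetacean": CETACEAN_DTDF,
    "fish": FISH_DTDF,
}


@dataclass(frozen=True)
class ConsumerGroup:
    """All samples of one species in one period, plus the taxon DTDF."""

    species: str
    period: str
    samples: tuple[IsotopeSample, ...]
    dtdf: DiscriminationFactor

    def __post_init__(self) -> None:
        samples = tuple(self.samples)
        object.__setattr__(self, "samples", samples)
        for s in samples:
            if s.species != self.species or s.period != self.period:
                raise ValueError(
                    f"sample labelled ({s.species!r}, {s.period!r}) does not "
                    f"belong to group ({self.species!r}, {self.period!r})"
                )

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of (d13C, d15N) values."""
        return np.array([[s.d13c, s.d15n] for s in self.samples], dtype=float)

    def dtdf_corrected(self) -> "ConsumerGroup":
        """Subtract the taxon DTDF mean from every individual.

        Places consumer values on the prey-equivalent scale, as required
        before community-level trophic-structure analysis.
        """
        lam = self.dtdf.mean_arr
        corrected = tuple(
            replace(s, d13c=s.d13c - lam[0], d15n=s.d15n - lam[1])
            for s in self.samples
        )
        return replace(self, samples=corrected)


def group_from_samples(
    samples: Iterable[IsotopeSample], dtdf: DiscriminationFactor
) -> ConsumerGroup:
    """Build a ConsumerGroup from samples that share species and period."""
    samples = tuple(samples)
    if not samples:
        raise InsufficientDataError("cannot build a group from zero samples")
    return ConsumerGroup(samples[0].species, samples[0].period, samples, dtdf)


def delta_from_ratio(r_sample: float, r_standard: float) -> float:
    """Delta notation: ((Rsample/Rstandard) - 1) * 1e3, in permil.

    Both ratios must be strictly positive.
    """
    if r_sample <= 0 or r_standard <= 0:
        raise ValueError("isotope ratios must be strictly positive")
    return (r_sample / r_standard - 1.0) * 1e3


_REQUIRED_COLUMNS = ("species", "period", "d13c", "d15n")


def _resolve_columns(columns: Sequence[str]) -> dict[str, str]:
    lookup = {str(c).strip().lower(): c for c in columns}
    resolved = {}
    for want in _REQUIRED_COLUMNS:
        if want not in lookup:
            raise FormatError(f"missing required column: {want}")
        resolved[want] = lookup[want]
    return resolved


def read_isotope_csv(path: str | Path) -> list[IsotopeSample]:
    """Read samples from a comma-delimited UTF-8 CSV.

    Required header columns (case-insensitive): species, period, d13C, d15N.
    Rows where an isotope cell is empty are dropped with a warning; a cell
    that is present but not numeric raises :class:`ParseError` naming the
    row. Returned samples preserve file order.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    cols = _resolve_columns(df.columns)
    out: list[IsotopeSample] = []
    n_dropped = 0
    for idx, row in df.iterrows():
        raw13 = row[cols["d13c"]].strip()
        raw15 = row[cols["d15n"]].strip()
        if raw13 == "" or raw15 == "":
            n_dropped += 1
            continue
        try:
            d13c, d15n = float(raw13), float(raw15)
        except ValueError as exc:
            # +2: header line plus 1-based numbering
            raise ParseError(
                f"non-numeric isotope value in row {int(idx) + 2} of {path}"
            ) from exc
        out.append(
            IsotopeSample(row[cols["species"]], row[cols["period"]], d13c, d15n)
        )
    if n_dropped:
        warnings.warn(
            f"{path}: dropped {n_dropped} row(s) with missing isotope values",
            stacklevel=2,
        )
    return out


def write_isotope_csv(samples: Iterable[IsotopeSample], path: str | Path) -> None:
    """Write samples as CSV readable by :func:`read_isotope_csv`."""
    df = pd.DataFrame(
        [(s.species, s.period, s.d13c, s.d15n) for s in samples],
        columns=["species", "period", "d13C", "d15N"],
    )
    df.to_csv(path, index=False, encoding="utf-8")


@dataclass(frozen=True)
class GroupSummary:
    """Per-isotope descriptive statistics for one consumer group.

    ``mean``/``sd``/``range`` are (d13C, d15N) tuples; ``sd`` uses the n-1
    denominator and ``range`` is max - min of the individual values.
    """

    species: str
    period: str
    n: int
    mean: tuple[float, float]
    sd: tuple[float, float]
    range: tuple[float, float]


def summarize_group(group: ConsumerGroup) -> GroupSummary:
    """Mean, SD (n-1), n and individual range per isotope for a group."""
    if len(group) < 2:
        raise InsufficientDataError(
            f"group ({group.species!r}, {group.period!r}) has {len(group)} "
            "sample(s); need at least 2"
        )
    xy = group.xy
    mean = xy.mean(axis=0)
    sd = xy.std(axis=0, ddof=1)
    rng = xy.max(axis=0) - xy.min(axis=0)
    return GroupSummary(
        species=group.species,
        period=group.period,
        n=len(group),
        mean=(float(mean[0]), float(mean[1])),
        sd=(float(sd[0]), float(sd[1])),
        range=(float(rng[0]), float(rng[1])),
    )


def source_from_samples(
    samples: Sequence[IsotopeSample], name: str
) -> SourceDistribution:
    """Summarize raw prey samples into a SourceDistribution (SD uses n-1)."""
    if len(samples) < 2:
        raise InsufficientDataError(
            f"source {name!r}: need at least 2 samples, got {len(samples)}"
        )
    xy = np.array([[s.d13c, s.d15n] for s in samples], dtype=float)
    mean = xy.mean(axis=0)
    sd = xy.std(axis=0, ddof=1)
    if np.any(sd == 0):
        warnings.warn(
            f"source {name!r} has zero SD on at least one isotope; it will be "
            "treated as a (near-)point source in likelihoods",
            stacklevel=2,
        )
    return SourceDistribution(
        name, (float(mean[0]), float(mean[1])), (float(sd[0]), float(sd[1])), len(samples)
    )
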