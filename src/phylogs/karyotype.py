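"""Karyotype asymmetry metrics from per-chromosome arm measurements.

Metrics computed on the haploid complement of ``x`` chromosomes:

* **HCL** — haploid chromosome length, the summed length of the complement.
* **AsK%** — karyotype asymmetry index: sum of long-arm lengths over HCL x 100.
  Ranges from 50 (all metacentric) to 100 (all telocentric).
* **CI** — centromeric index per chromosome: short arm over total length x 100,
  in (0, 50] by the long >= short convention.
* **CV_CL** — coefficient of variation of chromosome lengths (interchromosomal
  asymmetry), in percent.
* **CV_CI** — coefficient of variation of centromeric indices (intrachromosomal
  asymmetry), in percent.

Coefficients of variation use the sample standard deviation (n-1 denominator)
by default; a population-SD mode is available for cross-checks.  All metrics
are invariant under uniform rescaling of arm lengths, so measurement units
(micrometres or relative lengths) do not matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KaryotypeError",
    "Karyotype",
    "KaryotypeMetrics",
    "normalize_karyotype",
    "haploid_complement_length",
    "ask_percent",
    "centromeric_index",
    "cv_cl",
    "cv_ci",
    "summarize_karyotype",
    "read_karyotype_table",
    "write_metrics_table",
]


class KaryotypeError(ValueError):
    """Raised for inconsistent chromosome measurements."""


@dataclass
class Karyotype:
    """A haploid chromosome complement with arm lengths.

    ``chromosomes`` holds ``x`` (short_arm, long_arm) pairs with
    ``long_arm >= short_arm >= 0`` and at least one positive arm each;
    ``two_n = x * ploidy`` is the somatic chromosome count.
    """

    species: str
    chromosomes: list[tuple[float, float]]
    x: int
    ploidy: int = 2

    def __post_init__(self) -> None:
        if self.x < 1 or self.ploidy < 1:
            raise KaryotypeError("x and ploidy must be positive integers")
        if len(self.chromosomes) != self.x:
            raise KaryotypeError(
                f"{self.species or 'karyotype'}: expected x={self.x} chromosomes, "
                f"got {len(self.chromosomes)}"
            )
        for short, long in self.chromosomes:
            if short < 0 or long < 0:
                raise KaryotypeError("negative arm length")
            if short + long <= 0:
                raise KaryotypeError("chromosome with both arms zero")
            if long < short:
                raise KaryotypeError(
                    "long arm shorter than short arm; use normalize_karyotype"
                )

    @property
    def two_n(self) -> int:
        return self.x * self.ploidy

    def total_lengths(self) -> np.ndarray:
        return np.array([s + l for s, l in self.chromosomes])


@dataclass
class KaryotypeMetrics:
    """Bundle of the asymmetry metrics for one species."""

    species: str
    hcl: float
    ask_percent: float
    cv_ci: float
    cv_cl: float
    ci_values: list[float] = field(default_factory=list)
    x: int = 12
    ploidy: int = 2

    @property
    def two_n(self) -> int:
        return self.x * self.ploidy


def normalize_karyotype(
    raw: Sequence[tuple[float, float]],
    x: int,
    ploidy: int = 2,
    species: str = "",
) -> Karyotype:
    """Build a validated haploid :class:`Karyotype` from raw arm measurements.

    Arms are swapped where needed so ``long >= short``, and chromosomes are
    arranged by decreasing short-arm length then decreasing total length.
    Raw tables may list either the haploid complement (``x`` rows) or the
    full somatic complement (``x * ploidy`` rows); in the latter case
    homologous chromosomes are collapsed to one representative per group by
    averaging, after sorting by total length.
    """
    if not raw:
        raise KaryotypeError("empty measurement list")
    arms = []
    for short, long in raw:
        if short < 0 or long < 0:
            raise KaryotypeError(f"negative arm length in {species or 'input'}")
        if long < short:
            short, long = long, short
        arms.append((float(short), float(long)))

    if len(arms) == x * ploidy and ploidy > 1:
        # somatic complement: group homologs by size rank and average
        arms.sort(key=lambda a: -(a[0] + a[1]))
        collapsed = []
        for g in range(x):
            grp = arms[g * ploidy : (g + 1) * ploidy]
            collapsed.append(
                (
                    float(np.mean([a[0] for a in grp])),
                    float(np.mean([a[1] for a in grp])),
                )
            )
        arms = collapsed
    elif len(arms) != x:
        raise KaryotypeError(
            f"{species or 'karyotype'}: {len(arms)} chromosomes do not match "
            f"x={x} (haploid) or x*ploidy={x * ploidy} (somatic)"
        )

    arms.sort(key=lambda a: (-a[0], -(a[0] + a[1])))
    return Karyotype(species=species, chromosomes=arms, x=x, ploidy=ploidy)


def haploid_complement_length(k: Karyotype) -> float:
    """HCL: total length of the haploid complement (sum of short + long arms)."""
    return float(k.total_lengths().sum())


def ask_percent(k: Karyotype) -> float:
    """Karyotype asymmetry index: long-arm length over total complement length x 100."""
    hcl = haploid_complement_length(k)
    if hcl <= 0:
        raise KaryotypeError("HCL is zero")
    long_sum = sum(l for _, l in k.chromosomes)
    return 100.0 * long_sum / hcl


def centromeric_index(short: float, long: float) -> float:
    """Centromeric index: short-arm length over chromosome length x 100."""
    total = short + long
    if total <= 0:
        raise KaryotypeError("chromosome of zero length")
    return 100.0 * short / total


def _cv(values: np.ndarray, population: bool) -> float:
    mean = values.mean()
    if mean == 0:
        raise KaryotypeError("zero mean in CV computation")
    sd = values.std(ddof=0 if population else 1)
    return float(100.0 * sd / mean)


def cv_cl(k: Karyotype, population: bool = False) -> float:
    """Coefficient of variation of chromosome lengths (interchromosomal asymmetry)."""
    lengths = k.total_lengths()
    if len(lengths) < 2:
        raise KaryotypeError("CV requires at least two chromosomes")
    return _cv(lengths, population)


def cv_ci(k: Karyotype, population: bool = False) -> float:
    """Coefficient of variation of centromeric indices (intrachromosomal asymmetry)."""
    if len(k.chromosomes) < 2:
        raise KaryotypeError("CV requires at least two chromosomes")
    cis = np.array([centromeric_index(s, l) for s, l in k.chromosomes])
    return _cv(cis, population)


def summarize_karyotype(k: Karyotype, population: bool = False) -> KaryotypeMetrics:
    """Compute the full karyotype data matrix row for one species."""
    return KaryotypeMetrics(
        species=k.species,
        hcl=haploid_complement_length(k),
        ask_percent=ask_percent(k),
        cv_ci=cv_ci(k, population=population),
        cv_cl=cv_cl(k, population=population),
        ci_values=[centromeric_index(s, l) for s, l in k.chromosomes],
        x=k.x,
        ploidy=k.ploidy,
    )


def read_karyotype_table(path: str | Path) -> dict[str, Karyotype]:
    """Read a long-format arm-measurement TSV into per-species karyotypes.

    Required columns: species, chromosome_id, short_arm_um, long_arm_um, x,
    ploidy.  Measurements are normalized (arm order, homolog averaging) on
    the way in.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"species", "chromosome_id", "short_arm_um", "long_arm_um", "x", "ploidy"}
    missing = required - set(df.columns)
    if missing:
        raise KaryotypeError(f"karyotype table missing columns: {sorted(missing)}")
    out: dict[str, Karyotype] = {}
    for species, grp in df.groupby("species", sort=False):
        x_vals = grp["x"].unique()
        p_vals = grp["ploidy"].unique()
        if len(x_vals) != 1 or len(p_vals) != 1:
            raise KaryotypeError(f"{species}: inconsistent x/ploidy across rows")
        raw = list(zip(grp["short_arm_um"], grp["long_arm_um"]))
        out[str(species)] = normalize_karyotype(
            raw, x=int(x_vals[0]), ploidy=int(p_vals[0]), species=str(species)
        )
    return out


def write_metrics_table(metrics: Sequence[KaryotypeMetrics], path: str | Path) -> pd.DataFrame:
    """Write the karyotype data matrix TSV (values reported at 4 decimals)."""
    df = pd.DataFrame(
        {
            "species": [m.species for m in metrics],
            "HCL": [round(m.hcl, 4) for m in metrics],
            "AsK_pct": [round(m.ask_percent, 4) for m in metrics],
            "CV_CI": [round(m.cv_ci, 4) for m in metrics],
            "CV_CL": [round(m.cv_cl, 4) for m in metrics],
            "x": [m.x for m in metrics],
            "two_n": [m.two_n for m in metrics],
            "ploidy": [m.ploidy for m in metrics],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return df
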