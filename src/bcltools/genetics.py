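"""Single-locus genetics of berry color.

Mendelian segregation of the black/white phenotype (3:1 goodness of fit),
allele-frequency tabulation across germplasm collections, marker x
phenotype contingency, the dosage effect of functional BCL haplotypes on
wine anthocyanin content, and aggregation of the HapF1 survey in wild
*V. sylvestris* populations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def round_half_up(x: float, digits: int = 0) -> float:
    """Half-up rounding as used in printed percentage tables (banker's
    rounding would turn 6.5% into 6%)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Segregation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegregationResult:
    observed: tuple[int, int]          # (dominant, recessive)
    expected_ratio: tuple[float, float]
    chi_square: float
    p_value: float
    df: int = 1


def segregation_test(n_dominant: int, n_recessive: int,
                     ratio: tuple[float, float] = (3, 1)) -> SegregationResult:
    """Pearson goodness of fit to a Mendelian ratio, no continuity
    correction, df = 1."""
    if n_dominant < 0 or n_recessive < 0:
        raise ValueError("counts must be non-negative")
    total = n_dominant + n_recessive
    if total == 0:
        raise ValueError("total count must be positive")
    r = np.asarray(ratio, float)
    expected = r / r.sum() * total
    chi2, p = stats.chisquare([n_dominant, n_recessive], expected)
    return SegregationResult((n_dominant, n_recessive),
                             (float(ratio[0]), float(ratio[1])),
                             float(chi2), float(p))


# ---------------------------------------------------------------------------
# Allele frequency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlleleFrequencyResult:
    carriers: int
    population: int
    copies_per_carrier: int
    percent_exact: float
    percent: int  # printed report: integer, half-up


def allele_frequency(carriers: int, population: int,
                     copies_per_carrier: int = 1) -> AlleleFrequencyResult:
    """Allele frequency in a diploid population, as a percentage.

    By default each carrier is assumed heterozygous (one copy), the way
    carrier tallies from allele-typing surveys are usually reported.
    """
    if population <= 0:
        raise ValueError("population must be positive")
    if not 0 <= carriers <= population:
        raise ValueError("carriers must be between 0 and population")
    exact = carriers * copies_per_carrier / (2 * population) * 100.0
    return AlleleFrequencyResult(carriers, population, copies_per_carrier,
                                 exact, int(round_half_up(exact)))


# ---------------------------------------------------------------------------
# Genotype x phenotype contingency
# ---------------------------------------------------------------------------

PHENOTYPES = ("black", "light", "white")


@dataclass
class ContingencyResult:
    table: pd.DataFrame                 # marker present/absent x phenotype
    fisher_p: float                     # 2x2 collapse, black vs non-black
    perfect_separation: bool
    odds_ratio: float


def phenotype_contingency(calls: Mapping[str, bool],
                          phenotypes: Mapping[str, str]) -> ContingencyResult:
    """Marker presence against berry-skin phenotype classes.

    The exact test is Fisher's on the 2x2 collapse (black vs non-black);
    perfect separation (every black-fruited accession carries the marker
    and no marker-free accession is black) is flagged explicitly.
    """
    if set(calls) != set(phenotypes):
        raise ValueError("accession sets differ between calls and phenotypes")
    classes = [c for c in PHENOTYPES
               if c in set(phenotypes.values())] or list(PHENOTYPES)
    idx = ["present", "absent"]
    table = pd.DataFrame(0, index=idx, columns=classes)
    for acc, present in calls.items():
        ph = phenotypes[acc]
        if ph not in table.columns:
            raise ValueError(f"unknown phenotype {ph!r} for {acc!r}")
        table.loc["present" if present else "absent", ph] += 1
    black = table["black"] if "black" in table.columns else pd.Series(
        0, index=idx)
    non_black = table.sum(axis=1) - black
    two_by_two = np.array([[black["present"], non_black["present"]],
                           [black["absent"], non_black["absent"]]])
    if two_by_two.sum() <= 1:
        odds, p = np.nan, 1.0
    else:
        odds, p = stats.fisher_exact(two_by_two)
    separated = (black["absent"] == 0 and non_black["present"] == 0
                 and black["present"] > 0 and non_black["absent"] > 0)
    return ContingencyResult(table, float(p), bool(separated), float(odds))


# ---------------------------------------------------------------------------
# Haplotype dosage effect on anthocyanin content
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DosageComparison:
    mean_2copy: float      # mg/L
    mean_1copy: float      # mg/L
    percent_difference: float
    t_statistic: float
    p_value: float
    n_2copy: int
    n_1copy: int


def dosage_comparison(values_2copy: Sequence[float],
                      values_1copy: Sequence[float]) -> DosageComparison:
    """Welch two-sample comparison of anthocyanin content (mg/L) between
    genotypes with two functional haplotypes and one.

    percent difference = (mean_2copy - mean_1copy) / mean_1copy * 100.
    """
    a = np.asarray(values_2copy, float)
    b = np.asarray(values_1copy, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    pct = (a.mean() - b.mean()) / b.mean() * 100.0
    return DosageComparison(float(a.mean()), float(b.mean()), float(pct),
                            float(t), float(p), len(a), len(b))


# ---------------------------------------------------------------------------
# Survey aggregation
# ---------------------------------------------------------------------------

#: HapF1 detections in wild V. sylvestris WGS datasets by sampling region
#: (region, n examined, n with HapF1 detected)
TABLE3_SYLVESTRIS: list[tuple[str, int, int]] = [
    ("Portugal", 4, 0),
    ("Spain", 20, 0),
    ("Tunisia", 2, 0),
    ("France", 10, 0),
    ("Europe", 9, 0),
    ("Switzerland", 5, 0),
    ("Germany", 5, 0),
    ("Austria", 4, 0),
    ("Italy", 40, 0),
    ("Croatia", 5, 0),
    ("Hungary", 5, 0),
    ("Bulgaria", 5, 0),
    ("Roumania", 3, 0),
    ("Turkey", 5, 0),
    ("Crimea", 10, 1),
    ("Israel", 11, 7),
    ("Iran", 10, 6),
    ("Caucasia", 6, 3),
    ("Armenia", 10, 8),
    ("Azerbaijan", 10, 6),
    ("Georgia", 10, 9),
]


@dataclass
class SurveySummary:
    table: pd.DataFrame
    total_examined: int
    total_detected: int


def aggregate_survey(rows: Sequence[tuple[str, int, int]] | pd.DataFrame
                     ) -> SurveySummary:
    """Per-region detection frequency (integer percent, half-up; regions
    with no detections are reported as 'Not detected') and grand totals."""
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
        df.columns = ["region", "n_examined", "n_detected"]
    else:
        df = pd.DataFrame(rows, columns=["region", "n_examined",
                                         "n_detected"])
    if ((df["n_detected"] < 0) | (df["n_detected"] > df["n_examined"])).any():
        raise ValueError("detections must be between 0 and examined")
    df["frequency_percent"] = [
        int(round_half_up(d / n * 100.0)) if n else 0
        for d, n in zip(df["n_detected"], df["n_examined"])]
    df["display"] = [
        f"{d} ({f}%)" if d else "Not detected"
        for d, f in zip(df["n_detected"], df["frequency_percent"])]
    return SurveySummary(df, int(df["n_examined"].sum()),
                         int(df["n_detected"].sum()))
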