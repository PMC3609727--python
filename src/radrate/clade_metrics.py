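"""Per-clade statistics: nucleotide diversity, crown-group diversification
rates, sampled-fraction species extrapolation, and the rate-diversity
correlation.

Nucleotide diversity follows Nei's estimator with pairwise deletion: a site
enters a pair's comparison only when both sequences carry an unambiguous
base there. Its variance is the total-variance expression

    Var(pi) = (n+1) / (3 (n-1) L) * pi  +  2 (n^2 + n + 3) / (9 n (n-1)) * pi^2

with L the mean number of sites compared per pair (pairwise deletion leaves
no single L; the mean is the least-surprising reduction, and a
complete-deletion mode is exposed as an alternative).

The crown-group net diversification estimator at zero relative extinction is
r = (ln n - ln 2) / t for a clade of n species with crown age t Myr.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .chronology import (
    CalibrationSpec,
    Chronogram,
    crown_age,
    propagate_calibration_ci,
    rescale_chronogram,
)
from .phylo_io import BASES, Alignment, CladeDefinition

#: Species-sampling constants of the study group: total described species
#: and the number represented in the molecular data set.
DEFAULT_TOTAL_SPECIES = 500
DEFAULT_SAMPLED_SPECIES = 169


@dataclass
class DiversityResult:
    """Nei's nucleotide diversity for one set of sequences."""

    pi: float
    var_pi: float
    n_seq: int
    L_mean: float


@dataclass
class DiversificationEstimate:
    n: int
    t: float
    epsilon: float
    rate: float


@dataclass
class CladeSummary:
    """One report row: species numbers, diversity, ages, CIs and rates."""

    name: str
    n_min: int
    n_max: int
    n_seq: int
    pi: float
    var_pi: float
    age_20: float
    dr20_min: float
    dr20_max: float
    age_25: float
    ci_25: tuple[float, float]
    dr25_min: float
    dr25_max: float
    monophyletic: bool = True


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the report convention), e.g. 2.5 -> 3, -2.5 -> -3."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pairwise_diff(seq_a: str, seq_b: str) -> tuple[int, int]:
    """Count differing and comparable sites between two aligned sequences.

    A site is comparable when both symbols are unambiguous bases (A/C/G/T);
    gaps and IUPAC ambiguity codes are excluded pairwise.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequence length mismatch: {len(seq_a)} vs {len(seq_b)}"
        )
    sites = 0
    diffs = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a in BASES and b in BASES:
            sites += 1
            if a != b:
                diffs += 1
    return diffs, sites


def _shared_columns(aln: Alignment) -> list[int]:
    """0-based columns where every sequence has an unambiguous base."""
    return [
        j
        for j in range(aln.ncol)
        if all(s[j] in BASES for s in aln.seqs)
    ]


def nucleotide_diversity(
    aln: Alignment, complete_deletion: bool = False
) -> DiversityResult:
    """Nei's nucleotide diversity and its variance over all sequence pairs.

    With ``complete_deletion`` the comparison is restricted to columns where
    every sequence carries an unambiguous base, and L is that shared count;
    otherwise deletion is pairwise and L is the mean pairwise site count.
    """
    if aln.nseq < 2:
        raise ValueError("nucleotide diversity requires at least 2 sequences")
    seqs = aln.seqs
    if complete_deletion:
        keep = _shared_columns(aln)
        seqs = ["".join(s[j] for j in keep) for s in seqs]
    dists = []
    site_counts = []
    for (la, sa), (lb, sb) in itertools.combinations(zip(aln.labels, seqs), 2):
        diffs, sites = pairwise_diff(sa, sb)
        if sites == 0:
            raise ValueError(f"no comparable sites between {la!r} and {lb!r}")
        dists.append(diffs / sites)
        site_counts.append(sites)
    pi = sum(dists) / len(dists)
    L = float(np.mean(site_counts))
    n = aln.nseq
    var_pi = ((n + 1) / (3 * (n - 1) * L)) * pi + (
        2 * (n * n + n + 3) / (9 * n * (n - 1))
    ) * pi * pi
    return DiversityResult(pi=pi, var_pi=var_pi, n_seq=n, L_mean=L)


def ms_crown_rate(n: float, t: float, epsilon: float = 0.0) -> float:
    """Crown-group net diversification rate (species per Myr) at extinction
    fraction ``epsilon``. Only ``epsilon = 0`` is implemented:
    r = (ln n - ln 2) / t."""
    if epsilon != 0.0:
        raise NotImplementedError(
            "only the zero relative-extinction estimator is implemented"
        )
    if n < 2:
        raise ValueError("crown rate undefined for fewer than 2 species")
    if t <= 0:
        raise ValueError("crown age must be > 0")
    return (math.log(n) - math.log(2.0)) / t


def ms_stem_rate(n: float, t: float) -> float:
    """Stem-group net diversification rate at zero extinction: ln(n) / t."""
    if n < 1:
        raise ValueError("stem rate requires n >= 1")
    if t <= 0:
        raise ValueError("stem age must be > 0")
    return math.log(n) / t


def extrapolate_species(
    k_clade: int,
    k_total_sampled: int = DEFAULT_SAMPLED_SPECIES,
    n_total: int = DEFAULT_TOTAL_SPECIES,
) -> int:
    """Extrapolate a clade's species richness from its sampled fraction.

    round-half-away-from-zero(k_clade * n_total / k_total_sampled), assuming
    even sampling across clades.
    """
    if k_clade < 1:
        raise ValueError("k_clade must be >= 1")
    if k_total_sampled < k_clade:
        raise ValueError("k_total_sampled must be >= k_clade")
    return int(round_half_away(k_clade * n_total / k_total_sampled, 0))


def correlate_rate_diversity(
    rates: Sequence[float], pis: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation of diversification rate against nucleotide
    diversity, with the two-sided t-test p-value."""
    x = np.asarray(rates, dtype=float)
    y = np.asarray(pis, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors differ in length")
    if len(x) < 3:
        raise ValueError("correlation requires at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def summarize_clade(
    chrono25: Chronogram,
    aln: Alignment,
    clade: CladeDefinition,
    calib: CalibrationSpec,
    alt_root_age: float = 20.0,
    complete_deletion: bool = False,
    k_total_sampled: int = DEFAULT_SAMPLED_SPECIES,
    n_total: int = DEFAULT_TOTAL_SPECIES,
) -> CladeSummary:
    """Assemble one report row for a clade.

    The crown age is read from the chronogram dated at ``calib.root_age``;
    the alternative-calibration age comes from exact linear rescaling; the
    age CI from linear propagation of the calibration interval. When the
    clade has no literature species count, its maximal species number is
    extrapolated from the sampled fraction.
    """
    clade.validate_against(chrono25)
    subtree, monophyletic = chrono25.extract_clade(clade)
    age25 = crown_age(chrono25, clade)
    scale = alt_root_age / calib.root_age
    age_alt = age25 * scale
    ci_25 = propagate_calibration_ci(age25, calib)
    clade_aln = aln.subset(sorted(clade.tips))
    div = nucleotide_diversity(clade_aln, complete_deletion=complete_deletion)
    n_max = (
        clade.n_max_known
        if clade.n_max_known is not None
        else extrapolate_species(clade.n_min, k_total_sampled, n_total)
    )
    return CladeSummary(
        name=clade.name,
        n_min=clade.n_min,
        n_max=n_max,
        n_seq=div.n_seq,
        pi=div.pi,
        var_pi=div.var_pi,
        age_20=age_alt,
        dr20_min=ms_crown_rate(clade.n_min, age_alt),
        dr20_max=ms_crown_rate(n_max, age_alt),
        age_25=age25,
        ci_25=ci_25,
        dr25_min=ms_crown_rate(clade.n_min, age25),
        dr25_max=ms_crown_rate(n_max, age25),
        monophyletic=monophyletic,
    )


def format_summary_row(s: CladeSummary) -> dict[str, str]:
    """Apply the report rounding rules (the only place rounding happens):
    2 decimals for ages and rates, 4 for pi, 6 for Var(pi)."""

    def f2(x: float) -> str:
        return f"{round_half_away(x, 2):.2f}"

    return {
        "clade": s.name,
        "n_min": str(s.n_min),
        "n_max": str(s.n_max),
        "n_seq": str(s.n_seq),
        "pi": f"{round_half_away(s.pi, 4):.4f}",
        "var_pi": f"{round_half_away(s.var_pi, 6):.6f}",
        "age_20myr": f2(s.age_20),
        "dr20_min": f2(s.dr20_min),
        "dr20_max": f2(s.dr20_max),
        "age_25myr_pl": f2(s.age_25),
        "ci_95": f"{f2(s.ci_25[0])}-{f2(s.ci_25[1])}",
        "dr25_min": f2(s.dr25_min),
        "dr25_max": f2(s.dr25_max),
    }


REPORT_COLUMNS = [
    "clade",
    "n_min",
    "n_max",
    "n_seq",
    "pi",
    "var_pi",
    "age_20myr",
    "dr20_min",
    "dr20_max",
    "age_25myr_pl",
    "ci_95",
    "dr25_min",
    "dr25_max",
]
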