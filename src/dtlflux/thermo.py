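"""Genome-streamlining statistics and proteome thermal-adaptation metrics.

Streamlined (host-dependent or hyperthermophile) genomes show high
coding density and frequent overlapping genes; proteomes adapted to
high optimal growth temperature (OGT) are enriched in the IVYWREL
residues and in charged versus polar non-charged residues (CvP-bias).
This module computes those per-genome statistics and the ordinary
least-squares comparative regressions built on them (genome size vs
gene count, OGT vs genome size, IVYWREL vs OGT).

Coding density uses the UNION of CDS intervals so it is bounded by 1
even for genomes where nearly half the genes overlap.  A gene is
"overlapping" when it shares at least one base pair with another gene,
on either strand.  Composition metrics are defined over the 20
canonical amino-acid letters; ambiguous residues (B, J, Z, X, U, O, *)
are excluded from denominators and tallied separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .simulate import SyntheticAnnotation

__all__ = [
    "GenomeStats",
    "ThermoMetrics",
    "RegressionFit",
    "genome_stats",
    "ivywrel_fraction",
    "cvp_bias",
    "aa_frequencies",
    "predict_ogt",
    "calibrate_ogt",
    "thermo_metrics",
    "linear_fit",
    "DEFAULT_OGT_COEFFICIENTS",
    "IVYWREL_SET",
    "CHARGED_SET",
    "POLAR_SET",
    "CANONICAL_AA",
]

CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
AMBIGUOUS_AA = frozenset("BJZXUO*")
IVYWREL_SET = frozenset("IVYWREL")
CHARGED_SET = frozenset("DEKR")   # histidine excluded by convention
POLAR_SET = frozenset("NQST")

# linear IVYWREL -> OGT predictor (degC = a + b * fraction); configuration,
# meant to be replaced by calibrate_ogt() on a labelled set
DEFAULT_OGT_COEFFICIENTS = (-335.0, 937.0)


@dataclass(frozen=True)
class GenomeStats:
    genome_id: str
    total_length: int
    gc: float
    coding_density: float
    overlap_fraction: float
    gene_count: int
    mean_gene_length: float


@dataclass(frozen=True)
class ThermoMetrics:
    genome_id: str
    ivywrel: float
    cvp_bias: float
    predicted_ogt: float
    residue_count: int
    rejected_residues: int = 0


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    adj_r_squared: float
    p_value: float
    n: int


# ---------------------------------------------------------------------------
# genome statistics
# ---------------------------------------------------------------------------

def _union_length(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total, cur_start, cur_end = 0, *intervals[0]
    for start, end in intervals[1:]:
        if start > cur_end:
            total += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    return total + (cur_end - cur_start)


def _overlapping_genes(intervals: list[tuple[int, int]]) -> int:
    """Number of intervals sharing >= 1 position with another interval."""
    n = len(intervals)
    order = sorted(range(n), key=lambda i: intervals[i])
    overlapping = [False] * n
    active: list[int] = []  # indices with running max end
    for idx in order:
        start, end = intervals[idx]
        active = [j for j in active if intervals[j][1] > start]
        if active:
            overlapping[idx] = True
            for j in active:
                overlapping[j] = True
        active.append(idx)
    return sum(overlapping)


def genome_stats(annotation: SyntheticAnnotation,
                 sequence: Optional[str] = None) -> GenomeStats:
    """Streamlining statistics of one genome.

    Coding density = |union of CDS intervals| / genome length.  The
    overlapping-gene fraction counts genes intersecting at least one
    other gene (strand-agnostic), divided by the gene count; both are 0
    for a geneless record.  GC is computed from ``sequence`` when
    given, else taken from the annotation metadata.
    """
    for g in annotation.genes:
        if g.end > annotation.length or g.start < 0:
            raise ValueError(
                f"gene [{g.start}, {g.end}) on {g.contig} outside contig "
                f"bounds [0, {annotation.length})")
    intervals = [(g.start, g.end) for g in annotation.genes]
    n = len(intervals)
    union = _union_length(intervals)
    density = union / annotation.length if annotation.length else 0.0
    overlap_frac = _overlapping_genes(intervals) / n if n else 0.0
    if sequence is not None:
        seq = sequence.upper()
        acgt = sum(seq.count(b) for b in "ACGT")
        gc = (seq.count("G") + seq.count("C")) / acgt if acgt else 0.0
    else:
        gc = annotation.gc
    mean_len = float(np.mean([e - s for s, e in intervals])) if n else 0.0
    return GenomeStats(
        genome_id=annotation.genome_id,
        total_length=annotation.length,
        gc=gc,
        coding_density=density,
        overlap_fraction=overlap_frac,
        gene_count=n,
        mean_gene_length=mean_len,
    )


# ---------------------------------------------------------------------------
# amino-acid composition metrics
# ---------------------------------------------------------------------------

def _residue_counts(sequences: Union[str, Iterable[str]]) -> tuple[dict[str, int], int]:
    if isinstance(sequences, str):
        sequences = [sequences]
    counts: dict[str, int] = {}
    rejected = 0
    for seq in sequences:
        for ch in seq.upper():
            if ch in CANONICAL_AA:
                counts[ch] = counts.get(ch, 0) + 1
            elif ch in AMBIGUOUS_AA:
                rejected += 1
            elif ch.isspace():
                continue
            else:
                raise ValueError(f"unexpected residue letter {ch!r}")
    return counts, rejected


def aa_frequencies(sequences: Union[str, Iterable[str]]) -> dict[str, float]:
    """Frequencies of the 20 canonical residues over a proteome."""
    counts, _ = _residue_counts(sequences)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no canonical residues in input")
    return {aa: counts.get(aa, 0) / total for aa in sorted(CANONICAL_AA)}


def ivywrel_fraction(sequences: Union[str, Iterable[str]]) -> float:
    """Fraction of I, V, Y, W, R, E, L among canonical residues.

    Order- and concatenation-invariant: any re-splitting of the same
    residues gives the same value.
    """
    counts, _ = _residue_counts(sequences)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no canonical residues in input")
    return sum(counts.get(aa, 0) for aa in IVYWREL_SET) / total


def cvp_bias(sequences: Union[str, Iterable[str]],
             charged: frozenset = CHARGED_SET,
             polar: frozenset = POLAR_SET) -> float:
    """CvP-bias in percentage points: 100*(f_DEKR - f_NQST)."""
    counts, _ = _residue_counts(sequences)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no canonical residues in input")
    f_charged = sum(counts.get(aa, 0) for aa in charged) / total
    f_polar = sum(counts.get(aa, 0) for aa in polar) / total
    return 100.0 * (f_charged - f_polar)


def predict_ogt(ivywrel: float,
                coefficients: tuple[float, float] = DEFAULT_OGT_COEFFICIENTS,
                ) -> float:
    """OGT (degC) from the IVYWREL fraction via a linear predictor."""
    a, b = coefficients
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ValueError("coefficients must be finite")
    return a + b * ivywrel


def calibrate_ogt(ivywrel_values: Sequence[float],
                  known_ogts: Sequence[float]) -> tuple[float, float]:
    """Fit (intercept, slope) of the OGT predictor on a labelled set."""
    fit = linear_fit(list(ivywrel_values), list(known_ogts))
    return fit.intercept, fit.slope


def thermo_metrics(genome_id: str, sequences: Union[str, Iterable[str]],
                   coefficients: tuple[float, float] = DEFAULT_OGT_COEFFICIENTS,
                   ) -> ThermoMetrics:
    """All composition metrics of one proteome in a single pass."""
    counts, rejected = _residue_counts(sequences)
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"proteome of {genome_id!r} has no canonical residues")
    ivy = sum(counts.get(aa, 0) for aa in IVYWREL_SET) / total
    f_charged = sum(counts.get(aa, 0) for aa in CHARGED_SET) / total
    f_polar = sum(counts.get(aa, 0) for aa in POLAR_SET) / total
    return ThermoMetrics(
        genome_id=genome_id,
        ivywrel=ivy,
        cvp_bias=100.0 * (f_charged - f_polar),
        predicted_ogt=predict_ogt(ivy, coefficients),
        residue_count=total,
        rejected_residues=rejected,
    )


# ---------------------------------------------------------------------------
# regressions
# ---------------------------------------------------------------------------

def linear_fit(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Ordinary least squares y = a + b*x with adjusted R^2.

    adj R^2 = 1 - (1 - R^2)(n - 1)/(n - 2); the slope p-value is the
    two-sided t-test of b = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: x is constant")
    if np.ptp(y) == 0:  # flat response: define R^2 = 0, not 0/0
        return RegressionFit(slope=0.0, intercept=float(y[0]), r_squared=0.0,
                             adj_r_squared=1.0 - (n - 1) / (n - 2),
                             p_value=1.0, n=n)
    res = stats.linregress(x, y)
    r2 = res.rvalue ** 2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(r2),
        adj_r_squared=float(adj),
        p_value=float(res.pvalue),
        n=n,
    )
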