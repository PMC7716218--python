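"""Mendelian segregation and allelism analysis.

Pearson chi-square goodness of fit of observed mutant/wild-type counts to a
stated integer ratio (no continuity correction), inheritance-mode inference
from F1 uniformity plus the F2 1:3 test, and complementation-test verdicts.
Decisions use the df=1 critical value 3.841 at alpha = 0.05; p-values are
reported as supplementary output.
"""
from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

CHI2_CRITICAL_DF1 = 3.841

SINGLE_RECESSIVE = "SINGLE_RECESSIVE"
UNDETERMINED = "UNDETERMINED"

DIFFERENT_GENES = "DIFFERENT_GENES"
SAME_GENE = "SAME_GENE"
INCONCLUSIVE = "INCONCLUSIVE"


@dataclass(frozen=True)
class SegregationResult:
    n_total: int
    n_mutant: int
    n_wildtype: int
    expected_ratio: tuple[int, int]  # mutant : wildtype
    chi2: float
    df: int
    p_value: float
    significant_at_0_05: bool


@dataclass(frozen=True)
class AllelismResult:
    n_f1: int
    n_f1_mutant: int
    verdict: str


def chi_square_counts(observed: list[int], ratio: list[int]) -> tuple[float, int, float]:
    """Pearson chi-square of observed class counts against an integer ratio.

    Returns (chi2, df, p).  Generalizes to k classes with df = k - 1.
    """
    if len(observed) != len(ratio) or len(observed) < 2:
        raise ValueError("observed and ratio must have the same length >= 2")
    if any(o < 0 for o in observed):
        raise ValueError("counts must be >= 0")
    if any(r <= 0 for r in ratio):
        raise ValueError("ratio terms must be positive integers")
    n = sum(observed)
    if n == 0:
        raise ValueError("total count must be > 0")
    total_ratio = sum(ratio)
    expected = [n * r / total_ratio for r in ratio]
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    df = len(observed) - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def chi_square_ratio(
    n_mutant: int, n_wildtype: int, ratio_mutant: int = 1, ratio_wildtype: int = 3
) -> SegregationResult:
    """Test mutant/wild-type counts against a two-class ratio (default 1:3)."""
    chi2, df, p = chi_square_counts([n_mutant, n_wildtype], [ratio_mutant, ratio_wildtype])
    return SegregationResult(
        n_total=n_mutant + n_wildtype,
        n_mutant=n_mutant,
        n_wildtype=n_wildtype,
        expected_ratio=(ratio_mutant, ratio_wildtype),
        chi2=chi2,
        df=df,
        p_value=p,
        significant_at_0_05=chi2 > CHI2_CRITICAL_DF1,
    )


def infer_inheritance(f1_all_wildtype: bool, f2_result: SegregationResult) -> str:
    """SINGLE_RECESSIVE iff the F1 is uniformly wild type and the F2 fits 1:3."""
    if f2_result.expected_ratio != (1, 3):
        raise ValueError("inheritance inference requires an F2 test against 1:3")
    if f1_all_wildtype and not f2_result.significant_at_0_05:
        return SINGLE_RECESSIVE
    return UNDETERMINED


def allelism_test(n_f1: int, n_f1_mutant: int) -> AllelismResult:
    """Complementation-test verdict from F1 phenotypes of a mutant x mutant cross.

    A uniformly wild-type F1 means the two recessive mutations complement
    (DIFFERENT_GENES); a uniformly mutant F1 means non-complementation
    (SAME_GENE); no plants, or a mixed F1, is INCONCLUSIVE.
    """
    if n_f1 < 0 or n_f1_mutant < 0:
        raise ValueError("counts must be >= 0")
    if n_f1_mutant > n_f1:
        raise ValueError("n_f1_mutant cannot exceed n_f1")
    if n_f1 == 0:
        verdict = INCONCLUSIVE
    elif n_f1_mutant == 0:
        verdict = DIFFERENT_GENES
    elif n_f1_mutant == n_f1:
        verdict = SAME_GENE
    else:
        verdict = INCONCLUSIVE
    return AllelismResult(n_f1, n_f1_mutant, verdict)
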