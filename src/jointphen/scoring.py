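"""Histology score arithmetic, gene prioritization, and enrichment testing.

Covers the semi-quantitative scoring around the imaging pipelines: OARSI
cartilage grades (0-6 per section, five section levels per knee
compartment), synovitis severity (three 0-3 subscores), the 21-point gene
prioritization ledger, and Fisher's exact enrichment test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from ._util import round_to_half

__all__ = [
    "COMPARTMENTS",
    "OARSISectionScores",
    "PriorityLedger",
    "PriorityScore",
    "weighted_oarsi",
    "compartment_summary",
    "synovitis_severity",
    "literature_subscore",
    "priority_score",
    "fisher_exact_two_sided",
]

#: The four knee compartments scored per joint.
COMPARTMENTS = ("MTP", "MFC", "LTP", "LFC")
_MAX_SECTIONS = 5
_MAX_GRADE = 6


@dataclass
class OARSISectionScores:
    """Per-compartment section grades (0-6 each, at most five sections)."""

    scores: Mapping[str, Sequence[float]]

    def __post_init__(self) -> None:
        for comp, vals in self.scores.items():
            if comp not in COMPARTMENTS:
                raise ValueError(f"unknown compartment {comp!r}")
            if len(vals) > _MAX_SECTIONS:
                raise ValueError(f"{comp}: at most {_MAX_SECTIONS} sections")
            for v in vals:
                if not (0 <= v <= _MAX_GRADE):
                    raise ValueError(f"{comp}: grade {v} outside 0..{_MAX_GRADE}")


def weighted_oarsi(score_sum: float, n_scoreable: int) -> float:
    """Weight a compartment sum score for missing sections.

    weighted = score + (5 - N) * (score / N), rounded to the nearest 0.5
    (ties round up), where N is the number of scoreable sections out of
    the intended five.  At N = 5 the formula is the identity.
    """
    if not (1 <= n_scoreable <= _MAX_SECTIONS):
        raise ValueError("n_scoreable must be between 1 and 5")
    weighted = score_sum + (_MAX_SECTIONS - n_scoreable) * (score_sum / n_scoreable)
    return round_to_half(weighted)


def compartment_summary(scores: OARSISectionScores) -> dict:
    """Per-compartment sum and max scores plus total joint summaries.

    The total joint sum adds the compartment sums; the total joint max is
    the highest single-section grade across all compartments.
    """
    per = {}
    for comp in COMPARTMENTS:
        vals = list(scores.scores.get(comp, []))
        per[comp] = {
            "sum": float(np.sum(vals)) if vals else 0.0,
            "max": float(np.max(vals)) if vals else 0.0,
            "n_scoreable": len(vals),
        }
    return {
        "compartments": per,
        "total_joint_sum": float(sum(c["sum"] for c in per.values())),
        "total_joint_max": float(max(c["max"] for c in per.values())),
    }


def synovitis_severity(pannus: float, hyperplasia: float, inflammation: float) -> float:
    """Synovitis severity 0-9: pannus + lining hyperplasia + sub-synovial
    inflammation, each graded 0-3."""
    for name, v in (
        ("pannus", pannus),
        ("hyperplasia", hyperplasia),
        ("inflammation", inflammation),
    ):
        if not (0 <= v <= 3):
            raise ValueError(f"{name} subscore {v} outside 0..3")
    return float(pannus + hyperplasia + inflammation)


@dataclass
class PriorityLedger:
    """Evidence feeding the 21-point gene prioritization.

    Joint-screen evidence (max 6): the three outlier criteria plus the
    three abnormal phenotype categories, one point each.  Skeletal
    phenotypes in other resources (max 5, one per database: in-house bone
    pipeline, IMPReSS, DMDD, PubMed, MGI).  Expression in skeletal
    tissues/cells (max 4: skeleton, chondrocytes, osteoblasts/osteocytes,
    osteoclasts).  Disease association (max 4: monogenic via MGI and via
    OMIM, GWAS arthritis, GWAS skeletal).  Structured literature searches
    (max 2: PubMed and Google Scholar result bins).
    """

    screen_criteria: tuple[bool, bool, bool] = (False, False, False)  # range, wilcoxon, mahalanobis
    category_flags: tuple[bool, bool, bool] = (False, False, False)  # morphology, integrity, subchondral
    skeletal_phenotype_sources: tuple[bool, bool, bool, bool, bool] = (False,) * 5
    expression_flags: tuple[bool, bool, bool, bool] = (False,) * 4
    disease_flags: tuple[bool, bool, bool, bool] = (False,) * 4
    literature_counts: tuple[int, int] = (0, 0)  # (pubmed_n, scholar_n)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.literature_counts):
            raise ValueError("literature counts must be non-negative")


@dataclass
class PriorityScore:
    joint: float
    skeletal: float
    expression: float
    disease: float
    literature: float
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = self.joint + self.skeletal + self.expression + self.disease + self.literature


def literature_subscore(pubmed_n: int, scholar_n: int) -> tuple[float, float]:
    """Bin literature counts: PubMed 0 (<1), 0.5 (1-24), 1 (>25); Scholar
    0 (<100), 0.5 (100-999), 1 (>1000).

    The printed bin edges leave exactly 25 publications and exactly 1000
    results unassigned; both resolve to the higher bin with a warning.
    """
    if pubmed_n < 0 or scholar_n < 0:
        raise ValueError("counts must be non-negative")
    if pubmed_n == 25:
        warnings.warn("25 publications falls in a bin gap; scored as the higher bin",
                      stacklevel=2)
        pub = 1.0
    elif pubmed_n < 1:
        pub = 0.0
    elif pubmed_n <= 24:
        pub = 0.5
    else:
        pub = 1.0
    if scholar_n == 1000:
        warnings.warn("1000 results falls in a bin gap; scored as the higher bin",
                      stacklevel=2)
        sch = 1.0
    elif scholar_n < 100:
        sch = 0.0
    elif scholar_n <= 999:
        sch = 0.5
    else:
        sch = 1.0
    return pub, sch


def priority_score(ledger: PriorityLedger) -> PriorityScore:
    """Sum the five capped category subscores into the 0-21 total."""
    joint = min(3, sum(ledger.screen_criteria)) + min(3, sum(ledger.category_flags))
    skeletal = min(5, sum(ledger.skeletal_phenotype_sources))
    expression = min(4, sum(ledger.expression_flags))
    disease = min(4, sum(ledger.disease_flags))
    pub, sch = literature_subscore(*ledger.literature_counts)
    return PriorityScore(
        joint=float(joint),
        skeletal=float(skeletal),
        expression=float(expression),
        disease=float(disease),
        literature=pub + sch,
    )


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact P of a 2x2 count table.

    Sums hypergeometric probabilities (margins fixed) of every table at
    most as probable as the observed one.  Empty margins give P = 1.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t_float = np.asarray(table, dtype=float)
        if np.any(t_float < 0) or np.any(t_float != np.round(t_float)):
            raise ValueError("table must contain non-negative integer counts")
        t = t_float.astype(int)
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])
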