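"""Single-cell RT-mPCR occurrence analysis.

Patch-clamp harvested cytoplasm from individual layer II/III pyramidal
cells is probed by multiplex RT-PCR for a fixed panel of transcripts:
neuronal markers (vGluT1, GAD65, GAD67) and key genes of glucose
metabolism (transporters GluT1/GluT3, hexokinase HK1, phosphofructo-
kinase isoforms, G6PDx of the pentose phosphate pathway, and the
glycogen enzymes Gys1/PygB).  Each cell yields a boolean detection
vector over the panel; the analysis compares detection frequencies
between non-transgenic (nonTg) and triple-transgenic Alzheimer-model
(3xTgAD) cells with two-sided Fisher exact tests.

Features may be single genes or boolean combinations of two genes
("GluT1 AND GluT3", "GluT1 OR GluT3", "GluT1 AND NOT GluT3"), covering
co-detection and "only one of the pair" composites.

:func:`reference_cohort` rebuilds the published 59-cell dataset (31
nonTg + 28 3xTgAD) from its reported marginal detection counts and the
fully determined GluT1/GluT3 joint distribution.  The joint structure
across the remaining genes was not reported; the reconstruction assigns
detections to cells in panel order (synthetic independent-marginals
fill-in), so only marginal counts and the GluT pair composites are
meaningful on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .stats import Contingency2x2, fisher_exact_two_sided, percent_occurrence

__all__ = [
    "GENE_PANEL",
    "AMPLICON_SIZES_BP",
    "GenePanel",
    "CellExpressionRecord",
    "OccurrenceComparison",
    "occurrence",
    "compare_genotypes",
    "glut_composites",
    "reference_cohort",
    "records_to_frame",
    "frame_to_records",
]

GENOTYPES = ("nonTg", "3xTgAD")

#: Panel genes in reporting order.
GENE_PANEL: tuple[str, ...] = (
    "vGluT1", "GAD65", "GAD67",
    "GluT1", "GluT3",
    "HK1", "Pfkfb3", "PFK1m", "PFK1l", "PFK1p",
    "G6PDx", "Gys1", "PygB",
)

#: (first-round, nested) PCR amplicon sizes in base pairs — panel metadata.
AMPLICON_SIZES_BP: dict[str, tuple[int, int]] = {
    "vGluT1": (259, 153),
    "GAD65": (375, 248),
    "GAD67": (598, 255),
    "GluT1": (333, 164),
    "GluT3": (358, 310),
    "HK1": (472, 330),
    "Pfkfb3": (494, 365),
    "PFK1m": (247, 160),
    "PFK1l": (408, 169),
    "PFK1p": (306, 219),
    "G6PDx": (303, 143),
    "Gys1": (313, 157),
    "PygB": (292, 110),
}


@dataclass(frozen=True)
class GenePanel:
    """Ordered transcript panel with amplicon-size metadata."""

    genes: tuple[str, ...] = GENE_PANEL
    amplicon_sizes_bp: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(AMPLICON_SIZES_BP)
    )

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("panel gene names must be unique")


@dataclass(frozen=True)
class CellExpressionRecord:
    """One cell: genotype plus boolean detection over the panel."""

    cell_id: str
    genotype: str
    detected: Mapping[str, bool]

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        missing = set(GENE_PANEL) - set(self.detected)
        extra = set(self.detected) - set(GENE_PANEL)
        if missing or extra:
            raise ValueError(
                f"detection vector must cover the panel exactly "
                f"(missing {sorted(missing)}, extra {sorted(extra)})"
            )


@dataclass(frozen=True)
class OccurrenceComparison:
    """Per-feature genotype comparison: counts, integer percents, Fisher p."""

    feature: str
    k1: int
    n1: int
    k2: int
    n2: int
    percent1: int
    percent2: int
    fisher_p: float


# ---------------------------------------------------------------------------
# feature evaluation
# ---------------------------------------------------------------------------

def _feature_predicate(feature: str):
    """Compile a feature string into a per-record predicate.

    Grammar: ``GENE``, ``A AND B``, ``A OR B``, with either operand
    optionally negated by ``NOT`` (e.g. ``GluT1 AND NOT GluT3``).
    """
    tokens = feature.split()

    def term(toks: list[str]):
        if not toks:
            raise ValueError(f"malformed feature {feature!r}")
        neg = False
        if toks[0].upper() == "NOT":
            neg = True
            toks = toks[1:]
        if not toks:
            raise ValueError(f"malformed feature {feature!r}")
        gene = toks[0]
        if gene not in GENE_PANEL:
            raise ValueError(f"unknown gene {gene!r} in feature {feature!r}")
        return (lambda rec: neg ^ bool(rec.detected[gene])), toks[1:]

    pred1, rest = term(tokens)
    if not rest:
        return pred1
    op = rest[0].upper()
    if op not in ("AND", "OR"):
        raise ValueError(f"malformed feature {feature!r}")
    pred2, rest = term(rest[1:])
    if rest:
        raise ValueError(f"feature {feature!r} may combine at most two genes")
    if op == "AND":
        return lambda rec: pred1(rec) and pred2(rec)
    return lambda rec: pred1(rec) or pred2(rec)


def occurrence(
    records: Sequence[CellExpressionRecord], feature: str
) -> dict[str, tuple[int, int]]:
    """Count cells satisfying ``feature`` per genotype, as {genotype: (k, n)}."""
    if not records:
        raise ValueError("no records")
    pred = _feature_predicate(feature)
    out: dict[str, tuple[int, int]] = {}
    for gt in GENOTYPES:
        group = [r for r in records if r.genotype == gt]
        if group:
            out[gt] = (sum(pred(r) for r in group), len(group))
    return out


def compare_genotypes(
    records: Sequence[CellExpressionRecord], features: Iterable[str]
) -> list[OccurrenceComparison]:
    """One comparison row per feature: counts, percents and Fisher p."""
    present = {r.genotype for r in records}
    if set(GENOTYPES) - present:
        raise ValueError("both genotypes must be present")
    rows = []
    for feat in features:
        occ = occurrence(records, feat)
        (k1, n1), (k2, n2) = occ["nonTg"], occ["3xTgAD"]
        res = fisher_exact_two_sided(Contingency2x2(k1, n1 - k1, k2, n2 - k2))
        rows.append(
            OccurrenceComparison(
                feature=feat,
                k1=k1, n1=n1, k2=k2, n2=n2,
                percent1=percent_occurrence(k1, n1),
                percent2=percent_occurrence(k2, n2),
                fisher_p=res.p,
            )
        )
    return rows


def glut_composites() -> dict[str, str]:
    """Display name -> feature expression for the GluT1/GluT3 composites."""
    return {
        "GluT1 AND GluT3": "GluT1 AND GluT3",
        "GluT1 only": "GluT1 AND NOT GluT3",
        "GluT3 only": "GluT3 AND NOT GluT1",
        "GluT1 OR GluT3": "GluT1 OR GluT3",
    }


# ---------------------------------------------------------------------------
# reference dataset reconstruction
# ---------------------------------------------------------------------------

# Published marginal detection counts (cells detected) per genotype.
_MARGINALS: dict[str, tuple[int, int]] = {  # gene -> (k nonTg of 31, k 3xTgAD of 28)
    "vGluT1": (31, 28),
    "GAD65": (0, 0),
    "GAD67": (0, 0),
    "HK1": (13, 15),
    "Pfkfb3": (4, 1),
    "PFK1m": (26, 18),
    "PFK1l": (11, 8),
    "PFK1p": (18, 14),
    "G6PDx": (5, 5),
    "Gys1": (0, 2),
    "PygB": (9, 8),
}

# GluT1/GluT3 joint distribution (both, only GluT1, only GluT3) per genotype;
# the remainder of each group detects neither transporter.
_GLUT_JOINT = {"nonTg": (7, 2, 8), "3xTgAD": (1, 4, 5)}
_GROUP_SIZES = {"nonTg": 31, "3xTgAD": 28}


def reference_cohort() -> list[CellExpressionRecord]:
    """Deterministic reconstruction of the published 59-cell dataset.

    Every marginal detection count, and the GluT1/GluT3 joint
    distribution, equals the published value.  Joint structure among the
    other genes is synthetic: detections are assigned to the first k
    cells of each group in a fixed order, so analyses that depend on
    cross-gene co-detection outside the GluT pair are unsupported.
    """
    records: list[CellExpressionRecord] = []
    for gt in GENOTYPES:
        n = _GROUP_SIZES[gt]
        both, only1, only3 = _GLUT_JOINT[gt]
        for i in range(n):
            det = {g: i < _MARGINALS[g][0 if gt == "nonTg" else 1] for g in _MARGINALS}
            det["GluT1"] = i < both + only1
            det["GluT3"] = i < both or both + only1 <= i < both + only1 + only3
            records.append(
                CellExpressionRecord(
                    cell_id=f"{gt}-{i + 1:02d}", genotype=gt, detected=det
                )
            )
    return records


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[CellExpressionRecord]) -> pd.DataFrame:
    """One row per cell; columns cell_id, genotype, then one bool per gene."""
    return pd.DataFrame(
        [
            {"cell_id": r.cell_id, "genotype": r.genotype,
             **{g: bool(r.detected[g]) for g in GENE_PANEL}}
            for r in records
        ]
    )


def frame_to_records(frame: pd.DataFrame) -> list[CellExpressionRecord]:
    return [
        CellExpressionRecord(
            cell_id=str(row["cell_id"]),
            genotype=str(row["genotype"]),
            detected={g: bool(row[g]) for g in GENE_PANEL},
        )
        for _, row in frame.iterrows()
    ]


def write_records_csv(records: Sequence[CellExpressionRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records_csv(path: str | Path) -> list[CellExpressionRecord]:
    return frame_to_records(pd.read_csv(path))
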