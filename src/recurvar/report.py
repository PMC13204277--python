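"""Gene-level aggregation of prioritized variants, clinical-panel
overlap, and cohort demographic summaries."""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import pandas as pd

from .deleterious import DeleteriousnessCall
from .model import VariantKey
from .sharing import CohortMatrix, recurrent_variants

logger = logging.getLogger(__name__)

GENE_SEPARATOR = ";"


@dataclass
class PrioritizedSet:
    """Variants passing both recurrence and deleteriousness, with genes."""

    variants: List[Tuple[VariantKey, int, DeleteriousnessCall]]
    genes: Set[str]
    panel_overlap: Set[str] = field(default_factory=set)
    n_unannotated_recurrent: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key, n_samples, call in self.variants:
            rows.append(
                {
                    "chrom": key.chrom,
                    "pos": key.pos,
                    "ref": key.ref,
                    "alt": key.alt,
                    "n_samples": n_samples,
                    "rationale": call.rationale,
                    "votes": call.votes,
                    "gene": call.gene or ".",
                }
            )
        return pd.DataFrame(
            rows, columns=["chrom", "pos", "ref", "alt", "n_samples", "rationale", "votes", "gene"]
        )


def split_genes(gene: Optional[str], separator: str = GENE_SEPARATOR) -> Set[str]:
    """Split a multi-gene annotation string into unique symbols."""
    if not gene:
        return set()
    return {g.strip() for g in gene.split(separator) if g.strip()}


def prioritize(
    matrix: CohortMatrix,
    calls: Mapping[VariantKey, DeleteriousnessCall],
    min_samples: Optional[int] = None,
    gene_separator: str = GENE_SEPARATOR,
) -> PrioritizedSet:
    """Intersect the recurrence and deleteriousness criteria.

    A variant is advanced only when it is carried by at least
    ``min_samples`` samples (default 80% of the cohort, rounded up) AND
    its deleteriousness call is prioritized.  Recurrent variants with no
    annotation can never be advanced; they are counted for diagnostics.
    """
    recurrent = recurrent_variants(matrix, min_samples)
    sums = dict(zip(matrix.variants, (int(s) for s in matrix.row_sums())))
    chosen: List[Tuple[VariantKey, int, DeleteriousnessCall]] = []
    n_unannotated = 0
    for key in sorted(recurrent, key=lambda k: k.sort_key):
        call = calls.get(key)
        if call is None:
            n_unannotated += 1
            continue
        if call.prioritized:
            chosen.append((key, sums[key], call))
    genes: Set[str] = set()
    for _, _, call in chosen:
        genes |= split_genes(call.gene, gene_separator)
    return PrioritizedSet(variants=chosen, genes=genes, n_unannotated_recurrent=n_unannotated)


def panel_overlap(genes: Iterable[str], panel: Iterable[str]) -> Set[str]:
    """Case-insensitive exact-symbol intersection with a clinical panel.

    Symbols are whitespace-trimmed; no alias or HGNC resolution is
    attempted.  Returns the matching symbols as given in ``genes``.
    """
    panel_set = {p.strip().casefold() for p in panel}
    if not panel_set:
        logger.warning("panel is empty; overlap is trivially empty")
        return set()
    return {g for g in genes if g.strip().casefold() in panel_set}


# Column names of the demographic table dialect shipped by the synthetic
# generator (and matching typical clinical summary tables).
_DEMO_COLUMNS = {
    "age": "Age (Years)",
    "sex": "Gender",
    "race": "Race",
    "onset": "Age of Epilepsy Diagnosis (Years)",
    "seizure": "Seizure Type",
    "past_asm": "Past ASMs",
    "current_asm": "Current ASMs",
}


def _asm_count(cell: object) -> Optional[int]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return None
    text = str(cell).strip()
    if not text or text == ".":
        return None
    return len([a for a in text.split(",") if a.strip()])


def cohort_summary(
    patients: pd.DataFrame, columns: Optional[Mapping[str, str]] = None
) -> Dict[str, object]:
    """Demographic and treatment-history summary of a patient table.

    Reports mean/range of age and onset age, sex counts, seizure-type
    category counts and percentages (categories normalized by sorting is
    NOT done — the comma-separated combination is the category, joined
    with '+'), and median/range of past and current antiseizure-drug
    counts, where a drug count is the number of comma-separated agents.
    """
    cols = dict(_DEMO_COLUMNS)
    if columns:
        cols.update(columns)
    n = len(patients)
    ages = patients[cols["age"]].astype(float)
    onsets = patients[cols["onset"]].astype(float)
    sex_counts = patients[cols["sex"]].str.strip().value_counts().to_dict()
    seizure = (
        patients[cols["seizure"]]
        .map(lambda s: "+".join(part.strip() for part in str(s).split(",")))
        .value_counts()
        .to_dict()
    )
    seizure_pct = {k: round(100.0 * v / n, 1) for k, v in seizure.items()}

    def _counts(col: str) -> List[int]:
        out = []
        for cell in patients[col]:
            c = _asm_count(cell)
            if c is None:
                logger.warning("unparsable ASM cell %r; counted missing", cell)
            else:
                out.append(c)
        return out

    past = _counts(cols["past_asm"])
    current = _counts(cols["current_asm"])
    return {
        "n_patients": n,
        "mean_age": round(float(ages.mean()), 1),
        "age_range": (float(ages.min()), float(ages.max())),
        "mean_onset": round(float(onsets.mean()), 1),
        "onset_range": (float(onsets.min()), float(onsets.max())),
        "sex_counts": sex_counts,
        "seizure_type_counts": seizure,
        "seizure_type_pct": seizure_pct,
        "past_asm_median": float(statistics.median(past)) if past else None,
        "past_asm_range": (min(past), max(past)) if past else None,
        "current_asm_median": float(statistics.median(current)) if current else None,
        "current_asm_range": (min(current), max(current)) if current else None,
    }
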