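"""Deleteriousness consensus over nine in-silico predictors and the
two-arm prioritization rule.

A variant is flagged deleterious when either arm fires:

* **high impact** — the annotation's impact class is HIGH (predicted
  loss of function: frameshift, stop-gain, canonical splice-site), or
* **ensemble missense** — the variant is a nonsynonymous SNV and at
  least one of the two ensemble classifiers (radial-kernel SVM,
  logistic regression) calls it deleterious.  ``ensemble_mode="and"``
  requires both.

Call codes follow the usual dbNSFP conventions; the rubric mapping each
predictor's codes to "deleterious" is fully configurable because the
upstream annotation dialect varies by database release.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Tuple

import pandas as pd

from .model import MISSING_CODES, PREDICTORS, AnnotationRecord, VariantKey

logger = logging.getLogger(__name__)

Rubric = Dict[str, FrozenSet[str]]

#: Codes counted as deleterious per predictor (dbNSFP conventions):
#: D damaging/deleterious, P possibly damaging, A disease-causing
#: automatic, H/M high/medium functional impact.
DEFAULT_RUBRIC: Rubric = {
    "SIFT": frozenset({"D"}),
    "Polyphen2_HDIV": frozenset({"D", "P"}),
    "Polyphen2_HVAR": frozenset({"D", "P"}),
    "LRT": frozenset({"D"}),
    "MutationTaster": frozenset({"A", "D"}),
    "MutationAssessor": frozenset({"H", "M"}),
    "FATHMM": frozenset({"D"}),
    "MetaSVM_radial": frozenset({"D"}),
    "MetaLR": frozenset({"D"}),
}

# Benign/neutral codes we recognise; anything else non-missing draws a warning.
_KNOWN_BENIGN: Dict[str, FrozenSet[str]] = {
    "SIFT": frozenset({"T"}),
    "Polyphen2_HDIV": frozenset({"B"}),
    "Polyphen2_HVAR": frozenset({"B"}),
    "LRT": frozenset({"N", "U"}),
    "MutationTaster": frozenset({"N", "P"}),
    "MutationAssessor": frozenset({"L", "N"}),
    "FATHMM": frozenset({"T"}),
    "MetaSVM_radial": frozenset({"T"}),
    "MetaLR": frozenset({"T"}),
}

HIGH_IMPACT = "high_impact"
ENSEMBLE_MISSENSE = "ensemble_missense"
BOTH = "both"

ENSEMBLE_PREDICTORS: Tuple[str, str] = ("MetaSVM_radial", "MetaLR")
MISSENSE_CLASS = "nonsynonymous SNV"


def validate_rubric(rubric: Mapping[str, Iterable[str]]) -> Rubric:
    if set(rubric) != set(PREDICTORS):
        raise ValueError("rubric must name exactly the nine predictors")
    out = {name: frozenset(codes) for name, codes in rubric.items()}
    if any(not codes for codes in out.values()):
        raise ValueError("every predictor needs a non-empty deleterious code set")
    return out


@dataclass(frozen=True)
class DeleteriousnessCall:
    key: VariantKey
    votes: int
    n_missing: int
    is_high_impact: bool
    is_ensemble_deleterious: bool
    prioritized: bool
    rationale: Optional[str]
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.votes <= 9 and 0 <= self.n_missing <= 9):
            raise ValueError("votes and n_missing must lie in 0..9")
        if self.prioritized and not (self.is_high_impact or self.is_ensemble_deleterious):
            raise ValueError("prioritized requires at least one arm to fire")


def count_votes(
    ann: AnnotationRecord, rubric: Optional[Mapping[str, Iterable[str]]] = None
) -> Tuple[int, int]:
    """Count deleterious votes across the nine predictors.

    Missing codes never vote and never rescale: votes are absolute
    counts out of nine.  Unknown codes count as non-deleterious with a
    warning naming the code.
    """
    rub = validate_rubric(rubric) if rubric is not None else DEFAULT_RUBRIC
    votes = 0
    n_missing = 0
    for name in PREDICTORS:
        code = ann.predictor_calls[name]
        if code in MISSING_CODES:
            n_missing += 1
        elif code in rub[name]:
            votes += 1
        elif code not in _KNOWN_BENIGN.get(name, frozenset()):
            logger.warning("unknown %s code %r at %s; counted non-deleterious", name, code, ann.key)
    return votes, n_missing


def classify(
    ann: AnnotationRecord,
    rubric: Optional[Mapping[str, Iterable[str]]] = None,
    ensemble_mode: str = "or",
) -> DeleteriousnessCall:
    """Apply the two-arm deleteriousness rule to one annotated variant."""
    if ensemble_mode not in ("or", "and"):
        raise ValueError(f"ensemble_mode must be 'or' or 'and', got {ensemble_mode!r}")
    rub = validate_rubric(rubric) if rubric is not None else DEFAULT_RUBRIC
    votes, n_missing = count_votes(ann, rub)
    is_high = ann.impact == "HIGH"
    ens_votes = [
        ann.predictor_calls[name] not in MISSING_CODES and ann.predictor_calls[name] in rub[name]
        for name in ENSEMBLE_PREDICTORS
    ]
    ens_fires = all(ens_votes) if ensemble_mode == "and" else any(ens_votes)
    is_ensemble = ann.exonic_class == MISSENSE_CLASS and ens_fires
    prioritized = is_high or is_ensemble
    if is_high and is_ensemble:
        rationale: Optional[str] = BOTH
    elif is_high:
        rationale = HIGH_IMPACT
    elif is_ensemble:
        rationale = ENSEMBLE_MISSENSE
    else:
        rationale = None
    return DeleteriousnessCall(
        key=ann.key,
        votes=votes,
        n_missing=n_missing,
        is_high_impact=is_high,
        is_ensemble_deleterious=is_ensemble,
        prioritized=prioritized,
        rationale=rationale,
        gene=ann.gene,
    )


def vote_histogram(
    anns: Iterable[AnnotationRecord],
    rubric: Optional[Mapping[str, Iterable[str]]] = None,
    gene_list: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Histogram of exact deleterious-vote counts (0..9) over exonic variants.

    Reports per-bin variant counts, percentages of the exonic total, and
    distinct gene counts; when ``gene_list`` is given (e.g. a known
    epilepsy-gene list) an extra column counts the genes per bin that
    appear on it.
    """
    rub = validate_rubric(rubric) if rubric is not None else DEFAULT_RUBRIC
    listed = (
        {g.strip().casefold() for g in gene_list} if gene_list is not None else None
    )
    per_bin_vars = {k: 0 for k in range(10)}
    per_bin_genes: Dict[int, set] = {k: set() for k in range(10)}
    total = 0
    for ann in anns:
        votes, _ = count_votes(ann, rub)
        per_bin_vars[votes] += 1
        total += 1
        if ann.gene:
            per_bin_genes[votes].update(g.strip() for g in ann.gene.split(";") if g.strip())
    rows = []
    for k in range(10):
        genes = per_bin_genes[k]
        row = {
            "votes": k,
            "n_variants": per_bin_vars[k],
            "pct": round(100.0 * per_bin_vars[k] / total, 1) if total else 0.0,
            "n_genes": len(genes),
        }
        if listed is not None:
            row["n_listed_genes"] = sum(1 for g in genes if g.casefold() in listed)
        rows.append(row)
    return pd.DataFrame(rows)


def impact_summary(
    anns_per_sample: Mapping[str, Iterable[AnnotationRecord]]
) -> pd.DataFrame:
    """Per-sample counts of HIGH/MODERATE/LOW/MODIFIER impact classes.

    Returns one row per sample plus a final ``mean`` row with cohort
    means.  Records without an impact class are ignored (counted in the
    ``no_impact`` column).
    """
    rows: List[Dict[str, object]] = []
    classes = ("HIGH", "MODERATE", "LOW", "MODIFIER")
    for sample_id, anns in anns_per_sample.items():
        counts = {c: 0 for c in classes}
        n_absent = 0
        for ann in anns:
            if ann.impact in counts:
                counts[ann.impact] += 1
            else:
                n_absent += 1
        rows.append({"sample_id": sample_id, **counts, "no_impact": n_absent})
    df = pd.DataFrame(rows)
    if df.empty:
        logger.warning("impact summary requested for empty cohort")
        return df
    mean_row = {"sample_id": "mean", "no_impact": df["no_impact"].mean()}
    for c in classes:
        mean_row[c] = df[c].mean()
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
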