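"""Core data model shared by all pipeline stages.

The pipeline keys everything on the normalized identity of a single
alternate allele: ``(chrom, pos, ref, alt)`` after multi-allelic
splitting.  No left-alignment or other normalization is performed —
per-sample caller output is assumed internally consistent, so exact
string equality is the matching rule across samples and annotation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Tuple

#: The nine in-silico deleteriousness predictors consumed by the voting
#: stage, in canonical order.  ``MetaSVM_radial`` and ``MetaLR`` are the
#: ensemble classifiers used by the missense arm of the prioritization rule.
PREDICTORS: Tuple[str, ...] = (
    "SIFT",
    "Polyphen2_HDIV",
    "Polyphen2_HVAR",
    "LRT",
    "MutationTaster",
    "MutationAssessor",
    "FATHMM",
    "MetaSVM_radial",
    "MetaLR",
)

#: Functional classes recognised in annotation input.
FUNC_CLASSES: Tuple[str, ...] = (
    "exonic",
    "intronic",
    "intergenic",
    "ncRNA_intronic",
    "UTR3",
    "UTR5",
    "upstream",
    "downstream",
    "splicing",
    "other",
)

IMPACT_CLASSES: Tuple[str, ...] = ("HIGH", "MODERATE", "LOW", "MODIFIER")

MISSING_CODES = frozenset({".", "", None})

_CHROM_RE = re.compile(r"^(chr)?(.+)$", re.IGNORECASE)


def chrom_sort_key(chrom: str) -> Tuple[int, str]:
    """Natural ordering key for human chromosome names.

    Orders 1..22 numerically, then X, Y, MT; anything else sorts after
    those, lexicographically.  A leading ``chr`` prefix is ignored for
    ordering only — names themselves are never rewritten here.
    """
    body = _CHROM_RE.match(chrom).group(2)
    if body.isdigit():
        return (int(body), "")
    upper = body.upper()
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if upper in special:
        return (special[upper], "")
    return (26, upper)


@dataclass(frozen=True)
class VariantKey:
    """Identity of one alternate allele at one genomic site.

    ``alt`` always holds exactly one allele: multi-allelic VCF records
    are split into one key per ALT before anything downstream sees them.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be 1-based positive, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if "," in self.alt:
            raise ValueError("alt must hold exactly one allele; split multi-allelics first")

    @property
    def sort_key(self) -> Tuple[Tuple[int, str], int, str, str]:
        return (chrom_sort_key(self.chrom), self.pos, self.ref, self.alt)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class SampleCall:
    """One sample's evidence for one keyed alternate allele.

    ``ad`` keeps the full per-allele depths of the source record (ref
    first), even after multi-allelic splitting, so allele balance can be
    recomputed; ``alt_index`` records which allele index of the source
    record this key's alt occupied, which is what the genotype refers to.
    """

    sample_id: str
    qual: float
    dp: int
    ad: Optional[Tuple[int, ...]]
    gt_alleles: Tuple[int, ...]
    alt_index: int = 1

    def __post_init__(self) -> None:
        if self.qual < 0:
            raise ValueError(f"negative QUAL {self.qual} (corrupt input)")
        if self.dp < 0:
            raise ValueError(f"negative DP {self.dp} (corrupt input)")
        if self.ad is not None and any(a < 0 for a in self.ad):
            raise ValueError(f"negative AD entry in {self.ad} (corrupt input)")

    def carries_alt(self) -> bool:
        """True if the called genotype contains this key's alt allele."""
        return self.alt_index in self.gt_alleles


@dataclass(frozen=True)
class AnnotationRecord:
    """Per-variant functional annotation as consumed from the input table.

    ``predictor_calls`` always has exactly nine entries (one per
    :data:`PREDICTORS`); missing calls are encoded as ``"."`` and never
    dropped.  Raw call codes are kept verbatim — their interpretation is
    deferred to the deleteriousness rubric.
    """

    key: VariantKey
    func_class: str
    exonic_class: Optional[str]
    gene: Optional[str]
    predictor_calls: Mapping[str, str] = field(default_factory=dict)
    impact: Optional[str] = None
    ref_afs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        calls = {name: self.predictor_calls.get(name, ".") for name in PREDICTORS}
        for name, code in calls.items():
            if code in MISSING_CODES:
                calls[name] = "."
        object.__setattr__(self, "predictor_calls", calls)
        for cohort, af in self.ref_afs.items():
            if not (0.0 <= af <= 1.0):
                raise ValueError(f"reference AF for {cohort} out of [0,1]: {af}")
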