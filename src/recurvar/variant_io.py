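"""Readers and writers: per-sample VCFs, annotation tables, variant
tables, gene panels, and the YAML run configuration.

VCF parsing goes through pysam.  Multi-allelic records are split into
one keyed pair per ALT, with the record's full AD vector preserved so
allele balance stays computable; symbolic ALTs (``<NON_REF>``, ``<DEL>``
...) and spanning deletions (``*``) carry no testable allele identity
and are skipped but counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import pysam
import yaml

from .model import PREDICTORS, AnnotationRecord, SampleCall, VariantKey, chrom_sort_key

logger = logging.getLogger(__name__)

#: Default column mapping for ANNOVAR "multianno"-style tables.  All of
#: it is overridable through the YAML config's ``column_map`` section.
DEFAULT_COLUMN_MAP: Dict[str, object] = {
    "chrom": "Chr",
    "pos": "Start",
    "ref": "Ref",
    "alt": "Alt",
    "func_class": "Func.refGene",
    "exonic_class": "ExonicFunc.refGene",
    "gene": "Gene.refGene",
    "impact": "SnpEff_impact",
    "predictors": {
        "SIFT": "SIFT_pred",
        "Polyphen2_HDIV": "Polyphen2_HDIV_pred",
        "Polyphen2_HVAR": "Polyphen2_HVAR_pred",
        "LRT": "LRT_pred",
        "MutationTaster": "MutationTaster_pred",
        "MutationAssessor": "MutationAssessor_pred",
        "FATHMM": "FATHMM_pred",
        "MetaSVM_radial": "MetaSVM_pred",
        "MetaLR": "MetaLR_pred",
    },
    "ref_afs": {
        "kg1000": "1000g2015aug_all",
        "gnomad": "gnomAD_genome_ALL",
        "epi25": "Epi25_AF",
    },
}

_MISSING = {".", "", "NA", "nan"}


@dataclass
class VcfReadResult:
    """Keyed per-sample calls plus parse counters."""

    pairs: List[Tuple[VariantKey, SampleCall]] = field(default_factory=list)
    n_symbolic_skipped: int = 0
    n_malformed: int = 0

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def read_sample_vcf(path: str, sample_id: Optional[str] = None) -> VcfReadResult:
    """Read one sample's calls from a VCF 4.x file (plain or bgzipped).

    Every non-symbolic ALT of every record yields one (VariantKey,
    SampleCall) pair.  ``sample_id`` may be omitted for single-sample
    files; it must name a header sample otherwise.
    """
    vf = pysam.VariantFile(path)
    samples = list(vf.header.samples)
    if sample_id is None:
        if len(samples) != 1:
            raise ValueError(f"{path} holds {len(samples)} samples; sample_id is required")
        sample_id = samples[0]
    elif sample_id not in samples:
        raise ValueError(f"sample {sample_id!r} not in header of {path}")
    result = VcfReadResult()
    for rec in vf:
        try:
            sdata = rec.samples[sample_id]
            ad = sdata.get("AD")
            ad = tuple(int(a) for a in ad) if ad is not None and ad[0] is not None else None
            gt = sdata.get("GT") or ()
            gt_alleles = tuple(-1 if a is None else int(a) for a in gt)
            dp = sdata.get("DP")
            if dp is None:
                dp = sum(ad) if ad is not None else 0
            qual = float(rec.qual) if rec.qual is not None else 0.0
            alts = rec.alts or ()
            for i, alt in enumerate(alts, start=1):
                if alt is None or alt.startswith("<") or alt == "*":
                    result.n_symbolic_skipped += 1
                    continue
                key = VariantKey(chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt)
                call = SampleCall(
                    sample_id=sample_id, qual=qual, dp=int(dp), ad=ad,
                    gt_alleles=gt_alleles, alt_index=i,
                )
                result.pairs.append((key, call))
        except (ValueError, TypeError, KeyError) as exc:
            result.n_malformed += 1
            logger.warning("skipping malformed record %s:%s in %s: %s", rec.chrom, rec.pos, path, exc)
    return result


def read_cohort_vcfs(paths_by_sample: Mapping[str, str]) -> Dict[str, List[Tuple[VariantKey, SampleCall]]]:
    """Read one VCF per sample into the cohort mapping the QC stage consumes."""
    return {sid: read_sample_vcf(path, sid).pairs for sid, path in paths_by_sample.items()}


def _parse_af(cell: str, context: str) -> Optional[float]:
    if cell is None or cell.strip() in _MISSING:
        return None
    try:
        af = float(cell)
    except ValueError:
        logger.warning("unparsable allele frequency %r (%s); treated as missing", cell, context)
        return None
    if not 0.0 <= af <= 1.0:
        logger.warning("allele frequency %r out of [0,1] (%s); treated as missing", cell, context)
        return None
    return af


def read_annotation_table(
    path: str, column_map: Optional[Mapping[str, object]] = None
) -> List[AnnotationRecord]:
    """Read a tab-delimited annotation table into AnnotationRecords.

    ``column_map`` names the table columns holding each field (defaults
    to the ANNOVAR multianno dialect).  "." and empty cells become
    missing; predictor codes are kept verbatim.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    mandatory = [cmap["chrom"], cmap["pos"], cmap["ref"], cmap["alt"], cmap["func_class"]]
    for col in mandatory:
        if col not in df.columns:
            raise ValueError(f"mandatory column {col!r} missing from {path}")
    pred_map: Mapping[str, str] = cmap["predictors"]  # type: ignore[assignment]
    af_map: Mapping[str, str] = cmap["ref_afs"]  # type: ignore[assignment]
    records: List[AnnotationRecord] = []
    for _, row in df.iterrows():
        key = VariantKey(
            chrom=row[cmap["chrom"]],
            pos=int(row[cmap["pos"]]),
            ref=row[cmap["ref"]],
            alt=row[cmap["alt"]],
        )
        exonic = row.get(cmap["exonic_class"], ".")
        gene = row.get(cmap["gene"], ".")
        impact = row.get(cmap["impact"], ".")
        preds = {
            name: (row[col] if col in df.columns else ".")
            for name, col in pred_map.items()
        }
        ref_afs = {}
        for cohort, col in af_map.items():
            if col in df.columns:
                af = _parse_af(row[col], f"{cohort} at {key}")
                if af is not None:
                    ref_afs[cohort] = af
        records.append(
            AnnotationRecord(
                key=key,
                func_class=row[cmap["func_class"]],
                exonic_class=None if exonic in _MISSING else exonic,
                gene=None if gene in _MISSING else gene,
                predictor_calls=preds,
                impact=None if impact in _MISSING else impact,
                ref_afs=ref_afs,
            )
        )
    return records


KEY_COLUMNS = ["chrom", "pos", "ref", "alt"]


def write_variant_table(df: pd.DataFrame, path: str) -> None:
    """Write a variant table as TSV in deterministic row and column order.

    Rows are sorted by natural chromosome order, then pos, ref, alt;
    the four key columns come first.  An empty frame yields a
    header-only file.  Re-reading with :func:`read_variant_table`
    reproduces the frame.
    """
    for col in KEY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"variant table requires column {col!r}")
    ordered_cols = KEY_COLUMNS + [c for c in df.columns if c not in KEY_COLUMNS]
    out = df[ordered_cols].copy()
    if len(out):
        sort_keys = out.apply(
            lambda r: (chrom_sort_key(str(r["chrom"])), int(r["pos"]), str(r["ref"]), str(r["alt"])),
            axis=1,
        )
        out = out.iloc[sort_keys.argsort(kind="stable").to_numpy()].reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False)


def read_variant_table(path: str) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_variant_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    if "pos" in df.columns and len(df):
        df["pos"] = df["pos"].astype(int)
    return df


def read_panel(path: str) -> List[str]:
    """Read a clinical panel gene list: one symbol per line, '#' comments."""
    symbols: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                symbols.append(line)
    if not symbols:
        logger.warning("panel file %s holds no gene symbols", path)
    return symbols


def read_reference_af_table(path: str) -> Dict[VariantKey, float]:
    """Read one reference cohort's allele frequencies (chrom, pos, ref, alt, af)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    required = {"chrom", "pos", "ref", "alt", "af"}
    if not required.issubset(df.columns):
        raise ValueError(f"reference AF table {path} needs columns {sorted(required)}")
    table: Dict[VariantKey, float] = {}
    for row in df.itertuples(index=False):
        af = _parse_af(str(row.af), f"{path} at {row.chrom}:{row.pos}")
        if af is not None:
            table[VariantKey(str(row.chrom), int(row.pos), row.ref, row.alt)] = af
    return table


def read_ancestry_table(path: str) -> Dict[str, str]:
    """Read a sample -> ancestry-group assignment TSV (sample_id, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"}.issubset(df.columns):
        raise ValueError(f"ancestry table {path} needs sample_id and group columns")
    return dict(zip(df["sample_id"], df["group"]))


def load_config(path: str) -> Dict[str, object]:
    """Load the YAML run configuration (column_map, thresholds, cohort layout)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg
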