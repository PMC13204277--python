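"""Synthetic annotated-cohort generator.

Emulates the inputs of a small whole-genome-sequenced cohort so the
whole pipeline is testable without any download: per-sample VCFs with
QUAL/DP/AD drawn so configured fractions of calls fail each QC
criterion, an annotation table in the default multianno dialect, per
reference-cohort allele-frequency tables, a clinical panel file, an
ancestry assignment table, a patient demographic table, and a JSON
ground-truth manifest.

The generator's structural guarantees make the manifest an exact
oracle: planted variants appear in at least their configured carrier
count of samples with QC-passing calls and deleterious annotation,
while background variants present in eight or more samples are never
given a deleterious annotation, and QC failures can only lower sharing
counts — so the pipeline's prioritized set equals the planted set
exactly at the generating thresholds.
"""

from __future__ import annotations

import io
import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import PREDICTORS, VariantKey

# Default background sharing spectrum over k = 1..10 carriers.  Heavy
# singleton mass with a long decreasing tail and a small bump of fully
# shared variants, the shape typical of multi-sample germline cohorts.
DEFAULT_SHARING: Tuple[float, ...] = (
    0.372, 0.137, 0.1296, 0.11, 0.09, 0.07, 0.04, 0.005, 0.0104, 0.036,
)

#: Functional-class mix of a post-filtering whole-genome callset:
#: overwhelmingly noncoding, with a sub-percent exonic fraction.
DEFAULT_FUNC_MIX: Dict[str, float] = {
    "intergenic": 0.547,
    "intronic": 0.349,
    "ncRNA_intronic": 0.064,
    "UTR3": 0.0095,
    "UTR5": 0.0016,
    "upstream": 0.0065,
    "downstream": 0.0065,
    "exonic": 0.006,
    "splicing": 0.0002,
    "other": 0.0097,
}

#: Distribution of deleterious-vote counts (0..9) for exonic SNVs: most
#: variants draw no deleterious call; consensus across many predictors
#: is rare.
DEFAULT_VOTE_MIX: Tuple[float, ...] = (
    0.781, 0.106, 0.046, 0.025, 0.015, 0.010, 0.008, 0.005, 0.003, 0.001,
)

LOF_CLASSES = ("frameshift insertion", "frameshift deletion", "stopgain", "stoploss", "startloss")

_DELETERIOUS_CODE = {
    "SIFT": "D", "Polyphen2_HDIV": "D", "Polyphen2_HVAR": "D", "LRT": "D",
    "MutationTaster": "A", "MutationAssessor": "H", "FATHMM": "D",
    "MetaSVM_radial": "D", "MetaLR": "D",
}
_BENIGN_CODE = {
    "SIFT": "T", "Polyphen2_HDIV": "B", "Polyphen2_HVAR": "B", "LRT": "N",
    "MutationTaster": "N", "MutationAssessor": "L", "FATHMM": "T",
    "MetaSVM_radial": "T", "MetaLR": "T",
}
_NON_ENSEMBLE = tuple(p for p in PREDICTORS if p not in ("MetaSVM_radial", "MetaLR"))

PANEL_GENES: Tuple[str, ...] = (
    "APOL4", "KMT2C", "SON", "VDR", "SCN1A", "SCN2A", "KCNQ2", "KCNQ3",
    "DEPDC5", "GABRG2", "GABRA1", "CHD2", "SLC2A1", "STXBP1", "PCDH19",
    "CDKL5", "TSC1", "TSC2", "LGI1", "PRRT2",
)

REFERENCE_COHORTS = ("kg1000", "gnomad", "epi25")

_ANCESTRY_PATTERN = ("AFR", "AFR", "AMR", "ASN", "ASN", "EUR", "EUR", "EUR", "EUR", "EUR")

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class PlantedVariant:
    """Specification of one ground-truth prioritized variant."""

    min_carriers: int = 8
    arm: str = "high_impact"  # or "ensemble_missense"
    gene: Optional[str] = None
    enriched: bool = False  # cohort AF well above the reference AF

    def __post_init__(self) -> None:
        if self.arm not in ("high_impact", "ensemble_missense"):
            raise ValueError(f"unknown deleterious arm {self.arm!r}")


DEFAULT_PLANTED: Tuple[PlantedVariant, ...] = (
    PlantedVariant(min_carriers=10, arm="high_impact", gene="VDR", enriched=True),
    PlantedVariant(min_carriers=9, arm="high_impact", gene="KMT2C"),
    PlantedVariant(min_carriers=8, arm="high_impact", gene="SON"),
    PlantedVariant(min_carriers=8, arm="high_impact", gene="APOL4", enriched=True),
    PlantedVariant(min_carriers=10, arm="ensemble_missense", gene="MUC6", enriched=True),
    PlantedVariant(min_carriers=9, arm="ensemble_missense", gene="OR10D3"),
    PlantedVariant(min_carriers=8, arm="ensemble_missense", gene="KCNJ12"),
)


@dataclass
class SimulationConfig:
    n_samples: int = 10
    n_background_variants: int = 2000
    sharing_distribution: Tuple[float, ...] = DEFAULT_SHARING
    planted: Tuple[PlantedVariant, ...] = DEFAULT_PLANTED
    qc_fail_fractions: Dict[str, float] = field(
        default_factory=lambda: {"qual": 0.03, "depth": 0.03, "fraction": 0.03}
    )
    func_class_mix: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FUNC_MIX))
    predictor_vote_mix: Tuple[float, ...] = DEFAULT_VOTE_MIX
    het_fraction: float = 0.8
    missing_af_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if len(self.sharing_distribution) != self.n_samples:
            raise ValueError("sharing_distribution needs one probability per carrier count 1..n")
        for name, vec in (
            ("sharing_distribution", self.sharing_distribution),
            ("func_class_mix", tuple(self.func_class_mix.values())),
            ("predictor_vote_mix", self.predictor_vote_mix),
        ):
            if abs(sum(vec) - 1.0) > 1e-6:
                raise ValueError(f"{name} must sum to 1 (got {sum(vec):.6f})")
            if any(p < 0 for p in vec):
                raise ValueError(f"{name} holds a negative probability")
        if sum(self.qc_fail_fractions.values()) > 0.9:
            raise ValueError("qc_fail_fractions leave too few passing calls")
        for spec in self.planted:
            if spec.min_carriers > self.n_samples:
                raise ValueError(
                    f"planted spec wants {spec.min_carriers} carriers in {self.n_samples} samples"
                )
        if not 0.0 <= self.het_fraction <= 1.0:
            raise ValueError("het_fraction must lie in [0,1]")


# --- internal variant bookkeeping -------------------------------------------

@dataclass
class _SimVariant:
    key: VariantKey
    carriers: Tuple[str, ...]
    func_class: str
    exonic_class: Optional[str]
    gene: Optional[str]
    impact: Optional[str]
    predictor_calls: Dict[str, str]
    ref_afs: Dict[str, float]
    planted: bool = False
    arm: Optional[str] = None
    enriched: bool = False


def _draw_allele_pair(rng: np.random.Generator, exonic_class: Optional[str]) -> Tuple[str, str]:
    base = BASES[rng.integers(0, 4)]
    if exonic_class == "frameshift insertion":
        ins = "".join(BASES[rng.integers(0, 4)] for _ in range(int(rng.integers(1, 4))))
        return base, base + ins
    if exonic_class == "frameshift deletion":
        tail = "".join(BASES[rng.integers(0, 4)] for _ in range(int(rng.integers(1, 4))))
        return base + tail, base
    alt = BASES[rng.integers(0, 4)]
    while alt == base:
        alt = BASES[rng.integers(0, 4)]
    return base, alt


def _unique_position(rng: np.random.Generator, used: Dict[str, set]) -> Tuple[str, int]:
    chrom = "chr1" if rng.integers(0, 2) == 0 else "chr2"
    while True:
        pos = int(rng.integers(1, 100_000_000))
        if pos not in used[chrom]:
            used[chrom].add(pos)
            return chrom, pos


def _assign_predictors(
    rng: np.random.Generator,
    votes: int,
    pool: Sequence[str],
    missing_prob: float = 0.1,
) -> Dict[str, str]:
    """Predictor codes with exactly ``votes`` deleterious calls from ``pool``."""
    calls = {name: "." for name in PREDICTORS}
    chosen = rng.choice(len(pool), size=votes, replace=False) if votes else []
    voters = {pool[int(i)] for i in chosen}
    for name in PREDICTORS:
        if name in voters:
            calls[name] = _DELETERIOUS_CODE[name]
        elif name in pool:
            calls[name] = "." if rng.random() < missing_prob else _BENIGN_CODE[name]
        # predictors outside the pool stay missing; callers overwrite them
        # when they must be pinned (e.g. ensembles on recurrent background)
    return calls


def _expected_af(k: int, n: int, het_fraction: float) -> float:
    """Alt allele frequency implied by k carriers under the het/hom mix."""
    per_carrier = het_fraction * 1.0 + (1.0 - het_fraction) * 2.0
    return min(0.999, (k * per_carrier) / (2.0 * n))


def _background_variant(
    i: int, rng: np.random.Generator, cfg: SimulationConfig,
    samples: Sequence[str], used: Dict[str, set],
) -> _SimVariant:
    n = cfg.n_samples
    k = int(rng.choice(np.arange(1, n + 1), p=np.asarray(cfg.sharing_distribution)))
    carriers = tuple(sorted(str(s) for s in rng.choice(samples, size=k, replace=False)))
    classes = list(cfg.func_class_mix)
    func = str(rng.choice(classes, p=np.asarray([cfg.func_class_mix[c] for c in classes])))
    recurrence_gate = k >= math.ceil(0.8 * n)
    if recurrence_gate and func == "splicing":
        func = "intronic"  # recurrent background must stay non-deleterious
    exonic_class: Optional[str] = None
    impact: Optional[str] = "MODIFIER"
    calls = {name: "." for name in PREDICTORS}
    gene = f"GENE{i:05d}" if func != "intergenic" else None
    if func == "splicing":
        impact = "HIGH"
    elif func == "exonic":
        if recurrence_gate:
            missense = rng.random() < 0.5
            exonic_class = "nonsynonymous SNV" if missense else "synonymous SNV"
            impact = "MODERATE" if missense else "LOW"
            if missense:
                votes = min(int(rng.choice(10, p=np.asarray(cfg.predictor_vote_mix))), 7)
                calls = _assign_predictors(rng, votes, _NON_ENSEMBLE)
                calls["MetaSVM_radial"] = _BENIGN_CODE["MetaSVM_radial"]
                calls["MetaLR"] = _BENIGN_CODE["MetaLR"]
        else:
            u = rng.random()
            if u < 0.49:
                exonic_class, impact = "synonymous SNV", "LOW"
            elif u < 0.96:
                exonic_class, impact = "nonsynonymous SNV", "MODERATE"
                votes = int(rng.choice(10, p=np.asarray(cfg.predictor_vote_mix)))
                calls = _assign_predictors(rng, votes, PREDICTORS)
            else:
                exonic_class = str(rng.choice(LOF_CLASSES))
                impact = "HIGH"
    ref, alt = _draw_allele_pair(rng, exonic_class)
    chrom, pos = _unique_position(rng, used)
    ref_afs: Dict[str, float] = {}
    if rng.random() >= cfg.missing_af_fraction:
        af = _expected_af(k, n, cfg.het_fraction)
        ref_afs["kg1000"] = round(af, 6)
        for cohort in ("gnomad", "epi25"):
            ref_afs[cohort] = round(float(np.clip(af * rng.uniform(0.9, 1.1), 1e-4, 0.999)), 6)
    return _SimVariant(
        key=VariantKey(chrom, pos, ref, alt), carriers=carriers, func_class=func,
        exonic_class=exonic_class, gene=gene, impact=impact,
        predictor_calls=calls, ref_afs=ref_afs,
    )


def _planted_variant(
    spec: PlantedVariant, idx: int, rng: np.random.Generator, cfg: SimulationConfig,
    samples: Sequence[str], used: Dict[str, set],
) -> _SimVariant:
    carriers = tuple(sorted(str(s) for s in rng.choice(samples, size=spec.min_carriers, replace=False)))
    gene = spec.gene or f"PLANT{idx:02d}"
    if spec.arm == "high_impact":
        exonic_class = str(rng.choice(("frameshift insertion", "frameshift deletion", "stopgain")))
        impact = "HIGH"
        calls = {name: "." for name in PREDICTORS}
    else:
        exonic_class = "nonsynonymous SNV"
        impact = "MODERATE"
        calls = {name: _BENIGN_CODE[name] for name in PREDICTORS}
        calls["MetaSVM_radial"] = "D"
        calls["MetaLR"] = "D"
        calls["SIFT"] = "D"
        calls["Polyphen2_HDIV"] = "D"
    ref, alt = _draw_allele_pair(rng, exonic_class)
    chrom, pos = _unique_position(rng, used)
    if spec.enriched:
        base_af = float(rng.uniform(0.01, 0.08))
    else:
        base_af = _expected_af(spec.min_carriers, cfg.n_samples, cfg.het_fraction)
    ref_afs = {"kg1000": round(base_af, 6)}
    for cohort in ("gnomad", "epi25"):
        ref_afs[cohort] = round(float(np.clip(base_af * rng.uniform(0.9, 1.1), 1e-4, 0.999)), 6)
    return _SimVariant(
        key=VariantKey(chrom, pos, ref, alt), carriers=carriers, func_class="exonic",
        exonic_class=exonic_class, gene=gene, impact=impact, predictor_calls=calls,
        ref_afs=ref_afs, planted=True, arm=spec.arm, enriched=spec.enriched,
    )


# --- per-call simulation ----------------------------------------------------

def _passing_depths(rng: np.random.Generator, het: bool) -> Tuple[float, int, int, int]:
    qual = float(rng.uniform(100.0, 2000.0))
    dp = int(rng.integers(20, 61))
    if het:
        alt = int(rng.binomial(dp, 0.5))
        while alt == 0 or alt / dp < 1.0 / 6.0:
            alt = int(rng.binomial(dp, 0.5))
    else:
        alt = dp - int(rng.binomial(dp, 0.02))
        while alt == 0 or alt / dp < 1.0 / 6.0:
            alt = dp - int(rng.binomial(dp, 0.02))
    return qual, dp, dp - alt, alt


def _failing_call(rng: np.random.Generator, mode: str, het: bool) -> Tuple[float, int, int, int]:
    qual, dp, ref_ad, alt_ad = _passing_depths(rng, het)
    if mode == "qual":
        qual = float(rng.uniform(20.0, 99.99))
    elif mode == "depth":
        dp = int(rng.integers(5, 20))
        alt_ad = int(rng.binomial(dp, 0.5))
        while alt_ad / dp < 1.0 / 6.0:
            alt_ad = int(rng.binomial(dp, 0.5))
        ref_ad = dp - alt_ad
    elif mode == "fraction":
        max_alt = int(math.ceil(dp / 6.0)) - 1
        alt_ad = int(rng.integers(0, max_alt + 1))
        ref_ad = dp - alt_ad
    else:
        raise ValueError(mode)
    return qual, dp, ref_ad, alt_ad


# --- writers -----------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000001>
##contig=<ID=chr2,length=100000001>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def _write_vcf(path: str, sample: str, rows: List[Tuple[VariantKey, float, int, int, int, bool]]) -> None:
    rows = sorted(rows, key=lambda r: r[0].sort_key)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(sample=sample))
        for key, qual, dp, ref_ad, alt_ad, het in rows:
            gt = "0/1" if het else "1/1"
            fh.write(
                f"{key.chrom}\t{key.pos}\t.\t{key.ref}\t{key.alt}\t{qual:.2f}\tPASS\t.\t"
                f"GT:AD:DP\t{gt}:{ref_ad},{alt_ad}:{dp}\n"
            )


def _af_cell(v: _SimVariant, cohort: str) -> str:
    return f"{v.ref_afs[cohort]:.6g}" if cohort in v.ref_afs else "."


def _write_annotation(path: str, variants: List[_SimVariant]) -> None:
    pred_cols = {
        "SIFT": "SIFT_pred", "Polyphen2_HDIV": "Polyphen2_HDIV_pred",
        "Polyphen2_HVAR": "Polyphen2_HVAR_pred", "LRT": "LRT_pred",
        "MutationTaster": "MutationTaster_pred", "MutationAssessor": "MutationAssessor_pred",
        "FATHMM": "FATHMM_pred", "MetaSVM_radial": "MetaSVM_pred", "MetaLR": "MetaLR_pred",
    }
    af_cols = {"kg1000": "1000g2015aug_all", "gnomad": "gnomAD_genome_ALL", "epi25": "Epi25_AF"}
    rows = []
    for v in sorted(variants, key=lambda v: v.key.sort_key):
        row = {
            "Chr": v.key.chrom, "Start": v.key.pos, "Ref": v.key.ref, "Alt": v.key.alt,
            "Func.refGene": v.func_class,
            "Gene.refGene": v.gene or ".",
            "ExonicFunc.refGene": v.exonic_class or ".",
            "SnpEff_impact": v.impact or ".",
        }
        for name, col in pred_cols.items():
            row[col] = v.predictor_calls[name]
        for cohort, col in af_cols.items():
            row[col] = _af_cell(v, cohort)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_reference_tables(out_dir: str, variants: List[_SimVariant]) -> Dict[str, str]:
    files = {}
    for cohort in REFERENCE_COHORTS:
        rows = [
            {"chrom": v.key.chrom, "pos": v.key.pos, "ref": v.key.ref, "alt": v.key.alt,
             "af": f"{v.ref_afs[cohort]:.6g}"}
            for v in sorted(variants, key=lambda v: v.key.sort_key)
            if cohort in v.ref_afs
        ]
        fname = f"ref_af_{cohort}.tsv"
        pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "af"]).to_csv(
            os.path.join(out_dir, fname), sep="\t", index=False
        )
        files[cohort] = fname
    return files


# --- the demographic fixture --------------------------------------------------

#: Ten-patient demographic/treatment table of a pharmacoresistant GGE
#: cohort (ASM = antiseizure medication; GTC/AB/M = tonic-clonic,
#: absence, myoclonic seizures).
PATIENT_TABLE_TSV = """\
Patient Number\tAge (Years)\tGender\tRace\tAge of Epilepsy Diagnosis (Years)\tFamily History of Epilepsy\tSeizure Type\tHistory of Generalized Status Epilepticus\tPast ASMs\tCurrent ASMs
1\t29\tM\tblack\t14\tNo\tGTC, AB\tYes\tVPA, PHT\tLMG, ZNS, LEV, PRP, CLB
2\t36\tM\twhite\t17\tFDR\tGTC, AB\tNo\tVPA, LEV, LCM\tZNS, BRV
3\t34\tF\twhite\t31\tSDR\tGTC, AB\tYes\tVPA, LEV, LMG, OXC\tZNS, BRV, CLN
4\t20\tM\tother-ind sub\t12\tNo\tGTC\tNo\tLEV\tZNS, BRV, CLB
5\t23\tF\tother-ind sub\t13\tNo\tGTC, M\tNo\tLEV\tVPA, TPM, LMG
6\t49\tF\tother-mid es\t19\tNo\tGTC, M\tNo\tLEV, PHT, LCM\tVPA, ZNS, PRP
7\t38\tF\tblack\t4\tFDR\tGTC, AB\tYes\tLMG, TPM, OXC, CBZ, ECL, PHB\tVPA, LEV, PHT
8\t52\tF\twhite\t12\tNo\tGTC, AB\tNo\tCBZ, LMG, LEV, PHB, PRP\tVPA, BRV
9\t31\tF\twhite\t10\tNo\tGTC, AB, M\tNo\tLEV, PHT, TPM\tLMG, ZNS
10\t30\tF\thispanic\t5\tSDR\tGTC\tYes\tLMG, CBZ\tVPA, PRP, BRV, CBT
"""


def generate_patient_table(path: Optional[str] = None) -> pd.DataFrame:
    """The ten-patient demographic table, optionally written as TSV."""
    df = pd.read_csv(io.StringIO(PATIENT_TABLE_TSV), sep="\t")
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


# --- the generator ------------------------------------------------------------

def generate_cohort(
    config: Optional[SimulationConfig] = None,
    out_dir: str = ".",
    seed: Optional[int] = None,
) -> Dict[str, object]:
    """Generate a full synthetic cohort bundle; returns the manifest.

    Deterministic given the seed: the same seed yields a byte-identical
    bundle.  ``seed`` overrides ``config.seed`` when given.
    """
    cfg = config or SimulationConfig()
    if seed is not None:
        cfg = SimulationConfig(**{**asdict(cfg), "seed": int(seed)})
        cfg.planted = tuple(
            PlantedVariant(**p) if isinstance(p, dict) else p for p in cfg.planted
        )
    cfg.validate()
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    samples = [f"S{i:02d}" for i in range(1, cfg.n_samples + 1)]
    used: Dict[str, set] = {"chr1": set(), "chr2": set()}

    variants: List[_SimVariant] = []
    for idx, spec in enumerate(cfg.planted):
        variants.append(_planted_variant(spec, idx, rng, cfg, samples, used))
    for i in range(cfg.n_background_variants):
        variants.append(_background_variant(i, rng, cfg, samples, used))

    # Per-sample call simulation.
    fail_modes = ("qual", "depth", "fraction")
    f_q = cfg.qc_fail_fractions.get("qual", 0.0)
    f_d = cfg.qc_fail_fractions.get("depth", 0.0)
    f_f = cfg.qc_fail_fractions.get("fraction", 0.0)
    per_sample_rows: Dict[str, List[Tuple[VariantKey, float, int, int, int, bool]]] = {
        s: [] for s in samples
    }
    designed_failures = {m: 0 for m in fail_modes}
    n_calls = 0
    for v in variants:
        for s in v.carriers:
            het = bool(rng.random() < cfg.het_fraction)
            if v.planted:
                mode = None
            else:
                u = rng.random()
                if u < f_q:
                    mode = "qual"
                elif u < f_q + f_d:
                    mode = "depth"
                elif u < f_q + f_d + f_f:
                    mode = "fraction"
                else:
                    mode = None
            if mode is None:
                qual, dp, ref_ad, alt_ad = _passing_depths(rng, het)
            else:
                designed_failures[mode] += 1
                qual, dp, ref_ad, alt_ad = _failing_call(rng, mode, het)
            per_sample_rows[s].append((v.key, qual, dp, ref_ad, alt_ad, het))
            n_calls += 1

    files: Dict[str, object] = {"samples": {}}
    for s in samples:
        fname = f"{s}.vcf"
        _write_vcf(os.path.join(out_dir, fname), s, per_sample_rows[s])
        files["samples"][s] = fname

    _write_annotation(os.path.join(out_dir, "annotation.tsv"), variants)
    files["annotation"] = "annotation.tsv"
    files["reference_afs"] = _write_reference_tables(out_dir, variants)

    with open(os.path.join(out_dir, "panel.txt"), "w") as fh:
        fh.write("# clinical epilepsy panel (synthetic stand-in)\n")
        for g in PANEL_GENES:
            fh.write(g + "\n")
    files["panel"] = "panel.txt"

    ancestry = [(s, _ANCESTRY_PATTERN[i % len(_ANCESTRY_PATTERN)]) for i, s in enumerate(samples)]
    pd.DataFrame(ancestry, columns=["sample_id", "group"]).to_csv(
        os.path.join(out_dir, "ancestry.tsv"), sep="\t", index=False
    )
    files["ancestry"] = "ancestry.tsv"

    generate_patient_table(os.path.join(out_dir, "patients.tsv"))
    files["patients"] = "patients.tsv"

    planted_records = [
        {
            "chrom": v.key.chrom, "pos": v.key.pos, "ref": v.key.ref, "alt": v.key.alt,
            "gene": v.gene, "arm": v.arm, "n_carriers": len(v.carriers),
            "enriched": v.enriched,
        }
        for v in variants
        if v.planted
    ]
    expected_prioritized = sorted(str(v.key) for v in variants if v.planted)
    expected_genes = sorted({v.gene for v in variants if v.planted and v.gene})
    panel_lower = {g.casefold() for g in PANEL_GENES}
    manifest: Dict[str, object] = {
        "seed": cfg.seed,
        "n_samples": cfg.n_samples,
        "n_background_variants": cfg.n_background_variants,
        "samples": samples,
        "files": files,
        "planted": planted_records,
        "expected_prioritized": expected_prioritized,
        "expected_genes": expected_genes,
        "expected_panel_overlap": sorted(g for g in expected_genes if g.casefold() in panel_lower),
        "qc": {
            "n_calls": n_calls,
            "designed_failures": designed_failures,
            "fail_fractions": {m: cfg.qc_fail_fractions.get(m, 0.0) for m in fail_modes},
        },
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
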