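"""End-to-end orchestration: bundle directory in, prioritized set out.

Wires the stages together in the canonical order: read per-sample VCFs,
apply per-sample QC, build the presence matrix and sharing spectrum,
classify deleteriousness from the annotation table, intersect recurrence
with deleteriousness, compare prioritized variants' allele frequencies
against reference tables, and intersect prioritized genes with the
clinical panel.
"""

from __future__ import annotations

import glob
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import pandas as pd

from .deleterious import DeleteriousnessCall, classify
from .freq_compare import FrequencyTestResult, compare_cohort_frequencies
from .model import SampleCall, VariantKey
from .qc import QCThresholds, filter_cohort
from .report import PrioritizedSet, panel_overlap, prioritize
from .sharing import (
    CohortMatrix,
    SharingSpectrum,
    alt_allele_counts,
    build_matrix,
    default_min_samples,
    spectrum,
    wilson_lower_bound,
)
from .variant_io import (
    read_annotation_table,
    read_cohort_vcfs,
    read_panel,
    read_reference_af_table,
)


@dataclass
class PipelineResult:
    qc_summary: pd.DataFrame
    matrix: CohortMatrix
    spectrum: SharingSpectrum
    calls: Dict[VariantKey, DeleteriousnessCall]
    prioritized: PrioritizedSet
    freq_results: List[FrequencyTestResult] = field(default_factory=list)
    freq_excluded: List[VariantKey] = field(default_factory=list)
    min_samples: int = 0
    wilson_lower: float = 0.0

    @property
    def prioritized_keys(self) -> set:
        return {key for key, _, _ in self.prioritized.variants}


def discover_bundle(bundle_dir: str) -> Dict[str, object]:
    """Locate bundle files, preferring the manifest's layout when present."""
    manifest_path = os.path.join(bundle_dir, "manifest.json")
    if os.path.exists(manifest_path):
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        files = manifest["files"]
        layout = {
            "vcfs": {s: os.path.join(bundle_dir, f) for s, f in files["samples"].items()},
            "annotation": os.path.join(bundle_dir, files["annotation"]),
            "panel": os.path.join(bundle_dir, files["panel"]) if files.get("panel") else None,
            "reference_afs": {
                cohort: os.path.join(bundle_dir, f)
                for cohort, f in files.get("reference_afs", {}).items()
            },
        }
        return layout
    vcfs = {
        os.path.splitext(os.path.basename(p))[0]: p
        for p in sorted(glob.glob(os.path.join(bundle_dir, "*.vcf")))
    }
    if not vcfs:
        raise FileNotFoundError(f"no manifest.json and no *.vcf files in {bundle_dir}")
    annotation = os.path.join(bundle_dir, "annotation.tsv")
    panel = os.path.join(bundle_dir, "panel.txt")
    refs = {}
    for p in sorted(glob.glob(os.path.join(bundle_dir, "ref_af_*.tsv"))):
        name = os.path.basename(p)[len("ref_af_"):-len(".tsv")]
        refs[name] = p
    return {
        "vcfs": vcfs,
        "annotation": annotation if os.path.exists(annotation) else None,
        "panel": panel if os.path.exists(panel) else None,
        "reference_afs": refs,
    }


def run_bundle(
    bundle_dir: str,
    thresholds: Optional[QCThresholds] = None,
    min_samples: Optional[int] = None,
    rubric: Optional[Mapping[str, object]] = None,
    ensemble_mode: str = "or",
    presence: str = "genotype",
    trials_mode: str = "alleles",
    alpha: float = 0.05,
) -> PipelineResult:
    """Run the full prioritization pipeline on a bundle directory.

    ``trials_mode="alleles"`` tests alt allele counts over 2n
    chromosomes against the reference allele frequencies;
    ``"carriers"`` tests carrier counts over n individuals.
    """
    layout = discover_bundle(bundle_dir)
    cohort = read_cohort_vcfs(layout["vcfs"])
    kept, qc_summary = filter_cohort(cohort, thresholds)
    matrix = build_matrix(kept, presence=presence)
    spec = spectrum(matrix)

    calls: Dict[VariantKey, DeleteriousnessCall] = {}
    if layout.get("annotation"):
        for ann in read_annotation_table(layout["annotation"]):
            calls[ann.key] = classify(ann, rubric, ensemble_mode)

    k = default_min_samples(matrix.n_samples) if min_samples is None else min_samples
    prioritized = prioritize(matrix, calls, k)
    if layout.get("panel"):
        prioritized.panel_overlap = panel_overlap(prioritized.genes, read_panel(layout["panel"]))

    freq_results: List[FrequencyTestResult] = []
    excluded: List[VariantKey] = []
    ref_tables = {
        cohort_name: read_reference_af_table(path)
        for cohort_name, path in layout.get("reference_afs", {}).items()
    }
    target_keys = {key for key, _, _ in prioritized.variants}
    if ref_tables and target_keys:
        if trials_mode == "alleles":
            counts_all = alt_allele_counts(kept)
            observed = {key: counts_all[key] for key in target_keys}
            trials = 2 * matrix.n_samples
        elif trials_mode == "carriers":
            sums = dict(zip(matrix.variants, matrix.row_sums()))
            observed = {key: int(sums[key]) for key in target_keys}
            trials = matrix.n_samples
        else:
            raise ValueError(f"unknown trials_mode {trials_mode!r}")
        freq_results, excluded = compare_cohort_frequencies(observed, ref_tables, trials, alpha)

    return PipelineResult(
        qc_summary=qc_summary,
        matrix=matrix,
        spectrum=spec,
        calls=calls,
        prioritized=prioritized,
        freq_results=freq_results,
        freq_excluded=excluded,
        min_samples=k,
        wilson_lower=wilson_lower_bound(k, matrix.n_samples),
    )
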