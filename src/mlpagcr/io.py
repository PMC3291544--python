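"""Readers/writers for pipeline formats, run configuration and orchestration.

Tables are TSV, nested summaries JSON; every written report embeds the run
seed and a hash of the configuration in a comment header so that reruns
are verifiably reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import classify_matrix, localize_breakpoint, summarize_cohort
from .copynumber import CallingError, CopyNumberMatrix, PeakTable, call_copy_numbers
from .genome import GenomeAnnotation, load_annotation
from .probes import ProbeSet, read_probeset_tsv

__all__ = [
    "RunConfig",
    "read_peak_table",
    "write_copy_number_tsv",
    "write_classification_tsv",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_PEAK_COLS = ["sample_id", "size_bp", "height", "area", "is_control"]


def read_peak_table(path: str | Path) -> list[PeakTable]:
    """Read a capillary-export-style peak CSV into per-sample peak tables.

    Columns: sample_id, size_bp, height, area, is_control.  Duplicate
    (sample, size) rows and negative areas are errors (reported with their
    row number).
    """
    df = pd.read_csv(path)
    missing = [c for c in _PEAK_COLS if c not in df.columns]
    if missing:
        raise CallingError(f"{path}: missing columns {missing}")
    if df.duplicated(subset=["sample_id", "size_bp"]).any():
        row = int(df.index[df.duplicated(subset=["sample_id", "size_bp"])][0]) + 2
        raise CallingError(f"{path}: duplicate (sample_id, size_bp) at row {row}")
    neg = df.index[df["area"] < 0]
    if len(neg):
        raise CallingError(f"{path}: negative area at row {int(neg[0]) + 2}")
    tables = []
    for sample_id, group in df.groupby("sample_id", sort=False):
        flags = set(group["is_control"].astype(bool))
        if len(flags) != 1:
            raise CallingError(f"{path}: inconsistent is_control for sample {sample_id}")
        tables.append(
            PeakTable(
                sample_id=str(sample_id),
                peaks=list(zip(group["size_bp"].astype(float), group["area"].astype(float))),
                is_control=flags.pop(),
            )
        )
    return tables


def write_peak_csv(tables: list[PeakTable], path: str | Path) -> None:
    rows = []
    for t in tables:
        for size, area in t.peaks:
            rows.append(
                {"sample_id": t.sample_id, "size_bp": size, "height": area,
                 "area": area, "is_control": t.is_control}
            )
    pd.DataFrame(rows, columns=_PEAK_COLS).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Configuration of one end-to-end calling/classification run."""

    annotation_path: str
    chromosomes_path: str | None
    telomeric_probes_path: str
    peaks_path: str
    out_dir: str
    centromeric_probes_path: str | None = None
    annotation_dialect: str = "tsv"
    normalization_mode: str = "GLOBAL_SUM"
    ambiguity_tolerance: float = 0.3
    mc_replicates: int = 2000
    seed: int = 0
    assay_arm: str = "chrV-L"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for name in ("annotation_path", "telomeric_probes_path", "peaks_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        for name in ("chromosomes_path", "centromeric_probes_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")

    def digest(self) -> str:
        """Hash of the analysis-relevant configuration (output location
        excluded, so reruns into different directories compare equal)."""
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def _header(config: RunConfig) -> str:
    return (
        f"# mlpagcr {__version__} | seed={config.seed} | config={config.digest()}\n"
    )


def write_copy_number_tsv(matrix: CopyNumberMatrix, path: str | Path,
                          config: RunConfig | None = None) -> None:
    with open(path, "w") as fh:
        if config is not None:
            fh.write(_header(config))
        matrix.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.4f")


def write_classification_tsv(classifications, path: str | Path,
                             config: RunConfig | None = None) -> None:
    rows = [
        {
            "isolate": c.isolate,
            "status": c.status.value,
            "assay_deletion": c.has_assay_deletion,
            "arm_duplications": ",".join(c.arm_duplications) or ".",
            "whole_chromosome_duplications": ",".join(c.whole_chromosome_duplications) or ".",
            "events": c.event_notation(),
        }
        for c in classifications
    ]
    with open(path, "w") as fh:
        if config is not None:
            fh.write(_header(config))
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute call -> classify -> summarize and write the report bundle.

    Returns a dict with the in-memory results; writes the copy-number
    matrix, the per-isolate classification table and the cohort summary
    JSON under ``config.out_dir``.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    annotation = load_annotation(
        config.annotation_path, config.annotation_dialect, config.chromosomes_path
    )
    telomeric = read_probeset_tsv(config.telomeric_probes_path)
    centromeric = (
        read_probeset_tsv(config.centromeric_probes_path)
        if config.centromeric_probes_path
        else None
    )
    samples = read_peak_table(config.peaks_path)
    logger.info("loaded %d samples (%d controls)", len(samples),
                sum(s.is_control for s in samples))

    if centromeric is not None:
        # call both panels separately, then join per isolate
        tel_samples = [_subset_panel(s, telomeric) for s in samples]
        cen_samples = [_subset_panel(s, centromeric) for s in samples]
        tel_matrix = call_copy_numbers(
            tel_samples, telomeric, config.normalization_mode,
            tolerance=config.ambiguity_tolerance,
        )
        cen_matrix = call_copy_numbers(
            cen_samples, centromeric, config.normalization_mode,
            tolerance=config.ambiguity_tolerance,
        )
        matrix = CopyNumberMatrix(
            ratios=tel_matrix.ratios.join(cen_matrix.ratios),
            calls=tel_matrix.calls.join(cen_matrix.calls),
            flags=tel_matrix.flags.join(cen_matrix.flags),
            probeset=telomeric,
        )
    else:
        matrix = call_copy_numbers(
            samples, telomeric, config.normalization_mode,
            tolerance=config.ambiguity_tolerance,
        )
    logger.info("called %d isolates x %d probes", *matrix.calls.shape)

    classifications = classify_matrix(
        matrix, telomeric, annotation, centromeric, config.assay_arm
    )
    summary = summarize_cohort(classifications)
    logger.info(
        "cohort: n=%d deletions=%d arm-dups=%d no-dup=%d ambiguous=%d",
        summary.n, summary.n_assay_deletions, summary.n_arm_duplication_isolates,
        summary.n_no_duplication, summary.n_ambiguous,
    )

    write_copy_number_tsv(matrix, out_dir / "copy_numbers.tsv", config)
    write_classification_tsv(classifications, out_dir / "classifications.tsv", config)
    with open(out_dir / "cohort_summary.json", "w") as fh:
        json.dump(
            {"seed": config.seed, "config": config.digest(),
             "summary": summary.to_dict()},
            fh, indent=2,
        )
    return {
        "matrix": matrix,
        "classifications": classifications,
        "summary": summary,
    }


def _subset_panel(sample: PeakTable, panel: ProbeSet) -> PeakTable:
    """Keep only the peaks matching a panel's product-length range."""
    lengths = [p.product_length for p in panel]
    lo, hi = min(lengths) - 1, max(lengths) + 1
    return PeakTable(
        sample.sample_id,
        [(s, a) for s, a in sample.peaks if lo <= s <= hi],
        sample.is_control,
    )
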