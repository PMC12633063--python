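"""End-to-end orchestration: filter -> annotate -> quantify -> normalize -> test.

The pipeline is a deterministic composition of the stage operations; a
machine-readable manifest records counts at each stage, input digests and
the configuration hash so a run can be audited and reproduced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import annotate_scan
from .proteoform_quant import (
    SpectrumQuant,
    filter_psms,
    psms_by_scan,
    spectrum_abundance,
    subdivide_by_psm_count,
)
from .reporter_stats import (
    ProteoformGroupResult,
    build_reporter_matrix,
    channel_normalize,
    coverage_mask,
    group_and_test,
)
from .spectra_io import PSMRecord, RunConfig, Spectrum

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "PipelineResult", "run_pipeline"]


@dataclass
class RunManifest:
    config_digest: str
    seed: int
    software_version: str
    input_digests: dict[str, str] = field(default_factory=dict)
    psms_in: int = 0
    psms_kept: int = 0
    scans_with_kept_psm: int = 0
    scans_quantified: int = 0
    scans_coverage_pass: int = 0
    groups_tested: int = 0
    psm_count_partition: dict[int, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        data = dataclasses.asdict(self)
        data["psm_count_partition"] = {
            str(k): v for k, v in data["psm_count_partition"].items()
        }
        text = json.dumps(data, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class PipelineResult:
    results: list[ProteoformGroupResult]
    scan_quants: list[SpectrumQuant]
    reporter_log2: pd.DataFrame
    manifest: RunManifest


def _digest_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(
    spectra: list[Spectrum],
    psms: list[PSMRecord],
    config: RunConfig | None = None,
    *,
    strict: bool = False,
    input_paths: dict[str, str | Path] | None = None,
) -> PipelineResult:
    """Run the full quantification on in-memory spectra and PSMs.

    Stages: (1) PSM confidence filtering; (2) subdivision of scans by PSM
    count, dropping scans with more candidates than the acquisition's
    precursor cap; (3) fragment annotation with isotope confirmation and
    per-scan proteoform abundance; (4) reporter extraction over all scans
    with a kept PSM, channel normalization, log2 transform and the
    per-condition coverage filter; (5) proteoform grouping, log2 fold
    changes and two-sided Welch t-tests.
    """
    config = config or RunConfig()
    manifest = RunManifest(
        config_digest=config.digest(),
        seed=config.seed,
        software_version=__version__,
    )
    for name, path in (input_paths or {}).items():
        manifest.input_digests[name] = _digest_file(path)

    def warn(msg: str):
        if strict:
            raise RuntimeError(msg)
        logger.warning(msg)
        manifest.warnings.append(msg)

    spectra_by_id = {s.scan_id: s for s in spectra}
    manifest.psms_in = len(psms)

    kept, rejected = filter_psms(psms, config)
    manifest.psms_kept = len(kept)
    logger.info("PSM filter: kept %d / %d", len(kept), len(psms))

    missing = [r.scan_id for r in kept if r.scan_id not in spectra_by_id]
    if missing:
        warn(f"{len(missing)} kept PSMs reference scans absent from the spectra")
        kept = [r for r in kept if r.scan_id in spectra_by_id]

    partition = subdivide_by_psm_count(kept)
    manifest.psm_count_partition = {n: len(s) for n, s in sorted(partition.items())}
    by_scan = psms_by_scan(kept)
    overloaded = {
        sid for sid, recs in by_scan.items() if len(recs) > config.max_psms_per_scan
    }
    if overloaded:
        warn(
            f"{len(overloaded)} scans exceed {config.max_psms_per_scan} candidate "
            "PSMs and were excluded"
        )
        by_scan = {sid: r for sid, r in by_scan.items() if sid not in overloaded}
    manifest.scans_with_kept_psm = len(by_scan)

    scan_quants: list[SpectrumQuant] = []
    for sid in sorted(by_scan):
        annotations = annotate_scan(spectra_by_id[sid], by_scan[sid], config)
        sq = spectrum_abundance(annotations, by_scan[sid], sid, config)
        scan_quants.append(sq)
    quantifiable = [sq for sq in scan_quants if sq.quantifiable]
    manifest.scans_quantified = len(quantifiable)
    logger.info(
        "quantified %d / %d scans", len(quantifiable), len(scan_quants)
    )

    if not by_scan:
        return PipelineResult([], scan_quants, pd.DataFrame(), manifest)

    # reporter matrix over every scan with a kept PSM (normalization means
    # are taken over this full set), then coverage-filter for grouping
    raw = build_reporter_matrix(spectra_by_id, sorted(by_scan), config)
    normalized = channel_normalize(raw)
    covered = coverage_mask(raw, config)
    manifest.scans_coverage_pass = int(covered.sum())
    with np.errstate(divide="ignore"):
        log2_matrix = np.log2(normalized[covered])

    results = group_and_test(quantifiable, log2_matrix, config)
    manifest.groups_tested = len(results)
    logger.info("tested %d proteoform groups", len(results))
    return PipelineResult(results, scan_quants, log2_matrix, manifest)
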