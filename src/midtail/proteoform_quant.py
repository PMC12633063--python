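"""PSM filtering and per-spectrum proteoform abundance.

A proteoform's abundance in a scan is the annotated fragment-ion intensity
attributable to it alone, divided by the total annotated fragment-ion
intensity of all candidate proteoforms.  In chimeric scans (several
co-isolated precursors, typically positional isomers) the intensity of
fragment ions shared between candidates is divided equally among them.
Only isotope-confirmed, non-reporter annotations enter the calculation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .annotation import PeakAnnotation
from .spectra_io import PSMRecord, RunConfig

__all__ = [
    "SpectrumQuant",
    "filter_psms",
    "subdivide_by_psm_count",
    "spectrum_abundance",
]


@dataclass
class SpectrumQuant:
    """Per-scan proteoform abundance fractions."""

    scan_id: str
    fractions: dict[str, float]
    total_intensity: float
    n_psms: int
    quantifiable: bool = True


def filter_psms(
    records: list[PSMRecord], config: RunConfig
) -> tuple[list[PSMRecord], list[PSMRecord]]:
    """Keep high-confidence PSMs: PEP <= pep_max and delta >= delta_min.

    Both thresholds are inclusive (a record at exactly PEP 0.05 and delta
    10 is kept).  Returns (kept, rejected); their union is the input.
    """
    kept, rejected = [], []
    for r in records:
        if r.pep <= config.pep_max and r.delta_mod_score >= config.delta_min:
            kept.append(r)
        else:
            rejected.append(r)
    return kept, rejected


def subdivide_by_psm_count(kept: list[PSMRecord]) -> dict[int, set[str]]:
    """Partition scan ids by how many kept PSMs each scan carries."""
    per_scan: dict[str, int] = {}
    for r in kept:
        per_scan[r.scan_id] = per_scan.get(r.scan_id, 0) + 1
    partition: dict[int, set[str]] = {}
    for scan_id, n in per_scan.items():
        partition.setdefault(n, set()).add(scan_id)
    return partition


def psms_by_scan(kept: list[PSMRecord]) -> dict[str, list[PSMRecord]]:
    by_scan: dict[str, list[PSMRecord]] = {}
    for r in kept:
        by_scan.setdefault(r.scan_id, []).append(r)
    return by_scan


def spectrum_abundance(
    annotations: list[PeakAnnotation],
    psms_for_scan: list[PSMRecord],
    scan_id: str | None = None,
    config: RunConfig | None = None,
) -> SpectrumQuant:
    """Apportion confirmed annotated intensity among a scan's proteoforms.

    credit(P) = sum of unique(P) peak intensities
              + sum over shared peaks containing P of intensity / |shared set|
    fraction(P) = credit(P) / sum of credits.

    Credited intensity is conserved: the credits sum to the total confirmed
    annotated fragment intensity.  A proteoform with no credited intensity
    keeps fraction 0.  A scan with zero confirmed intensity is flagged
    unquantifiable (fractions undefined -> all zero, excluded downstream).
    """
    require_confirmed = config.require_isotope_confirmation if config else True
    keys = sorted({psm.proteoform.key for psm in psms_for_scan})
    if scan_id is None:
        scan_id = psms_for_scan[0].scan_id if psms_for_scan else ""
    credits = {k: 0.0 for k in keys}
    total = 0.0
    for ann in annotations:
        if ann.is_reporter or not ann.proteoforms:
            continue
        if require_confirmed and not ann.isotope_confirmed:
            continue
        members = [k for k in ann.proteoforms if k in credits]
        if not members:
            continue
        share = ann.intensity / len(members)
        for k in members:
            credits[k] += share
        total += ann.intensity
    if total <= 0:
        return SpectrumQuant(
            scan_id, {k: 0.0 for k in keys}, 0.0, len(psms_for_scan), quantifiable=False
        )
    fractions = {k: credits[k] / total for k in keys}
    return SpectrumQuant(scan_id, fractions, total, len(psms_for_scan))
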