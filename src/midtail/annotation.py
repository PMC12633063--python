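"""EThcD fragment-ion annotation of MS2 scans.

For each scan, theoretical a/b/c/y/z ions (with optional neutral losses) are
generated for every candidate proteoform assigned to the scan, matched to
observed peaks within a ppm tolerance, confirmed by the presence of a heavy
isotope (A+1) peak, and classified as unique to one proteoform or shared
between several — the classification that drives chimeric-spectrum
intensity apportionment downstream.

TMT reporter-region peaks are flagged and excluded from fragment matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem_core import fragment_mz, ppm_error
from .spectra_io import PSMRecord, RunConfig, Spectrum

__all__ = [
    "TheoreticalIon",
    "PeakAnnotation",
    "generate_ion_sets",
    "match_peaks",
    "confirm_heavy_isotope",
    "attribute",
    "annotate_scan",
]


@dataclass(frozen=True)
class TheoreticalIon:
    proteoform_key: str
    series: str
    index: int
    charge: int
    neutral_loss: str | None
    mz: float

    @property
    def label(self) -> str:
        loss = f"-{self.neutral_loss}" if self.neutral_loss else ""
        return f"{self.series}{self.index}{loss}^{self.charge}"


@dataclass
class PeakAnnotation:
    """An observed peak bound to the theoretical ions it matches."""

    peak_index: int
    mz: float
    intensity: float
    ions: tuple[TheoreticalIon, ...]
    ppm_errors: tuple[float, ...]
    is_reporter: bool = False
    isotope_confirmed: bool | None = None
    proteoforms: frozenset[str] = frozenset()

    @property
    def is_unique(self) -> bool:
        return len(self.proteoforms) == 1


def generate_ion_sets(
    psms_for_scan: list[PSMRecord],
    config: RunConfig,
    max_charge: int | None = None,
) -> list[TheoreticalIon]:
    """All theoretical fragment ions of a scan's candidate proteoforms.

    Series from config (default a, b, c, y, z), indices 1..n-1, charges 1 up
    to min(precursor charge - 1, config cap) — pass the scan-derived cap as
    ``max_charge`` — each with and without every configured neutral loss.
    Ion sets are generated per distinct proteoform key, so two PSMs claiming
    the same proteoform contribute one set.
    """
    if not psms_for_scan:
        return []
    if max_charge is None:
        max_charge = config.max_fragment_charge
    if max_charge < 1:
        return []
    ions: list[TheoreticalIon] = []
    seen: set[str] = set()
    for psm in psms_for_scan:
        p = psm.proteoform
        key = p.key
        if key in seen:
            continue
        seen.add(key)
        ions.extend(_proteoform_ions(p, config, max_charge))
    return ions


_ION_CACHE: dict[tuple, tuple[TheoreticalIon, ...]] = {}


def _proteoform_ions(p, config: RunConfig, max_charge: int) -> tuple[TheoreticalIon, ...]:
    cache_key = (
        p.key,
        p.backbone,
        tuple(config.fragment_series),
        tuple(sorted(config.neutral_losses)),
        max_charge,
    )
    cached = _ION_CACHE.get(cache_key)
    if cached is not None:
        return cached
    key = p.key
    n = len(p.sequence)
    losses: list[tuple[str | None, dict | None]] = [(None, None)]
    losses += [(name, comp) for name, comp in config.neutral_losses.items()]
    ions: list[TheoreticalIon] = []
    for series in config.fragment_series:
        for index in range(1, n):
            for charge in range(1, max_charge + 1):
                for loss_name, loss_comp in losses:
                    ions.append(
                        TheoreticalIon(
                            key,
                            series,
                            index,
                            charge,
                            loss_name,
                            fragment_mz(p, series, index, charge, loss_comp),
                        )
                    )
    result = tuple(ions)
    if len(_ION_CACHE) > 4096:
        _ION_CACHE.clear()
    _ION_CACHE[cache_key] = result
    return result


def charge_range_for_scan(spectrum: Spectrum, config: RunConfig) -> int:
    """Fragment charges considered: 1..min(precursor charge - 1, cap).

    A scan with unknown precursor charge (0) falls back to the config cap.
    """
    if spectrum.precursor_charge <= 0:
        return config.max_fragment_charge
    return min(spectrum.precursor_charge - 1, config.max_fragment_charge)


def match_peaks(
    spectrum: Spectrum,
    ions: list[TheoreticalIon],
    config: RunConfig,
) -> list[PeakAnnotation]:
    """Match theoretical ions to observed peaks within the ppm tolerance.

    Each ion is assigned to its best in-tolerance peak (smallest |ppm|,
    ties to the higher intensity); each peak carries all ions assigned to
    it, so a peak is annotated at most once.  The tolerance is inclusive.
    Reporter-region peaks are flagged and never matched to fragments.
    """
    mz = spectrum.mz
    inten = spectrum.intensity
    lo_rep, hi_rep = config.reporter_region
    reporter_mask = (mz >= lo_rep) & (mz <= hi_rep)
    tol = config.fragment_tol_ppm

    # inclusive boundary with a nano-ppm guard against float rounding of
    # peaks constructed at exactly +/- tol
    tol_eps = tol + 1e-9
    assigned: dict[int, list[tuple[TheoreticalIon, float]]] = {}
    for ion in ions:
        delta = ion.mz * tol_eps * 1e-6
        lo = np.searchsorted(mz, ion.mz - delta, side="left")
        hi = np.searchsorted(mz, ion.mz + delta, side="right")
        best: int | None = None
        best_ppm = None
        for j in range(lo, hi):
            if reporter_mask[j]:
                continue
            err = ppm_error(mz[j], ion.mz)
            if abs(err) > tol_eps:
                continue
            if (
                best is None
                or abs(err) < abs(best_ppm)
                or (abs(err) == abs(best_ppm) and inten[j] > inten[best])
            ):
                best, best_ppm = j, err
        if best is not None:
            assigned.setdefault(best, []).append((ion, best_ppm))

    annotations = [
        PeakAnnotation(
            peak_index=j,
            mz=float(mz[j]),
            intensity=float(inten[j]),
            ions=tuple(ion for ion, _ in matches),
            ppm_errors=tuple(err for _, err in matches),
        )
        for j, matches in sorted(assigned.items())
    ]
    # reporter peaks surface as annotations too (flagged, no ions) so the
    # per-scan dump shows them; they never enter fragment quantification
    for j in np.nonzero(reporter_mask)[0]:
        annotations.append(
            PeakAnnotation(
                peak_index=int(j),
                mz=float(mz[j]),
                intensity=float(inten[j]),
                ions=(),
                ppm_errors=(),
                is_reporter=True,
            )
        )
    annotations.sort(key=lambda a: a.peak_index)
    return annotations


def confirm_heavy_isotope(
    spectrum: Spectrum, annotation: PeakAnnotation, config: RunConfig
) -> bool:
    """True iff a peak sits one heavy-isotope spacing above the annotated peak.

    The expected A+1 position is the observed peak m/z plus spacing/charge
    for any matched ion's charge, within the fragment ppm tolerance.  The
    default spacing is the 13C gap (1.003355 Da); large peptide fragments'
    A+1 peaks are dominated by 13C even though other one-neutron
    substitutions (15N) land within tolerance anyway.
    """
    if annotation.is_reporter or not annotation.ions:
        return False
    mz = spectrum.mz
    tol = config.fragment_tol_ppm
    charges = {ion.charge for ion in annotation.ions}
    for charge in charges:
        for spacing in config.isotope_spacings:
            expected = annotation.mz + spacing / charge
            delta = expected * tol * 1e-6
            lo = np.searchsorted(mz, expected - delta, side="left")
            hi = np.searchsorted(mz, expected + delta, side="right")
            if hi > lo:
                return True
    return False


def attribute(
    annotations: list[PeakAnnotation], psms_for_scan: list[PSMRecord]
) -> list[PeakAnnotation]:
    """Set each annotation's proteoform attribution (unique vs shared).

    An annotation is unique when all its matched ions belong to a single
    candidate proteoform; otherwise it is shared among every proteoform
    with an in-tolerance ion on that peak.
    """
    candidate_keys = {psm.proteoform.key for psm in psms_for_scan}
    for ann in annotations:
        keys = frozenset(ion.proteoform_key for ion in ann.ions) & frozenset(
            candidate_keys
        )
        ann.proteoforms = keys
    return annotations


def annotate_scan(
    spectrum: Spectrum, psms_for_scan: list[PSMRecord], config: RunConfig
) -> list[PeakAnnotation]:
    """Generate, match, isotope-confirm and attribute in one pass."""
    ions = generate_ion_sets(
        psms_for_scan, config, max_charge=charge_range_for_scan(spectrum, config)
    )
    annotations = match_peaks(spectrum, ions, config)
    for ann in annotations:
        if not ann.is_reporter and ann.ions:
            ann.isotope_confirmed = confirm_heavy_isotope(spectrum, ann, config)
    return attribute(annotations, psms_for_scan)


def annotation_table(scan_id: str, annotations: list[PeakAnnotation]):
    """Per-scan annotation dump rows (for the optional debug TSV)."""
    import pandas as pd

    rows = []
    for ann in annotations:
        if ann.is_reporter:
            rows.append(
                dict(scan_id=scan_id, mz=ann.mz, intensity=ann.intensity,
                     ion="reporter", ppm=np.nan, confirmed=False, attribution="")
            )
            continue
        for ion, err in zip(ann.ions, ann.ppm_errors):
            rows.append(
                dict(
                    scan_id=scan_id,
                    mz=ann.mz,
                    intensity=ann.intensity,
                    ion=f"{ion.proteoform_key}:{ion.label}",
                    ppm=err,
                    confirmed=bool(ann.isotope_confirmed),
                    attribution="unique" if ann.is_unique else "shared",
                )
            )
    return pd.DataFrame(
        rows, columns=["scan_id", "mz", "intensity", "ion", "ppm", "confirmed", "attribution"]
    )
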