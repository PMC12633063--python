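"""Ground-truth simulation of middle-down H3 tail experiments.

Emulates the acquisition this pipeline targets: charge-8 precursors of
TMT-labeled 36-mer H3 tails in the 480-540 m/z selection window, c/z-
dominant EThcD fragment spectra with carbon-binomial isotope envelopes,
TMT 6-plex reporter ions with condition-wise fold changes and
multiplicative log-normal noise, chimeric co-isolation of positional
isomers (up to 5 co-isolates), and a PSM table containing true assignments
plus decoy rows that fail the confidence filters.

Intensity conventions
---------------------
A proteoform's total monoisotopic fragment current in a scan is
proportional to its precursor mixing fraction: the per-scan budget is
split over its emitted ions by series weight (then jittered and dropped
by the noise model).  Isotope peaks are appended at binomial envelope
ratios relative to each monoisotopic peak.  Reporter intensities are equal
across channels before fold changes, mirroring a 1:1:1:1:1:1 6-plex mix.

``unique_ions_only`` restricts emission to fragment ions that discriminate
the co-isolated proteoforms — ions (including their isotope peaks) that
collide with the partner's theoretical ion set, or with any other emitted
peak, are withheld.  This isolates the shared-intensity apportionment
arithmetic from the structural bias equal splitting of heavily shared ion
sets would otherwise impose; see the methods note.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import generate_ion_sets
from .chem_core import (
    MODIFICATIONS,
    Proteoform,
    RESIDUE_COMPOSITIONS,
    TMT6PLEX_COMPOSITION,
    ISOTOPE_SPACING_13C,
    ABUNDANCE_13C,
    fragment_mz,
    parse_proteoform_key,
    precursor_mz,
)
from .spectra_io import PSMRecord, RunConfig, Spectrum

__all__ = [
    "SimulationDesign",
    "GroundTruth",
    "ReporterExperiment",
    "simulate_experiment",
    "simulate_reporter_experiment",
    "make_fixture",
    "FIXTURES",
]

PRECURSOR_WINDOW = (480.0, 540.0)


@dataclass
class SimulationDesign:
    """Everything that defines a simulated experiment.

    ``proteoforms`` carries (key, global abundance) pairs; ``fold_changes``
    maps proteoform key -> condition -> linear fold change (default 1).
    Fragment noise: ``dropout`` is the per-ion omission probability,
    ``intensity_cv`` the log-normal sigma (natural log) of per-ion jitter.
    Reporter noise: ``reporter_sigma`` is the log-normal sigma of the
    multiplicative channel noise; ``brightness_sigma`` a per-scan common
    brightness jitter.  A fixed ``seed`` fixes all randomness.
    """

    proteoforms: list[tuple[str, float]]
    n_scans: int = 100
    fold_changes: dict[str, dict[str, float]] = field(default_factory=dict)
    chimera_prob: float = 0.0
    max_coisolates: int = 2
    mixture: tuple[float, ...] | None = None
    fragment_series: dict[str, float] = field(
        default_factory=lambda: {"c": 1.0, "z": 1.0, "a": 0.2, "b": 0.2, "y": 0.3}
    )
    fragment_charges: tuple[int, ...] = (1, 2)
    n_isotope_peaks: int = 3
    base_fragment_intensity: float = 1.0e5
    dropout: float = 0.0
    intensity_cv: float = 0.0
    chaff_peaks: int = 0
    reporter_base: float = 1.0e4
    reporter_sigma: float = 0.0
    brightness_sigma: float = 0.0
    decoy_rate: float = 0.0
    precursor_charge: int = 8
    unique_ions_only: bool = False
    backbone: str = "H3.1"
    seed: int = 0

    def __post_init__(self):
        if not self.proteoforms:
            raise ValueError("design needs at least one proteoform")
        if not 0.0 <= self.chimera_prob <= 1.0:
            raise ValueError("chimera_prob must be in [0, 1]")
        if not 1 <= self.max_coisolates <= 5:
            raise ValueError("max_coisolates must be in 1..5")
        for _, abundance in self.proteoforms:
            if abundance <= 0:
                raise ValueError("abundances must be > 0")


@dataclass
class GroundTruth:
    """True per-scan composition and per-proteoform fold changes."""

    scan_fractions: dict[str, dict[str, float]]
    fold_changes: dict[str, dict[str, float]]
    true_records: list[PSMRecord]
    decoy_records: list[PSMRecord]


@dataclass
class ReporterExperiment:
    """A reporter-level simulation (no fragment spectra).

    ``matrix`` holds raw linear reporter intensities (scans x channels);
    ``scan_groups`` maps each scan to its proteoform group and
    ``true_log2fc`` records each group's designed log2 fold change for the
    config's (treated, control) contrast.
    """

    matrix: pd.DataFrame
    scan_groups: dict[str, str]
    true_log2fc: dict[str, float]
    config: RunConfig


# ---------------------------------------------------------------------------
# fragment-level helpers


def _fragment_carbons(p: Proteoform, series: str, index: int) -> int:
    """Light-carbon count of a backbone fragment (drives the A+1 envelope)."""
    seq = p.sequence
    n = len(seq)
    if series in ("a", "b", "c"):
        residues = range(1, index + 1)
    else:
        residues = range(n - index + 1, n + 1)
    placements = p.placement_map
    carbons = 0
    for i in residues:
        carbons += RESIDUE_COMPOSITIONS[seq[i - 1]].get("C", 0)
        spec = placements.get(i)
        if spec is not None and spec.composition is not None:
            carbons += spec.composition.get("C", 0)
        if seq[i - 1] == "H":
            carbons += TMT6PLEX_COMPOSITION["C"]
    if series == "a":
        carbons -= 1
    return carbons


def _envelope_ratios(n_carbons: int, n_peaks: int) -> np.ndarray:
    """Intensity of A+k relative to the monoisotopic peak."""
    p = ABUNDANCE_13C
    ratios = [1.0]
    prev = 1.0
    for k in range(1, n_peaks):
        # binomial pmf ratio: C(n,k)p^k q^(n-k) / C(n,k-1)...
        prev *= (n_carbons - k + 1) / k * (p / (1 - p))
        ratios.append(prev)
    return np.asarray(ratios)


@dataclass(frozen=True)
class _SimIon:
    series: str
    index: int
    charge: int
    mz: float
    weight: float
    carbons: int


def _sim_ion_set(p: Proteoform, design: SimulationDesign) -> list[_SimIon]:
    ions = []
    n = len(p.sequence)
    for series, weight in design.fragment_series.items():
        if weight <= 0:
            continue
        for index in range(1, n):
            carbons = _fragment_carbons(p, series, index)
            for charge in design.fragment_charges:
                ions.append(
                    _SimIon(
                        series,
                        index,
                        charge,
                        fragment_mz(p, series, index, charge),
                        weight,
                        carbons,
                    )
                )
    return ions


def _theory_mz_universe(
    proteoform: Proteoform, config: RunConfig, max_charge: int
) -> np.ndarray:
    """All annotation-side theoretical ion m/z of a proteoform (for the
    unique-ion collision filter)."""
    psm = PSMRecord(scan_id="_", proteoform=proteoform, pep=0.0, delta_mod_score=99.0)
    ions = generate_ion_sets([psm], config, max_charge=max_charge)
    return np.sort(np.asarray([ion.mz for ion in ions]))


def _within_ppm(sorted_mz: np.ndarray, value: float, ppm: float) -> int:
    delta = value * ppm * 1e-6
    lo = np.searchsorted(sorted_mz, value - delta, side="left")
    hi = np.searchsorted(sorted_mz, value + delta, side="right")
    return hi - lo


def _discriminating_ions(
    proteoforms: list[Proteoform],
    design: SimulationDesign,
    config: RunConfig,
) -> dict[str, list[_SimIon]]:
    """Per proteoform, emitted ions that cannot be confused with any other
    co-isolated proteoform nor with each other's isotope peaks.

    Guard band: 3x the fragment tolerance around every theoretical ion of
    the partners (full annotation universe, losses included) and around
    every other emitted envelope peak.
    """
    guard = 3.0 * config.fragment_tol_ppm
    max_charge = min(design.precursor_charge - 1, config.max_fragment_charge)
    universes = {
        p.key: _theory_mz_universe(p, config, max_charge) for p in proteoforms
    }
    candidates: dict[str, list[_SimIon]] = {}
    for p in proteoforms:
        others = [universes[q.key] for q in proteoforms if q.key != p.key]
        keep = []
        for ion in _sim_ion_set(p, design):
            peaks = ion.mz + np.arange(design.n_isotope_peaks) * (
                ISOTOPE_SPACING_13C / ion.charge
            )
            collides = any(
                _within_ppm(u, mz, guard) > 0 for u in others for mz in peaks
            )
            if not collides:
                keep.append(ion)
        candidates[p.key] = keep

    # pairwise collisions among all emitted envelope peaks (both proteoforms)
    entries = []  # (key, ion_idx, mz)
    for key, ions in candidates.items():
        for i, ion in enumerate(ions):
            for k in range(design.n_isotope_peaks):
                entries.append((key, i, ion.mz + k * ISOTOPE_SPACING_13C / ion.charge))
    entries.sort(key=lambda t: t[2])
    drop: set[tuple[str, int]] = set()
    for a in range(len(entries)):
        key_a, ia, mz_a = entries[a]
        for b in range(a + 1, len(entries)):
            key_b, ib, mz_b = entries[b]
            if (mz_b - mz_a) / mz_a * 1e6 > guard:
                break
            if (key_a, ia) != (key_b, ib):
                drop.add((key_a, ia))
                drop.add((key_b, ib))
    return {
        key: [ion for i, ion in enumerate(ions) if (key, i) not in drop]
        for key, ions in candidates.items()
    }


def _merge_peaks(mz: np.ndarray, intensity: np.ndarray, tol_da: float = 0.002):
    if mz.size == 0:
        return mz, intensity
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    out_mz, out_int = [mz[0]], [intensity[0]]
    for m, i in zip(mz[1:], intensity[1:]):
        if m - out_mz[-1] <= tol_da:
            # intensity-weighted centroid of coincident peaks
            total = out_int[-1] + i
            out_mz[-1] = (out_mz[-1] * out_int[-1] + m * i) / total
            out_int[-1] = total
        else:
            out_mz.append(m)
            out_int.append(i)
    return np.asarray(out_mz), np.asarray(out_int)


# ---------------------------------------------------------------------------
# full simulation


def simulate_experiment(
    design: SimulationDesign, config: RunConfig | None = None
) -> tuple[list[Spectrum], list[PSMRecord], GroundTruth]:
    """Simulate spectra + PSM table + ground truth for a design.

    Deterministic under a fixed ``design.seed``.  PSM rows for the true
    proteoforms carry passing scores (PEP <= 0.05, delta >= 10); decoy rows
    are added at ``decoy_rate`` per scan and always fail one filter.
    """
    config = config or RunConfig()
    rng = np.random.default_rng(design.seed)
    proteoforms = {
        key: parse_proteoform_key(key, design.backbone)
        for key, _ in design.proteoforms
    }
    abundances = np.asarray([a for _, a in design.proteoforms], float)
    abundances = abundances / abundances.sum()
    keys = [key for key, _ in design.proteoforms]

    for key in keys:
        mz8 = precursor_mz(proteoforms[key], design.precursor_charge)
        if not PRECURSOR_WINDOW[0] <= mz8 <= PRECURSOR_WINDOW[1]:
            warnings.warn(
                f"{key}: precursor {mz8:.3f} m/z at charge "
                f"{design.precursor_charge} outside the "
                f"{PRECURSOR_WINDOW[0]:.0f}-{PRECURSOR_WINDOW[1]:.0f} selection window"
            )

    combo_cache: dict[frozenset, dict[str, list[_SimIon]]] = {}
    single_cache: dict[str, list[_SimIon]] = {}

    def ions_for(combo: tuple[str, ...]) -> dict[str, list[_SimIon]]:
        if design.unique_ions_only and len(combo) > 1:
            fkey = frozenset(combo)
            if fkey not in combo_cache:
                combo_cache[fkey] = _discriminating_ions(
                    [proteoforms[k] for k in combo], design, config
                )
            return combo_cache[fkey]
        for key in combo:
            if key not in single_cache:
                single_cache[key] = _sim_ion_set(proteoforms[key], design)
        return {key: single_cache[key] for key in combo}

    channel_mz = config.reporter_channels
    channel_cond = config.channel_conditions

    spectra: list[Spectrum] = []
    true_records: list[PSMRecord] = []
    decoy_records: list[PSMRecord] = []
    scan_fractions: dict[str, dict[str, float]] = {}

    for scan_no in range(design.n_scans):
        scan_id = f"S{scan_no + 1:05d}"
        chimeric = len(keys) > 1 and rng.random() < design.chimera_prob
        if chimeric:
            k = int(rng.integers(2, design.max_coisolates + 1))
            k = min(k, len(keys))
            chosen = tuple(
                rng.choice(len(keys), size=k, replace=False, p=abundances)
            )
            combo = tuple(keys[i] for i in chosen)
            if design.mixture is not None:
                if len(design.mixture) != len(combo):
                    raise ValueError("mixture length must equal co-isolate count")
                fractions = np.asarray(design.mixture, float)
            else:
                fractions = rng.dirichlet(np.full(len(combo), 2.0))
        else:
            combo = (keys[int(rng.choice(len(keys), p=abundances))],)
            fractions = np.asarray([1.0])
        fractions = fractions / fractions.sum()
        scan_fractions[scan_id] = dict(zip(combo, fractions))

        ions_by_key = ions_for(combo)
        peak_mz: list[float] = []
        peak_int: list[float] = []
        for key, fraction in zip(combo, fractions):
            ions = ions_by_key[key]
            if not ions:
                continue
            weights = np.asarray([ion.weight for ion in ions])
            weights = weights / weights.sum()
            budget = design.base_fragment_intensity * fraction
            jitter = (
                np.exp(rng.normal(0.0, design.intensity_cv, len(ions)))
                if design.intensity_cv > 0
                else np.ones(len(ions))
            )
            keep = (
                rng.random(len(ions)) >= design.dropout
                if design.dropout > 0
                else np.ones(len(ions), bool)
            )
            for ion, w, j, kept in zip(ions, weights, jitter, keep):
                if not kept:
                    continue
                mono = budget * w * j
                ratios = _envelope_ratios(ion.carbons, design.n_isotope_peaks)
                for kk, ratio in enumerate(ratios):
                    peak_mz.append(ion.mz + kk * ISOTOPE_SPACING_13C / ion.charge)
                    peak_int.append(mono * ratio)

        # reporter ions: equal base across channels, scaled by the scan's
        # mixture-weighted condition fold change, with log-normal noise
        brightness = (
            math.exp(rng.normal(0.0, design.brightness_sigma))
            if design.brightness_sigma > 0
            else 1.0
        )
        for channel, mz in channel_mz.items():
            cond = channel_cond[channel][0]
            fc = sum(
                frac * design.fold_changes.get(key, {}).get(cond, 1.0)
                for key, frac in zip(combo, fractions)
            )
            noise = (
                math.exp(rng.normal(0.0, design.reporter_sigma))
                if design.reporter_sigma > 0
                else 1.0
            )
            peak_mz.append(mz)
            peak_int.append(design.reporter_base * brightness * fc * noise)

        if design.chaff_peaks > 0:
            n_frag = max(len(peak_mz) - len(channel_mz), 1)
            mean_int = float(np.sum(peak_int)) / n_frag
            for _ in range(design.chaff_peaks):
                peak_mz.append(float(rng.uniform(150.0, 2000.0)))
                peak_int.append(float(rng.uniform(0.05, 0.5)) * mean_int)

        mz_arr, int_arr = _merge_peaks(np.asarray(peak_mz), np.asarray(peak_int))
        spectra.append(
            Spectrum(
                scan_id,
                precursor_mz(proteoforms[combo[0]], design.precursor_charge),
                design.precursor_charge,
                mz_arr,
                int_arr,
            )
        )

        for key in combo:
            true_records.append(
                PSMRecord(
                    scan_id=scan_id,
                    proteoform=proteoforms[key],
                    pep=float(rng.uniform(0.0, 0.05)),
                    delta_mod_score=float(rng.uniform(10.0, 60.0)),
                )
            )
        if rng.random() < design.decoy_rate:
            decoy_key = keys[int(rng.integers(len(keys)))]
            if rng.random() < 0.5:
                pep, delta = float(rng.uniform(0.0500001, 0.5)), float(
                    rng.uniform(10.0, 60.0)
                )
            else:
                pep, delta = float(rng.uniform(0.0, 0.05)), float(
                    rng.uniform(0.0, 9.999)
                )
            decoy_records.append(
                PSMRecord(
                    scan_id=scan_id,
                    proteoform=proteoforms[decoy_key],
                    pep=pep,
                    delta_mod_score=delta,
                )
            )

    truth = GroundTruth(
        scan_fractions=scan_fractions,
        fold_changes={k: dict(v) for k, v in design.fold_changes.items()},
        true_records=true_records,
        decoy_records=decoy_records,
    )
    return spectra, true_records + decoy_records, truth


# ---------------------------------------------------------------------------
# reporter-level simulation


def simulate_reporter_experiment(
    group_log2fc: dict[str, float],
    scans_per_group: int,
    config: RunConfig | None = None,
    sigma: float = 0.3,
    brightness_sigma: float = 0.0,
    base: float = 1.0e4,
    seed: int = 0,
) -> ReporterExperiment:
    """Simulate reporter matrices directly (no fragment spectra).

    Each group's fold change is applied symmetrically about the common
    base — treated channels x 2^(fc/2), control channels x 2^(-fc/2) — so a
    fold-change grid balanced around zero leaves the channel means equal in
    expectation and channel normalization unbiased.  ``sigma`` is log2-scale
    iid normal noise per channel entry.  ``brightness_sigma`` adds a per-scan
    common intensity jitter; note that because the downstream t-test pools
    per-scan per-channel values as if independent, scan-level brightness
    variation makes it conservative (it cancels from the fold-change
    estimate but inflates the pooled variance), so it defaults to 0.
    """
    config = config or RunConfig()
    rng = np.random.default_rng(seed)
    (treated, control) = config.contrasts[0]
    channels = list(config.reporter_channels)
    rows = {}
    scan_groups: dict[str, str] = {}
    scan_no = 0
    for key, fc in group_log2fc.items():
        for _ in range(scans_per_group):
            scan_no += 1
            sid = f"R{scan_no:06d}"
            scan_groups[sid] = key
            brightness = rng.normal(0.0, brightness_sigma)
            row = {}
            for ch in channels:
                cond = config.channel_conditions[ch][0]
                shift = fc / 2.0 if cond == treated else -fc / 2.0
                row[ch] = base * 2.0 ** (
                    brightness + shift + rng.normal(0.0, sigma)
                )
            rows[sid] = row
    matrix = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=channels)
    return ReporterExperiment(
        matrix=matrix,
        scan_groups=scan_groups,
        true_log2fc=dict(group_log2fc),
        config=config,
    )


# ---------------------------------------------------------------------------
# fixtures

ISOMER_PAIR = ("H3K9me1", "H3K14me1")

FIXTURES = (
    "isomer-pair",
    "isomer-pair-noisy",
    "null-experiment",
    "grid-recovery",
    "survey",
)


def _survey_proteoforms() -> list[tuple[str, float]]:
    keys = [
        "H3unmod",
        "H3K4me1",
        "H3K4me3",
        "H3K9me1",
        "H3K9me2",
        "H3K9me3",
        "H3K14ac",
        "H3K23ac",
        "H3K27me2",
        "H3K27me3",
        "H3K9me2/K14ac",
        "H3K14ac/K23ac/K27me2",
    ]
    weights = [3.0, 1.0, 0.5, 1.5, 2.0, 1.0, 1.5, 1.0, 2.0, 1.0, 0.8, 0.6]
    return list(zip(keys, weights))


def make_fixture(name: str, seed: int | None = None, **overrides):
    """Build one of the documented reproducible datasets.

    - ``isomer-pair``: 20 noise-free chimeric scans of the K9me1/K14me1
      positional isomer pair at mixing ratio 0.7/0.3, discriminating ions
      only.  Returns (spectra, psms, GroundTruth).
    - ``isomer-pair-noisy``: same pair over 200 scans with ion dropout 0.1
      and intensity CV 0.2.
    - ``null-experiment``: reporter-level, 200 proteoform groups with zero
      true fold change, sigma 0.3, 10 scans/group.  Returns a
      ReporterExperiment.
    - ``grid-recovery``: reporter-level, true log2 fold changes on the grid
      {-2,-1,0,1,2} x 40 groups each, sigma 0.3, 10 scans/group.
    - ``survey``: 1000 mixed scans over 12 proteoforms with chimeras,
      noise, chaff and decoy PSMs — the general-purpose end-to-end dataset.

    ``seed`` overrides each fixture's documented default; ``overrides``
    adjust design fields (full-simulation fixtures only).
    """
    if name == "isomer-pair":
        design = SimulationDesign(
            proteoforms=[(ISOMER_PAIR[0], 0.7), (ISOMER_PAIR[1], 0.3)],
            n_scans=20,
            chimera_prob=1.0,
            mixture=(0.7, 0.3),
            fragment_series={"c": 1.0, "z": 1.0},
            n_isotope_peaks=2,
            unique_ions_only=True,
            seed=1 if seed is None else seed,
        )
        design = replace(design, **overrides)
        return simulate_experiment(design)
    if name == "isomer-pair-noisy":
        design = SimulationDesign(
            proteoforms=[(ISOMER_PAIR[0], 0.7), (ISOMER_PAIR[1], 0.3)],
            n_scans=200,
            chimera_prob=1.0,
            mixture=(0.7, 0.3),
            fragment_series={"c": 1.0, "z": 1.0},
            n_isotope_peaks=2,
            unique_ions_only=True,
            dropout=0.1,
            intensity_cv=0.2,
            seed=1 if seed is None else seed,
        )
        design = replace(design, **overrides)
        return simulate_experiment(design)
    if name == "null-experiment":
        groups = {f"H3group{i:03d}": 0.0 for i in range(200)}
        return simulate_reporter_experiment(
            groups, scans_per_group=10, seed=2 if seed is None else seed
        )
    if name == "grid-recovery":
        groups = {}
        for fc in (-2.0, -1.0, 0.0, 1.0, 2.0):
            for i in range(40):
                groups[f"H3grid{fc:+.0f}_{i:02d}"] = fc
        return simulate_reporter_experiment(
            groups, scans_per_group=10, seed=3 if seed is None else seed
        )
    if name == "survey":
        design = SimulationDesign(
            proteoforms=_survey_proteoforms(),
            n_scans=1000,
            chimera_prob=0.3,
            max_coisolates=3,
            dropout=0.1,
            intensity_cv=0.2,
            chaff_peaks=5,
            reporter_sigma=0.2,
            brightness_sigma=0.3,
            decoy_rate=0.1,
            fold_changes={
                "H3K4me1": {"treated": 2.0},
                "H3K9me3": {"treated": 0.5},
                "H3K14ac/K23ac/K27me2": {"treated": 2.0},
            },
            seed=4 if seed is None else seed,
        )
        design = replace(design, **overrides)
        return simulate_experiment(design)
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURES}")
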