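"""Reading spectra and PSM tables, proteoform keys, result tables, run config.

Two spectrum formats are supported: standard mzML (read via pyteomics, and a
minimal uncompressed writer for round-trips) and a plain peak-list TSV
dialect so fixtures and simulated data need no XML:

    # scan=<id> precursor_mz=<float> charge=<int>
    <m/z>\t<intensity>
    ...
    (blank line between scans)

The PSM table is a minimal CSV/TSV schema with Byonic-flavored modification
strings; a column-mapping lets real exports be adapted without code changes:

    scan_id, sequence, mods, pep, delta_mod_score

where ``mods`` is a semicolon-joined list of ``K4(Trimethyl)`` tokens
(1-based histone residue numbering) and ``sequence`` selects the H3.1 or
H3.3 backbone.
"""

from __future__ import annotations

import base64
import hashlib
import logging
import re
import struct
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .chem_core import (
    BACKBONES,
    ELECTRON_MASS,
    Composition,
    ModificationSpec,
    Proteoform,
    composition_mass,
    format_proteoform_key,
    modification_by_name,
    parse_proteoform_key,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "PSMRecord",
    "RunConfig",
    "read_spectra",
    "write_peaklist_tsv",
    "write_mzml",
    "read_psm_table",
    "write_psm_table",
    "parse_mod_string",
    "format_mod_string",
    "parse_proteoform_key",
    "format_proteoform_key",
    "write_quant_table",
    "default_reporter_table",
]


@dataclass(frozen=True)
class Spectrum:
    """A centroided MS2 scan: peaks sorted by m/z, non-negative intensity."""

    scan_id: str
    precursor_mz: float
    precursor_charge: int
    mz: np.ndarray
    intensity: np.ndarray
    ms_level: int = 2

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape:
            raise ValueError(f"scan {self.scan_id}: mz/intensity length mismatch")
        if np.any(inten < 0):
            raise ValueError(f"scan {self.scan_id}: negative intensity")
        if mz.size > 1 and np.any(np.diff(mz) < 0):
            warnings.warn(f"scan {self.scan_id}: peaks not sorted; sorting")
            order = np.argsort(mz, kind="stable")
            mz, inten = mz[order], inten[order]
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


@dataclass(frozen=True)
class PSMRecord:
    """A peptide-spectrum match with its search-engine confidence scores."""

    scan_id: str
    proteoform: Proteoform
    pep: float
    delta_mod_score: float

    def __post_init__(self):
        if not 0.0 <= self.pep <= 1.0:
            raise ValueError(f"PEP {self.pep} outside [0, 1]")
        if self.delta_mod_score < 0:
            raise ValueError("delta mod score must be >= 0")


# ---------------------------------------------------------------------------
# Run configuration


def default_reporter_table() -> dict[str, float]:
    """TMT 6-plex reporter ion m/z, derived from isotopologue compositions.

    The reporter cation is the C8H16N+ immonium-like fragment of the tag;
    channels alternate 15N / 13C substitutions so neighbors are split by the
    ~6 mDa N/C isotope gap.  Electron mass is subtracted (cations).
    """
    base = {"C": 8, "H": 16, "N": 1}
    variants = {
        "126": {},
        "127": {"15N": 1},
        "128": {"13C": 2},
        "129": {"13C": 2, "15N": 1},
        "130": {"13C": 4},
        "131": {"13C": 4, "15N": 1},
    }
    table = {}
    for channel, swap in variants.items():
        comp = dict(base)
        n13 = swap.get("13C", 0)
        if n13:
            comp["C"] -= n13
            comp["13C"] = n13
        if swap.get("15N"):
            comp["N"] -= 1
            comp["15N"] = 1
        table[channel] = composition_mass(comp) - ELECTRON_MASS
    return table


def _default_channel_conditions() -> dict[str, tuple[str, int]]:
    return {
        "126": ("control", 1),
        "127": ("control", 2),
        "128": ("control", 3),
        "129": ("treated", 1),
        "130": ("treated", 2),
        "131": ("treated", 3),
    }


@dataclass
class RunConfig:
    """All tunables of a quantification run.

    Defaults follow the study design this pipeline implements: 15 ppm
    fragment / 500 ppm precursor tolerance, PSM filters PEP <= 0.05 and
    delta-mod score >= 10 (both inclusive), at least 2 reporter ions per
    condition, two-sided Welch t-test at alpha 0.05.
    """

    fragment_tol_ppm: float = 15.0
    precursor_tol_ppm: float = 500.0
    reporter_tol_ppm: float = 15.0
    reporter_channels: dict[str, float] = field(default_factory=default_reporter_table)
    channel_conditions: dict[str, tuple[str, int]] = field(
        default_factory=_default_channel_conditions
    )
    contrasts: list[tuple[str, str]] = field(
        default_factory=lambda: [("treated", "control")]
    )
    pep_max: float = 0.05
    delta_min: float = 10.0
    min_reporters_per_condition: int = 2
    alpha: float = 0.05
    max_psms_per_scan: int = 5
    max_fragment_charge: int = 3
    fragment_series: tuple[str, ...] = ("a", "b", "c", "y", "z")
    neutral_losses: dict[str, dict[str, int]] = field(
        default_factory=lambda: {"H2O": {"H": 2, "O": 1}, "NH3": {"N": 1, "H": 3}}
    )
    reporter_region: tuple[float, float] = (125.5, 132.0)
    isotope_spacings: tuple[float, ...] = (1.003355,)
    require_isotope_confirmation: bool = True
    weight_by_fraction: bool = False
    bh_correction: bool = False
    seed: int = 0
    psm_columns: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name in ("fragment_tol_ppm", "precursor_tol_ppm", "reporter_tol_ppm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        conditions = {c for c, _ in self.channel_conditions.values()}
        if not conditions:
            raise ValueError("channel_conditions must define at least one condition")
        # normalize sequence fields so YAML round-trips hash identically
        self.channel_conditions = {
            ch: tuple(v) for ch, v in self.channel_conditions.items()
        }
        self.fragment_series = tuple(self.fragment_series)
        self.isotope_spacings = tuple(float(s) for s in self.isotope_spacings)
        self.reporter_region = tuple(float(x) for x in self.reporter_region)
        self.contrasts = [tuple(c) for c in self.contrasts]
        for a, b in self.contrasts:
            if a not in conditions or b not in conditions:
                raise ValueError(f"contrast ({a}, {b}) names unknown condition")

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for cond, _ in self.channel_conditions.values():
            if cond not in seen:
                seen.append(cond)
        return seen

    def channels_for(self, condition: str) -> list[str]:
        return [
            ch for ch, (cond, _) in self.channel_conditions.items() if cond == condition
        ]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "channel_conditions" in raw:
            raw["channel_conditions"] = {
                str(ch): tuple(v) for ch, v in raw["channel_conditions"].items()
            }
        if "reporter_channels" in raw:
            raw["reporter_channels"] = {
                str(ch): float(v) for ch, v in raw["reporter_channels"].items()
            }
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: getattr(self, k) for k in self.__dataclass_fields__
        }
        data["channel_conditions"] = {
            ch: list(v) for ch, v in data["channel_conditions"].items()
        }
        data["contrasts"] = [list(c) for c in data["contrasts"]]
        data["fragment_series"] = list(data["fragment_series"])
        data["isotope_spacings"] = list(data["isotope_spacings"])
        data["reporter_region"] = list(data["reporter_region"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def digest(self) -> str:
        payload = repr(sorted(self.__dict__.items(), key=lambda kv: kv[0]))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Peak-list TSV dialect

_SCAN_HEADER = re.compile(
    r"^#\s*scan=(\S+)\s+precursor_mz=([\d.eE+-]+)\s+charge=(\d+)\s*$"
)


def _read_peaklist_tsv(path: Path) -> list[Spectrum]:
    spectra: list[Spectrum] = []
    scan_id = None
    header: tuple[str, float, int] | None = None
    mzs: list[float] = []
    intens: list[float] = []

    def flush():
        nonlocal header, mzs, intens
        if header is not None:
            sid, pmz, z = header
            spectra.append(
                Spectrum(sid, pmz, z, np.array(mzs, float), np.array(intens, float))
            )
        header, mzs, intens = None, [], []

    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = _SCAN_HEADER.match(line)
            if m is None:
                raise ValueError(f"{path}:{lineno}: malformed scan header: {line!r}")
            flush()
            header = (m.group(1), float(m.group(2)), int(m.group(3)))
            continue
        if header is None:
            raise ValueError(f"{path}:{lineno}: peak row before any scan header")
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'mz<TAB>intensity'")
        mzs.append(float(parts[0]))
        intens.append(float(parts[1]))
    flush()
    if not spectra:
        warnings.warn(f"{path}: no spectra found")
    return spectra


def write_peaklist_tsv(spectra: Iterable[Spectrum], path: str | Path) -> None:
    lines: list[str] = []
    for s in spectra:
        lines.append(
            f"# scan={s.scan_id} precursor_mz={s.precursor_mz:.6f} "
            f"charge={s.precursor_charge}"
        )
        for mz, inten in zip(s.mz, s.intensity):
            lines.append(f"{mz:.6f}\t{inten:.6f}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# mzML

def _encode_array(values: np.ndarray) -> str:
    raw = struct.pack(f"<{values.size}d", *np.asarray(values, float))
    return base64.b64encode(raw).decode()


def write_mzml(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write a minimal centroided mzML (64-bit, uncompressed) readable by
    standard mzML parsers."""
    parts = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '  <run id="run">',
        f'    <spectrumList count="{len(spectra)}">',
    ]
    for i, s in enumerate(spectra):
        mz_b64 = _encode_array(s.mz)
        int_b64 = _encode_array(s.intensity)
        parts.append(
            f'      <spectrum index="{i}" id="scan={s.scan_id}" '
            f'defaultArrayLength="{s.n_peaks}">'
        )
        parts.append(
            f'        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" '
            f'value="{s.ms_level}"/>'
        )
        parts.append(
            '        <cvParam cvRef="MS" accession="MS:1000127" '
            'name="centroid spectrum" value=""/>'
        )
        parts.append(
            "        <precursorList count=\"1\"><precursor>"
            "<selectedIonList count=\"1\"><selectedIon>"
            f'<cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" '
            f'value="{s.precursor_mz:.6f}"/>'
            f'<cvParam cvRef="MS" accession="MS:1000041" name="charge state" '
            f'value="{s.precursor_charge}"/>'
            "</selectedIon></selectedIonList></precursor></precursorList>"
        )
        parts.append('        <binaryDataArrayList count="2">')
        for accession, name, b64 in (
            ("MS:1000514", "m/z array", mz_b64),
            ("MS:1000515", "intensity array", int_b64),
        ):
            parts.append(f'          <binaryDataArray encodedLength="{len(b64)}">')
            parts.append(
                '            <cvParam cvRef="MS" accession="MS:1000523" '
                'name="64-bit float" value=""/>'
            )
            parts.append(
                '            <cvParam cvRef="MS" accession="MS:1000576" '
                'name="no compression" value=""/>'
            )
            parts.append(
                f'            <cvParam cvRef="MS" accession="{accession}" '
                f'name="{name}" value=""/>'
            )
            parts.append(f"            <binary>{b64}</binary>")
            parts.append("          </binaryDataArray>")
        parts.append("        </binaryDataArrayList>")
        parts.append("      </spectrum>")
    parts += ["    </spectrumList>", "  </run>", "</mzML>", ""]
    Path(path).write_text("\n".join(parts))


def _decode_binary(element, ns: str) -> np.ndarray:
    """Decode one mzML binaryDataArray (64/32-bit, zlib or uncompressed)."""
    import zlib

    accessions = {
        cv.get("accession") for cv in element.findall(f"{ns}cvParam")
    }
    binary = element.find(f"{ns}binary")
    raw = base64.b64decode((binary.text or "").encode())
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: Path) -> list[Spectrum]:
    """Minimal namespace-aware mzML reader (lxml + base64)."""
    from lxml import etree

    tree = etree.parse(str(path))
    root = tree.getroot()
    ns = ""
    if root.tag.startswith("{"):
        ns = root.tag[: root.tag.index("}") + 1]

    def cv_values(el) -> dict[str, str]:
        return {
            cv.get("accession"): cv.get("value", "")
            for cv in el.findall(f"{ns}cvParam")
        }

    spectra: list[Spectrum] = []
    for sp in root.iter(f"{ns}spectrum"):
        sid = sp.get("id", "")
        m = re.search(r"scan=(\S+)", sid)
        scan_id = m.group(1) if m else sid
        params = cv_values(sp)
        ms_level = int(params.get("MS:1000511", 2))
        precursor_mz, charge = 0.0, 0
        for ion in sp.iter(f"{ns}selectedIon"):
            ion_params = cv_values(ion)
            precursor_mz = float(ion_params.get("MS:1000744", 0.0))
            charge = int(float(ion_params.get("MS:1000041", 0) or 0))
            break
        mz = intensity = None
        for arr in sp.iter(f"{ns}binaryDataArray"):
            accessions = {cv.get("accession") for cv in arr.findall(f"{ns}cvParam")}
            values = _decode_binary(arr, ns)
            if "MS:1000514" in accessions:
                mz = values
            elif "MS:1000515" in accessions:
                intensity = values
        if mz is None or intensity is None:
            raise ValueError(f"{path}: scan {scan_id} lacks m/z or intensity array")
        spectra.append(
            Spectrum(scan_id, precursor_mz, charge, mz, intensity, ms_level=ms_level)
        )
    if not spectra:
        warnings.warn(f"{path}: no spectra found")
    return spectra


def read_spectra(path: str | Path, format: str | None = None) -> list[Spectrum]:
    """Read MS2 spectra from mzML or the peak-list TSV dialect.

    ``format`` is inferred from the extension when omitted (".mzml" vs
    anything else -> TSV).
    """
    path = Path(path)
    if format is None:
        format = "mzML" if path.suffix.lower() == ".mzml" else "peaklist-tsv"
    if format == "mzML":
        return _read_mzml(path)
    if format == "peaklist-tsv":
        return _read_peaklist_tsv(path)
    raise ValueError(f"unknown spectrum format {format!r}")


# ---------------------------------------------------------------------------
# PSM table

_MOD_TOKEN = re.compile(r"^\s*([A-Z])(\d+)\(([A-Za-z0-9_-]+)\)\s*$")

#: canonical column names; a RunConfig.psm_columns mapping of
#: {actual header -> canonical name} adapts other exports
PSM_COLUMNS = ("scan_id", "sequence", "mods", "pep", "delta_mod_score")


def parse_mod_string(mods: str, backbone: str) -> Proteoform:
    """Parse ``"K4(Trimethyl); K9(Acetyl)"`` into a Proteoform."""
    mods = (mods or "").strip()
    if not mods:
        return Proteoform(backbone)
    placements: list[tuple[int, ModificationSpec]] = []
    for token in mods.split(";"):
        if not token.strip():
            continue
        m = _MOD_TOKEN.match(token)
        if m is None:
            raise ValueError(f"malformed modification token: {token!r}")
        letter, pos_s, name = m.groups()
        pos = int(pos_s)
        spec = modification_by_name(name)
        seq = BACKBONES[backbone]
        if pos > len(seq) or seq[pos - 1] != letter:
            raise ValueError(f"residue {pos} of {backbone} is not {letter}")
        placements.append((pos, spec))
    return Proteoform(backbone, tuple(placements))


def format_mod_string(p: Proteoform) -> str:
    seq = p.sequence
    return "; ".join(
        f"{seq[pos - 1]}{pos}({spec.name})" for pos, spec in p.placements
    )


def _backbone_for_sequence(seq: str) -> str:
    for name, s in BACKBONES.items():
        if s == seq:
            return name
    raise ValueError(f"sequence is not an H3.1/H3.3 tail: {seq!r}")


def read_psm_table(
    path: str | Path, config: RunConfig | None = None
) -> tuple[list[PSMRecord], pd.DataFrame]:
    """Read a PSM table; returns (records, rejects).

    Rows that cannot be parsed or violate placement rules are collected in
    the rejects frame (with a ``reason`` column), never silently dropped.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    mapping = (config.psm_columns if config else {}) or {}
    df = df.rename(columns=mapping)
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PSM table missing required columns: {missing}")
    records: list[PSMRecord] = []
    rejects: list[dict] = []
    for _, row in df.iterrows():
        try:
            backbone = _backbone_for_sequence(row["sequence"])
            proteoform = parse_mod_string(row["mods"], backbone)
            records.append(
                PSMRecord(
                    scan_id=str(row["scan_id"]),
                    proteoform=proteoform,
                    pep=float(row["pep"]),
                    delta_mod_score=float(row["delta_mod_score"]),
                )
            )
        except (ValueError, KeyError) as exc:
            rejects.append({**row.to_dict(), "reason": str(exc)})
    rejects_df = pd.DataFrame(rejects, columns=list(df.columns) + ["reason"])
    if len(records) + len(rejects_df) != len(df):
        raise AssertionError("accepted + rejected rows != input rows")
    return records, rejects_df


def write_psm_table(records: Iterable[PSMRecord], path: str | Path) -> None:
    rows = [
        {
            "scan_id": r.scan_id,
            "sequence": r.proteoform.sequence,
            "mods": format_mod_string(r.proteoform),
            "pep": r.pep,
            "delta_mod_score": r.delta_mod_score,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(PSM_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Results table


def write_quant_table(results, path: str | Path, config: RunConfig | None = None):
    """Write proteoform group results as a key-sorted TSV.

    Columns: proteoform, n_scans, mean_log2_<condition>..., then per
    contrast log2fc_<A>_vs_<B> and p_<A>_vs_<B>, and a coverage flag.
    Returns the DataFrame written.
    """
    rows = []
    for r in sorted(results, key=lambda r: r.proteoform_key):
        row: dict = {"proteoform": r.proteoform_key, "n_scans": r.n_scans}
        for cond, mean in r.condition_means.items():
            row[f"mean_log2_{cond}"] = mean
        for (a, b), fc in r.log2fc.items():
            row[f"log2fc_{a}_vs_{b}"] = fc
            row[f"p_{a}_vs_{b}"] = r.p_value.get((a, b), float("nan"))
        row["coverage_pass"] = all(r.coverage_pass.values()) if r.coverage_pass else True
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        cols = ["proteoform", "n_scans"]
        if config is not None:
            cols += [f"mean_log2_{c}" for c in config.conditions]
            for a, b in config.contrasts:
                cols += [f"log2fc_{a}_vs_{b}", f"p_{a}_vs_{b}"]
        cols += ["coverage_pass"]
        df = pd.DataFrame(columns=cols)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return df
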