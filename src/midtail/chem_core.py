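"""Exact monoisotopic mass chemistry for sortase-tagged, TMT-labeled histone
H3 tail proteoforms and their EThcD fragment ions.

The analyte is the 36-residue N-terminal tail of histone H3 (H3.1 or H3.3),
released and labeled by sortase transpeptidation: every histidine carries a
fixed TMT 6-plex mass and the C-terminus carries a fixed correction that
accounts for the sortase-installed tag (the mass difference between the
native His and the appended Lys + 2,3-diaminopropionamide stub).

All masses are monoisotopic, in daltons.  Fragment ions follow the
conventions of ETD-based fragmentation: the z series is the z-dot (z+1)
radical species.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "Composition",
    "ModificationSpec",
    "Proteoform",
    "composition_mass",
    "proteoform_mass",
    "fragment_neutral_mass",
    "fragment_mz",
    "isotope_envelope",
    "ppm_error",
    "sortase_cterm_correction",
    "parse_proteoform_key",
    "format_proteoform_key",
    "default_modifications",
    "H3_1_TAIL",
    "H3_3_TAIL",
    "BACKBONES",
    "RESIDUE_COMPOSITIONS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "WATER_MASS",
    "ISOTOPE_SPACING_13C",
    "ISOTOPE_SPACING_15N",
    "CTERM_CORRECTION_DA",
    "TMT6PLEX_DELTA_DA",
]

# Monoisotopic atomic masses (Da), NIST/AME.  Heavy isotopes are distinct
# symbols so label chemistry (TMT isotopologues) is expressible.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503223,
    "C": 12.0,
    "N": 14.00307400443,
    "O": 15.99491461957,
    "P": 30.97376199842,
    "S": 31.9720711744,
    "13C": 13.00335483507,
    "15N": 15.00010889888,
}

PROTON_MASS = 1.00727646688
ELECTRON_MASS = 0.00054857990907
#: spacing between the A and A+1 isotopologue peaks of a carbon-rich ion
ISOTOPE_SPACING_13C = MONOISOTOPIC_MASS["13C"] - MONOISOTOPIC_MASS["C"]
ISOTOPE_SPACING_15N = MONOISOTOPIC_MASS["15N"] - MONOISOTOPIC_MASS["N"]
#: natural abundance of 13C
ABUNDANCE_13C = 0.0107


class Composition(dict):
    """Elemental composition: element symbol -> non-negative integer count.

    A thin dict with mass arithmetic; symbols must be keys of
    ``MONOISOTOPIC_MASS`` (heavy isotopes spelled ``13C``, ``15N``).
    """

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        for symbol, count in self.items():
            if symbol not in MONOISOTOPIC_MASS:
                raise KeyError(f"unknown element symbol: {symbol!r}")
            if not isinstance(count, int) or count < 0:
                raise ValueError(f"count for {symbol} must be a non-negative integer")

    @classmethod
    def from_formula(cls, formula: str) -> "Composition":
        """Parse a plain formula such as ``"C2H2O"`` (no isotope labels)."""
        tokens = re.findall(r"([A-Z][a-z]?)(\d*)", formula)
        counts: dict[str, int] = {}
        consumed = ""
        for symbol, num in tokens:
            if not symbol:
                continue
            consumed += symbol + num
            counts[symbol] = counts.get(symbol, 0) + (int(num) if num else 1)
        if consumed != formula:
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls(counts)

    @property
    def mass(self) -> float:
        return composition_mass(self)

    def __add__(self, other: Mapping[str, int]) -> "Composition":
        out = dict(self)
        for k, v in other.items():
            out[k] = out.get(k, 0) + v
        return Composition(out)


def composition_mass(comp: Mapping[str, int]) -> float:
    """Monoisotopic mass of an elemental composition, in Da."""
    total = 0.0
    for symbol, count in comp.items():
        try:
            atomic = MONOISOTOPIC_MASS[symbol]
        except KeyError:
            raise KeyError(f"unknown element symbol: {symbol!r}") from None
        if count < 0:
            raise ValueError(f"negative count for {symbol}")
        total += count * atomic
    return total


WATER_MASS = composition_mass({"H": 2, "O": 1})
NH3_MASS = composition_mass({"N": 1, "H": 3})
CO_MASS = composition_mass({"C": 1, "O": 1})

# Residue (i.e. amino-acid-minus-water) compositions of the 20 standard residues.
RESIDUE_COMPOSITIONS: dict[str, Composition] = {
    "G": Composition({"C": 2, "H": 3, "N": 1, "O": 1}),
    "A": Composition({"C": 3, "H": 5, "N": 1, "O": 1}),
    "S": Composition({"C": 3, "H": 5, "N": 1, "O": 2}),
    "P": Composition({"C": 5, "H": 7, "N": 1, "O": 1}),
    "V": Composition({"C": 5, "H": 9, "N": 1, "O": 1}),
    "T": Composition({"C": 4, "H": 7, "N": 1, "O": 2}),
    "C": Composition({"C": 3, "H": 5, "N": 1, "O": 1, "S": 1}),
    "L": Composition({"C": 6, "H": 11, "N": 1, "O": 1}),
    "I": Composition({"C": 6, "H": 11, "N": 1, "O": 1}),
    "N": Composition({"C": 4, "H": 6, "N": 2, "O": 2}),
    "D": Composition({"C": 4, "H": 5, "N": 1, "O": 3}),
    "Q": Composition({"C": 5, "H": 8, "N": 2, "O": 2}),
    "K": Composition({"C": 6, "H": 12, "N": 2, "O": 1}),
    "E": Composition({"C": 5, "H": 7, "N": 1, "O": 3}),
    "M": Composition({"C": 5, "H": 9, "N": 1, "O": 1, "S": 1}),
    "H": Composition({"C": 6, "H": 7, "N": 3, "O": 1}),
    "F": Composition({"C": 9, "H": 9, "N": 1, "O": 1}),
    "R": Composition({"C": 6, "H": 12, "N": 4, "O": 1}),
    "Y": Composition({"C": 9, "H": 9, "N": 1, "O": 2}),
    "W": Composition({"C": 11, "H": 10, "N": 2, "O": 1}),
}

RESIDUE_MASSES: dict[str, float] = {
    aa: composition_mass(c) for aa, c in RESIDUE_COMPOSITIONS.items()
}

#: H3 N-terminal tail sequences (residue i of the peptide is histone residue i)
H3_1_TAIL = "ARTKQTARKSTGGKAPRKQLATKAARKSAPATGGGH"
H3_3_TAIL = "ARTKQTARKSTGGKAPRKQLATKAARKSAPSTGGGH"
BACKBONES: dict[str, str] = {"H3.1": H3_1_TAIL, "H3.3": H3_3_TAIL}


@dataclass(frozen=True)
class ModificationSpec:
    """A named mass delta with elemental composition and placement rules.

    ``composition`` may be None for modifications defined only by a literal
    mass (the sortase C-terminal correction).  When both are given the
    composition mass must reproduce ``delta_mass`` within 1e-4 Da.
    """

    name: str
    delta_mass: float
    targets: frozenset[str] = frozenset()
    max_per_peptide: int = 0
    composition: Composition | None = None
    fixed: bool = False
    abbrev: str | None = None

    def __post_init__(self):
        if self.max_per_peptide < 0:
            raise ValueError("max_per_peptide must be >= 0")
        if self.composition is not None:
            calc = composition_mass(self.composition)
            if abs(calc - self.delta_mass) > 1e-4:
                raise ValueError(
                    f"{self.name}: composition mass {calc:.6f} does not match "
                    f"declared delta {self.delta_mass:.6f}"
                )


def _dap_composition() -> Composition:
    """2,3-diaminopropionamide, H2N-CH2-CH(NH2)-CONH2."""
    return Composition({"C": 3, "H": 9, "N": 3, "O": 1})


def sortase_cterm_correction() -> float:
    """Analytic value of the sortase C-terminal fixed correction (Da).

    The sortase-ligated tag replaces the tail's C-terminal His with
    Lys + 2,3-diaminopropionamide, so the correction is
    M(Lys residue) + M(2,3-diaminopropionamide) - M(H2O) - M(His residue).
    """
    return (
        RESIDUE_MASSES["K"]
        + composition_mass(_dap_composition())
        - WATER_MASS
        - RESIDUE_MASSES["H"]
    )


#: printed value of the C-terminal correction; stored literally, the analytic
#: derivation above reproduces it to < 1e-4 Da
CTERM_CORRECTION_DA = 76.1001
TMT6PLEX_DELTA_DA = 229.162932

TMT6PLEX_COMPOSITION = Composition(
    {"C": 8, "13C": 4, "H": 20, "N": 1, "15N": 1, "O": 2}
)


def default_modifications() -> dict[str, ModificationSpec]:
    """The variable and fixed modification table used for H3 tail searches.

    Keyed by short abbreviation (me1/me2/me3/ac/ph/pr for variable mods;
    TMT6plex and cterm for the fixed chemistry).
    """
    variable = [
        ModificationSpec(
            "Methyl", 14.015650, frozenset("KR"), 3,
            Composition({"C": 1, "H": 2}), abbrev="me1",
        ),
        ModificationSpec(
            "Dimethyl", 28.031300, frozenset("KR"), 3,
            Composition({"C": 2, "H": 4}), abbrev="me2",
        ),
        ModificationSpec(
            "Trimethyl", 42.046950, frozenset("K"), 3,
            Composition({"C": 3, "H": 6}), abbrev="me3",
        ),
        ModificationSpec(
            "Phospho", 79.966331, frozenset("ST"), 2,
            Composition({"H": 1, "P": 1, "O": 3}), abbrev="ph",
        ),
        ModificationSpec(
            "Acetyl", 42.010565, frozenset("K"), 5,
            Composition({"C": 2, "H": 2, "O": 1}), abbrev="ac",
        ),
        ModificationSpec(
            "Propionyl", 56.026215, frozenset("K"), 1,
            Composition({"C": 3, "H": 4, "O": 1}), abbrev="pr",
        ),
    ]
    fixed = [
        ModificationSpec(
            "TMT6plex", TMT6PLEX_DELTA_DA, frozenset("H"), 0,
            TMT6PLEX_COMPOSITION, fixed=True, abbrev="TMT6plex",
        ),
        ModificationSpec(
            "SortaseCterm", CTERM_CORRECTION_DA, frozenset(), 0,
            None, fixed=True, abbrev="cterm",
        ),
    ]
    return {m.abbrev: m for m in variable + fixed}


def load_modifications(path: str | None = None) -> dict[str, ModificationSpec]:
    """Load a modification table from YAML (the shipped v1 table by default).

    The shipped file mirrors :func:`default_modifications`; users may point
    this at an extended copy.
    """
    import yaml

    if path is None:
        from importlib.resources import files

        text = files("midtail.data").joinpath("modifications.yaml").read_text()
    else:
        from pathlib import Path

        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    mods: dict[str, ModificationSpec] = {}
    for entry in raw["modifications"]:
        comp = entry.get("composition")
        spec = ModificationSpec(
            name=entry["name"],
            delta_mass=float(entry["delta_mass"]),
            targets=frozenset(entry.get("targets") or ()),
            max_per_peptide=int(entry.get("max_per_peptide", 0)),
            composition=Composition({str(k): int(v) for k, v in comp.items()})
            if comp
            else None,
            fixed=bool(entry.get("fixed", False)),
            abbrev=entry.get("abbrev"),
        )
        mods[spec.abbrev] = spec
    return mods


MODIFICATIONS = default_modifications()
_MODS_BY_NAME = {m.name: m for m in MODIFICATIONS.values()}


def modification_by_name(name: str) -> ModificationSpec:
    """Look up a modification by its full name (e.g. ``"Trimethyl"``)."""
    try:
        return _MODS_BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown modification name: {name!r}") from None


@dataclass(frozen=True)
class Proteoform:
    """An H3 tail backbone plus positioned variable modifications.

    ``placements`` maps 1-based residue index to a ModificationSpec; index i
    is histone residue i, so index 4 is H3K4.  Fixed chemistry (TMT on His,
    the C-terminal sortase correction) is implicit and not part of
    ``placements``.
    """

    backbone: str = "H3.1"
    placements: tuple[tuple[int, ModificationSpec], ...] = ()

    def __post_init__(self):
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}")
        seq = self.sequence
        placements = tuple(sorted(self.placements, key=lambda t: t[0]))
        object.__setattr__(self, "placements", placements)
        seen: dict[int, str] = {}
        counts: dict[str, int] = {}
        for pos, spec in placements:
            if not 1 <= pos <= len(seq):
                raise ValueError(f"placement index {pos} outside 1..{len(seq)}")
            if pos in seen:
                raise ValueError(f"duplicate placement at residue {pos}")
            seen[pos] = spec.name
            if seq[pos - 1] not in spec.targets:
                raise ValueError(
                    f"{spec.name} not allowed on {seq[pos - 1]}{pos} "
                    f"(targets {''.join(sorted(spec.targets))})"
                )
            counts[spec.name] = counts.get(spec.name, 0) + 1
            if counts[spec.name] > spec.max_per_peptide:
                raise ValueError(
                    f"more than {spec.max_per_peptide} {spec.name} placements"
                )

    @classmethod
    def from_placements(
        cls, placements: Mapping[int, ModificationSpec], backbone: str = "H3.1"
    ) -> "Proteoform":
        return cls(backbone, tuple(placements.items()))

    @property
    def sequence(self) -> str:
        return BACKBONES[self.backbone]

    @property
    def placement_map(self) -> dict[int, ModificationSpec]:
        return dict(self.placements)

    @property
    def key(self) -> str:
        return format_proteoform_key(self)

    def with_placement(self, pos: int, spec: ModificationSpec) -> "Proteoform":
        return Proteoform(self.backbone, self.placements + ((pos, spec),))


def format_proteoform_key(p: Proteoform) -> str:
    """Canonical proteoform key, e.g. ``"H3K14ac/K23ac/K27me2"``.

    Tokens are sorted by residue position; an unmodified tail is
    ``"H3unmod"``.  The H3.1/H3.3 backbone is tracked separately.
    """
    if not p.placements:
        return "H3unmod"
    seq = p.sequence
    tokens = [
        f"{seq[pos - 1]}{pos}{spec.abbrev}" for pos, spec in p.placements
    ]
    return "H3" + "/".join(tokens)


_KEY_TOKEN = re.compile(r"^([A-Z])(\d+)([a-z]+\d?)$")


def parse_proteoform_key(key: str, backbone: str = "H3.1") -> Proteoform:
    """Parse a proteoform key back into a Proteoform (inverse of format).

    The backbone variant is not encoded in the key and must be supplied.
    """
    if not key.startswith("H3"):
        raise ValueError(f"proteoform key must start with 'H3': {key!r}")
    body = key[2:]
    if body == "unmod" or body == "":
        return Proteoform(backbone)
    placements: list[tuple[int, ModificationSpec]] = []
    seq = BACKBONES[backbone]
    for token in body.split("/"):
        m = _KEY_TOKEN.match(token)
        if m is None:
            raise ValueError(f"malformed proteoform key token: {token!r}")
        letter, pos_s, abbrev = m.groups()
        pos = int(pos_s)
        spec = MODIFICATIONS.get(abbrev)
        if spec is None or spec.fixed:
            raise ValueError(f"unknown modification abbreviation: {abbrev!r}")
        if pos > len(seq) or seq[pos - 1] != letter:
            raise ValueError(
                f"token {token!r}: residue {pos} of {backbone} is not {letter}"
            )
        placements.append((pos, spec))
    return Proteoform(backbone, tuple(placements))


def proteoform_mass(p: Proteoform, *, fixed_mods: bool = True) -> float:
    """Neutral monoisotopic mass of a proteoform (Da).

    Includes the water terminus, all variable placements and — by default —
    the fixed chemistry: one TMT 6-plex per His residue plus the sortase
    C-terminal correction.
    """
    seq = p.sequence
    mass = sum(RESIDUE_MASSES[aa] for aa in seq) + WATER_MASS
    mass += sum(spec.delta_mass for _, spec in p.placements)
    if fixed_mods:
        mass += seq.count("H") * TMT6PLEX_DELTA_DA
        mass += CTERM_CORRECTION_DA
    return mass


# Neutral-mass offsets of each series relative to the plain residue sum.
# N-terminal: a = b - CO, b = residues, c = b + NH3.
# C-terminal (includes the water terminus W): y = residues + W,
# z = z-dot radical = y - NH3 + H.
_NTERM_OFFSETS = {"a": -CO_MASS, "b": 0.0, "c": NH3_MASS}
_CTERM_OFFSETS = {
    "y": WATER_MASS,
    "z": WATER_MASS - NH3_MASS + MONOISOTOPIC_MASS["H"],
}
FRAGMENT_SERIES = ("a", "b", "c", "y", "z")


def _residue_mass_at(p: Proteoform, i: int, placements: Mapping[int, ModificationSpec],
                     fixed_mods: bool) -> float:
    aa = p.sequence[i - 1]
    m = RESIDUE_MASSES[aa]
    spec = placements.get(i)
    if spec is not None:
        m += spec.delta_mass
    if fixed_mods and aa == "H":
        m += TMT6PLEX_DELTA_DA
    return m


def fragment_neutral_mass(
    p: Proteoform,
    series: str,
    index: int,
    neutral_loss: Mapping[str, int] | float | None = None,
    *,
    fixed_mods: bool = True,
) -> float:
    """Neutral mass of a backbone fragment (Da).

    ``index`` counts residues from the fragment's own terminus: c5 covers
    residues 1..5, z5 the last five residues.  C-terminal fragments carry
    the sortase C-terminal correction; any His inside the fragment carries
    TMT.  ``neutral_loss`` is a composition (or literal Da) subtracted from
    the fragment.
    """
    n = len(p.sequence)
    if not 1 <= index <= n - 1:
        raise ValueError(f"fragment index {index} outside 1..{n - 1}")
    placements = p.placement_map
    if series in _NTERM_OFFSETS:
        residues = range(1, index + 1)
        mass = _NTERM_OFFSETS[series]
    elif series in _CTERM_OFFSETS:
        residues = range(n - index + 1, n + 1)
        mass = _CTERM_OFFSETS[series]
        if fixed_mods:
            mass += CTERM_CORRECTION_DA
    else:
        raise ValueError(f"unsupported fragment series {series!r}")
    for i in residues:
        mass += _residue_mass_at(p, i, placements, fixed_mods)
    if neutral_loss is not None:
        loss = (
            neutral_loss
            if isinstance(neutral_loss, (int, float))
            else composition_mass(neutral_loss)
        )
        mass -= loss
    return mass


def fragment_mz(
    p: Proteoform,
    series: str,
    index: int,
    charge: int,
    neutral_loss: Mapping[str, int] | float | None = None,
    *,
    fixed_mods: bool = True,
) -> float:
    """m/z of a protonated backbone fragment ion."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    neutral = fragment_neutral_mass(
        p, series, index, neutral_loss, fixed_mods=fixed_mods
    )
    return (neutral + charge * PROTON_MASS) / charge


def precursor_mz(p: Proteoform, charge: int) -> float:
    """m/z of the protonated intact proteoform at the given charge."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (proteoform_mass(p) + charge * PROTON_MASS) / charge


def _binomial_pmf(n: int, p: float, k: int) -> float:
    from math import comb

    return comb(n, k) * p**k * (1.0 - p) ** (n - k)


def carbon_count(comp_or_proteoform) -> int:
    """Number of (light) carbon atoms, driving the A+1 envelope."""
    if isinstance(comp_or_proteoform, Proteoform):
        n = sum(
            RESIDUE_COMPOSITIONS[aa].get("C", 0) for aa in comp_or_proteoform.sequence
        )
        for _, spec in comp_or_proteoform.placements:
            if spec.composition is not None:
                n += spec.composition.get("C", 0)
        # fixed chemistry: TMT per His (4 of its carbons are already 13C)
        n += comp_or_proteoform.sequence.count("H") * TMT6PLEX_COMPOSITION["C"]
        return n
    return int(comp_or_proteoform.get("C", 0))


def isotope_envelope(
    comp_or_proteoform,
    charge: int,
    n_peaks: int,
    mono_mz: float | None = None,
) -> list[tuple[float, float]]:
    """Coarse carbon-binomial isotope envelope of an ion.

    Peaks are spaced by the 13C-12C gap over the charge, starting at the
    monoisotopic m/z; relative intensities follow a binomial over the carbon
    count with 13C abundance 0.0107, normalized so the tallest peak is 1.
    Fine structure (15N, 18O, 34S) is deliberately ignored.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    if mono_mz is None:
        if isinstance(comp_or_proteoform, Proteoform):
            mono_mz = precursor_mz(comp_or_proteoform, charge)
        else:
            mono_mz = (
                composition_mass(comp_or_proteoform) + charge * PROTON_MASS
            ) / charge
    n_c = carbon_count(comp_or_proteoform)
    raw = [_binomial_pmf(n_c, ABUNDANCE_13C, k) for k in range(n_peaks)]
    top = max(raw)
    spacing = ISOTOPE_SPACING_13C / charge
    return [
        (mono_mz + k * spacing, raw[k] / top) for k in range(n_peaks)
    ]


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be > 0")
    return 1e6 * (observed - theoretical) / theoretical
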