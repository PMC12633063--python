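import numpy as np
import pytest

from midtail.chem_core import MODIFICATIONS, Proteoform
from midtail.spectra_io import RunConfig, Spectrum


@pytest.fixture
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture
def unmod() -> Proteoform:
    return Proteoform("H3.1")


def make_spectrum(scan_id, peaks, precursor_mz=494.67, charge=8):
    """Build a Spectrum from a list of (mz, intensity) pairs."""
    peaks = sorted(peaks)
    mz = np.array([p[0] for p in peaks], float)
    inten = np.array([p[1] for p in peaks], float)
    return Spectrum(scan_id, precursor_mz, charge, mz, inten)


def random_proteoform(rng: np.random.Generator) -> Proteoform:
    """A random valid proteoform: backbone + placements respecting caps."""
    backbone = "H3.1" if rng.random() < 0.5 else "H3.3"
    p = Proteoform(backbone)
    seq = p.sequence
    candidates = []
    for abbrev in ("me1", "me2", "me3", "ac", "ph", "pr"):
        spec = MODIFICATIONS[abbrev]
        for pos, aa in enumerate(seq, start=1):
            if aa in spec.targets:
                candidates.append((pos, spec))
    order = rng.permutation(len(candidates))
    n_target = int(rng.integers(0, 6))
    for idx in order:
        if len(p.placements) >= n_target:
            break
        pos, spec = candidates[idx]
        try:
            p = p.with_placement(pos, spec)
        except ValueError:
            continue
    return p
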