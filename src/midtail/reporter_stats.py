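"""TMT reporter extraction, channel normalization, and group statistics.

Reporter ion intensities are extracted per channel, each channel is scaled
so its average over all PSM-bearing scans equals the most intense channel's
average (correcting mixing/labeling bias), intensities are log2
transformed, scans must show at least ``min_reporters_per_condition``
reporters in every condition, and per-proteoform log2 fold changes between
conditions are assessed with a two-sided Welch t-test on the pooled
per-scan per-channel log2 signals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .proteoform_quant import SpectrumQuant
from .spectra_io import RunConfig, Spectrum

__all__ = [
    "ProteoformGroupResult",
    "extract_reporters",
    "build_reporter_matrix",
    "channel_normalize",
    "coverage_filter",
    "coverage_mask",
    "group_and_test",
]


@dataclass
class ProteoformGroupResult:
    """Per-proteoform-group fold change and significance."""

    proteoform_key: str
    scan_ids: tuple[str, ...]
    condition_means: dict[str, float]
    log2fc: dict[tuple[str, str], float]
    p_value: dict[tuple[str, str], float]
    q_value: dict[tuple[str, str], float] = field(default_factory=dict)
    coverage_pass: dict[str, bool] = field(default_factory=dict)
    untestable: dict[tuple[str, str], bool] = field(default_factory=dict)

    @property
    def n_scans(self) -> int:
        return len(self.scan_ids)


def extract_reporters(
    spectrum: Spectrum,
    channel_table: dict[str, float] | None = None,
    tol_ppm: float = 15.0,
) -> dict[str, float]:
    """Per channel, the closest in-tolerance peak's intensity (NaN if none)."""
    if channel_table is None:
        from .spectra_io import default_reporter_table

        channel_table = default_reporter_table()
    out: dict[str, float] = {}
    mz = spectrum.mz
    for channel, target in channel_table.items():
        delta = target * tol_ppm * 1e-6
        lo = np.searchsorted(mz, target - delta, side="left")
        hi = np.searchsorted(mz, target + delta, side="right")
        if hi == lo:
            out[channel] = float("nan")
            continue
        window = mz[lo:hi]
        j = lo + int(np.argmin(np.abs(window - target)))
        out[channel] = float(spectrum.intensity[j])
    return out


def build_reporter_matrix(
    spectra: dict[str, Spectrum], scan_ids, config: RunConfig
) -> pd.DataFrame:
    """Raw reporter matrix: rows = scans with a kept PSM, columns = channels."""
    rows = {}
    for sid in scan_ids:
        rows[sid] = extract_reporters(
            spectra[sid], config.reporter_channels, config.reporter_tol_ppm
        )
    df = pd.DataFrame.from_dict(rows, orient="index")
    return df.reindex(columns=list(config.reporter_channels))


def channel_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each channel to the maximum average channel.

    Channel means are taken over all rows (PSM-bearing scans), ignoring
    missing entries; each channel is multiplied by max(means)/its mean so
    all post-normalization channel means equal the original maximum.  The
    operation is idempotent.
    """
    means = matrix.mean(axis=0, skipna=True)
    bad = means.index[means.isna() | (means <= 0)]
    if len(bad):
        raise ValueError(
            f"channel(s) {list(bad)} have no usable reporter signal to normalize"
        )
    factors = means.max() / means
    return matrix * factors


def coverage_filter(
    reporters: dict[str, float] | pd.Series,
    channel_conditions: dict[str, tuple[str, int]],
    min_per_condition: int = 2,
) -> bool:
    """True iff every condition has >= min non-missing reporters in the scan."""
    counts: dict[str, int] = {}
    for ch, (cond, _) in channel_conditions.items():
        val = reporters.get(ch, float("nan"))
        ok = val is not None and not (isinstance(val, float) and math.isnan(val))
        counts.setdefault(cond, 0)
        if ok:
            counts[cond] += 1
    return all(n >= min_per_condition for n in counts.values())


def coverage_mask(matrix: pd.DataFrame, config: RunConfig) -> pd.Series:
    return pd.Series(
        {
            sid: coverage_filter(
                matrix.loc[sid],
                config.channel_conditions,
                config.min_reporters_per_condition,
            )
            for sid in matrix.index
        },
        dtype=bool,
    )


def _welch_two_sided(a: np.ndarray, b: np.ndarray) -> float:
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)


def group_and_test(
    scan_quants: list[SpectrumQuant],
    log2_matrix: pd.DataFrame,
    config: RunConfig,
    scan_fractions: dict[str, dict[str, float]] | None = None,
) -> list[ProteoformGroupResult]:
    """Group scans by proteoform and test condition contrasts.

    All log2 reporter signals of a group's scans are pooled per condition;
    the log2 fold change of a contrast (A, B) is mean(A) - mean(B), and its
    p-value comes from a two-sided Welch t-test on the pooled values.  By
    default a chimeric scan contributes its full reporter signal to every
    proteoform it is assigned to; with ``config.weight_by_fraction`` the
    linear-space intensity is multiplied by the scan's proteoform fraction
    before the log2 transform.

    ``log2_matrix`` must already be channel-normalized and log2-scaled,
    restricted to coverage-passing scans.  A contrast with fewer than two
    pooled values in either condition is flagged untestable (p = NaN, fold
    change still reported).
    """
    groups: dict[str, list[tuple[str, float]]] = {}
    for sq in scan_quants:
        if not sq.quantifiable or sq.scan_id not in log2_matrix.index:
            continue
        for key, fraction in sq.fractions.items():
            if fraction <= 0:
                continue
            groups.setdefault(key, []).append((sq.scan_id, fraction))

    cond_channels = {c: config.channels_for(c) for c in config.conditions}
    results: list[ProteoformGroupResult] = []
    for key in sorted(groups):
        members = groups[key]
        scan_ids = tuple(sid for sid, _ in members)
        pooled: dict[str, list[float]] = {c: [] for c in cond_channels}
        for sid, fraction in members:
            row = log2_matrix.loc[sid]
            offset = math.log2(fraction) if config.weight_by_fraction else 0.0
            for cond, channels in cond_channels.items():
                for ch in channels:
                    val = row.get(ch, float("nan"))
                    if not math.isnan(val):
                        pooled[cond].append(val + offset)
        condition_means = {
            c: (float(np.mean(v)) if v else float("nan")) for c, v in pooled.items()
        }
        log2fc: dict[tuple[str, str], float] = {}
        p_value: dict[tuple[str, str], float] = {}
        untestable: dict[tuple[str, str], bool] = {}
        for a, b in config.contrasts:
            log2fc[(a, b)] = condition_means[a] - condition_means[b]
            va, vb = np.asarray(pooled[a]), np.asarray(pooled[b])
            if va.size < 2 or vb.size < 2:
                p_value[(a, b)] = float("nan")
                untestable[(a, b)] = True
            else:
                p_value[(a, b)] = _welch_two_sided(va, vb)
                untestable[(a, b)] = False
        results.append(
            ProteoformGroupResult(
                proteoform_key=key,
                scan_ids=scan_ids,
                condition_means=condition_means,
                log2fc=log2fc,
                p_value=p_value,
                untestable=untestable,
            )
        )

    if config.bh_correction and results:
        for contrast in config.contrasts:
            idx = [
                i
                for i, r in enumerate(results)
                if not math.isnan(r.p_value[tuple(contrast)])
            ]
            if not idx:
                continue
            ps = [results[i].p_value[tuple(contrast)] for i in idx]
            qs = stats.false_discovery_control(ps, method="bh")
            for i, q in zip(idx, qs):
                results[i].q_value[tuple(contrast)] = float(q)
    return results
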