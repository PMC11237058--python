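"""Chromatographic peak detection, fragment-based precursor screening,
coeluting label-pair detection and blank filtering.

The screening workflow mirrors how glutathione-conjugate discovery is done
on data-dependent MS2 data: find every precursor whose spectrum contains a
diagnostic fragment (for glutathione conjugates, m/z 308.0912 in positive
mode), group the matching precursors isobarically (±2 ppm, single linkage),
and count the chromatographic peaks passing width/intensity filters in the
associated extracted-ion chromatograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ScreenError",
    "Chromatogram",
    "ChromPeak",
    "MS2Record",
    "ScreenHit",
    "detect_chrom_peaks",
    "fragment_precursor_screen",
    "find_label_pairs",
    "blank_filter",
]


class ScreenError(ValueError):
    """Invalid screening input or parameters."""


@dataclass(frozen=True)
class Chromatogram:
    """Extracted-ion chromatogram: intensity vs time for one precursor window.

    Time is in seconds and must be strictly increasing; intensities are
    non-negative detector counts.
    """

    time_s: np.ndarray
    intensity: np.ndarray
    precursor_mz: float = float("nan")
    id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ScreenError("time and intensity must be equal-length 1-D arrays")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ScreenError("time axis must be strictly increasing")
        if np.any(y < 0):
            raise ScreenError("intensities must be non-negative")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "intensity", y)


@dataclass(frozen=True)
class ChromPeak:
    """A detected chromatographic peak (valley-to-valley delimitation)."""

    apex_time_s: float
    apex_intensity: float
    left_s: float
    right_s: float

    @property
    def base_width_s(self) -> float:
        return self.right_s - self.left_s

    def __post_init__(self) -> None:
        if not (self.left_s <= self.apex_time_s <= self.right_s):
            raise ScreenError("peak apex must lie within its bounds")
        if self.right_s <= self.left_s:
            raise ScreenError("peak width must be positive")


@dataclass(frozen=True)
class MS2Record:
    """One data-dependent MS2 spectrum: precursor plus fragment list."""

    precursor_mz: float
    rt_min: float
    fragments_mz: np.ndarray
    fragments_intensity: np.ndarray
    id: str = ""
    meta: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        fmz = np.asarray(self.fragments_mz, dtype=float)
        fint = np.asarray(self.fragments_intensity, dtype=float)
        if fmz.shape != fint.shape or fmz.ndim != 1:
            raise ScreenError("fragment m/z and intensity must be equal-length 1-D arrays")
        if np.any(fint < 0):
            raise ScreenError("fragment intensities must be non-negative")
        # fragments cannot exceed the (singly charged) precursor by more
        # than the isotope envelope allows
        if fmz.size and np.any(fmz >= self.precursor_mz + 1.0):
            raise ScreenError("fragment m/z exceeds precursor m/z + 1")
        object.__setattr__(self, "fragments_mz", fmz)
        object.__setattr__(self, "fragments_intensity", fint)


@dataclass(frozen=True)
class ScreenHit:
    """One isobaric precursor group carrying the diagnostic fragment."""

    group_mz: float
    member_mz: tuple
    record_ids: tuple
    fragment_mz_matched: tuple
    fragment_ppm_error: tuple
    n_chrom_peaks: int = 0


def detect_chrom_peaks(
    xic: Chromatogram,
    min_width_s: float = 6.0,
    min_intensity: float = 1e5,
) -> list[ChromPeak]:
    """Detect local-maximum peaks delimited at flanking minima and filter them.

    A peak is retained when its valley-to-valley base width exceeds
    ``min_width_s`` **and** its apex intensity is at least ``min_intensity``
    (the paper-style "width > 6 s and intensity >= 1e5" contract). Returned
    sorted by apex time.
    """
    y = xic.intensity
    t = xic.time_s
    n = y.size
    if n < 3:
        return []
    # strict local maxima with plateau handling: a plateau counts once, at
    # its first index
    peaks: list[ChromPeak] = []
    i = 1
    while i < n - 1:
        if y[i] > y[i - 1]:
            j = i
            while j < n - 1 and y[j + 1] == y[j]:
                j += 1
            if j < n - 1 and y[j + 1] < y[j]:
                # apex span [i, j]; walk down to flanking minima
                left = i
                while left > 0 and y[left - 1] < y[left]:
                    left -= 1
                right = j
                while right < n - 1 and y[right + 1] < y[right]:
                    right += 1
                apex = i + int(np.argmax(y[i : j + 1]))
                peak = ChromPeak(
                    apex_time_s=float(t[apex]),
                    apex_intensity=float(y[apex]),
                    left_s=float(t[left]),
                    right_s=float(t[right]),
                )
                if peak.base_width_s > min_width_s and peak.apex_intensity >= min_intensity:
                    peaks.append(peak)
            i = j + 1
        else:
            i += 1
    return sorted(peaks, key=lambda p: p.apex_time_s)


def _match_fragment(record: MS2Record, fragment_mz: float, tol_ppm: float):
    """Best fragment within tol_ppm of fragment_mz, or None."""
    if record.fragments_mz.size == 0:
        return None
    ppm = 1e6 * (record.fragments_mz - fragment_mz) / fragment_mz
    k = int(np.argmin(np.abs(ppm)))
    if abs(ppm[k]) <= tol_ppm:
        return float(record.fragments_mz[k]), float(ppm[k])
    return None


def fragment_precursor_screen(
    records: Sequence[MS2Record],
    fragment_mz: float,
    fragment_tol_ppm: float = 10.0,
    precursor_group_ppm: float = 2.0,
    xics: Mapping[int, Sequence[Chromatogram]] | None = None,
    min_peak_width_s: float = 6.0,
    min_peak_intensity: float = 1e5,
) -> list[ScreenHit]:
    """Screen MS2 records for a diagnostic fragment and group the precursors.

    Records containing a fragment within ``fragment_tol_ppm`` of
    ``fragment_mz`` are selected; their precursor m/z are grouped by
    single-linkage clustering with a ±``precursor_group_ppm`` link
    threshold. When ``xics`` maps group index -> chromatograms, each hit's
    ``n_chrom_peaks`` counts the peaks passing the width/intensity filters.
    """
    if fragment_tol_ppm < 0 or precursor_group_ppm < 0:
        raise ScreenError("tolerances must be non-negative")
    matched = []
    for rec in records:
        hit = _match_fragment(rec, fragment_mz, fragment_tol_ppm)
        if hit is not None:
            matched.append((rec, hit))
    if not matched:
        return []
    matched.sort(key=lambda rh: rh[0].precursor_mz)
    groups: list[list[tuple[MS2Record, tuple]]] = [[matched[0]]]
    for rec, hit in matched[1:]:
        prev_mz = groups[-1][-1][0].precursor_mz
        link_ppm = 1e6 * (rec.precursor_mz - prev_mz) / prev_mz
        if link_ppm <= precursor_group_ppm:
            groups[-1].append((rec, hit))
        else:
            groups.append([(rec, hit)])
    hits = []
    for gi, group in enumerate(groups):
        mzs = tuple(r.precursor_mz for r, _ in group)
        n_peaks = 0
        if xics is not None and gi in xics:
            for xic in xics[gi]:
                n_peaks += len(
                    detect_chrom_peaks(xic, min_peak_width_s, min_peak_intensity)
                )
        hits.append(
            ScreenHit(
                group_mz=float(np.mean(mzs)),
                member_mz=mzs,
                record_ids=tuple(r.id for r, _ in group),
                fragment_mz_matched=tuple(h[0] for _, h in group),
                fragment_ppm_error=tuple(h[1] for _, h in group),
                n_chrom_peaks=n_peaks,
            )
        )
    return hits


def find_label_pairs(
    features: Sequence[tuple[float, float, float]],
    mass_shift_da: float,
    mz_tol_ppm: float = 5.0,
    rt_tol_min: float = 0.1,
) -> list[tuple[int, int]]:
    """Find coeluting (light, heavy) feature pairs separated by a label shift.

    ``features`` is a sequence of (m/z, RT_min, area). Returns index pairs
    (i_light, i_heavy) with |mz_h - mz_l - shift| within ``mz_tol_ppm`` of
    the heavy m/z and |ΔRT| <= ``rt_tol_min``, sorted by light m/z then
    heavy m/z.
    """
    feats = [(float(m), float(r)) for m, r, *_ in features]
    pairs = []
    for i, (mz_l, rt_l) in enumerate(feats):
        for j, (mz_h, rt_h) in enumerate(feats):
            if i == j:
                continue
            if abs(mz_h - mz_l - mass_shift_da) <= mz_tol_ppm * 1e-6 * mz_h and abs(
                rt_h - rt_l
            ) <= rt_tol_min:
                pairs.append((i, j))
    pairs.sort(key=lambda ij: (feats[ij[0]][0], feats[ij[1]][0]))
    return pairs


def blank_filter(
    sample_means: Sequence[float],
    blank_means: Sequence[float],
    min_ratio: float = 3.0,
    feature_ids: Sequence | None = None,
) -> list:
    """Retain features whose sample mean is >= ``min_ratio`` x blank mean.

    A zero blank mean keeps the feature whenever its sample mean is
    positive. The boundary (exactly ``min_ratio`` x blank) is inclusive.
    Returns the retained feature ids (indices when ids are not given).
    """
    s = np.asarray(sample_means, dtype=float)
    b = np.asarray(blank_means, dtype=float)
    if s.shape != b.shape or s.ndim != 1:
        raise ScreenError("sample and blank vectors must be equal-length 1-D")
    ids = list(range(s.size)) if feature_ids is None else list(feature_ids)
    if len(ids) != s.size:
        raise ScreenError("feature_ids length mismatch")
    keep = np.where(b > 0, s >= min_ratio * b, s > 0)
    return [fid for fid, k in zip(ids, keep) if k]
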