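"""Normative bands and pointwise Z-score deviation profiles.

A normative band is the pointwise mean and sample standard deviation of
subject-averaged, time-normalized joint-angle waveforms from a reference
cohort.  A patient cycle is compared station-by-station:

    Z(t) = (x_patient(t) - mu_norm(t)) / sigma_norm(t)

Stations with |Z(t)| >= 1.96 (the two-sided standard-normal critical
value for 95% central coverage) are flagged, merged into maximal
contiguous regions, and localized to gait phases relative to the
stance-to-swing boundary (default 60% of the cycle).

No multiple-comparison correction is applied across stations or joints;
under the null each joint is expected to show ~5% falsely flagged
stations.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import norm

from .containers import NormalizedCycle

#: |Z| threshold: two-sided standard-normal critical value for 95%
#: central coverage, rounded to two decimals.
DEFAULT_THRESHOLD = round(float(norm.ppf(0.975)), 2)

#: Stance-to-swing boundary, % gait cycle (toe-off of normal gait).
DEFAULT_STANCE_END = 60.0

#: Sub-phase vocabulary: label -> (start %, end %); attached to a region
#: when the region midpoint falls inside the window.
SUBPHASE_WINDOWS = {
    "terminal stance": (50.0, 60.0),
    "pre-swing": (50.0, 65.0),
    "early-mid swing": (60.0, 85.0),
    "terminal swing": (85.0, 100.0),
}


class DegenerateBandError(ValueError):
    """Raised when sigma_norm(t) = 0 at some station."""


def subject_average(cycles: list) -> NormalizedCycle:
    """Pointwise arithmetic mean of one subject's normalized cycles."""
    if not cycles:
        raise ValueError("subject_average requires at least one cycle")
    joints = set(cycles[0].joints)
    n = cycles[0].n_stations
    for c in cycles:
        if set(c.joints) != joints or c.n_stations != n:
            raise ValueError("all cycles must share the same joint set and station count")
    angles = {j: np.mean([c.angles[j] for c in cycles], axis=0) for j in sorted(joints)}
    return NormalizedCycle(angles=angles, side=cycles[0].side,
                           cycle_id="subject_mean", n_stations=n)


@dataclass
class NormativeBand:
    """Pointwise normative mean and SD waveforms per joint.

    ``mu`` and ``sigma`` map joint -> 101-station arrays (deg);
    ``n_subjects`` is the cohort size; ``provenance`` records what
    reference population the band was built from (e.g. an adult cohort
    standing in for pediatric norms).
    """

    mu: dict
    sigma: dict
    n_subjects: int
    n_stations: int = 101
    provenance: str = "synthetic cohort"

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("a normative band requires n_subjects >= 2")
        self.mu = {j: np.asarray(v, dtype=float) for j, v in self.mu.items()}
        self.sigma = {j: np.asarray(v, dtype=float) for j, v in self.sigma.items()}
        for j in self.mu:
            if self.mu[j].shape != (self.n_stations,) or self.sigma[j].shape != (self.n_stations,):
                raise ValueError(f"band arrays for {j!r} must have {self.n_stations} stations")
            if (self.sigma[j] < 0).any():
                raise ValueError("sigma_norm must be nonnegative")

    @property
    def joints(self):
        return list(self.mu)

    @property
    def degenerate(self) -> bool:
        """True when sigma is zero at any station of any joint."""
        return any((s == 0).any() for s in self.sigma.values())


def build_normative_band(subject_means: list,
                         sigma_floor: float | None = None,
                         provenance: str = "synthetic cohort") -> NormativeBand:
    """Pointwise mean and sample SD (n-1 denominator) over subjects.

    ``sigma_floor`` optionally floors the SD waveforms at a minimum
    value (off by default); bands with any zero-SD station are flagged
    degenerate and rejected by Z-scoring.
    """
    if len(subject_means) < 2:
        raise ValueError(
            f"need >= 2 subject means to define a normative SD, got {len(subject_means)}"
        )
    joints = sorted(subject_means[0].joints)
    n = subject_means[0].n_stations
    mu, sigma = {}, {}
    for j in joints:
        stack = np.stack([s.angles[j] for s in subject_means])
        mu[j] = stack.mean(axis=0)
        sigma[j] = stack.std(axis=0, ddof=1)
        if sigma_floor is not None:
            sigma[j] = np.maximum(sigma[j], sigma_floor)
    return NormativeBand(mu=mu, sigma=sigma, n_subjects=len(subject_means),
                         n_stations=n, provenance=provenance)


@dataclass
class DeviationRegion:
    """A maximal run of flagged stations: [start, end] % inclusive, the
    extreme (signed) Z inside it, and optional phase labels."""

    start: float
    end: float
    extreme_z: float
    phase: str | None = None
    subphases: tuple = ()


@dataclass
class DeviationProfile:
    """Pointwise Z-scores and (after flagging) regions per joint."""

    z: dict                      # joint -> ndarray (n_stations,)
    threshold: float | None = None
    flags: dict | None = None    # joint -> bool ndarray
    regions: dict | None = None  # joint -> list of DeviationRegion
    n_stations: int = 101

    @property
    def joints(self):
        return list(self.z)

    @property
    def stations(self) -> np.ndarray:
        return np.linspace(0.0, 100.0, self.n_stations)


def zscore_waveform(patient: NormalizedCycle, band: NormativeBand) -> DeviationProfile:
    """Pointwise Z(t) = (x_patient(t) - mu(t)) / sigma(t) per joint.

    Raises DegenerateBandError if sigma is zero anywhere (never a
    silent infinity).
    """
    if patient.n_stations != band.n_stations:
        raise ValueError("patient cycle and band have different station counts")
    z = {}
    for j in band.joints:
        if j not in patient.angles:
            raise ValueError(f"patient cycle lacks joint {j!r}")
        sig = band.sigma[j]
        zero = np.flatnonzero(sig == 0)
        if zero.size:
            station = patient.stations[zero[0]]
            raise DegenerateBandError(
                f"degenerate normative band at station {station:g}% (joint {j!r}): "
                "sigma_norm = 0"
            )
        z[j] = (patient.angles[j] - band.mu[j]) / sig
    return DeviationProfile(z=z, n_stations=band.n_stations)


def _find_regions(flags: np.ndarray, z: np.ndarray, stations: np.ndarray) -> list:
    regions = []
    i = 0
    n = len(flags)
    while i < n:
        if flags[i]:
            j = i
            while j + 1 < n and flags[j + 1]:
                j += 1
            seg = z[i:j + 1]
            extreme = seg[np.argmax(np.abs(seg))]
            regions.append(DeviationRegion(start=float(stations[i]),
                                           end=float(stations[j]),
                                           extreme_z=float(extreme)))
            i = j + 1
        else:
            i += 1
    return regions


def flag_deviations(profile: DeviationProfile,
                    threshold: float = DEFAULT_THRESHOLD) -> DeviationProfile:
    """Flag stations with |Z| >= threshold (inclusive) and merge maximal
    flagged runs into regions carrying their extreme signed Z."""
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    stations = profile.stations
    flags, regions = {}, {}
    for j, z in profile.z.items():
        f = np.abs(z) >= threshold
        flags[j] = f
        regions[j] = _find_regions(f, z, stations)
    return replace(profile, threshold=threshold, flags=flags, regions=regions)


def localize_phases(profile: DeviationProfile,
                    stance_end: float = DEFAULT_STANCE_END) -> DeviationProfile:
    """Label each region stance / swing / stance-to-swing and attach
    sub-phase labels whose window contains the region midpoint.

    Boundary convention: a region starting exactly at ``stance_end`` is
    labeled swing (toe-off is the onset of swing); a region ending at or
    before ``stance_end`` is stance; a region spanning the boundary is
    stance-to-swing.
    """
    if profile.regions is None:
        raise ValueError("flag_deviations must be applied before localize_phases")
    new_regions = {}
    for j, regs in profile.regions.items():
        out = []
        for r in regs:
            if r.start >= stance_end:
                phase = "swing"
            elif r.end <= stance_end:
                phase = "stance"
            else:
                phase = "stance-to-swing"
            mid = 0.5 * (r.start + r.end)
            subs = tuple(name for name, (a, b) in SUBPHASE_WINDOWS.items()
                         if a <= mid <= b)
            out.append(replace(r, phase=phase, subphases=subs))
        new_regions[j] = out
    return replace(profile, regions=new_regions)


def unflagged_fraction(profile: DeviationProfile) -> float:
    """Fraction of stations (over all joints) inside the normative band."""
    if profile.flags is None:
        raise ValueError("flag_deviations must be applied first")
    total = sum(f.size for f in profile.flags.values())
    flagged = sum(int(f.sum()) for f in profile.flags.values())
    return 1.0 - flagged / total
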