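"""Core data model for SILAC phosphosite kinetic profiles.

The experiment measures, for every phosphosite, the log2 SILAC ratio of
stimulus vs control at 15 time points (0, 2, ..., 28 minutes) under two
stimuli (heat shock at 42C and cold stress at 18C, both from 30C control).
Profiles are kept on the log2 fold-change scale throughout; missing time
points are represented explicitly as NaN and are never imputed at the I/O
layer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, ParameterError

#: Standard acquisition grid, minutes: 0, 2, ..., 28 (15 points).
TIME_GRID: np.ndarray = np.arange(0, 30, 2, dtype=float)
TIME_GRID.setflags(write=False)

N_TIMEPOINTS = len(TIME_GRID)

STIMULI = ("heat", "cold")

_SITE_RE = re.compile(r"^(?P<protein>.+)_(?P<residue>[STY])(?P<position>\d+)_m(?P<mult>\d+)$")


@dataclass(frozen=True, order=True)
class PhosphoSiteID:
    """Identity of a quantified phosphosite form.

    A site is a residue (S/T/Y) at a 1-based position in a protein; peptide
    forms carrying different numbers of phosphogroups (multiplicity) are
    distinct records, because mono- and multi-phosphorylated forms of the
    same residue can behave differently.
    """

    protein: str
    position: int
    residue: str
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ParameterError(f"position must be >= 1, got {self.position}")
        if self.residue not in ("S", "T", "Y"):
            raise ParameterError(f"residue must be one of S/T/Y, got {self.residue!r}")
        if self.multiplicity < 1:
            raise ParameterError(f"multiplicity must be >= 1, got {self.multiplicity}")

    def __str__(self) -> str:
        return f"{self.protein}_{self.residue}{self.position}_m{self.multiplicity}"

    @classmethod
    def parse(cls, text: str) -> "PhosphoSiteID":
        """Parse the canonical string form ``PROT_S123_m1``."""
        m = _SITE_RE.match(text)
        if m is None:
            raise FormatError(f"unparseable site id: {text!r}")
        return cls(
            protein=m.group("protein"),
            position=int(m.group("position")),
            residue=m.group("residue"),
            multiplicity=int(m.group("mult")),
        )


@dataclass
class KineticProfile:
    """One phosphosite x one stimulus: a log2 fold-change time course.

    ``log2fc`` holds NaN at missing time points; ``localization_probs`` (the
    per-time-point probability that the phosphogroup is on the reported
    residue) may be absent entirely or NaN where unmeasured.
    """

    site: PhosphoSiteID
    stimulus: str
    log2fc: np.ndarray
    localization_probs: np.ndarray | None = None
    times: np.ndarray = field(default_factory=lambda: TIME_GRID)

    def __post_init__(self) -> None:
        self.log2fc = np.asarray(self.log2fc, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.stimulus not in STIMULI:
            raise ParameterError(f"stimulus must be one of {STIMULI}, got {self.stimulus!r}")
        if len(self.log2fc) != len(self.times):
            raise FormatError(
                f"{self.key}: {len(self.log2fc)} values for {len(self.times)} time points"
            )
        if np.any(np.diff(self.times) <= 0):
            raise FormatError("time grid must be strictly increasing")
        if self.localization_probs is not None:
            self.localization_probs = np.asarray(self.localization_probs, dtype=float)
            if len(self.localization_probs) != len(self.times):
                raise FormatError(f"{self.key}: localization prob length mismatch")

    @property
    def key(self) -> tuple[str, str]:
        return (str(self.site), self.stimulus)

    @property
    def missing_mask(self) -> np.ndarray:
        """True where the ratio was not quantified."""
        return np.isnan(self.log2fc)

    @property
    def n_quantified(self) -> int:
        return int(np.sum(~self.missing_mask))

    def mean_localization_prob(self) -> float:
        """Mean localization probability over quantified time points.

        Returns NaN when no probability accompanies any quantified point.
        """
        if self.localization_probs is None:
            return float("nan")
        probs = self.localization_probs[~self.missing_mask]
        probs = probs[~np.isnan(probs)]
        if probs.size == 0:
            return float("nan")
        return float(np.mean(probs))


class ProfileMatrix:
    """Collection of kinetic profiles keyed by (site string, stimulus).

    All member profiles share one time grid; at most one profile per key.
    """

    def __init__(self, profiles: list[KineticProfile] | None = None,
                 time_grid: np.ndarray = TIME_GRID):
        self.time_grid = np.asarray(time_grid, dtype=float)
        self._profiles: dict[tuple[str, str], KineticProfile] = {}
        for p in profiles or []:
            self.add(p)

    def add(self, profile: KineticProfile) -> None:
        if not np.array_equal(profile.times, self.time_grid):
            raise FormatError(f"{profile.key}: time grid differs from the matrix grid")
        if profile.key in self._profiles:
            raise FormatError(f"duplicate profile for {profile.key}")
        self._profiles[profile.key] = profile

    def __len__(self) -> int:
        return len(self._profiles)

    def __iter__(self):
        return iter(self._profiles.values())

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._profiles

    def get(self, site: str | PhosphoSiteID, stimulus: str) -> KineticProfile | None:
        return self._profiles.get((str(site), stimulus))

    def keys(self):
        return self._profiles.keys()

    @property
    def sites(self) -> list[str]:
        """Unique site ids, in insertion order."""
        seen: dict[str, None] = {}
        for site_id, _ in self._profiles:
            seen.setdefault(site_id)
        return list(seen)


@dataclass
class ProteinAbundanceTrack:
    """Protein-level log2 stimulus/control ratios from nonphosphorylated peptides.

    Used to flag proteins whose abundance drifts during the experiment, so
    that apparent phosphorylation dynamics on them can be excluded.
    """

    protein: str
    stimulus: str
    log2fc_series: np.ndarray
    times: np.ndarray = field(default_factory=lambda: TIME_GRID)

    def __post_init__(self) -> None:
        self.log2fc_series = np.asarray(self.log2fc_series, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.stimulus not in STIMULI:
            raise ParameterError(f"stimulus must be one of {STIMULI}")
        if len(self.log2fc_series) != len(self.times):
            raise FormatError(f"{self.protein}: track length mismatch")

    def max_abs_log2fc(self) -> float:
        vals = self.log2fc_series[~np.isnan(self.log2fc_series)]
        if vals.size == 0:
            return float("nan")
        return float(np.max(np.abs(vals)))
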