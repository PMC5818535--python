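"""CEST profile normalisation, scoring, and region comparison.

Saturation-transfer experiments report, per residue, the visible-state peak
intensity after continuous-wave saturation at a series of large offsets;
an extra spectrum saturated far off resonance (-100 kHz) is the reference.
Exchange with a broad membrane-bound state deepens the near-resonance dip,
so a scalar transfer score per residue is defined as

    score = 1 - mean(I | |offset| <= near_band) / mean(I | |offset| >= far_band)

clipped to [0, 1]. Scores are compared between conditions region by region
(N-terminus / NAC / C-terminus) with a seeded bootstrap over residues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from synucalc.errors import InputError
from synucalc.regions import DEFAULT_REGIONS, RegionMap

logger = logging.getLogger(__name__)

#: Saturation offsets (kHz) of the standard acquisition schedule.
OFFSET_SCHEDULE_KHZ = (-9.0, -7.0, -5.0, -4.0, -3.0, -1.5, 0.0, 1.5, 3.0, 4.0, 5.0, 7.0, 9.0)
#: Far-off-resonance reference offset (kHz).
REFERENCE_OFFSET_KHZ = -100.0


@dataclass
class CestProfile:
    """Normalised saturation-transfer intensities of one residue."""

    residue: int
    offsets: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.offsets.shape != self.intensities.shape:
            raise InputError("offsets and intensities must align")
        if np.any(self.intensities < 0):
            raise InputError("normalised intensities must be nonnegative")
        high = self.intensities > 1.2
        if np.any(high):
            logger.warning(
                "residue %d: %d normalised intensities above 1.2",
                self.residue,
                int(high.sum()),
            )


@dataclass(frozen=True)
class CestScore:
    residue: int
    score: float


def normalize_cest(
    raw: pd.DataFrame,
    reference: dict[int, float] | None = None,
    reference_offset: float = REFERENCE_OFFSET_KHZ,
) -> list[CestProfile]:
    """Divide each residue's intensities by its far-off-resonance reference.

    ``raw`` is a long table with columns ``residue, offset_kHz, intensity``;
    reference values are either supplied as a mapping or taken from rows at
    ``reference_offset``. Residues with a nonpositive (or missing) reference
    are excluded and logged.
    """
    required = {"residue", "offset_kHz", "intensity"}
    if not required <= set(raw.columns):
        raise InputError(f"CEST table needs columns {sorted(required)}")
    is_ref = np.isclose(raw["offset_kHz"], reference_offset)
    if reference is None:
        reference = (
            raw.loc[is_ref].groupby("residue")["intensity"].mean().to_dict()
        )
    body = raw.loc[~is_ref]
    profiles: list[CestProfile] = []
    for residue, grp in body.groupby("residue"):
        ref = reference.get(residue)
        if ref is None or ref <= 0:
            logger.warning("residue %s: missing/nonpositive reference, excluded", residue)
            continue
        grp = grp.sort_values("offset_kHz")
        profiles.append(
            CestProfile(
                residue=int(residue),
                offsets=grp["offset_kHz"].to_numpy(),
                intensities=grp["intensity"].to_numpy() / ref,
            )
        )
    return profiles


def cest_score(
    profile: CestProfile, near_band: float = 4.0, far_band: float = 7.0
) -> CestScore:
    """Scalar saturation-transfer score in [0, 1] for one residue profile."""
    near = np.abs(profile.offsets) <= near_band
    far = np.abs(profile.offsets) >= far_band
    if not near.any() or not far.any():
        raise InputError("near/far bands must each contain at least one offset")
    far_mean = profile.intensities[far].mean()
    if far_mean <= 0:
        raise InputError("far-band mean intensity must be positive")
    score = 1.0 - profile.intensities[near].mean() / far_mean
    return CestScore(residue=profile.residue, score=float(np.clip(score, 0.0, 1.0)))


def score_profiles(
    profiles: list[CestProfile], near_band: float = 4.0, far_band: float = 7.0
) -> list[CestScore]:
    return [cest_score(p, near_band, far_band) for p in profiles]


def compare_regions(
    scores_ca: list[CestScore],
    scores_noca: list[CestScore],
    regions: RegionMap = DEFAULT_REGIONS,
    n_boot: int = 1000,
    seed: int = 42,
) -> dict[str, dict]:
    """Per-region mean score difference (+Ca minus -Ca) with bootstrap CI.

    Both conditions must cover the same residues. The CI is a seeded
    percentile bootstrap (2.5/97.5%) over residues within each region.
    Empty regions are reported with ``status: "missing"``.
    """
    a = {s.residue: s.score for s in scores_ca}
    b = {s.residue: s.score for s in scores_noca}
    if set(a) != set(b):
        raise InputError("conditions must cover the same residues")
    rng = np.random.default_rng(seed)
    out: dict[str, dict] = {}
    for label in regions.labels:
        members = [r for r in regions.residues(label) if r in a]
        if not members:
            out[label] = {"status": "missing"}
            continue
        diff = np.array([a[r] - b[r] for r in members])
        boots = np.array(
            [diff[rng.integers(0, len(diff), len(diff))].mean() for _ in range(n_boot)]
        )
        out[label] = {
            "status": "ok",
            "mean_diff": float(diff.mean()),
            "ci_low": float(np.percentile(boots, 2.5)),
            "ci_high": float(np.percentile(boots, 97.5)),
            "n_residues": len(members),
        }
    return out


def scores_to_frame(scores: list[CestScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {"residue": [s.residue for s in scores], "score": [s.score for s in scores]}
    )
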