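"""Protein region definitions for the 140-residue alpha-synuclein sequence.

The three canonical segments are the membrane-binding N terminus (aa 1-60),
the aggregation-prone non-amyloid-beta component (NAC, aa 61-95) and the
acidic C terminus (aa 96-140). Intervals are half-open on residue indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from synucalc.errors import InputError

N_RESIDUES = 140


@dataclass(frozen=True)
class RegionMap:
    """Partition of residues 1..140 into three labelled half-open intervals."""

    n_term: tuple[int, int] = (1, 61)
    nac: tuple[int, int] = (61, 96)
    c_term: tuple[int, int] = (96, 141)
    labels: tuple[str, str, str] = field(
        default=("N-terminus", "NAC", "C-terminus")
    )

    def __post_init__(self) -> None:
        ivals = (self.n_term, self.nac, self.c_term)
        covered = set()
        for lo, hi in ivals:
            if lo >= hi:
                raise InputError(f"empty region interval [{lo}, {hi})")
            span = set(range(lo, hi))
            if covered & span:
                raise InputError("region intervals overlap")
            covered |= span
        if covered != set(range(1, N_RESIDUES + 1)):
            raise InputError("regions must partition residues 1..140")

    def label_of(self, residue: int) -> str:
        for (lo, hi), name in zip(
            (self.n_term, self.nac, self.c_term), self.labels
        ):
            if lo <= residue < hi:
                return name
        raise InputError(f"residue {residue} outside 1..{N_RESIDUES}")

    def residues(self, label: str) -> range:
        for (lo, hi), name in zip(
            (self.n_term, self.nac, self.c_term), self.labels
        ):
            if name == label:
                return range(lo, hi)
        raise InputError(f"unknown region label {label!r}")


DEFAULT_REGIONS = RegionMap()

#: Residues whose amide resonances shift most upon calcium binding
#: (all C-terminal; used as the default perturbation preset).
CALCIUM_SHIFT_SITES = (104, 107, 112, 119, 123, 124, 126, 127, 129, 130, 135, 136, 137)
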