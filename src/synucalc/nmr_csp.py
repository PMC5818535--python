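"""Chemical-shift-perturbation analysis and multi-ligand binding fits.

A calcium titration followed by 1H-15N HSQC yields, per residue, amide
chemical shifts (delta_H, delta_N) and peak intensities at each total
calcium concentration. Shift changes are combined into a weighted CSP

    ``Delta_delta = sqrt(0.5 * (dH**2 + 0.15 * dN**2))``

and interpreted through a multi-ligand equilibrium in which L calcium ions
bind one protein molecule as a single unit with dissociation constant K_D:

    P_free + Ca_L  <=>  P_bound(Ca)_L .

Solving the mass-action system for the bound fraction chi_B as a function of
total protein P and total calcium C gives the closed form

    chi_B = (P + C/L + K_D - sqrt((P + C/L + K_D)**2 - 4*P*C/L)) / (2*P),

which is fitted globally across residues, with one saturation shift
``Delta_delta_sat`` per residue, to recover K_D and L.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from synucalc.errors import FitError, InputError
from synucalc.regions import N_RESIDUES

logger = logging.getLogger(__name__)

#: Relative weight of the 15N shift in the combined CSP.
NITROGEN_WEIGHT = 0.15


@dataclass(frozen=True)
class ShiftRecord:
    """Amide peak position and height for one residue at one titration point."""

    residue: int
    delta_H: float
    delta_N: float
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if not 1 <= self.residue <= N_RESIDUES:
            raise InputError(f"residue {self.residue} outside 1..{N_RESIDUES}")
        if self.intensity < 0:
            raise InputError("intensity must be nonnegative")


@dataclass(frozen=True)
class CSPValue:
    residue: int
    delta_delta: float


@dataclass
class TitrationSeries:
    """Per-residue shifts/intensities on a common residue set across a titration.

    Arrays are indexed ``[concentration, residue]`` with ``ligand_concs``
    strictly ascending (first point, usually 0 ligand, serves as reference).
    Concentrations in µM.
    """

    protein_conc: float
    ligand_concs: np.ndarray
    residues: np.ndarray
    delta_H: np.ndarray
    delta_N: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.ligand_concs = np.asarray(self.ligand_concs, dtype=float)
        self.residues = np.asarray(self.residues, dtype=int)
        for name in ("delta_H", "delta_N", "intensity"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.protein_conc <= 0:
            raise InputError("protein_conc must be positive")
        if np.any(self.ligand_concs < 0) or np.any(np.diff(self.ligand_concs) <= 0):
            raise InputError("ligand_concs must be nonnegative, strictly ascending")
        shape = (len(self.ligand_concs), len(self.residues))
        for name in ("delta_H", "delta_N", "intensity"):
            if getattr(self, name).shape != shape:
                raise InputError(f"{name} must have shape {shape}")

    @property
    def n_points(self) -> int:
        return len(self.ligand_concs)

    def csp_matrix(self) -> np.ndarray:
        """Weighted CSP of each residue at each concentration vs the first point."""
        dH = self.delta_H - self.delta_H[0]
        dN = self.delta_N - self.delta_N[0]
        return np.sqrt(0.5 * (dH**2 + NITROGEN_WEIGHT * dN**2))

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: residue, conc_uM, delta_H_ppm, delta_N_ppm, intensity."""
        rows = []
        for i, c in enumerate(self.ligand_concs):
            rows.append(
                pd.DataFrame(
                    {
                        "residue": self.residues,
                        "conc_uM": c,
                        "delta_H_ppm": self.delta_H[i],
                        "delta_N_ppm": self.delta_N[i],
                        "intensity": self.intensity[i],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, protein_conc: float) -> "TitrationSeries":
        required = {"residue", "conc_uM", "delta_H_ppm", "delta_N_ppm", "intensity"}
        missing = required - set(df.columns)
        if missing:
            raise InputError(f"peak list missing columns: {sorted(missing)}")
        concs = np.sort(df["conc_uM"].unique())
        residues = np.sort(df["residue"].unique())
        piv = df.set_index(["conc_uM", "residue"])
        if piv.index.duplicated().any():
            raise InputError("duplicate (conc, residue) rows in peak list")
        arrays = {}
        for col in ("delta_H_ppm", "delta_N_ppm", "intensity"):
            wide = df.pivot(index="conc_uM", columns="residue", values=col)
            if wide.isna().any().any():
                raise InputError("every concentration must cover the same residues")
            arrays[col] = wide.loc[concs, residues].to_numpy()
        return cls(
            protein_conc=protein_conc,
            ligand_concs=concs,
            residues=residues,
            delta_H=arrays["delta_H_ppm"],
            delta_N=arrays["delta_N_ppm"],
            intensity=arrays["intensity"],
        )


@dataclass
class BindingFitResult:
    K_D: float
    L: float
    delta_sat_per_residue: dict[int, float]
    residues_used: list[int]
    se: dict[str, float]
    rss: float
    n_obs: int
    n_clipped: int = 0
    message: str = ""
    cov: np.ndarray | None = field(default=None, repr=False)

    def chi_B_curve(self, protein_conc: float, ligand_concs: np.ndarray) -> np.ndarray:
        return binding_model_chiB(protein_conc, np.asarray(ligand_concs), self.K_D, self.L)


def compute_csp(free: ShiftRecord, bound: ShiftRecord) -> CSPValue:
    """Weighted CSP between a reference (free) and perturbed (bound) peak."""
    if free.residue != bound.residue:
        raise InputError(
            f"residue mismatch: {free.residue} vs {bound.residue}"
        )
    dH = bound.delta_H - free.delta_H
    dN = bound.delta_N - free.delta_N
    return CSPValue(
        residue=free.residue,
        delta_delta=float(np.sqrt(0.5 * (dH**2 + NITROGEN_WEIGHT * dN**2))),
    )


def chi_B(delta_obs: float, delta_sat: float) -> float:
    """Bound fraction from an observed CSP and the saturation CSP.

    Values above 1 (possible with noisy shifts) are clipped to 1 and logged.
    """
    if delta_sat <= 0:
        raise InputError("delta_sat must be positive")
    if delta_obs < 0:
        raise InputError("delta_obs must be nonnegative")
    ratio = delta_obs / delta_sat
    if ratio > 1:
        logger.info("chi_B %.4f clipped to 1", ratio)
        return 1.0
    return ratio


def binding_model_chiB(protein_conc, ligand_conc, K_D, L):
    """Bound protein fraction of the L-ligand binding model (closed form).

    Accepts scalar or array ``ligand_conc``; returns the same shape.
    Monotone nondecreasing in ligand concentration, in [0, 1].
    """
    if protein_conc <= 0:
        raise InputError("protein_conc must be positive")
    if L <= 0:
        raise InputError("L must be positive")
    if K_D < 0:
        raise InputError("K_D must be nonnegative")
    C = np.asarray(ligand_conc, dtype=float)
    if np.any(C < 0):
        raise InputError("ligand_conc must be nonnegative")
    P = protein_conc
    S = P + C / L + K_D
    disc = S * S - 4.0 * P * C / L
    if np.any(disc < 0):
        # mathematically disc >= 0; tiny negatives can arise from rounding
        warnings.warn("negative discriminant clamped to 0", RuntimeWarning)
        disc = np.clip(disc, 0.0, None)
    chi = (S - np.sqrt(disc)) / (2.0 * P)
    chi = np.clip(chi, 0.0, 1.0)
    return float(chi) if np.ndim(ligand_conc) == 0 else chi


def select_major_perturbations(series: TitrationSeries) -> list[int]:
    """Residues whose CSP at the top concentration exceeds mean + 2 SD."""
    csp_max = series.csp_matrix()[-1]
    cut = csp_max.mean() + 2.0 * csp_max.std()
    return [int(r) for r in series.residues[csp_max > cut]]


def fit_binding(
    series: TitrationSeries,
    residues: list[int] | None = None,
    init: tuple[float, float] = (100.0, 5.0),
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((1e-6, 1e4), (1e-3, 50.0)),
) -> BindingFitResult:
    """Global least-squares fit of (K_D, L, Delta_delta_sat per residue).

    The observed weighted CSPs of the selected residues at every titration
    point are fitted jointly to ``chi_B(C; K_D, L) * Delta_delta_sat_r``;
    this is the global bound-fraction fit expressed in shift space (each
    residue's chi_B residual is weighted by its saturation shift, which
    avoids dividing by the still-unknown Delta_delta_sat). Standard errors
    come from the Jacobian at the optimum. Deterministic given data and init.
    """
    if series.n_points < 4:
        raise InputError("need at least 4 titration points")
    if residues is None:
        residues = select_major_perturbations(series)
    if len(residues) == 0:
        raise InputError("no residues selected for the binding fit")
    missing = set(residues) - set(series.residues.tolist())
    if missing:
        raise InputError(f"residues not in series: {sorted(missing)}")

    csp = series.csp_matrix()
    cols = [int(np.where(series.residues == r)[0][0]) for r in residues]
    obs = csp[:, cols]  # (C, R)
    n_obs = obs.size
    n_par = 2 + len(cols)
    if n_obs < n_par:
        raise InputError("fewer observations than fit parameters")
    if np.allclose(obs, 0.0):
        raise FitError("no CSP signal in selected residues; K_D is unbounded")

    C = series.ligand_concs
    P = series.protein_conc
    dsat0 = np.maximum(obs[-1], 1e-6)

    def residual(theta):
        kd, lign = theta[0], theta[1]
        dsat = theta[2:]
        chi = binding_model_chiB(P, C, kd, lign)
        return (chi[:, None] * dsat[None, :] - obs).ravel()

    theta0 = np.concatenate([[init[0], init[1]], dsat0])
    lo = np.concatenate([[bounds[0][0], bounds[1][0]], np.zeros(len(cols))])
    hi = np.concatenate([[bounds[0][1], bounds[1][1]], np.full(len(cols), np.inf)])
    theta0 = np.clip(theta0, lo, hi)
    res = least_squares(residual, theta0, bounds=(lo, hi), method="trf", x_scale="jac")
    if not res.success:
        raise FitError(f"binding fit failed to converge: {res.message}")

    rss = float(2.0 * res.cost)
    dof = max(n_obs - n_par, 1)
    s2 = rss / dof
    jtj = res.jac.T @ res.jac
    try:
        cov = s2 * np.linalg.pinv(jtj)
        se_kd = float(np.sqrt(max(cov[0, 0], 0.0)))
        se_l = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        cov, se_kd, se_l = None, float("nan"), float("nan")

    return BindingFitResult(
        K_D=float(res.x[0]),
        L=float(res.x[1]),
        delta_sat_per_residue={int(r): float(d) for r, d in zip(residues, res.x[2:])},
        residues_used=[int(r) for r in residues],
        se={"K_D": se_kd, "L": se_l},
        rss=rss,
        n_obs=n_obs,
        message=res.message,
        cov=cov,
    )


def rank_perturbed_residues(
    series: TitrationSeries,
    top_k: int | None = None,
    threshold: float | None = None,
) -> list[int]:
    """Residues ranked by CSP at the top concentration, filtered by rule.

    With neither ``top_k`` nor ``threshold`` given, the mean + 2 SD rule is
    applied. Returns residue indices sorted by decreasing CSP.
    """
    if series.n_points < 2:
        raise InputError("need at least 2 concentrations to rank perturbations")
    csp_max = series.csp_matrix()[-1]
    order = np.argsort(-csp_max, kind="stable")
    ranked = series.residues[order]
    values = csp_max[order]
    if top_k is not None:
        keep = ranked[: int(top_k)]
        return [int(r) for r, v in zip(keep, values) if v > 0]
    if threshold is None:
        threshold = csp_max.mean() + 2.0 * csp_max.std()
    return [int(r) for r, v in zip(ranked, values) if v > threshold]


def detect_broadening(
    series: TitrationSeries,
    ratio_threshold: float = 0.7,
    shift_cut: float = 0.05,
) -> list[int]:
    """Residues whose peak intensity collapses without a large shift.

    Flags residues with ``I(C_max)/I(0) < ratio_threshold`` whose CSP at the
    top point stays below ``shift_cut`` (ppm), separating exchange broadening
    from fast-exchange shifting. Residues with zero reference intensity are
    skipped with a warning.
    """
    i0 = series.intensity[0]
    i1 = series.intensity[-1]
    csp_max = series.csp_matrix()[-1]
    out = []
    for r, a, b, d in zip(series.residues, i0, i1, csp_max):
        if a <= 0:
            warnings.warn(f"residue {r}: zero reference intensity, skipped")
            continue
        if d > shift_cut:
            continue
        if b / a < ratio_threshold:
            out.append(int(r))
    return out


def fit_report(result: BindingFitResult, series: TitrationSeries) -> tuple[pd.DataFrame, dict]:
    """Per-residue CSV table and JSON-ready summary of a binding fit."""
    csp_max = series.csp_matrix()[-1]
    table = pd.DataFrame(
        {
            "residue": series.residues,
            "delta_delta": csp_max,
            "delta_sat": [
                result.delta_sat_per_residue.get(int(r), np.nan) for r in series.residues
            ],
        }
    )
    summary = {
        "K_D_uM": result.K_D,
        "L": result.L,
        "se": result.se,
        "residues_used": result.residues_used,
        "rss": result.rss,
        "n_obs": result.n_obs,
    }
    return table, summary
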