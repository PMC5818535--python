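"""CSV dialects used across the toolkit.

All files are UTF-8 with a header row:

- peak lists:      ``residue,conc_uM,delta_H_ppm,delta_N_ppm,intensity``
- CEST tables:     ``residue,offset_kHz,intensity`` (reference rows at -100.0)
- localisations:   ``x_nm,y_nm[,frame,uncertainty_nm]`` (ThunderSTORM-style)
- vesicle spots:   ``x_nm,y_nm`` (one file per field)
- ThT long format: ``time_h,well,condition,fluorescence``
- spectra:         ``mz,intensity``
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from synucalc.errors import InputError
from synucalc.ms import Spectrum
from synucalc.nmr_csp import TitrationSeries
from synucalc.smlm import Rect
from synucalc.tht import ThTCurve
from synucalc.vesicles import SpotTable


def read_peaklist(path, protein_conc: float) -> TitrationSeries:
    return TitrationSeries.from_dataframe(pd.read_csv(path), protein_conc)


def write_peaklist(series: TitrationSeries, path) -> None:
    series.to_dataframe().to_csv(path, index=False)


def read_cest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"residue", "offset_kHz", "intensity"}
    if not required <= set(df.columns):
        raise InputError(f"CEST file needs columns {sorted(required)}")
    return df


def read_localizations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"x_nm", "y_nm"} <= set(df.columns):
        raise InputError("localisation file needs columns x_nm, y_nm")
    return df


def read_spots(path, field: Rect | None = None) -> SpotTable:
    df = pd.read_csv(path)
    if not {"x_nm", "y_nm"} <= set(df.columns):
        raise InputError("spot file needs columns x_nm, y_nm")
    pts = df[["x_nm", "y_nm"]].to_numpy(dtype=float)
    if field is None:
        pad = 1.0
        field = Rect(
            float(pts[:, 0].min() - pad),
            float(pts[:, 1].min() - pad),
            float(pts[:, 0].max() + pad),
            float(pts[:, 1].max() + pad),
        )
    return SpotTable(points=pts, field=field)


def read_tht(path) -> list[ThTCurve]:
    df = pd.read_csv(path)
    required = {"time_h", "well", "condition", "fluorescence"}
    if not required <= set(df.columns):
        raise InputError(f"ThT file needs columns {sorted(required)}")
    curves = []
    for (well, condition), grp in df.groupby(["well", "condition"], sort=True):
        grp = grp.sort_values("time_h")
        curves.append(
            ThTCurve(
                times=grp["time_h"].to_numpy(),
                fluorescence=grp["fluorescence"].to_numpy(),
                well=str(well),
                condition=str(condition),
            )
        )
    return curves


def read_spectrum(path) -> Spectrum:
    df = pd.read_csv(path)
    if not {"mz", "intensity"} <= set(df.columns):
        raise InputError("spectrum file needs columns mz, intensity")
    df = df.sort_values("mz")
    return Spectrum(mz=df["mz"].to_numpy(), intensity=df["intensity"].to_numpy())


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_coerce))


def _coerce(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
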