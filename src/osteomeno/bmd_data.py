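"""Curation of cross-sectional BMD study tables.

Input is the standard schema one extracts from published cross-sectional
dual-energy X-ray absorptiometry studies: per study and skeletal site, mean
BMD with standard deviation and cohort size at a handful of times relative
to menopause onset. Curation (i) normalizes each study by its value at
onset, (ii) pools studies within time bins using cohort-size weights, and
(iii) offers a windowed ordinary-least-squares loss-rate diagnostic.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CurationError

__all__ = [
    "StudyDataset",
    "BMDObservationSeries",
    "normalize_study",
    "aggregate",
    "linear_loss_rate",
    "read_studies",
    "studies_to_frame",
]

logger = logging.getLogger(__name__)

#: CSV column schema for study tables.
CSV_COLUMNS = ("study_id", "site", "menopause_type", "time_years",
               "mean_bmd", "sd", "n")

MENOPAUSE_TYPES = ("natural", "surgical")


@dataclass
class StudyDataset:
    """One study's BMD series: (time since onset, mean, SD, cohort size)."""

    study_id: str
    site: str
    menopause_type: str
    points: pd.DataFrame  # columns: time_years, mean_bmd, sd, n

    def __post_init__(self) -> None:
        required = {"time_years", "mean_bmd", "sd", "n"}
        missing = required - set(self.points.columns)
        if missing:
            raise CurationError(f"study {self.study_id}: missing columns {sorted(missing)}")
        if self.menopause_type not in MENOPAUSE_TYPES:
            raise CurationError(
                f"study {self.study_id}: menopause_type must be one of {MENOPAUSE_TYPES}"
            )
        pts = self.points
        if not np.isfinite(pts["time_years"]).all():
            raise CurationError(f"study {self.study_id}: non-finite times")
        if (pts["n"] < 1).any():
            raise CurationError(f"study {self.study_id}: cohort sizes must be >= 1")
        if (pts["sd"] < 0).any():
            raise CurationError(f"study {self.study_id}: negative SD")
        self.points = pts.sort_values("time_years").reset_index(drop=True)


@dataclass
class BMDObservationSeries:
    """Onset-normalized BMD observations, possibly pooled across studies."""

    times_years: np.ndarray
    mean_normalized_bmd: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.times_years = np.asarray(self.times_years, dtype=float)
        self.mean_normalized_bmd = np.asarray(self.mean_normalized_bmd, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if (self.mean_normalized_bmd <= 0).any():
            raise CurationError("normalized BMD values must be > 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_years": self.times_years,
            "mean_normalized_bmd": self.mean_normalized_bmd,
            "sd": self.sd,
            "n": self.n,
        })


def normalize_study(
    d: StudyDataset, onset_window: float = 1.0
) -> BMDObservationSeries:
    """Normalize a study by its BMD value at (or nearest to) onset.

    Every mean is divided by the mean of the observation closest to time 0;
    SDs are scaled by the same factor, so SD/mean ratios are preserved.
    A study with no observation within ``onset_window`` years of onset
    cannot be normalized and raises :class:`CurationError`.
    """
    pts = d.points
    i_ref = int(np.abs(pts["time_years"]).idxmin())
    if abs(pts.loc[i_ref, "time_years"]) > onset_window:
        raise CurationError(
            f"study {d.study_id}: no observation within {onset_window} years "
            "of menopause onset; cannot normalize"
        )
    ref = float(pts.loc[i_ref, "mean_bmd"])
    if ref <= 0:
        raise CurationError(f"study {d.study_id}: nonpositive onset BMD")
    return BMDObservationSeries(
        times_years=pts["time_years"].to_numpy(dtype=float),
        mean_normalized_bmd=pts["mean_bmd"].to_numpy(dtype=float) / ref,
        sd=pts["sd"].to_numpy(dtype=float) / ref,
        n=pts["n"].to_numpy(dtype=float),
        provenance=(d.study_id,),
    )


def aggregate(
    series: Sequence[BMDObservationSeries],
    bin_width: float = 1.0,
    weighted: bool = True,
) -> BMDObservationSeries:
    """Pool normalized series within time bins.

    Within each bin of width ``bin_width`` years the pooled mean is the
    cohort-size-weighted mean of the contributing study means (unweighted if
    ``weighted=False``) and the pooled variance combines the within-study
    and between-study components:

        s² = [Σ (n_i - 1) s_i² + Σ n_i (x_i - m)²] / (Σ n_i - 1)

    The reported bin time is the weighted mean observation time. Empty bins
    are simply absent; the result is invariant to the order of the input
    series.
    """
    if len(series) == 0:
        raise CurationError("aggregate requires at least one series")
    if bin_width <= 0:
        raise CurationError("bin_width must be > 0")
    rows = []
    for s in sorted(series, key=lambda s: s.provenance):
        for t, m, sd, n in zip(s.times_years, s.mean_normalized_bmd, s.sd, s.n):
            rows.append((np.floor(t / bin_width), t, m, sd, n, s.provenance))
    df = pd.DataFrame(rows, columns=["bin", "t", "mean", "sd", "n", "prov"])

    out_t, out_m, out_sd, out_n = [], [], [], []
    provenance: list[str] = []
    for _, grp in df.groupby("bin", sort=True):
        w = grp["n"].to_numpy() if weighted else np.ones(len(grp))
        ntot = float(grp["n"].sum())
        m = float(np.average(grp["mean"], weights=w))
        if ntot > 1:
            within = float(((grp["n"] - 1) * grp["sd"] ** 2).sum())
            between = float((grp["n"] * (grp["mean"] - m) ** 2).sum())
            sd = np.sqrt((within + between) / (ntot - 1))
        else:
            sd = float(grp["sd"].iloc[0])
        out_t.append(float(np.average(grp["t"], weights=w)))
        out_m.append(m)
        out_sd.append(sd)
        out_n.append(ntot)
        for prov in grp["prov"]:
            provenance.extend(prov)
    return BMDObservationSeries(
        times_years=np.array(out_t),
        mean_normalized_bmd=np.array(out_m),
        sd=np.array(out_sd),
        n=np.array(out_n),
        provenance=tuple(dict.fromkeys(provenance)),
    )


def linear_loss_rate(
    series: BMDObservationSeries, window_years: float = 15.0
) -> float:
    """OLS slope of normalized BMD over [0, window], in percent per year.

    A diagnostic mirroring the linear loss rates quoted by cohort studies;
    it plays no role in model calibration.
    """
    mask = (series.times_years >= 0) & (series.times_years <= window_years)
    t = series.times_years[mask]
    y = series.mean_normalized_bmd[mask]
    if len(t) < 2:
        raise CurationError("need at least two points inside the window")
    if np.ptp(t) == 0:
        raise CurationError("all in-window observations share one time")
    slope = np.polyfit(t, y, 1)[0]
    return float(slope * 100.0)


def read_studies(path: str | Path) -> list[StudyDataset]:
    """Read study tables from CSV (schema: ``study_id, site, menopause_type,
    time_years, mean_bmd, sd, n``), with line-numbered validation errors."""
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise CurationError(f"{path}: missing columns {sorted(missing)}")
    for col in ("time_years", "mean_bmd", "sd", "n"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise CurationError(
                f"{path}: non-numeric {col!r} at line {int(bad[0]) + 2}"
            )
        df[col] = pd.to_numeric(df[col])
    bad = df.index[~df["menopause_type"].isin(MENOPAUSE_TYPES)]
    if len(bad):
        raise CurationError(
            f"{path}: invalid menopause_type at line {int(bad[0]) + 2}"
        )
    studies = []
    for (sid, site, mtype), grp in df.groupby(
        ["study_id", "site", "menopause_type"], sort=True
    ):
        studies.append(StudyDataset(
            study_id=str(sid),
            site=str(site),
            menopause_type=str(mtype),
            points=grp[["time_years", "mean_bmd", "sd", "n"]].reset_index(drop=True),
        ))
    return studies


def studies_to_frame(studies: Iterable[StudyDataset]) -> pd.DataFrame:
    """Flatten studies back into the CSV schema."""
    frames = []
    for d in studies:
        f = d.points.copy()
        f.insert(0, "menopause_type", d.menopause_type)
        f.insert(0, "site", d.site)
        f.insert(0, "study_id", d.study_id)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)[list(CSV_COLUMNS)]
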