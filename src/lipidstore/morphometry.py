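"""Photogrammetric volumetrics: width profiles to total body volume.

A whale imaged from above is measured as a total length plus widths at 5%
stations along the body axis (MorphoMetrix-style output).  Cross-section
heights are inferred from body-site-specific height:width ratios, each
segment between adjacent stations is modelled as a stack of ellipses whose
axes vary linearly along the segment, and segment volumes are summed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "WidthProfile",
    "HWRatioTable",
    "VolumeEstimate",
    "scale_pixels_to_metres",
    "heights_from_widths",
    "segment_volume",
    "total_body_volume",
    "default_hw_ratios",
    "read_width_profiles",
    "write_volumes_csv",
]

N_STATIONS = 21  # 0%, 5%, ..., 100% of total length from the rostrum
STATIONS = np.linspace(0.0, 1.0, N_STATIONS)


@dataclass
class WidthProfile:
    """Scaled body measurements from one overhead image.

    ``stations`` are fractions of total length measured from the rostrum
    (0) to the fluke notch (1); ``widths`` are in metres at each station.
    The 0% and 100% stations are closed (width forced to zero) because the
    body tapers to the rostrum tip and fluke notch.
    """

    whale_id: str
    image_id: str
    length_m: float
    widths: np.ndarray
    stations: np.ndarray = field(default_factory=lambda: STATIONS.copy())
    heights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        self.stations = np.asarray(self.stations, dtype=float)
        if self.length_m <= 0:
            raise ValueError("total length must be positive")
        if self.widths.shape != self.stations.shape:
            raise ValueError("widths and stations must have the same shape")
        if np.any(self.widths < 0):
            raise ValueError("widths must be non-negative")
        if np.any(np.diff(self.stations) <= 0):
            raise ValueError("stations must be strictly increasing")
        if self.stations[0] != 0.0 or self.stations[-1] != 1.0:
            raise ValueError("stations must start at 0 and end at 1")
        # closed ends: rostrum tip and fluke notch have zero cross-section
        self.widths = self.widths.copy()
        self.widths[0] = 0.0
        self.widths[-1] = 0.0
        if self.heights is not None:
            self.heights = np.asarray(self.heights, dtype=float)
            self.heights[0] = 0.0
            self.heights[-1] = 0.0


@dataclass
class HWRatioTable:
    """Body-site-specific dorsoventral height to lateral width ratios."""

    stations: np.ndarray
    ratios: np.ndarray

    def __post_init__(self) -> None:
        self.stations = np.asarray(self.stations, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if np.any(self.ratios <= 0):
            raise ValueError("height:width ratios must be positive")
        order = np.argsort(self.stations)
        self.stations = self.stations[order]
        self.ratios = self.ratios[order]

    def at(self, stations: np.ndarray, interpolate: bool = True) -> np.ndarray:
        """Ratio at each requested station, linearly interpolated if needed."""
        stations = np.asarray(stations, dtype=float)
        if not interpolate:
            missing = ~np.isin(np.round(stations, 9), np.round(self.stations, 9))
            if missing.any():
                raise ValueError(
                    f"no ratio tabulated at stations {stations[missing]} and "
                    "interpolation is disabled"
                )
        return np.interp(stations, self.stations, self.ratios)


@dataclass(frozen=True)
class VolumeEstimate:
    whale_id: str
    image_id: str
    length_m: float
    v_b: float
    segment_volumes: np.ndarray

    def __post_init__(self) -> None:
        if not np.isclose(self.v_b, self.segment_volumes.sum()):
            raise ValueError("total volume must equal the sum of segment volumes")


def scale_pixels_to_metres(
    pixel_length: float,
    altitude_m: float,
    focal_length_mm: float,
    sensor_width_mm: float,
    image_width_px: float,
) -> float:
    """Convert an image measurement in pixels to metres via the GSD.

    The ground sampling distance of a nadir image is
    altitude * sensor_width / (focal_length * image_width) metres per pixel.
    """
    if min(altitude_m, focal_length_mm, sensor_width_mm, image_width_px) <= 0:
        raise ValueError("altitude, focal length, sensor and image width must be > 0")
    if pixel_length < 0:
        raise ValueError("pixel length must be non-negative")
    gsd = altitude_m * sensor_width_mm / (focal_length_mm * image_width_px)
    return pixel_length * gsd


def heights_from_widths(
    profile: WidthProfile,
    ratios: HWRatioTable,
    interpolate: bool = True,
) -> WidthProfile:
    """Fill cross-section heights as H(s) = W(s) * ratio(s); widths unchanged."""
    r = ratios.at(profile.stations, interpolate=interpolate)
    return WidthProfile(
        whale_id=profile.whale_id,
        image_id=profile.image_id,
        length_m=profile.length_m,
        widths=profile.widths,
        stations=profile.stations,
        heights=profile.widths * r,
    )


def segment_volume(w1: float, h1: float, w2: float, h2: float, seg_len: float) -> float:
    """Volume of one body segment modelled as a stack of ellipses.

    Width and height vary linearly between the segment ends, so the
    cross-sectional area (pi/4) W(x) H(x) is quadratic in x and integrates
    in closed form:

        V = (pi/4) * l * [ (W1 H1 + W2 H2)/3 + (W1 H2 + W2 H1)/6 ]

    A cylinder (equal ends) gives (pi/4) l W H; a cone to a point gives a
    third of that.
    """
    if min(w1, h1, w2, h2) < 0:
        raise ValueError("cross-section dimensions must be non-negative")
    if seg_len <= 0:
        raise ValueError("segment length must be positive")
    return (np.pi / 4.0) * seg_len * (
        (w1 * h1 + w2 * h2) / 3.0 + (w1 * h2 + w2 * h1) / 6.0
    )


def total_body_volume(profile: WidthProfile) -> VolumeEstimate:
    """Sum elliptical segment volumes over the full body.

    Requires heights already filled (see :func:`heights_from_widths`).  With
    the standard 21 stations this is 20 segments, each of length L/20.
    """
    if profile.heights is None:
        raise ValueError("heights must be filled before computing volume")
    if profile.stations.size < 2:
        raise ValueError("need at least two stations")
    w, h = profile.widths, profile.heights
    seg_lens = np.diff(profile.stations) * profile.length_m
    segs = (np.pi / 4.0) * seg_lens * (
        (w[:-1] * h[:-1] + w[1:] * h[1:]) / 3.0
        + (w[:-1] * h[1:] + w[1:] * h[:-1]) / 6.0
    )
    return VolumeEstimate(
        whale_id=profile.whale_id,
        image_id=profile.image_id,
        length_m=profile.length_m,
        v_b=float(segs.sum()),
        segment_volumes=segs,
    )


def default_hw_ratios() -> HWRatioTable:
    """Packaged sperm-whale height:width ratio table.

    Synthetic reconstruction: plausible site-specific ratios for a sperm
    whale body plan (tall rectangular head, laterally compressed peduncle),
    standing in for measured ratios that are not redistributable.  Users
    with measured ratios should load their own table.
    """
    with resources.files("lipidstore.data").joinpath(
        "hw_ratios_synthetic.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    return HWRatioTable(df["station"].to_numpy(), df["ratio"].to_numpy())


def read_width_profiles(path) -> list[WidthProfile]:
    """Read MorphoMetrix-style width tables (long or wide layout).

    Long layout: columns whale_id, image_id, length_m, station, width_m.
    Wide layout: columns whale_id, image_id, length_m, w00, w05, ..., w100
    (widths in metres at 0%..100% of length).
    """
    df = pd.read_csv(path)
    profiles = []
    if {"station", "width_m"} <= set(df.columns):
        for (wid, iid), g in df.groupby(["whale_id", "image_id"], sort=False):
            g = g.sort_values("station")
            profiles.append(
                WidthProfile(
                    whale_id=str(wid),
                    image_id=str(iid),
                    length_m=float(g["length_m"].iloc[0]),
                    widths=g["width_m"].to_numpy(),
                    stations=g["station"].to_numpy(),
                )
            )
    else:
        width_cols = [c for c in df.columns if c.startswith("w") and c[1:].isdigit()]
        width_cols.sort(key=lambda c: int(c[1:]))
        stations = np.array([int(c[1:]) / 100.0 for c in width_cols])
        for row in df.itertuples(index=False):
            profiles.append(
                WidthProfile(
                    whale_id=str(row.whale_id),
                    image_id=str(row.image_id),
                    length_m=float(row.length_m),
                    widths=np.array([getattr(row, c) for c in width_cols], float),
                    stations=stations,
                )
            )
    return profiles


def write_volumes_csv(estimates: list[VolumeEstimate], path) -> None:
    pd.DataFrame(
        {
            "whale_id": [e.whale_id for e in estimates],
            "image_id": [e.image_id for e in estimates],
            "length_m": [e.length_m for e in estimates],
            "volume_m3": [e.v_b for e in estimates],
        }
    ).to_csv(path, index=False)
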