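"""Mean-latitude-axis morphometry.

The medial curve of a corresponded surface is obtained by partitioning the
parameter sphere into equal-width iso-latitude (colatitude) bands and
averaging each band's surface points.  Point 1 is the anterior tip (the
north parameter pole after alignment) and the last point the posterior tip.
Per band the profile records:

* ``local_length`` — Euclidean distance between neighbouring medial points;
* ``radius``       — mean distance from the medial point to the band's
  surface points;
* ``area``         — cross-sectional area, by default the area of the band's
  iso-latitude contour polygon (sites ordered by longitude) projected onto
  the plane through the medial point orthogonal to the local axis tangent;
  ``area_mode="pi_r2"`` gives the pi r^2 alternative for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .harmonics import CorrespondedSurface


class MorphometryError(ValueError):
    """Raised for invalid band configurations (e.g. empty bands)."""


@dataclass
class MedialProfile:
    """Ordered medial-axis profile, anterior (band 0) to posterior."""

    medial_points: np.ndarray  # (n_bands, 3) mm
    local_length: np.ndarray  # (n_bands - 1,) mm
    radius: np.ndarray  # (n_bands,) mm
    area: np.ndarray  # (n_bands,) mm^2
    band_assignment: np.ndarray  # (n_sites,) band index per sample site
    provenance: dict = field(default_factory=dict)

    @property
    def n_bands(self) -> int:
        return len(self.medial_points)

    @property
    def total_length(self) -> float:
        return float(self.local_length.sum())

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-band table; local_length is associated with the leading band."""
        n = self.n_bands
        return pd.DataFrame(
            {
                "band": np.arange(n),
                "position": np.arange(n) / (n - 1),
                "length": np.concatenate([[np.nan], self.local_length]),
                "radius": self.radius,
                "area": self.area,
                **{k: v for k, v in self.provenance.items() if np.isscalar(v)},
            }
        )


def _polygon_area_2d(pts2: np.ndarray) -> float:
    x, y = pts2[:, 0], pts2[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def mean_latitude_axis(
    surface: CorrespondedSurface,
    n_bands: int = 100,
    area_mode: str = "polygon",
) -> MedialProfile:
    """Compute the mean latitude axis and its length/radius/area profiles."""
    if n_bands < 3:
        raise MorphometryError(f"n_bands must be >= 3, got {n_bands}")
    if area_mode not in ("polygon", "pi_r2"):
        raise MorphometryError(f"unknown area_mode {area_mode!r}")
    theta = surface.theta
    edges = np.linspace(0.0, np.pi, n_bands + 1)
    band = np.clip(np.digitize(theta, edges[1:-1]), 0, n_bands - 1)
    counts = np.bincount(band, minlength=n_bands)
    if (counts == 0).any():
        empty = np.flatnonzero(counts == 0)
        raise MorphometryError(
            f"{len(empty)} empty colatitude band(s) (first at index {empty[0]}); "
            "lower n_bands or sample the surface at a higher subdivision"
        )
    pts = surface.points
    medial = np.stack(
        [pts[band == b].mean(axis=0) for b in range(n_bands)]
    )
    local_length = np.linalg.norm(np.diff(medial, axis=0), axis=1)

    radius = np.array(
        [
            float(np.linalg.norm(pts[band == b] - medial[b], axis=1).mean())
            for b in range(n_bands)
        ]
    )

    # local tangent by central differences (one-sided at the tips)
    tangent = np.gradient(medial, axis=0)
    tangent /= np.maximum(np.linalg.norm(tangent, axis=1, keepdims=True), 1e-12)

    area = np.empty(n_bands)
    if area_mode == "pi_r2":
        area[:] = np.pi * radius**2
    else:
        for b in range(n_bands):
            sel = band == b
            ring = pts[sel]
            if len(ring) < 3:
                area[b] = np.pi * radius[b] ** 2  # degenerate tip band
                continue
            order = np.argsort(surface.phi[sel], kind="stable")
            ring = ring[order] - medial[b]
            t = tangent[b]
            # orthonormal in-plane basis
            e1 = np.cross(t, [0.0, 0.0, 1.0])
            if np.linalg.norm(e1) < 1e-8:
                e1 = np.cross(t, [0.0, 1.0, 0.0])
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(t, e1)
            proj = np.column_stack([ring @ e1, ring @ e2])
            area[b] = _polygon_area_2d(proj)
    return MedialProfile(
        medial_points=medial,
        local_length=local_length,
        radius=radius,
        area=area,
        band_assignment=band,
        provenance=dict(surface.provenance, n_bands=n_bands, area_mode=area_mode),
    )


def profiles_to_frame(profiles: dict, n_bands: int | None = None) -> pd.DataFrame:
    """Stack ``{(subject, age_days, gender, side): MedialProfile}`` into a tidy table.

    Columns: subject, age_days, gender, side, band, position, length, radius, area.
    """
    frames = []
    for (subject, age_days, gender, side), prof in profiles.items():
        df = prof.to_frame()
        df.insert(0, "subject", subject)
        df.insert(1, "age_days", age_days)
        df.insert(2, "gender", gender)
        df.insert(3, "side", side)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out
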