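"""Measurement rules for single-particle holoenzyme geometry.

Two quantities are measured per subunit, following the convention used for
negative-stain single-particle images of CaMKII holoenzymes:

* the *kinase radius of extension* — distance from the hub-complex centre
  (the pore) to the centre of the kinase density, plus a fixed 22.5 Å
  append for the average kinase-domain radius, giving the full extension
  to the kinase outer edge;
* the *clockwise neighbour separation* — centre-to-centre distance from
  each kinase density to its nearest neighbour in the clockwise direction.

"Clockwise" is fixed in image/screen convention (y increasing downward),
which equals decreasing mathematical polar angle.  The statistics are
direction-symmetric; the convention only affects per-edge labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble_synth import HoloenzymeParticle

__all__ = [
    "GeometryConstants",
    "ParticleMeasurement",
    "MeasurementError",
    "DEFAULT_CONSTANTS",
    "kinase_radius",
    "clockwise_separations",
    "measure_particle",
    "measure_ensemble",
]


class MeasurementError(ValueError):
    """Degenerate or invalid particle geometry."""


@dataclass(frozen=True)
class GeometryConstants:
    """Fixed lengths of the measurement model (Å)."""

    kinase_radius_append: float = 22.5
    hub_radius: float = 55.0
    kinase_diameter: float = 45.0
    pairing_threshold: float = 45.0   # = kinase diameter: steric contact
    compact_threshold: float = 100.0  # kinase touching the hub

    def __post_init__(self) -> None:
        if abs(self.kinase_diameter - 2 * self.kinase_radius_append) > 1e-9:
            raise MeasurementError("kinase_diameter must be 2x the append")
        if abs(self.pairing_threshold - self.kinase_diameter) > 1e-9:
            raise MeasurementError(
                "pairing threshold must equal the kinase diameter")


DEFAULT_CONSTANTS = GeometryConstants()


@dataclass
class ParticleMeasurement:
    """Measured radii and clockwise separations (Å) for one particle."""

    particle_id: int
    n_subunits: int
    radii: np.ndarray
    separations: np.ndarray

    def validate(self) -> None:
        if len(self.radii) != self.n_subunits:
            raise MeasurementError("radii length != n_subunits")
        if len(self.separations) != self.n_subunits:
            raise MeasurementError("separations length != n_subunits")
        if (np.asarray(self.radii) <= 0).any():
            raise MeasurementError("non-positive radius")
        if (np.asarray(self.separations) <= 0).any():
            raise MeasurementError("non-positive separation")


def kinase_radius(hub_centre, kinase_centre,
                  consts: GeometryConstants = DEFAULT_CONSTANTS) -> float:
    """Full kinase extension: centre-to-centre distance + 22.5 Å append."""
    hub = np.asarray(hub_centre, dtype=float)
    kin = np.asarray(kinase_centre, dtype=float)
    if not (np.isfinite(hub).all() and np.isfinite(kin).all()):
        raise MeasurementError("non-finite coordinates")
    d = float(np.linalg.norm(kin - hub))
    if d == 0.0:
        raise MeasurementError("kinase centre coincides with hub centre")
    return d + consts.kinase_radius_append


def clockwise_separations(coords) -> np.ndarray:
    """Distance from each point to its clockwise neighbour on the ring.

    Points are ordered by polar angle about their centroid (clockwise =
    decreasing mathematical angle; ties broken by radius, smaller first).
    The returned array is aligned with the *input* order: entry i is the
    separation from point i to its clockwise neighbour.
    """
    pts = np.asarray(coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise MeasurementError("need >= 3 two-dimensional points")
    if len(np.unique(pts, axis=0)) != len(pts):
        raise MeasurementError("duplicate positions are unsortable")
    centred = pts - pts.mean(axis=0)
    ang = np.arctan2(centred[:, 1], centred[:, 0])
    rad = np.hypot(centred[:, 0], centred[:, 1])
    order = np.lexsort((rad, -ang))  # decreasing angle, then smaller radius
    nxt = np.roll(order, -1)
    d = np.linalg.norm(pts[nxt] - pts[order], axis=1)
    out = np.empty(len(pts))
    out[order] = d
    return out


def measure_particle(obj, consts: GeometryConstants = DEFAULT_CONSTANTS,
                     hub_centre=(0.0, 0.0),
                     dropout: float = 0.0,
                     rng: np.random.Generator | None = None
                     ) -> ParticleMeasurement:
    """Measure one particle.

    Accepts either a :class:`HoloenzymeParticle` (pass-through if it has no
    coordinates, coordinate path otherwise) or a bare (n, 2) coordinate
    array of kinase centres.  ``dropout`` emulates unresolved densities by
    removing each subunit with that probability before measuring (synthetic
    data has none by default).
    """
    pid = 0
    if isinstance(obj, HoloenzymeParticle):
        pid = obj.particle_id
        if obj.coords is None:
            m = ParticleMeasurement(pid, obj.n_subunits,
                                    np.array(obj.radii, dtype=float),
                                    np.array(obj.separations, dtype=float))
            m.validate()
            return m
        coords = np.asarray(obj.coords, dtype=float)
    else:
        coords = np.asarray(obj, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise MeasurementError("expected an (n, 2) coordinate array")

    if dropout > 0.0:
        if rng is None:
            raise MeasurementError("dropout requires an rng")
        keep = rng.random(len(coords)) >= dropout
        if keep.sum() < 3:
            raise MeasurementError("dropout left fewer than 3 subunits")
        coords = coords[keep]

    radii = np.array([kinase_radius(hub_centre, c, consts) for c in coords])
    seps = clockwise_separations(coords)
    m = ParticleMeasurement(pid, len(coords), radii, seps)
    m.validate()
    return m


def measure_ensemble(particles, consts: GeometryConstants = DEFAULT_CONSTANTS,
                     **kwargs) -> list[ParticleMeasurement]:
    return [measure_particle(p, consts, **kwargs) for p in particles]
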