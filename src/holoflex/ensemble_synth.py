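"""Seeded synthetic conformational ensembles of CaMKII-like holoenzymes.

The holoenzyme is modelled as a rigid central hub (radius ~55 Å) carrying
12 — rarely 14 — kinase domains, each tethered by an intrinsically
disordered linker.  Per subunit the generator draws a *kinase radius of
extension* (hub centre to the outer edge of the kinase domain) from a
two-component truncated-Gaussian mixture: a dominant extended class
(mean 127 Å, s.d. 15 Å on [100, 175] Å) and a small compact class in which
the kinase domain docks against the hub (mean 88 Å, s.d. 5 Å on
[77, 100) Å).  Neighbouring kinase domains may transiently dimerize;
a per-particle pair count is drawn from a calibrated categorical and a
matching of that size is placed uniformly at random on the cycle of
subunits.  Centre-to-centre neighbour separations come from a second
two-component mixture: paired neighbours below the 45 Å steric-contact
threshold (mean 36 Å on [20, 45) Å), unpaired neighbours above it
(mean 62.5 Å on [45, 110] Å).

Two generation modes are provided:

``separation_explicit``
    samples radii and separations directly as independent marginals.  The
    hard support split at 45 Å makes threshold classification recover the
    generated pair labels exactly, so downstream classification tests are
    pure sampling tests.

``angular``
    realizes full 2D kinase-centre coordinates on the ring with exact
    360° closure; separations are then *computed* from the geometry (law
    of cosines), which couples them mechanically to the shared radii.
    Used for rendering and geometric property tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from functools import lru_cache
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

__all__ = [
    "ConfigurationError",
    "UsageError",
    "RealizationError",
    "TruncatedGaussian",
    "EnsembleConfig",
    "HoloenzymeParticle",
    "cycle_edges",
    "cycle_matchings",
    "sample_pair_assignment",
    "sample_radii",
    "sample_separations",
    "realize_coordinates",
    "generate_ensemble",
    "particles_to_frame",
    "frame_to_particles",
    "write_particles",
    "read_particles",
    "save_config",
    "load_config",
]

PAIRING_THRESHOLD_A = 45.0
COMPACT_THRESHOLD_A = 100.0

MODES = ("separation_explicit", "angular")


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


class UsageError(RuntimeError):
    """Operation called in the wrong generation mode."""


class RealizationError(RuntimeError):
    """Angular realization failed to produce a valid gap sequence."""


# --------------------------------------------------------------------------
# distributions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TruncatedGaussian:
    """Gaussian restricted to [lo, hi], sampled by inverse-CDF transform."""

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (self.lo < self.hi):
            raise ConfigurationError(f"empty support [{self.lo}, {self.hi}]")
        if self.sd < 0:
            raise ConfigurationError("negative s.d.")

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0.0:
            return np.full(n, float(self.mean))
        a = ndtr((self.lo - self.mean) / self.sd)
        b = ndtr((self.hi - self.mean) / self.sd)
        u = rng.uniform(a, b, size=n)
        return self.mean + self.sd * ndtri(u)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

def _default_pair_count_probs() -> tuple[float, ...]:
    # calibrated so that P(0)~10%, P(1-3)~60%, P(6)~2.5% and the implied
    # fraction of separations <45 Å is E[pairs]/12 = 2.46/12 ~ 20.5%
    return (0.10, 0.25, 0.20, 0.15, 0.165, 0.11, 0.025)


@dataclass
class EnsembleConfig:
    """All generator parameters.  Lengths in Å, angles in degrees."""

    n_particles: int = 1000
    seed: int = 0
    mode: str = "separation_explicit"
    p_tetradecamer: float = 0.035
    hub_radius: float = 55.0
    kinase_radius: float = 22.5          # kinase diameter = 45 Å
    p_compact: float = 0.025             # per-subunit compact probability
    radius_extended: TruncatedGaussian = field(
        default_factory=lambda: TruncatedGaussian(127.0, 15.0, 100.0, 175.0))
    radius_compact: TruncatedGaussian = field(
        default_factory=lambda: TruncatedGaussian(88.0, 5.0, 77.0, 100.0))
    pair_count_probs: tuple[float, ...] = field(
        default_factory=_default_pair_count_probs)
    sep_paired: TruncatedGaussian = field(
        default_factory=lambda: TruncatedGaussian(36.0, 5.0, 20.0, 45.0))
    sep_unpaired: TruncatedGaussian = field(
        default_factory=lambda: TruncatedGaussian(62.5, 11.0, 45.0, 110.0))
    angular_paired_gap_mean: float = 19.5    # degrees, angular mode only
    angular_paired_gap_sd: float = 2.5

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_particles <= 0:
            raise ConfigurationError("n_particles must be positive")
        if self.mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}")
        for name in ("p_tetradecamer", "p_compact"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1]")
        probs = np.asarray(self.pair_count_probs, dtype=float)
        if (probs < 0).any():
            raise ConfigurationError("pair_count_probs has negative mass")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigurationError("pair_count_probs must sum to 1")
        if len(probs) > 7:
            raise ConfigurationError("pair counts above 6 are not supported")
        if self.radius_compact.hi > self.radius_extended.lo:
            raise ConfigurationError(
                "compact radius support must lie entirely below extended")
        if self.sep_paired.hi > PAIRING_THRESHOLD_A:
            raise ConfigurationError(
                "paired separation support must lie below 45 Å")
        if self.sep_unpaired.lo < PAIRING_THRESHOLD_A:
            raise ConfigurationError(
                "unpaired separation support must lie at or above 45 Å")
        if self.hub_radius + 2 * self.kinase_radius > self.radius_extended.lo:
            raise ConfigurationError(
                "extended kinase domains would interpenetrate the hub")

    # ---- (de)serialisation ------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleConfig":
        d = dict(d)
        for key in ("radius_extended", "radius_compact",
                    "sep_paired", "sep_unpaired"):
            if key in d and isinstance(d[key], dict):
                d[key] = TruncatedGaussian(**d[key])
        if "pair_count_probs" in d:
            d["pair_count_probs"] = tuple(d["pair_count_probs"])
        return cls(**d)


def save_config(cfg: EnsembleConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=2))


def load_config(path: str | Path) -> EnsembleConfig:
    return EnsembleConfig.from_dict(json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------
# particles
# --------------------------------------------------------------------------

@dataclass
class HoloenzymeParticle:
    """One synthetic holoenzyme.

    ``radii`` are full kinase extensions (hub centre to kinase outer edge);
    ``separations[i]`` is the clockwise centre-to-centre distance from
    subunit i to subunit (i+1) mod n; ``pair_edges`` is a matching on the
    subunit cycle; ``coords`` (angular mode only) holds 2D kinase-centre
    positions in Å with the hub centre at the origin.
    """

    particle_id: int
    n_subunits: int
    radii: np.ndarray
    separations: np.ndarray
    pair_edges: frozenset
    compact_flags: np.ndarray
    coords: np.ndarray | None = None

    def validate(self) -> None:
        n = self.n_subunits
        if n not in (12, 14):
            raise ConfigurationError("n_subunits must be 12 or 14")
        if len(self.radii) != n or len(self.separations) != n:
            raise ConfigurationError("radii/separations length mismatch")
        seen: set[int] = set()
        for (i, j) in self.pair_edges:
            if j != (i + 1) % n:
                raise ConfigurationError(f"({i},{j}) is not a cycle edge")
            if i in seen or j in seen:
                raise ConfigurationError("pair_edges is not a matching")
            seen.update((i, j))


def cycle_edges(n: int) -> list[tuple[int, int]]:
    return [(i, (i + 1) % n) for i in range(n)]


@lru_cache(maxsize=None)
def cycle_matchings(n: int, k: int) -> tuple[frozenset, ...]:
    """All matchings of exactly k edges on the n-cycle (n <= 14 is cheap)."""
    if k == 0:
        return (frozenset(),)
    out = []
    for combo in combinations(cycle_edges(n), k):
        verts = [v for e in combo for v in e]
        if len(set(verts)) == 2 * k:
            out.append(frozenset(combo))
    return tuple(out)


# --------------------------------------------------------------------------
# sampling operations
# --------------------------------------------------------------------------

def _validate_probs(probs: Sequence[float]) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if (p < 0).any():
        raise ConfigurationError("categorical has negative mass")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ConfigurationError("categorical must sum to 1")
    return p / p.sum()


def sample_pair_assignment(n_subunits: int, probs: Sequence[float],
                           rng: np.random.Generator) -> frozenset:
    """Draw a pair count from ``probs`` then a uniform matching of that size
    on the subunit cycle."""
    p = _validate_probs(probs)
    if len(p) - 1 > n_subunits // 2:
        raise ConfigurationError(
            f"pair count {len(p) - 1} exceeds floor({n_subunits}/2)")
    k = int(rng.choice(len(p), p=p))
    matchings = cycle_matchings(n_subunits, k)
    return matchings[int(rng.integers(len(matchings)))]


def sample_radii(n: int, cfg: EnsembleConfig,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Kinase radii (Å) and compact flags for n subunits."""
    compact = rng.random(n) < cfg.p_compact
    radii = np.empty(n)
    n_c = int(compact.sum())
    radii[compact] = cfg.radius_compact.rvs(n_c, rng)
    radii[~compact] = cfg.radius_extended.rvs(n - n_c, rng)
    return radii, compact


def sample_separations(pair_edges: frozenset, cfg: EnsembleConfig,
                       rng: np.random.Generator,
                       n_subunits: int) -> np.ndarray:
    """Clockwise separations (Å); slot i covers edge (i, i+1 mod n)."""
    if cfg.mode != "separation_explicit":
        raise UsageError(
            "separations are computed from coordinates in angular mode")
    paired = np.zeros(n_subunits, dtype=bool)
    for (i, _) in pair_edges:
        paired[i] = True
    seps = np.empty(n_subunits)
    n_p = int(paired.sum())
    seps[paired] = cfg.sep_paired.rvs(n_p, rng)
    seps[~paired] = cfg.sep_unpaired.rvs(n_subunits - n_p, rng)
    return seps


def realize_coordinates(particle: HoloenzymeParticle, cfg: EnsembleConfig,
                        rng: np.random.Generator,
                        max_retries: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Place kinase centres on the ring (angular mode).

    Paired gaps are drawn from the paired-gap angle distribution; unpaired
    gaps are drawn around the equal-share residual angle (s.d. 25% of it)
    and rescaled so all gaps sum to exactly 360°.  Subunit i+1 sits at a
    smaller mathematical polar angle than subunit i, i.e. subunit order is
    clockwise in image (y-down) convention.  Returns (coords, separations);
    separations are recomputed from the geometry by the law of cosines.
    """
    n = particle.n_subunits
    paired_slots = np.zeros(n, dtype=bool)
    for (i, _) in particle.pair_edges:
        paired_slots[i] = True
    n_p = int(paired_slots.sum())

    gaps = None
    for _ in range(max_retries):
        g = np.empty(n)
        g[paired_slots] = rng.normal(cfg.angular_paired_gap_mean,
                                     cfg.angular_paired_gap_sd, n_p)
        residual = 360.0 - g[paired_slots].sum()
        m = n - n_p
        if m == 0:
            if abs(residual) > 1e-6:
                continue
        else:
            if residual <= 0:
                continue
            base = residual / m
            raw = rng.normal(base, 0.25 * base, m)
            if (raw <= 0).any():
                continue
            g[~paired_slots] = raw * (residual / raw.sum())
        if (g > 0).all():
            gaps = g
            break
    if gaps is None:
        raise RealizationError(
            f"no positive gap sequence after {max_retries} attempts")

    theta0 = rng.uniform(0.0, 360.0)
    theta = np.deg2rad(theta0 - np.concatenate(([0.0], np.cumsum(gaps[:-1]))))
    r_centre = particle.radii - cfg.kinase_radius
    coords = np.column_stack((r_centre * np.cos(theta),
                              r_centre * np.sin(theta)))
    r_next = np.roll(r_centre, -1)
    gap_rad = np.deg2rad(gaps)
    seps = np.sqrt(r_centre**2 + r_next**2
                   - 2.0 * r_centre * r_next * np.cos(gap_rad))
    return coords, seps


def generate_ensemble(cfg: EnsembleConfig) -> list[HoloenzymeParticle]:
    """Generate ``cfg.n_particles`` holoenzymes, reproducibly for a seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    particles: list[HoloenzymeParticle] = []
    for pid in range(cfg.n_particles):
        n_sub = 14 if rng.random() < cfg.p_tetradecamer else 12
        edges = sample_pair_assignment(n_sub, cfg.pair_count_probs, rng)
        radii, compact = sample_radii(n_sub, cfg, rng)
        p = HoloenzymeParticle(
            particle_id=pid, n_subunits=n_sub, radii=radii,
            separations=np.empty(n_sub), pair_edges=edges,
            compact_flags=compact)
        if cfg.mode == "separation_explicit":
            p.separations = sample_separations(edges, cfg, rng, n_sub)
        else:
            p.coords, p.separations = realize_coordinates(p, cfg, rng)
        particles.append(p)
    return particles


# --------------------------------------------------------------------------
# particle-table I/O
# --------------------------------------------------------------------------

def particles_to_frame(particles: Iterable[HoloenzymeParticle]) -> pd.DataFrame:
    rows = []
    for p in particles:
        paired_slot = np.zeros(p.n_subunits, dtype=int)
        for (i, _) in p.pair_edges:
            paired_slot[i] = 1
        for s in range(p.n_subunits):
            row = {
                "particle_id": p.particle_id,
                "subunit_index": s,
                "n_subunits": p.n_subunits,
                "radius_A": p.radii[s],
                "separation_A": p.separations[s],
                "paired": paired_slot[s],
                "compact": int(p.compact_flags[s]),
            }
            if p.coords is not None:
                row["x_A"] = p.coords[s, 0]
                row["y_A"] = p.coords[s, 1]
            rows.append(row)
    return pd.DataFrame(rows)


def frame_to_particles(df: pd.DataFrame) -> list[HoloenzymeParticle]:
    particles = []
    for pid, grp in df.groupby("particle_id", sort=True):
        grp = grp.sort_values("subunit_index")
        n = int(grp["n_subunits"].iloc[0])
        edges = frozenset((int(i), (int(i) + 1) % n)
                          for i in grp.loc[grp["paired"] == 1, "subunit_index"])
        coords = None
        if "x_A" in grp.columns and grp["x_A"].notna().all():
            coords = grp[["x_A", "y_A"]].to_numpy(dtype=float)
        particles.append(HoloenzymeParticle(
            particle_id=int(pid), n_subunits=n,
            radii=grp["radius_A"].to_numpy(dtype=float),
            separations=grp["separation_A"].to_numpy(dtype=float),
            pair_edges=edges,
            compact_flags=grp["compact"].to_numpy(dtype=bool),
            coords=coords))
    return particles


def write_particles(particles: Iterable[HoloenzymeParticle],
                    path: str | Path,
                    cfg: EnsembleConfig | None = None) -> None:
    """Write the per-subunit CSV; if cfg is given, a JSON sidecar
    ``<path>.config.json`` records the full configuration incl. seed."""
    path = Path(path)
    particles_to_frame(particles).to_csv(path, index=False)
    if cfg is not None:
        save_config(cfg, path.with_suffix(path.suffix + ".config.json"))


def read_particles(path: str | Path) -> list[HoloenzymeParticle]:
    return frame_to_particles(pd.read_csv(path))
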