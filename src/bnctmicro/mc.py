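"""Cell-lattice Monte Carlo: specific-energy tallies per source compartment.

One history is one capture reaction (a correlated alpha/7Li pair) or one
background primary.  The engine exploits translation invariance of the
periodic cell lattice: the primary is emitted from the central cell (or one
period, for uniform background sources) and energy is scored in *all* nuclei
of the periodic array.  By reciprocity this is identical in expectation to
randomising the source position relative to a single scored nucleus, which is
how the randomised-arrangement tally is defined, but every history contributes.

Tracks are straight; energy along a track comes from exact residual-range
differences on sub-steps, and each sub-step midpoint is classified into
nucleus / cytoplasm / extracellular by periodic membership tests.  Specific
energy z = E_dep / m_nucleus is accumulated per (history, nucleus) pair; each
pair with z > 0 is one single-event sample of f_n,1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .geometry import CellLattice
from .physics import (
    NITROGEN_PROTON_ENERGY_MEV,
    StoppingModel,
    default_stopping,
    isotropic_directions,
    sample_reactions,
)

__all__ = [
    "SimConfig",
    "SpecificEnergyHistogram",
    "TrackSample",
    "TallySet",
    "CompartmentEmptyError",
    "run_boron_component",
    "run_background_component",
    "domain_spectrum",
    "compute_R",
    "DOMAIN_DIAMETERS_UM",
]

MEV_TO_J = 1.602176634e-13
KEV_TO_J = 1.602176634e-16

#: domain diameters tallied for the parameter table [um]
DOMAIN_DIAMETERS_UM = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.7, 1.0)

COMPARTMENTS = ("nucleus", "cytoplasm", "extracellular")
BACKGROUND_COMPONENTS = ("N", "H", "gamma")


class CompartmentEmptyError(ValueError):
    """Raised when a source compartment has zero volume."""


@dataclass(frozen=True)
class SimConfig:
    """Engine configuration.

    ds_um: base sub-step length for track deposition; per-run the step is
    coarsened so no track needs more than ``max_steps`` sub-steps (long
    low-LET electron tracks) and never exceeds a quarter of the nucleus edge.
    Histogram bins are log-spaced, 60 per decade over 1e-4..1e3 Gy.
    """

    ds_um: float = 0.05
    max_steps: int = 1200
    z_bin_lo: float = 1e-6
    z_bin_hi: float = 1e6  # small-domain single events reach ~1e5 Gy
    bins_per_decade: int = 60
    domain_diameters: tuple[float, ...] = DOMAIN_DIAMETERS_UM
    n_domain_samples: int = 20000
    max_track_subsample: int = 200000
    h_spectrum: tuple[float, float] = (0.1, 2.0)
    gamma_electron_energy: float = 0.3

    def z_edges(self) -> np.ndarray:
        n_dec = np.log10(self.z_bin_hi / self.z_bin_lo)
        return np.geomspace(self.z_bin_lo, self.z_bin_hi,
                            int(round(n_dec * self.bins_per_decade)) + 1)

    def config_hash(self) -> str:
        import hashlib

        return hashlib.sha256(repr(self).encode()).hexdigest()[:12]


@dataclass
class SpecificEnergyHistogram:
    """Single-event specific-energy density f1(z) on log-spaced bins.

    ``counts`` are event counts per bin; ``density()`` normalises so that the
    density integrates to one.  Exact sample moments (first/second, over the
    events inside and outside the binned range) are carried alongside the
    binned representation.
    """

    edges: np.ndarray  # Gy, len nbins+1
    counts: np.ndarray  # len nbins
    n_events: int
    m1: float  # exact first sample moment [Gy]
    m2: float  # exact second sample moment [Gy^2]

    @classmethod
    def from_samples(cls, z: np.ndarray, edges: np.ndarray) -> "SpecificEnergyHistogram":
        z = np.asarray(z, dtype=float)
        z = z[z > 0]
        counts, _ = np.histogram(np.clip(z, edges[0], edges[-1]), bins=edges)
        m1 = float(z.mean()) if z.size else 0.0
        m2 = float((z**2).mean()) if z.size else 0.0
        return cls(edges=edges, counts=counts.astype(float), n_events=int(z.size),
                   m1=m1, m2=m2)

    def density(self) -> np.ndarray:
        """Probability density per bin (integrates to 1 over the bin range)."""
        total = self.counts.sum()
        if total <= 0:
            raise ValueError("empty histogram has no density")
        widths = np.diff(self.edges)
        return self.counts / (total * widths)

    def rel_se(self) -> np.ndarray:
        """Per-bin relative standard error (Poisson counting) for occupied bins."""
        with np.errstate(divide="ignore"):
            return np.where(self.counts > 0, 1.0 / np.sqrt(self.counts), np.inf)

    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def to_dict(self) -> dict:
        return {
            "edges": self.edges.tolist(),
            "counts": self.counts.tolist(),
            "n_events": self.n_events,
            "m1": self.m1,
            "m2": self.m2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpecificEnergyHistogram":
        return cls(np.asarray(d["edges"]), np.asarray(d["counts"]),
                   int(d["n_events"]), float(d["m1"]), float(d["m2"]))


@dataclass
class TrackSample:
    """Subsample of in-nucleus track sub-steps for the domain tally.

    ``let_kev_um`` holds the local stopping power of equal-length sub-steps
    lying inside nuclei; sampling these uniformly is sampling uniformly along
    the in-nucleus track length.
    """

    let_kev_um: np.ndarray
    step_um: float


@dataclass
class TallySet:
    """Monte Carlo output for one (lattice, source, component) condition."""

    f_n1: SpecificEnergyHistogram
    f_d1: dict[float, SpecificEnergyHistogram]
    mean_nucleus_dose_per_reaction: float  # Gy per (one reaction per lattice period)
    mean_nucleus_dose_se: float
    mean_total_dose_per_reaction: float  # Gy over the whole period mass
    events_per_history: float
    n_histories: int
    seed: int
    tracks: TrackSample | None = None
    meta: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = {
            "f_n1": self.f_n1.to_dict(),
            "f_d1": {str(k): v.to_dict() for k, v in self.f_d1.items()},
            "mean_nucleus_dose_per_reaction": self.mean_nucleus_dose_per_reaction,
            "mean_nucleus_dose_se": self.mean_nucleus_dose_se,
            "mean_total_dose_per_reaction": self.mean_total_dose_per_reaction,
            "events_per_history": self.events_per_history,
            "n_histories": self.n_histories,
            "seed": self.seed,
            "meta": self.meta,
            "format_version": 1,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "TallySet":
        d = json.loads(s)
        return cls(
            f_n1=SpecificEnergyHistogram.from_dict(d["f_n1"]),
            f_d1={float(k): SpecificEnergyHistogram.from_dict(v)
                  for k, v in d["f_d1"].items()},
            mean_nucleus_dose_per_reaction=d["mean_nucleus_dose_per_reaction"],
            mean_nucleus_dose_se=d["mean_nucleus_dose_se"],
            mean_total_dose_per_reaction=d["mean_total_dose_per_reaction"],
            events_per_history=d["events_per_history"],
            n_histories=d["n_histories"],
            seed=d["seed"],
            meta=d.get("meta", {}),
        )


# ---------------------------------------------------------------------------
# source sampling
# ---------------------------------------------------------------------------

def _sample_in_compartment(lattice: CellLattice, compartment: str,
                           rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform points in the named compartment of the central cell (period
    coordinates: the cell is centred at pitch/2 along each axis)."""
    p, a_c, a_n = lattice.pitch, lattice.a_c, lattice.a_n
    c = p / 2.0
    if compartment == "nucleus":
        return c + rng.uniform(-a_n / 2, a_n / 2, (n, 3))
    if compartment == "cytoplasm":
        return _rejection_box(rng, n, c, a_c / 2, a_n / 2)
    if compartment == "extracellular":
        if lattice.gap <= 0:
            raise CompartmentEmptyError("compartment has zero volume: "
                                        "extracellular space vanishes at gap=0")
        return _rejection_box(rng, n, c, p / 2, a_c / 2)
    raise ValueError(f"unknown compartment {compartment!r}")


def _rejection_box(rng, n, center, half_outer, half_inner) -> np.ndarray:
    """Uniform points in an outer cube minus a concentric inner cube."""
    accept_frac = 1.0 - (half_inner / half_outer) ** 3
    out = np.empty((0, 3))
    while out.shape[0] < n:
        m = int((n - out.shape[0]) / max(accept_frac, 1e-3) * 1.2) + 16
        pts = rng.uniform(-half_outer, half_outer, (m, 3))
        keep = np.abs(pts).max(axis=1) > half_inner
        out = np.vstack([out, pts[keep]])
    return center + out[:n]


# ---------------------------------------------------------------------------
# deposition
# ---------------------------------------------------------------------------

_KEY_BASE = 2048  # cell-index encoding base; tracks stay within +-1023 cells


def _choose_ds(cfg: SimConfig, r_max: float) -> float:
    return max(cfg.ds_um, r_max / cfg.max_steps, 1e-4)


def _deposit_batch(origins, dirs, energies, stopping: StoppingModel,
                   lattice: CellLattice, cfg: SimConfig, ds: float,
                   hist_offset=0, collect_tracks=False):
    """Score one particle per history on the periodic lattice.

    Returns (keys, z) for per-(history, nucleus) events plus optionally the
    in-nucleus sub-step LET sample.  ``keys`` encode (history id, cell index).
    """
    n = origins.shape[0]
    r0 = np.asarray(stopping.range(energies), dtype=float)
    r_max = float(r0.max())
    k_steps = max(1, int(np.ceil(r_max / ds)))
    half_n = lattice.a_n / 2.0
    p = lattice.pitch
    c = p / 2.0

    keys_out, de_out = [], []
    let_out = []
    chunk = max(1, int(4_000_000 // k_steps))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        m = hi - lo
        s_edges = ds * np.arange(k_steps + 1)[None, :]  # (1, K+1)
        res = np.clip(r0[lo:hi, None] - s_edges, 0.0, None)  # residual range
        e_res = stopping.energy_from_range(res)
        de = e_res[:, :-1] - e_res[:, 1:]  # (m, K) MeV
        mid = np.minimum(s_edges[:, :-1] + ds / 2.0, r0[lo:hi, None])
        pos = origins[lo:hi, None, :] + mid[..., None] * dirs[lo:hi, None, :]
        cell = np.floor(pos / p).astype(np.int64)
        frac = pos - cell * p - c
        inside = (np.abs(frac) <= half_n).all(axis=2) & (de > 0)
        if not inside.any():
            continue
        h_idx, s_idx = np.nonzero(inside)
        ci = cell[h_idx, s_idx]  # (k, 3)
        hid = hist_offset + lo + h_idx
        b = _KEY_BASE
        key = ((hid * b + (ci[:, 0] + b // 2)) * b + (ci[:, 1] + b // 2)) * b \
            + (ci[:, 2] + b // 2)
        keys_out.append(key)
        d = de[h_idx, s_idx]
        de_out.append(d)
        if collect_tracks:
            let_out.append(d / ds * 1e3)  # keV/um
    if keys_out:
        keys = np.concatenate(keys_out)
        de_all = np.concatenate(de_out)
    else:
        keys = np.empty(0, dtype=np.int64)
        de_all = np.empty(0)
    lets = np.concatenate(let_out) if let_out else np.empty(0)
    total_e_mev = float(energies.sum())
    return keys, de_all, lets, total_e_mev


def _aggregate_events(keys: np.ndarray, de: np.ndarray, m_n_kg: float):
    """Sum deposits per (history, nucleus) key; return event z [Gy] and the
    history index of each event."""
    if keys.size == 0:
        return np.empty(0), np.empty(0, dtype=np.int64)
    uniq, inv = np.unique(keys, return_inverse=True)
    e_mev = np.bincount(inv, weights=de, minlength=uniq.size)
    z = e_mev * MEV_TO_J / m_n_kg
    hist_idx = uniq // (_KEY_BASE**3)
    return z, hist_idx


def _finalize(z_events, hist_idx, n_histories, lattice, cfg, seed, lets, ds,
              total_e_mev, rng, meta):
    edges = cfg.z_edges()
    f_n1 = SpecificEnergyHistogram.from_samples(z_events, edges)
    per_hist = np.bincount(hist_idx.astype(np.int64), weights=z_events,
                           minlength=n_histories)
    mean_dose = float(per_hist.mean())
    se = float(per_hist.std(ddof=1) / np.sqrt(n_histories)) if n_histories > 1 else np.inf
    period_mass_kg = lattice.pitch**3 * 1e-15
    total_dose = total_e_mev * MEV_TO_J / period_mass_kg / n_histories

    if lets.size > cfg.max_track_subsample:
        lets = rng.choice(lets, cfg.max_track_subsample, replace=False)
    tracks = TrackSample(let_kev_um=lets, step_um=ds)

    f_d1 = {}
    for d_um in cfg.domain_diameters:
        if d_um < lattice.a_n and lets.size:
            f_d1[d_um] = domain_spectrum(lattice, tracks, d_um,
                                         cfg.n_domain_samples, rng)
    return TallySet(
        f_n1=f_n1, f_d1=f_d1,
        mean_nucleus_dose_per_reaction=mean_dose,
        mean_nucleus_dose_se=se,
        mean_total_dose_per_reaction=total_dose,
        events_per_history=z_events.size / n_histories,
        n_histories=n_histories, seed=seed, tracks=tracks, meta=meta,
    )


def run_boron_component(lattice: CellLattice, compartment: str, n_histories: int,
                        seed: int, cfg: SimConfig | None = None,
                        stopping: dict[str, StoppingModel] | None = None,
                        with_domains: bool = True) -> TallySet:
    """Tally the boron component for capture reactions in one compartment.

    Each history samples one reaction point uniformly in the compartment and
    one correlated alpha/7Li pair (branch drawn by its branching ratio,
    fragments back-to-back); both fragments are transported and their nucleus
    deposits combined per history.
    """
    if compartment == "uniform":
        raise ValueError("run compartments separately and mix by volume "
                         "fraction for the uniform reference")
    if n_histories < 1:
        raise ValueError("n_histories must be >= 1")
    cfg = cfg or SimConfig()
    if not with_domains:
        cfg = SimConfig(**{**cfg.__dict__, "domain_diameters": ()})
    stopping = stopping or default_stopping()
    rng = np.random.default_rng(seed)

    origins = _sample_in_compartment(lattice, compartment, rng, n_histories)
    _, dirs, e_a, e_li = sample_reactions(rng, n_histories)

    r_max = float(max(stopping["alpha"].range(e_a.max()),
                      stopping["li7"].range(e_li.max())))
    ds = _choose_ds(cfg, r_max)
    k1, d1, l1, e1 = _deposit_batch(origins, dirs, e_a, stopping["alpha"],
                                    lattice, cfg, ds, collect_tracks=True)
    k2, d2, l2, e2 = _deposit_batch(origins, -dirs, e_li, stopping["li7"],
                                    lattice, cfg, ds, collect_tracks=True)
    keys = np.concatenate([k1, k2])
    de = np.concatenate([d1, d2])
    lets = np.concatenate([l1, l2])
    z, hist_idx = _aggregate_events(keys, de, lattice.nucleus_mass_kg)
    meta = {"component": "B", "compartment": compartment,
            "config_hash": cfg.config_hash()}
    return _finalize(z, hist_idx, n_histories, lattice, cfg, seed, lets, ds,
                     e1 + e2, rng, meta)


def run_background_component(lattice: CellLattice, component: str,
                             n_histories: int, seed: int,
                             cfg: SimConfig | None = None,
                             stopping: dict[str, StoppingModel] | None = None,
                             with_domains: bool = True) -> TallySet:
    """Tally one of the uniform background components (N, H, gamma).

    Primaries start uniformly over one lattice period (cells and interstitium
    alike) with isotropic directions; N gives a fixed 0.584 MeV proton, H a
    recoil proton from the configured spectrum, gamma a constant-LET electron.
    """
    if component not in BACKGROUND_COMPONENTS:
        raise ValueError(f"unknown background component {component!r}")
    if n_histories < 1:
        raise ValueError("n_histories must be >= 1")
    cfg = cfg or SimConfig()
    if not with_domains:
        cfg = SimConfig(**{**cfg.__dict__, "domain_diameters": ()})
    stopping = stopping or default_stopping()
    rng = np.random.default_rng(seed)

    origins = rng.uniform(0.0, lattice.pitch, (n_histories, 3))
    dirs = isotropic_directions(rng, n_histories)
    if component == "N":
        energies = np.full(n_histories, NITROGEN_PROTON_ENERGY_MEV)
        model = stopping["proton"]
    elif component == "H":
        energies = rng.uniform(*cfg.h_spectrum, n_histories)
        model = stopping["proton"]
    else:
        energies = np.full(n_histories, cfg.gamma_electron_energy)
        model = stopping["electron"]

    ds = _choose_ds(cfg, float(model.range(energies.max())))
    keys, de, lets, e_tot = _deposit_batch(origins, dirs, energies, model,
                                           lattice, cfg, ds, collect_tracks=True)
    z, hist_idx = _aggregate_events(keys, de, lattice.nucleus_mass_kg)
    meta = {"component": component, "config_hash": cfg.config_hash()}
    return _finalize(z, hist_idx, n_histories, lattice, cfg, seed, lets, ds,
                     e_tot, rng, meta)


def domain_spectrum(lattice: CellLattice, tracks: TrackSample,
                    domain_diameter: float, n_domains: int,
                    seed_or_rng) -> SpecificEnergyHistogram:
    """Single-event specific-energy density for spherical domains in nuclei.

    Sphere centres are uniform in the nuclei; conditioning on a nonzero chord,
    that is uniform along the in-nucleus track length with the impact
    parameter following the disc distribution b = r*sqrt(U), whence the chord
    2*sqrt(r^2 - b^2) (mean 2d/3).  The local LET at the sampled track point
    converts the chord to deposited energy and z_d = E / m_domain.
    """
    if domain_diameter >= lattice.a_n:
        raise ValueError(
            f"domain diameter {domain_diameter} um must be smaller than the "
            f"nucleus edge {lattice.a_n} um")
    if tracks.let_kev_um.size == 0:
        raise ValueError("no in-nucleus track sample to place domains on")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    r = domain_diameter / 2.0
    lets = rng.choice(tracks.let_kev_um, n_domains, replace=True)
    b = r * np.sqrt(rng.random(n_domains))
    chord = 2.0 * np.sqrt(r**2 - b**2)
    e_kev = lets * chord
    m_d_kg = (np.pi / 6.0) * domain_diameter**3 * 1e-15
    z = e_kev * KEV_TO_J / m_d_kg
    cfg = SimConfig()
    return SpecificEnergyHistogram.from_samples(z, cfg.z_edges())


def compute_R(tallies: dict[str, TallySet], lattice: CellLattice):
    """Nucleus-dose ratios (R_n, R_c, R_e) for compartment-localised boron.

    The uniform reference is the volume-fraction-weighted mixture of the
    per-reaction mean nucleus doses, so sum(f_j * R_j) = 1 identically.
    """
    for comp in COMPARTMENTS:
        if comp not in tallies:
            raise ValueError(f"missing compartment tally {comp!r}")
    f = (lattice.f_n, lattice.f_c, lattice.f_e)
    zb = [tallies[c].mean_nucleus_dose_per_reaction for c in COMPARTMENTS]
    z_unif = sum(fi * zi for fi, zi in zip(f, zb))
    if z_unif <= 0:
        raise ValueError("uniform-reference nucleus dose is zero")
    return tuple(zi / z_unif for zi in zb)
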