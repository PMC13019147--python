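"""Precomputed SMK-parameter table and its multilinear interpolator.

The expensive cellular-scale Monte Carlo is run once per morphology grid node
(and per boron source compartment / background component); everything a
survival calculation needs is then served for arbitrary morphologies and
boron distributions by interpolation:

* compartment weights  N_n + N_c + N_e = 1  are computed exactly from the
  query's boron-distribution ratios and volume fractions (no interpolation);
* the nucleus-dose ratios R_n, R_c, R_e and the specific-energy moments are
  interpolated trilinearly: first along the V_cell/V_total knot line of each
  of the four surrounding (S_nucl, S_nucl/S_cell) corners, then bilinearly
  across those corners;
* kappa = N_n R_n + N_c R_c + N_e R_e, split into an intracellular part
  (nucleus + cytoplasm terms) and an extracellular part.

Because the R values at each node are normalised to the volume-weighted
uniform reference from the same tallies, a uniform boron distribution gives
kappa = 1 exactly at every node; off-node deviations from 1 measure the
interpolation (plus Monte Carlo) error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (
    MorphologyGrid,
    MorphologyParams,
    build_lattice,
    fractions_from_query,
)
from .mc import (
    BACKGROUND_COMPONENTS,
    COMPARTMENTS,
    SimConfig,
    compute_R,
    run_background_component,
    run_boron_component,
)
from .microdosim import summarize, z0_from_y0

__all__ = [
    "BoronDistribution",
    "NWeights",
    "KappaResult",
    "SMKInputs",
    "ParameterTable",
    "n_weights",
    "kappa",
    "build_table",
    "interpolate",
    "DEFAULT_DOMAIN_RADIUS_UM",
    "DEFAULT_Y0_KEV_UM",
]

#: MK-model defaults used when the user leaves domain parameters unspecified
#: (SCC VII fits from the radiobiology literature).
DEFAULT_DOMAIN_RADIUS_UM = 0.24
DEFAULT_Y0_KEV_UM = 125.0

_MOMENT_FIELDS = ("zbar_n_D", "zbar_n_F", "zbar_n_M2",
                  "zbar_d_D", "zbar_d_F", "zbar_d_star")


@dataclass(frozen=True)
class BoronDistribution:
    """Boron partitioning between compartments.

    ``cell_uptake``: cell-to-extracellular ratio; ``nuclear_uptake``:
    nucleus-to-cytoplasm ratio.  Each may be given as a concentration ratio
    (per unit volume, convention="concentration") or an abundance ratio
    (total amounts, convention="abundance").
    """

    cell_uptake: float
    nuclear_uptake: float = 1.0
    cell_convention: str = "concentration"
    nuclear_convention: str = "concentration"

    def __post_init__(self):
        if self.cell_uptake < 0 or self.nuclear_uptake < 0:
            raise ValueError("boron uptake ratios must be >= 0")
        for conv in (self.cell_convention, self.nuclear_convention):
            if conv not in ("concentration", "abundance"):
                raise ValueError(f"unknown ratio convention {conv!r}")


@dataclass(frozen=True)
class NWeights:
    """Fractions of 10B (hence capture reactions) per compartment; sum = 1."""

    N_n: float
    N_c: float
    N_e: float

    def __iter__(self):
        return iter((self.N_n, self.N_c, self.N_e))


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    kappa_intra: float
    kappa_extra: float


@dataclass(frozen=True)
class SMKInputs:
    """Everything the survival model needs at one query point."""

    kappa_intra: float
    kappa_extra: float
    #: per component in {"B", "N", "H", "gamma"}
    zbar_n_D: dict[str, float]
    zbar_d_D: dict[str, float]
    zbar_d_star: dict[str, float]
    zbar_n_F: dict[str, float] = field(default_factory=dict)

    @property
    def kappa(self) -> float:
        return self.kappa_intra + self.kappa_extra

    def to_json(self) -> str:
        return json.dumps({
            "kappa_intra": self.kappa_intra, "kappa_extra": self.kappa_extra,
            "zbar_n_D": self.zbar_n_D, "zbar_d_D": self.zbar_d_D,
            "zbar_d_star": self.zbar_d_star, "zbar_n_F": self.zbar_n_F,
        })

    @classmethod
    def from_json(cls, s: str) -> "SMKInputs":
        d = json.loads(s)
        return cls(kappa_intra=d["kappa_intra"], kappa_extra=d["kappa_extra"],
                   zbar_n_D=d["zbar_n_D"], zbar_d_D=d["zbar_d_D"],
                   zbar_d_star=d["zbar_d_star"], zbar_n_F=d.get("zbar_n_F", {}))


def n_weights(dist: BoronDistribution, fractions) -> NWeights:
    """Compartment fractions of boron from uptake ratios and volume fractions.

    Concentration convention: the extracellular concentration is the
    reference (C_extra = 1); the nuclear ratio scales the nucleus relative to
    the cytoplasm, and the cytoplasm concentration is chosen so that the
    volume-weighted cell concentration matches ``cell_uptake`` exactly.
    Abundance convention: amounts split directly by the given ratios.
    """
    f_n, f_c, f_e = fractions
    if abs(f_n + f_c + f_e - 1.0) > 1e-9:
        raise ValueError("volume fractions must sum to 1")

    # cell-level split: amount in cells vs extracellular space
    if dist.cell_convention == "concentration":
        a_cell = dist.cell_uptake * (f_n + f_c)
        a_extra = 1.0 * f_e
    else:
        a_cell = dist.cell_uptake
        a_extra = 1.0
    # intracellular split: nucleus vs cytoplasm
    if dist.nuclear_convention == "concentration":
        w_n = dist.nuclear_uptake * f_n
        w_c = f_c
    else:
        w_n = dist.nuclear_uptake
        w_c = 1.0
    w_sum = w_n + w_c
    if w_sum <= 0:  # cell has volume but ratios degenerate (e.g. f_c=0, A-ratio 0)
        w_n, w_c, w_sum = 0.0, 1.0, 1.0

    raw = np.array([a_cell * w_n / w_sum, a_cell * w_c / w_sum, a_extra])
    total = raw.sum()
    if total <= 0:
        raise ValueError("boron distribution is identically zero")
    nn, nc, ne = raw / total
    return NWeights(float(nn), float(nc), float(ne))


def kappa(n: NWeights, r) -> KappaResult:
    """Macroscopic-kerma -> nucleus-dose conversion factor and its split."""
    r_n, r_c, r_e = r
    k_intra = n.N_n * r_n + n.N_c * r_c
    k_extra = n.N_e * r_e
    return KappaResult(kappa=k_intra + k_extra, kappa_intra=k_intra,
                       kappa_extra=k_extra)


# ---------------------------------------------------------------------------
# table construction
# ---------------------------------------------------------------------------

@dataclass
class ParameterTable:
    """Precomputed grid of R ratios and specific-energy moments.

    Arrays are indexed [i_s_nucl, i_s_ratio, i_vfrac]; ``v_knots`` holds the
    per-(s_nucl, s_ratio) V_cell/V_total knot vector in increasing order.
    Moments are stored per boron compartment (B component) and per background
    component, for each tallied domain diameter.
    """

    grid: MorphologyGrid
    v_knots: np.ndarray                 # (ns, nr, nv)
    R: dict[str, np.ndarray]            # compartment -> (ns, nr, nv)
    moments: dict[tuple, np.ndarray]    # (source, field, d_um) -> (ns, nr, nv)
    domain_diameters: tuple[float, ...]
    components: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.v_knots.shape

    def node_index(self, s_nucl: float, s_ratio: float, gap: float):
        i = self.grid.s_nucl_values.index(s_nucl)
        j = self.grid.s_ratio_values.index(s_ratio)
        k = len(self.grid.gap_values) - 1 - self.grid.gap_values.index(gap)
        return i, j, k

    # -- serialization (long-format CSV + JSON metadata) -------------------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        rows = []
        ns, nr, nv = self.shape
        for i in range(ns):
            for j in range(nr):
                for k in range(nv):
                    row = {
                        "s_nucl": self.grid.s_nucl_values[i],
                        "s_ratio": self.grid.s_ratio_values[j],
                        "v_cell_frac": self.v_knots[i, j, k],
                    }
                    for comp in COMPARTMENTS:
                        row[f"R_{comp}"] = self.R[comp][i, j, k]
                    for key, arr in self.moments.items():
                        row["__".join(map(str, key))] = arr[i, j, k]
                    rows.append(row)
        pd.DataFrame(rows).to_csv(d / "table.csv", index=False)
        meta = {
            "s_nucl_values": list(self.grid.s_nucl_values),
            "s_ratio_values": list(self.grid.s_ratio_values),
            "gap_values": list(self.grid.gap_values),
            "domain_diameters": list(self.domain_diameters),
            "components": list(self.components),
            "provenance": self.provenance,
            "format_version": 1,
        }
        (d / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory) -> "ParameterTable":
        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text())
        grid = MorphologyGrid(
            tuple(meta["s_nucl_values"]),
            tuple(meta["s_ratio_values"]),
            tuple(meta["gap_values"]),
        )
        df = pd.read_csv(d / "table.csv")
        ns = len(grid.s_nucl_values)
        nr = len(grid.s_ratio_values)
        nv = len(grid.gap_values)
        if len(df) != ns * nr * nv:
            raise ValueError("table.csv row count does not match the grid")
        shape = (ns, nr, nv)
        v_knots = df["v_cell_frac"].to_numpy().reshape(shape)
        R = {c: df[f"R_{c}"].to_numpy().reshape(shape) for c in COMPARTMENTS}
        moments = {}
        for col in df.columns:
            parts = col.split("__")
            if len(parts) >= 3:
                key = tuple(parts[:-2]) + (parts[-2], float(parts[-1]))
                moments[key] = df[col].to_numpy().reshape(shape)
        return cls(grid=grid, v_knots=v_knots, R=R, moments=moments,
                   domain_diameters=tuple(meta["domain_diameters"]),
                   components=tuple(meta["components"]),
                   provenance=meta.get("provenance", {}))


def _node_seed(seed: int, i: int, j: int, k: int, which: int) -> int:
    return int(np.random.SeedSequence([seed, i, j, k, which]).generate_state(1)[0]
               % (2**31 - 1))


def build_table(
    grid: MorphologyGrid | None = None,
    cfg: SimConfig | None = None,
    n_histories: int = 4000,
    seed: int = 0,
    components: tuple[str, ...] = ("B",) + BACKGROUND_COMPONENTS,
    domain_radius_um: float = DEFAULT_DOMAIN_RADIUS_UM,
    y0_kev_um: float = DEFAULT_Y0_KEV_UM,
    n_background: int | None = None,
    se_target: float = 0.01,
    n_cap: int = 64000,
    progress: bool = False,
) -> ParameterTable:
    """Run the surrogate Monte Carlo over the whole morphology grid.

    Per node: three boron source compartments (for the R ratios and the
    boron-component moments) and, when requested, the three uniform
    background components.  The boron history budget adapts per compartment
    so that each compartment's contribution to the kappa statistical error
    stays near ``se_target`` (capped at ``n_cap`` histories); a fixed seed
    makes the whole build bit-reproducible.
    """
    grid = grid or MorphologyGrid()
    cfg = cfg or SimConfig(ds_um=0.1)
    n_background = n_background or n_histories

    ns, nr = len(grid.s_nucl_values), len(grid.s_ratio_values)
    nv = len(grid.gap_values)
    shape = (ns, nr, nv)
    v_knots = np.zeros(shape)
    R = {c: np.zeros(shape) for c in COMPARTMENTS}
    moments: dict[tuple, np.ndarray] = {}

    want_b = "B" in components
    for i, s_nucl in enumerate(grid.s_nucl_values):
        for j, s_ratio in enumerate(grid.s_ratio_values):
            # gaps descending -> v_cell_frac ascending along the knot line
            for k, gap in enumerate(reversed(grid.gap_values)):
                params = MorphologyParams(s_nucl, s_ratio, gap)
                lat = build_lattice(params)
                v_knots[i, j, k] = lat.v_cell_frac
                try:
                    _fill_node(lat, i, j, k, cfg, n_histories, n_background,
                               seed, components, want_b, R, moments, shape,
                               y0_kev_um, cfg.domain_diameters, se_target,
                               n_cap)
                except Exception as exc:
                    raise RuntimeError(
                        f"simulation failed at node s_nucl={s_nucl}, "
                        f"s_ratio={s_ratio}, gap={gap}: {exc}") from exc
            if progress:
                print(f"  built line s_nucl={s_nucl} s_ratio={s_ratio}",
                      flush=True)

    return ParameterTable(
        grid=grid, v_knots=v_knots, R=R, moments=moments,
        domain_diameters=tuple(cfg.domain_diameters), components=components,
        provenance={
            "seed": seed, "n_histories": n_histories,
            "config_hash": cfg.config_hash(),
            "domain_radius_um": domain_radius_um, "y0_kev_um": y0_kev_um,
        },
    )


def _fill_node(lat, i, j, k, cfg, n_histories, n_background, seed, components,
               want_b, R, moments, shape, y0, diameters, se_target, n_cap):
    def ensure(key):
        if key not in moments:
            moments[key] = np.zeros(shape)

    if want_b:
        tallies = {}
        f = (lat.f_n, lat.f_c, lat.f_e)
        for ci, comp in enumerate(COMPARTMENTS):
            t = run_boron_component(lat, comp, n_histories,
                                    _node_seed(seed, i, j, k, ci), cfg)
            tallies[comp] = t
        # adaptive top-up: each compartment's kappa-error contribution is
        # roughly f_j * z_j * relSE_j / z_unif; re-run noisy compartments
        z_unif = sum(fj * tallies[c].mean_nucleus_dose_per_reaction
                     for fj, c in zip(f, COMPARTMENTS))
        for ci, comp in enumerate(COMPARTMENTS):
            t = tallies[comp]
            zj = t.mean_nucleus_dose_per_reaction
            if zj <= 0 or z_unif <= 0:
                continue
            contrib = f[ci] * zj / z_unif * (t.mean_nucleus_dose_se / zj)
            if contrib > se_target:
                n_new = min(n_cap,
                            int(n_histories * (contrib / se_target) ** 2) + 1)
                if n_new > n_histories:
                    tallies[comp] = run_boron_component(
                        lat, comp, n_new, _node_seed(seed, i, j, k, ci), cfg)
        r = compute_R(tallies, lat)
        for comp, r_val in zip(COMPARTMENTS, r):
            R[comp][i, j, k] = r_val
        for comp in COMPARTMENTS:
            t = tallies[comp]
            _store_moments(moments, ensure, ("B", comp), t, y0, diameters,
                           i, j, k)
    for comp in components:
        if comp == "B":
            continue
        t = run_background_component(
            lat, comp, n_background,
            _node_seed(seed, i, j, k, 10 + BACKGROUND_COMPONENTS.index(comp)),
            cfg)
        _store_moments(moments, ensure, (comp,), t, y0, diameters, i, j, k)


def _store_moments(moments, ensure, prefix, tally, y0, diameters, i, j, k):
    """Store per-diameter moments; each tallied diameter carries the z0 of
    its own size (z0 ~ y0/d^2), so interpolating across diameters serves the
    saturation correction at the queried r_d."""
    for d_um in diameters:
        f_d1 = tally.f_d1.get(d_um)
        s = summarize(tally.f_n1, f_d1, z0_from_y0(y0, d_um / 2.0))
        for name in _MOMENT_FIELDS:
            key = prefix + (name, d_um)
            ensure(key)
            moments[key][i, j, k] = getattr(s, name)
    if not diameters:
        s = summarize(tally.f_n1, None, 1.0)
        for name in ("zbar_n_D", "zbar_n_F", "zbar_n_M2"):
            key = prefix + (name, 0.0)
            ensure(key)
            moments[key][i, j, k] = getattr(s, name)


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------

class HullWarning(UserWarning):
    """Query outside the table hull was clamped."""


def _bracket(values: np.ndarray, x: float, clamp: bool, what: str):
    """Return (i0, i1, t) with x = (1-t)*v[i0] + t*v[i1]."""
    v = np.asarray(values, dtype=float)
    if x < v[0] or x > v[-1]:
        if not clamp:
            raise ValueError(f"{what}={x} outside table hull [{v[0]}, {v[-1]}]")
        import warnings

        warnings.warn(f"{what}={x} clamped to table hull [{v[0]}, {v[-1]}]",
                      HullWarning, stacklevel=3)
        x = float(np.clip(x, v[0], v[-1]))
    i1 = int(np.searchsorted(v, x, side="left"))
    if i1 == 0:
        return 0, 0, 0.0
    if i1 >= v.size:
        return v.size - 1, v.size - 1, 0.0
    i0 = i1 - 1
    if v[i1] == v[i0]:
        return i0, i1, 0.0
    return i0, i1, (x - v[i0]) / (v[i1] - v[i0])


def _interp_node_array(arr, v_knots, i_pair, j_pair, v_query, clamp):
    """Trilinear: along the v knot line of each (i, j) corner, then bilinear."""
    (i0, i1, ti), (j0, j1, tj) = i_pair, j_pair
    out = 0.0
    for ii, wi in ((i0, 1 - ti), (i1, ti)):
        for jj, wj in ((j0, 1 - tj), (j1, tj)):
            if wi * wj == 0.0 and (ii, jj) != (i0, j0):
                continue
            k0, k1, tk = _bracket(v_knots[ii, jj], v_query, clamp,
                                  "v_cell_frac")
            line = arr[ii, jj]
            val = (1 - tk) * line[k0] + tk * line[k1]
            out += wi * wj * val
    return out


def interpolate(
    table: ParameterTable,
    morphology: tuple[float, float, float],
    dist: BoronDistribution,
    domain_radius_um: float | None = None,
    y0_kev_um: float | None = None,
    clamp: bool = True,
) -> SMKInputs:
    """Serve SMK inputs at an arbitrary morphology / boron distribution.

    ``morphology`` is (s_nucl, s_ratio, v_cell_frac).  R values and moments
    are interpolated trilinearly; compartment weights come exactly from the
    query's volume fractions, and the boron moments are combined across
    source compartments with their nucleus-dose shares N_j R_j / kappa.
    Saturation-corrected values are served at the tallied domain diameter
    nearest (or linearly interpolated across) 2 * r_d.
    """
    s_nucl, s_ratio, v_frac = morphology
    r_d = domain_radius_um or table.provenance.get("domain_radius_um",
                                                   DEFAULT_DOMAIN_RADIUS_UM)
    i_pair = _bracket(np.asarray(table.grid.s_nucl_values), s_nucl, clamp,
                      "s_nucl")
    j_pair = _bracket(np.asarray(table.grid.s_ratio_values), s_ratio, clamp,
                      "s_ratio")

    def at(arr):
        return _interp_node_array(arr, table.v_knots, i_pair, j_pair, v_frac,
                                  clamp)

    fractions = fractions_from_query(s_ratio, v_frac)
    nw = n_weights(dist, fractions)
    r = tuple(at(table.R[c]) for c in COMPARTMENTS)
    kres = kappa(nw, r)

    has_domains = bool(table.domain_diameters)
    d_lo, d_hi, td = _domain_bracket(table.domain_diameters, 2 * r_d)
    nucleus_only = ("zbar_n_D", "zbar_n_F", "zbar_n_M2")

    def moment(prefix, name):
        if not has_domains:
            if name not in nucleus_only:
                return 0.0
            return at(table.moments[prefix + (name, 0.0)])
        lo = at(table.moments[prefix + (name, d_lo)])
        if td == 0.0:
            return lo
        hi = at(table.moments[prefix + (name, d_hi)])
        return (1 - td) * lo + td * hi

    zbar_n_D, zbar_n_F, zbar_d_D, zbar_d_star = {}, {}, {}, {}
    if "B" in table.components:
        # nucleus-dose shares of the three source compartments
        shares = np.array([nw.N_n * r[0], nw.N_c * r[1], nw.N_e * r[2]])
        shares = shares / shares.sum() if shares.sum() > 0 else np.full(3, 1 / 3)
        for name, store in (("zbar_n_D", zbar_n_D), ("zbar_n_F", zbar_n_F),
                            ("zbar_d_D", zbar_d_D),
                            ("zbar_d_star", zbar_d_star)):
            store["B"] = float(sum(
                w * moment(("B", c), name)
                for w, c in zip(shares, COMPARTMENTS)))
    for comp in table.components:
        if comp == "B":
            continue
        zbar_n_D[comp] = float(moment((comp,), "zbar_n_D"))
        zbar_n_F[comp] = float(moment((comp,), "zbar_n_F"))
        zbar_d_D[comp] = float(moment((comp,), "zbar_d_D"))
        zbar_d_star[comp] = float(moment((comp,), "zbar_d_star"))

    return SMKInputs(kappa_intra=kres.kappa_intra,
                     kappa_extra=kres.kappa_extra,
                     zbar_n_D=zbar_n_D, zbar_d_D=zbar_d_D,
                     zbar_d_star=zbar_d_star, zbar_n_F=zbar_n_F)


def _domain_bracket(diameters, d_query):
    ds = sorted(diameters)
    if not ds:
        return 0.0, 0.0, 0.0
    if d_query <= ds[0]:
        return ds[0], ds[0], 0.0
    if d_query >= ds[-1]:
        return ds[-1], ds[-1], 0.0
    idx = int(np.searchsorted(ds, d_query))
    lo, hi = ds[idx - 1], ds[idx]
    return lo, hi, (d_query - lo) / (hi - lo)
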