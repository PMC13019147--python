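"""Parametric cubic-lattice cell models for cellular-scale BNCT dosimetry.

Tissue is idealised as an 11 x 11 x 11 array of identical cubic cells embedded
in extracellular medium.  Each cell carries a concentric cubic nucleus.  A
morphology is fixed by three measurable quantities: the nuclear cross-sectional
area S_nucl [um^2], the nuclear-to-cell cross-sectional area ratio
S_nucl/S_cell, and the intercellular gap [um].  The cell-volume fraction
V_cell/V_total = (a_c / (a_c + gap))^3 follows from these, and is the
coordinate actually used when the precomputed parameter table is queried.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MorphologyParams",
    "CellLattice",
    "MorphologyGrid",
    "build_lattice",
    "volume_fractions",
    "enumerate_grid",
]

#: edge count of the cell array along each axis
ARRAY_DIM = 11


@dataclass(frozen=True)
class MorphologyParams:
    """One point of the morphology space.

    Parameters
    ----------
    s_nucl : float
        Nuclear cross-sectional area [um^2] (area of the square face of the
        cubic nucleus).
    s_ratio : float
        Nuclear-to-cell cross-sectional area ratio S_nucl/S_cell, in (0, 1).
    gap : float
        Intercellular distance [um], >= 0.
    """

    s_nucl: float
    s_ratio: float
    gap: float

    def __post_init__(self) -> None:
        if not self.s_nucl > 0:
            raise ValueError(f"s_nucl must be > 0, got {self.s_nucl}")
        if not 0 < self.s_ratio < 1:
            raise ValueError(f"s_ratio must be in (0, 1), got {self.s_ratio}")
        if self.gap < 0:
            raise ValueError(f"gap must be >= 0, got {self.gap}")


@dataclass(frozen=True)
class CellLattice:
    """Concrete geometric realisation of a :class:`MorphologyParams` point.

    All lengths in um.  Cells are cubes of edge ``a_c`` on a cubic lattice of
    pitch ``p = a_c + gap``; the cubic nucleus of edge ``a_n`` is concentric
    with its cell.
    """

    a_n: float
    a_c: float
    gap: float
    pitch: float
    v_cell_frac: float
    array_dims: tuple[int, int, int] = (ARRAY_DIM, ARRAY_DIM, ARRAY_DIM)
    params: MorphologyParams | None = field(default=None, compare=False)

    @property
    def f_n(self) -> float:
        """Volume fraction of nuclei."""
        return (self.a_n / self.pitch) ** 3

    @property
    def f_c(self) -> float:
        """Volume fraction of cytoplasm."""
        return (self.a_c**3 - self.a_n**3) / self.pitch**3

    @property
    def f_e(self) -> float:
        """Volume fraction of extracellular space."""
        return 1.0 - (self.a_c / self.pitch) ** 3

    @property
    def nucleus_mass_kg(self) -> float:
        """Mass of one nucleus at unit density (1 g/cm^3)."""
        # a_n in um -> volume in m^3 is a_n^3 * 1e-18; density 1000 kg/m^3
        return self.a_n**3 * 1e-15

    def to_dict(self) -> dict:
        return {
            "a_n": self.a_n,
            "a_c": self.a_c,
            "gap": self.gap,
            "pitch": self.pitch,
            "v_cell_frac": self.v_cell_frac,
            "array_dims": list(self.array_dims),
        }


def build_lattice(params: MorphologyParams) -> CellLattice:
    """Realise a morphology point as a cubic cell lattice.

    ``a_n = sqrt(S_nucl)``, ``a_c = sqrt(S_nucl / s_ratio)`` and the lattice
    pitch is ``a_c + gap``, so that the square-face areas reproduce the input
    cross-sectional areas exactly and ``V_cell/V_total = (a_c/pitch)^3``.
    """
    a_n = float(np.sqrt(params.s_nucl))
    a_c = float(np.sqrt(params.s_nucl / params.s_ratio))
    pitch = a_c + params.gap
    v_cell_frac = (a_c / pitch) ** 3
    return CellLattice(
        a_n=a_n, a_c=a_c, gap=params.gap, pitch=pitch,
        v_cell_frac=v_cell_frac, params=params,
    )


def volume_fractions(lattice: CellLattice) -> tuple[float, float, float]:
    """Return (f_n, f_c, f_e), the nucleus / cytoplasm / extracellular volume
    fractions of one lattice period.  They sum to 1 exactly."""
    return lattice.f_n, lattice.f_c, lattice.f_e


def fractions_from_query(s_ratio: float, v_cell_frac: float) -> tuple[float, float, float]:
    """Volume fractions directly from the table query coordinates.

    f_n = V_cell/V_total * (S_nucl/S_cell)^(3/2) for cubic concentric nuclei;
    this is what the interpolator uses so that off-node queries get exact
    (not interpolated) compartment weights.
    """
    if not 0 < s_ratio < 1:
        raise ValueError(f"s_ratio must be in (0, 1), got {s_ratio}")
    if not 0 < v_cell_frac <= 1:
        raise ValueError(f"v_cell_frac must be in (0, 1], got {v_cell_frac}")
    f_n = v_cell_frac * s_ratio**1.5
    f_c = v_cell_frac - f_n
    f_e = 1.0 - v_cell_frac
    return f_n, f_c, f_e


@dataclass(frozen=True)
class MorphologyGrid:
    """The morphology grid over which the parameter table is precomputed.

    Defaults reproduce the 4 x 8 x 16 = 512-model study grid.
    """

    s_nucl_values: tuple[float, ...] = (9.0, 36.0, 81.0, 144.0)
    s_ratio_values: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
    gap_values: tuple[float, ...] = (
        0.1, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0,
        8.0, 9.0, 10.0, 11.0, 12.0, 13.0, 14.0,
    )

    def __len__(self) -> int:
        return len(self.s_nucl_values) * len(self.s_ratio_values) * len(self.gap_values)

    def to_json(self) -> str:
        """Serialise the axes plus the derived V_cell/V_total of every node."""
        nodes = [
            {
                "s_nucl": p.s_nucl,
                "s_ratio": p.s_ratio,
                "gap": p.gap,
                "v_cell_frac": build_lattice(p).v_cell_frac,
            }
            for p in enumerate_grid(self)
        ]
        return json.dumps(
            {
                "s_nucl_values": list(self.s_nucl_values),
                "s_ratio_values": list(self.s_ratio_values),
                "gap_values": list(self.gap_values),
                "nodes": nodes,
            },
            indent=1,
        )


def enumerate_grid(grid: MorphologyGrid | None = None) -> list[MorphologyParams]:
    """All grid combinations in deterministic s_nucl-major order."""
    grid = grid or MorphologyGrid()
    return [
        MorphologyParams(s, r, g)
        for s, r, g in itertools.product(
            grid.s_nucl_values, grid.s_ratio_values, grid.gap_values
        )
    ]
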