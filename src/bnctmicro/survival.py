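"""SMK cell survival for mixed BNCT fields and photon isoeffective dose.

The stochastic microdosimetric kinetic (SMK) model treats the nucleus
specific energy z_n accumulated over an irradiation as a random variable: a
compound Poisson sum of single events drawn from f_n,1.  Conditional on z_n
the surviving fraction is the microdosimetric linear-quadratic kernel

    s(z_n) = exp(-(alpha0 + beta0 * z*_dD) * z_n - beta0 * z_n**2),

and S = E[s(z_n)].  Two evaluation paths are provided:

* ``survival_mc`` — the reference: simulate the compound Poisson sum
  directly from the single-event density (event count Poisson with mean
  D / z_F).
* ``survival_moment`` — a second-order moment approximation usable when only
  the summary moments (not the full f_n,1) are available, as is the case for
  table-served parameters.  Expanding E[s(z_n)] around E[z_n] = D with the
  compound-Poisson variance Var[z_n] = zbar_n,D * D gives

      -ln S = A D + beta0 D^2 + beta0 s2 - (A + 2 beta0 D)^2 s2 / 2,

  with A = alpha0 + beta0 z*_dD and s2 the variance.  It is exact in the
  zero-variance limit (the deterministic MK closed form) and flagged with an
  error when the variance is large enough to drive -ln S negative, where the
  expansion has left its validity region and the MC path must be used.

The photon isoeffective dose D_isoE is the total dose of reference photons
(linear-quadratic alpha, beta), delivered in fractions of X Gy, that yields
the same survival:  n fractions with n (alpha X + beta X^2) = -ln S, hence
D_isoE = n X = -ln S / (alpha + beta X).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mc import SpecificEnergyHistogram
from .tables import SMKInputs

__all__ = [
    "RadiationField",
    "LQParams",
    "WeightFactors",
    "MomentApproximationError",
    "mix_single_event_densities",
    "nucleus_dose",
    "mixed_field_zbars",
    "survival_mc",
    "survival_moment",
    "iso_effective_dose",
    "weighted_dose",
    "skin_normalize",
    "TUMOR_WEIGHTS",
    "SKIN_WEIGHTS",
]

@dataclass(frozen=True)
class RadiationField:
    """Macroscopic absorbed-dose components at one spatial point [Gy]."""

    D_B: float  # boron dose (kerma approximation, already scaled by ppm)
    D_N: float
    D_H: float
    D_gamma: float

    def __post_init__(self):
        for name in ("D_B", "D_N", "D_H", "D_gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return {"B": self.D_B, "N": self.D_N, "H": self.D_H,
                "gamma": self.D_gamma}


@dataclass(frozen=True)
class LQParams:
    """SMK baseline (alpha0, beta0) and reference-photon (alpha, beta, X)."""

    alpha0: float = 0.0422   # Gy^-1
    beta0: float = 0.00822   # Gy^-2
    alpha: float = 0.0633    # Gy^-1
    beta: float = 0.00822    # Gy^-2
    X: float = 2.0           # Gy per photon fraction

    def __post_init__(self):
        if self.alpha0 < 0 or self.beta0 < 0:
            raise ValueError("alpha0 and beta0 must be >= 0")
        if self.alpha <= 0 and self.beta <= 0:
            raise ValueError("need alpha > 0 or beta > 0")
        if self.X <= 0:
            raise ValueError("X must be > 0")


@dataclass(frozen=True)
class WeightFactors:
    """Fixed CBE/RBE multipliers per component."""

    B: float
    N: float
    H: float
    gamma: float

    def __post_init__(self):
        for name in ("B", "N", "H", "gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"weight {name} must be > 0")

    def as_dict(self) -> dict[str, float]:
        return {"B": self.B, "N": self.N, "H": self.H, "gamma": self.gamma}


#: CBE/RBE weights for tumor and for the skin-normalisation rule
TUMOR_WEIGHTS = WeightFactors(B=3.8, N=2.5, H=2.5, gamma=2.5)
SKIN_WEIGHTS = WeightFactors(B=2.5, N=2.5, H=2.5, gamma=1.0)


class MomentApproximationError(ValueError):
    """The moment expansion left its validity region (use survival_mc)."""


def mix_single_event_densities(hists: dict[str, SpecificEnergyHistogram],
                               doses: dict[str, float]) -> SpecificEnergyHistogram:
    """Mixed-field single-event density.

    Events from independent components superpose as a marked Poisson
    process, so the mixture weight of component c is its event rate
    lambda_c = D_c / zbar_F_c; the mixed density is the rate-weighted mixture
    of the per-component densities.
    """
    comps = [c for c, d in doses.items() if d > 0 and c in hists]
    if not comps:
        raise ValueError("no component with positive dose and density")
    edges = hists[comps[0]].edges
    rates = np.array([doses[c] / hists[c].m1 for c in comps])
    w = rates / rates.sum()
    counts = np.zeros(edges.size - 1)
    m1 = m2 = 0.0
    for wc, c in zip(w, comps):
        h = hists[c]
        if not np.allclose(h.edges, edges):
            raise ValueError("histograms must share bin edges")
        counts += wc * h.counts / h.counts.sum()
        m1 += wc * h.m1
        m2 += wc * h.m2
    n_events = int(sum(hists[c].n_events for c in comps))
    return SpecificEnergyHistogram(edges=edges, counts=counts,
                                   n_events=n_events, m1=m1, m2=m2)


def nucleus_dose(field: RadiationField, smk: SMKInputs) -> dict[str, float]:
    """Cell-nucleus mean doses per component [Gy].

    Boron kerma is rescaled by kappa = kappa_intra + kappa_extra; the N, H
    and gamma components are uniform at the cellular scale (kappa = 1).
    """
    return {
        "B": (smk.kappa_intra + smk.kappa_extra) * field.D_B,
        "N": field.D_N,
        "H": field.D_H,
        "gamma": field.D_gamma,
    }


def mixed_field_zbars(field: RadiationField, smk: SMKInputs):
    """Dose-weighted mixed-field (z*_dD, zbar_n_D) over the components.

    Weights are the components' shares of the total nucleus dose.
    """
    doses = nucleus_dose(field, smk)
    d_tot = sum(doses.values())
    if d_tot <= 0:
        raise ValueError("total nucleus dose is zero")
    zstar = sum(doses[c] / d_tot * smk.zbar_d_star.get(c, 0.0)
                for c in doses)
    zn = sum(doses[c] / d_tot * smk.zbar_n_D.get(c, 0.0) for c in doses)
    return float(zstar), float(zn)


def survival_mc(D_tot: float, zstar_mix: float,
                f_n1_mix: SpecificEnergyHistogram, lq: LQParams,
                n_samples: int = 20000, seed: int = 0):
    """Compound-Poisson SMK survival (reference evaluation).

    Per sample: k ~ Poisson(D_tot / z_F) events, z_n the sum of k draws from
    the single-event density, survival kernel averaged over samples.
    Returns (S, standard_error).
    """
    if D_tot < 0:
        raise ValueError("D_tot must be >= 0")
    if D_tot == 0:
        return 1.0, 0.0
    rng = np.random.default_rng(seed)
    z_f = f_n1_mix.m1
    if not z_f > 0:
        raise ValueError("single-event density must have positive mean")
    # sample event z from the histogram: bin by counts, uniform within bin
    counts = f_n1_mix.counts
    probs = counts / counts.sum()
    lam = D_tot / z_f
    k = rng.poisson(lam, n_samples)
    total = int(k.sum())
    bins = rng.choice(counts.size, total, p=probs)
    lo = f_n1_mix.edges[bins]
    hi = f_n1_mix.edges[bins + 1]
    z_events = lo * (hi / lo) ** rng.random(total)  # log-uniform within bin
    owner = np.repeat(np.arange(n_samples), k)
    z_n = np.bincount(owner, weights=z_events, minlength=n_samples)
    a = lq.alpha0 + lq.beta0 * zstar_mix
    s = np.exp(-a * z_n - lq.beta0 * z_n**2)
    return float(s.mean()), float(s.std(ddof=1) / np.sqrt(n_samples))


def survival_moment(D_tot: float, zstar_mix: float, zbar_n_mix: float,
                    lq: LQParams) -> float:
    """Second-order moment approximation of the SMK survival."""
    if min(D_tot, zstar_mix, zbar_n_mix) < 0:
        raise ValueError("inputs must be >= 0")
    if D_tot == 0:
        return 1.0
    a = lq.alpha0 + lq.beta0 * zstar_mix
    s2 = zbar_n_mix * D_tot  # compound-Poisson variance of z_n
    neg_ln_s = (a * D_tot + lq.beta0 * D_tot**2 + lq.beta0 * s2
                - 0.5 * (a + 2.0 * lq.beta0 * D_tot) ** 2 * s2)
    if neg_ln_s < 0:
        raise MomentApproximationError(
            "event-size variance too large for the moment expansion "
            f"(-ln S = {neg_ln_s:.3g} < 0); evaluate with survival_mc")
    return float(np.exp(-neg_ln_s))


def iso_effective_dose(S: float, lq: LQParams) -> float:
    """Photon isoeffective dose [Gy] for survival S under fractions of X Gy."""
    if not 0 < S <= 1:
        raise ValueError(f"S must be in (0, 1], got {S}")
    return float(-np.log(S) / (lq.alpha + lq.beta * lq.X))


def weighted_dose(field: RadiationField, w: WeightFactors) -> float:
    """Fixed-factor CBE/RBE-weighted dose [Gy-Eq]."""
    doses = field.as_dict()
    weights = w.as_dict()
    return float(sum(weights[c] * doses[c] for c in doses))


def skin_normalize(depth_curves, blood_ppm: float = 20.0,
                   skin_blood_ratio: float = 1.1,
                   skin_weights: WeightFactors = SKIN_WEIGHTS,
                   target_gy_eq: float = 12.0) -> float:
    """Scale factor making the weighted skin (surface) dose hit the target.

    ``depth_curves`` is a DataFrame with columns depth_cm, dose_B_per_ppm,
    dose_N, dose_H, dose_gamma; the surface row is the minimum depth.  The
    skin boron concentration is blood_ppm * skin_blood_ratio.
    """
    surf = depth_curves.loc[depth_curves["depth_cm"].idxmin()]
    skin_ppm = blood_ppm * skin_blood_ratio
    field = RadiationField(
        D_B=float(surf["dose_B_per_ppm"]) * skin_ppm,
        D_N=float(surf["dose_N"]), D_H=float(surf["dose_H"]),
        D_gamma=float(surf["dose_gamma"]),
    )
    ref = weighted_dose(field, skin_weights)
    if ref <= 0:
        raise ValueError("weighted skin dose is zero; cannot normalize")
    return float(target_gy_eq / ref)
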