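"""Binding energetics and dose-response fitting.

Docking yields a free energy of binding ΔG (kcal/mol); the dissociation
constant follows as K_D = exp(ΔG / RT) and splits into microscopic rates
through K_D = k_off / k_on once an association rate is assumed.  The
dose-response side fits the three-parameter Hill equation
r(c) = R_max c^n / (EC50^n + c^n) to replicate peak-response tables.

T = 298 K is the default temperature: it reproduces the docking-derived
dissociation constants for GABA, P4S and flurazepam to three significant
figures, which fixes the convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lmfit import Model

__all__ = [
    "R_KCAL_PER_MOL_K",
    "BindingEnergetics",
    "HillFit",
    "kd_from_dg",
    "dg_from_kd",
    "koff_from_kd",
    "hill_fit",
    "hill_response",
]

R_KCAL_PER_MOL_K = 1.9872e-3  # gas constant, kcal mol^-1 K^-1


def kd_from_dg(dg_kcal_per_mol: float, temperature_k: float = 298.0) -> float:
    """Dissociation constant (M) from binding free energy: exp(ΔG/RT)."""
    if temperature_k <= 0:
        raise ValueError("temperature must be positive")
    return float(np.exp(dg_kcal_per_mol / (R_KCAL_PER_MOL_K * temperature_k)))


def dg_from_kd(kd_m: float, temperature_k: float = 298.0) -> float:
    """Binding free energy (kcal/mol) from the dissociation constant."""
    if kd_m <= 0 or temperature_k <= 0:
        raise ValueError("kd and temperature must be positive")
    return float(R_KCAL_PER_MOL_K * temperature_k * np.log(kd_m))


def koff_from_kd(kd_m: float, kon_per_m_s: float) -> float:
    """Unbinding rate (s^-1) from K_D = k_off / k_on."""
    if kd_m <= 0 or kon_per_m_s <= 0:
        raise ValueError("kd and kon must be positive")
    return kd_m * kon_per_m_s


@dataclass(frozen=True)
class BindingEnergetics:
    """ΔG, K_D and the microscopic rate split for one ligand."""

    dg_kcal_per_mol: float
    temperature_k: float = 298.0
    kon_per_m_s: float = 1e7  # order-of-magnitude association prior

    @property
    def kd_m(self) -> float:
        return kd_from_dg(self.dg_kcal_per_mol, self.temperature_k)

    @property
    def koff_per_s(self) -> float:
        return koff_from_kd(self.kd_m, self.kon_per_m_s)


@dataclass(frozen=True)
class HillFit:
    ec50_m: float
    hill_n: float
    r_max: float
    residual: float

    def __post_init__(self):
        if self.ec50_m <= 0 or self.hill_n <= 0:
            raise ValueError("EC50 and Hill coefficient must be positive")


def hill_response(conc_m, ec50_m: float, hill_n: float, r_max: float):
    c = np.asarray(conc_m, dtype=float)
    cn = np.power(c, hill_n)
    return r_max * cn / (np.power(ec50_m, hill_n) + cn)


def hill_fit(concentrations_m, responses, n_starts: int = 5) -> HillFit:
    """Least-squares Hill fit of a dose-response table.

    ``responses`` may be 1-D (one value per concentration) or 2-D with
    replicates along the second axis.  Requires at least four distinct
    concentrations; flat responses raise a degenerate-data error.
    EC50 and n are unchanged by rescaling all responses (R_max scales).
    """
    c = np.asarray(concentrations_m, dtype=float)
    r = np.asarray(responses, dtype=float)
    if r.ndim == 2:
        c = np.repeat(c, r.shape[1])
        r = r.ravel()
    if c.shape != r.shape:
        raise ValueError("concentrations and responses do not align")
    if np.unique(c).size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if (c <= 0).any():
        raise ValueError("concentrations must be positive")
    if (r < 0).any():
        raise ValueError("responses must be non-negative")
    if np.ptp(r) == 0:
        raise ValueError("degenerate data: responses are flat")

    model = Model(hill_response, independent_vars=["conc_m"])
    rmax0 = float(r.max())
    ec50_grid = np.geomspace(c.min(), c.max(), n_starts)
    best = None
    for ec0 in ec50_grid:
        params = model.make_params(ec50_m=ec0, hill_n=1.0, r_max=rmax0)
        params["ec50_m"].min = c.min() / 1e3
        params["ec50_m"].max = c.max() * 1e3
        params["hill_n"].min = 0.05
        params["hill_n"].max = 10.0
        params["r_max"].min = 0.0
        try:
            res = model.fit(r, params, conc_m=c)
        except Exception:
            continue
        rss = float(np.sum(res.residual ** 2))
        if best is None or rss < best[0]:
            best = (rss, res)
    if best is None:
        raise RuntimeError("Hill fit failed to converge from any start")
    rss, res = best
    return HillFit(
        ec50_m=float(res.params["ec50_m"].value),
        hill_n=float(res.params["hill_n"].value),
        r_max=float(res.params["r_max"].value),
        residual=rss,
    )
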