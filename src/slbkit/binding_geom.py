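"""Hill-equation binding-curve fits and membrane packing geometry.

Two Hill parameterizations are used by the upstream instruments:

* QCM-D frequency-shift isotherms: ``y = S + (E - S) x^n / (k^n + x^n)``
  with starting level S, end level E (below S for frequency shifts, which
  are negative on binding), Hill coefficient n and dissociation constant k.
* MST titrations: ``y = U + (B - U) / (1 + (EC50 / C)^n)`` with unbound and
  bound signal levels U, B and half-maximal concentration EC50.

The geometry helpers convert a surface protein density into the
hexagonal-lattice area per molecule, and a molecular footprint into the
number of lipids it covers and the anchor-lipid mole percentage at which the
membrane saturates.
"""

from __future__ import annotations

import numpy as np

import lmfit

from .core import BindingSeries, FitResult

__all__ = ["hill_qcmd", "hill_mst", "fit_hill_qcmd", "fit_hill_mst",
           "lattice_spacing", "max_packing"]


def hill_qcmd(x, S, E, n, k):
    """QCM-D Hill isotherm; handles x = 0 (returns S)."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(x > 0, x ** n / (k ** n + x ** n), 0.0)
    return S + (E - S) * frac


def hill_mst(C, U, B, EC50, n):
    """MST Hill curve; handles C = 0 (returns U)."""
    C = np.asarray(C, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(C > 0, 1.0 / (1.0 + (EC50 / C) ** n), 0.0)
    return U + (B - U) * frac


def _check_series(series: BindingSeries) -> None:
    if len(series.concentrations) < 4:
        raise ValueError("need at least 4 concentration points to fit")


def _finish(res, model_name: str, k_name: str,
            series: BindingSeries) -> FitResult:
    params = {name: float(p.value) for name, p in res.params.items()}
    stderr = {name: float(p.stderr) if p.stderr is not None else float("nan")
              for name, p in res.params.items()}
    ss_res = float(np.sum(res.residual ** 2))
    y = series.responses
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    out = FitResult(params=params, stderr=stderr, r_squared=r2,
                    model_name=model_name, success=bool(res.success),
                    message="" if res.success else res.message)
    k = params[k_name]
    c = series.concentrations
    pos = c[c > 0]
    if pos.size and not (pos.min() <= k <= pos.max()):
        out.message = (out.message + "; " if out.message else "") + \
            f"{k_name} outside the sampled concentration range (extrapolated)"
    n = params["n"]
    if abs(n - 0.2) < 1e-6 or abs(n - 10.0) < 1e-6:
        out.success = False
        out.message = (out.message + "; " if out.message else "") + \
            "Hill coefficient at bound"
    return out


def fit_hill_qcmd(series: BindingSeries) -> FitResult:
    """Fit the QCM-D Hill isotherm; returns S, E, n, k (k in uM).

    Initialization: S = first response, E = last, k = mid concentration,
    n = 1; bounds n in [0.2, 10], k > 0.  The response sign is used as-is
    (QCM-D frequency shifts are negative on binding, so E < S is expected).
    """
    _check_series(series)
    c, y = series.concentrations, series.responses
    model = lmfit.Model(hill_qcmd)
    pos = c[c > 0]
    pars = model.make_params(S=y[0], E=y[-1],
                             k=float(np.median(pos)) if pos.size else 1.0,
                             n=1.0)
    pars["n"].set(min=0.2, max=10.0)
    pars["k"].set(min=1e-12)
    weights = 1.0 / series.response_sd if series.response_sd is not None \
        else None
    res = model.fit(y, pars, x=c, weights=weights)
    return _finish(res, "hill_qcmd", "k", series)


def fit_hill_mst(series: BindingSeries) -> FitResult:
    """Fit the MST Hill curve; returns U, B, EC50 (uM), n."""
    _check_series(series)
    c, y = series.concentrations, series.responses
    model = lmfit.Model(hill_mst)
    pos = c[c > 0]
    pars = model.make_params(U=y[0], B=y[-1],
                             EC50=float(np.median(pos)) if pos.size else 1.0,
                             n=1.0)
    pars["n"].set(min=0.2, max=10.0)
    pars["EC50"].set(min=1e-12)
    weights = 1.0 / series.response_sd if series.response_sd is not None \
        else None
    res = model.fit(y, pars, C=c, weights=weights)
    return _finish(res, "hill_mst", "EC50", series)


def lattice_spacing(protein_density: float) -> float:
    """Hexagonal-lattice area per molecule (nm^2) from a surface density.

    ``protein_density`` is in pmol/cm^2.  The area per molecule on a
    hexagonal lattice is ``(2 / sqrt(3)) / (6.022 * density * 0.001)`` nm^2:
    the reciprocal of the number surface density (6.022e-3 molecules/nm^2
    per pmol/cm^2) times the hexagonal packing factor.
    """
    if not protein_density > 0:
        raise ValueError("protein density must be positive")
    return (2.0 / np.sqrt(3.0)) / (6.022 * protein_density * 0.001)


def max_packing(footprint_nm2: float,
                lipid_area_nm2: float = 0.5) -> tuple[float, float]:
    """Lipids covered per molecule and the saturating anchor-lipid percent.

    A molecule of the given footprint occupies ``footprint / lipid_area``
    lipids; the membrane is maximally covered when that one lipid in each
    covered patch is an anchor (Ni-chelating) lipid, i.e. at an anchor mole
    percentage of ``100 / lipids_per_molecule``.
    """
    if footprint_nm2 <= 0 or lipid_area_nm2 <= 0:
        raise ValueError("areas must be positive")
    lipids_per_molecule = footprint_nm2 / lipid_area_nm2
    return lipids_per_molecule, 100.0 / lipids_per_molecule
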