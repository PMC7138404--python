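"""Relaxation-compensated intravoxel incoherent motion (IVIM) modelling.

IVIM separates the diffusion-weighted signal into a slowly decaying tissue
compartment (diffusivity D) and a rapidly decaying pseudo-perfusion
compartment (pseudodiffusion coefficient D*) occupying a perfusion fraction f
of the voxel.  Because the two compartments relax at different rates, the
apparent fraction depends on TR/TE; the model therefore weights each
compartment by

    w_x = (1 - exp(-TR / T1_x)) * exp(-TE / T2_x),

with blood constants T1_b = 2200 ms, T2_b = 50 ms and tissue T1/T2 supplied
per voxel from acquired maps, yielding a relaxation-corrected (absolute) f:

    S(b)/S(0) = [f w_b e^(-b r_fast) + (1 - f) w_t e^(-b D)]
                / [f w_b + (1 - f) w_t].

Two conventions for the fast decay rate are in circulation; both are
supported through ``dstar_convention``: ``"total"`` (default) takes
r_fast = D* with the constraint D* >= D, ``"additive"`` takes
r_fast = D + D*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .config import BLOOD_T1_MS, BLOOD_T2_MS

# physiological fitting box, mm^2/s
D_BOUNDS = (0.0, 4e-3)
F_BOUNDS = (0.0, 1.0)
DSTAR_MAX = 1.0
#: b-values (s mm^-2) above this are treated as perfusion-free for the
#: segmented initialisation.
B_SPLIT = 175.0


def relaxation_weight(t1_ms, t2_ms, tr_ms, te_ms):
    """Steady-state compartment weight (1 - e^(-TR/T1)) * e^(-TE/T2)."""
    t1 = np.asarray(t1_ms, dtype=float)
    t2 = np.asarray(t2_ms, dtype=float)
    if np.any(t1 <= 0) or np.any(t2 <= 0):
        raise ValueError("relaxation times must be positive")
    return (1.0 - np.exp(-tr_ms / t1)) * np.exp(-te_ms / t2)


def ivim_signal(b, d, f, d_star, *, tissue_t1_ms, tissue_t2_ms,
                tr_ms=4000.0, te_ms=18.5, blood_t1_ms=BLOOD_T1_MS,
                blood_t2_ms=BLOOD_T2_MS, dstar_convention="total"):
    """Normalized IVIM signal S(b)/S(0) for one parameter set.

    ``b`` may be an array; the return has the same shape.  With
    ``dstar_convention="total"`` the fast compartment decays as
    exp(-b*D*); with ``"additive"`` as exp(-b*(D+D*)).
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    if not 0.0 <= f <= 1.0:
        raise ValueError("perfusion fraction f must lie in [0, 1]")
    w_b = relaxation_weight(blood_t1_ms, blood_t2_ms, tr_ms, te_ms)
    w_t = relaxation_weight(tissue_t1_ms, tissue_t2_ms, tr_ms, te_ms)
    if dstar_convention == "total":
        r_fast = d_star
    elif dstar_convention == "additive":
        r_fast = d + d_star
    else:
        raise ValueError("dstar_convention must be 'total' or 'additive'")
    num = f * w_b * np.exp(-b * r_fast) + (1.0 - f) * w_t * np.exp(-b * d)
    return num / (f * w_b + (1.0 - f) * w_t)


@dataclass
class IVIMVoxelFit:
    d: float
    f: float
    d_star: float
    rms_residual: float
    ok: bool


class IVIMModel:
    """Voxel-wise relaxation-compensated IVIM fit.

    Parameters
    ----------
    dwi : ndarray, shape (..., n_b)
        Diffusion-weighted signals (trace-combined; see Notes), last axis
        matching ``b_values``.
    b_values : array-like
        Diffusion weightings in s mm^-2; must include 0 and >=6 distinct
        values.
    tissue_t1_ms, tissue_t2_ms : scalar or ndarray broadcastable to voxels
        Tissue relaxation times per voxel (from acquired maps).
    tr_ms, te_ms : float
        Sequence timing, ms.
    blood_t1_ms, blood_t2_ms : float
        Blood relaxation constants, ms.
    dstar_convention : {"total", "additive"}
        Meaning of D* in the fast-decay exponent.

    Notes
    -----
    Acquisitions with several gradient directions/averages are expected to be
    combined to a single trace-weighted signal per b-value beforehand (see
    :func:`geometric_mean_directions`); the fit itself is isotropic.
    """

    def __init__(self, dwi, b_values, tissue_t1_ms, tissue_t2_ms, *,
                 tr_ms=4000.0, te_ms=18.5, blood_t1_ms=BLOOD_T1_MS,
                 blood_t2_ms=BLOOD_T2_MS, dstar_convention="total"):
        dwi = np.asarray(dwi, dtype=float)
        b = np.asarray(b_values, dtype=float)
        if b.ndim != 1 or dwi.shape[-1] != b.size:
            raise ValueError("last axis of dwi must match b_values")
        if np.unique(b).size < 6 or 0.0 not in b:
            raise ValueError("need >=6 distinct b-values including 0")
        self.dwi = dwi
        self.b = b
        self.shape = dwi.shape[:-1]
        self.t1 = np.broadcast_to(np.asarray(tissue_t1_ms, dtype=float),
                                  self.shape).reshape(-1)
        self.t2 = np.broadcast_to(np.asarray(tissue_t2_ms, dtype=float),
                                  self.shape).reshape(-1)
        self.tr_ms, self.te_ms = tr_ms, te_ms
        self.blood_t1_ms, self.blood_t2_ms = blood_t1_ms, blood_t2_ms
        if dstar_convention not in ("total", "additive"):
            raise ValueError("dstar_convention must be 'total' or 'additive'")
        self.dstar_convention = dstar_convention

    # -- internals --------------------------------------------------------
    def _fit_voxel(self, y, w_b, w_t):
        """Bounded NLLS for one voxel; y is S(b)/S(0)."""
        b = self.b
        # segmented initialisation: mono-exponential fit to the high-b tail
        hi = b > B_SPLIT
        yl = np.log(np.clip(y[hi], 1e-12, None))
        slope, icpt = np.polyfit(b[hi], yl, 1)
        d0 = float(np.clip(-slope, D_BOUNDS[0] + 1e-6, D_BOUNDS[1]))
        # intercept of the tail extrapolated to b=0 is (1-f_eff)
        f_eff0 = float(np.clip(1.0 - np.exp(icpt), 0.0, 0.95))
        # invert the relaxation weighting to a volume fraction
        f0 = f_eff0 * w_t / (w_b + f_eff0 * (w_t - w_b))
        f0 = float(np.clip(f0, 0.0, 1.0))
        extra0 = 10.0 * max(d0, 1e-4)  # fast rate well above D

        def resid(p):
            d, f, extra, s0 = p
            r_fast = d + extra
            num = (f * w_b * np.exp(-b * r_fast)
                   + (1.0 - f) * w_t * np.exp(-b * d))
            return s0 * num / (f * w_b + (1.0 - f) * w_t) - y

        # internal parameterisation r_fast = D + extra keeps D* >= D
        # feasible; the amplitude s0 is free so the noisy b=0 sample does
        # not propagate into the decay rates
        sol = least_squares(
            resid, x0=[d0, f0, extra0, 1.0],
            bounds=([D_BOUNDS[0], F_BOUNDS[0], 0.0, 0.1],
                    [D_BOUNDS[1], F_BOUNDS[1], DSTAR_MAX, 10.0]),
            method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=300)
        d, f, extra = sol.x[:3]
        if self.dstar_convention == "total":
            d_star = d + extra
        else:
            d_star = extra
        rms = float(np.sqrt(np.mean(sol.fun ** 2)))
        return IVIMVoxelFit(float(d), float(f), float(d_star), rms, True)

    def fit(self) -> "IVIMResults":
        y = self.dwi.reshape(-1, self.b.size)
        n = y.shape[0]
        w_b = relaxation_weight(self.blood_t1_ms, self.blood_t2_ms,
                                self.tr_ms, self.te_ms)
        w_ts = relaxation_weight(self.t1, self.t2, self.tr_ms, self.te_ms)
        d = np.full(n, np.nan)
        f = np.full(n, np.nan)
        ds = np.full(n, np.nan)
        rms = np.full(n, np.nan)
        ok = np.zeros(n, dtype=bool)
        i0 = int(np.argmin(self.b))
        for i in range(n):
            yi = y[i]
            if not np.all(np.isfinite(yi)) or yi[i0] <= 0:
                continue
            fit = self._fit_voxel(yi / yi[i0], w_b, float(w_ts[i]))
            d[i], f[i], ds[i] = fit.d, fit.f, fit.d_star
            rms[i], ok[i] = fit.rms_residual, fit.ok
        return IVIMResults(
            d=d.reshape(self.shape), f=f.reshape(self.shape),
            d_star=ds.reshape(self.shape), rms_residual=rms.reshape(self.shape),
            fitted=ok.reshape(self.shape), model=self)


class IVIMResults:
    """Parameter maps (D, f, D*) with diagnostics and median summaries."""

    def __init__(self, d, f, d_star, rms_residual, fitted, model):
        self.d = d
        self.f = f
        self.d_star = d_star
        self.rms_residual = rms_residual
        self.fitted = fitted
        self.model = model

    def median_params(self, selection=None) -> dict:
        """Median D, f, D* over ``selection`` (boolean mask or index array).

        The selection is meant to be the voxel set retained by the DCE
        goodness-of-fit filter, so diffusion and perfusion medians describe
        the same tissue.
        """
        if selection is None:
            selection = self.fitted
        sel = np.asarray(selection)
        if sel.dtype == bool:
            if not sel.any():
                raise ValueError("empty voxel selection")
            pick = sel & self.fitted
        else:
            if sel.size == 0:
                raise ValueError("empty voxel selection")
            pick = np.zeros_like(self.fitted, dtype=bool)
            pick.reshape(-1)[np.asarray(sel).reshape(-1)] = True
            pick &= self.fitted
        if not pick.any():
            raise ValueError("no fitted voxels in selection")
        return {
            "D": float(np.median(self.d[pick])),
            "f": float(np.median(self.f[pick])),
            "D_star": float(np.median(self.d_star[pick])),
            "n_voxels": int(pick.sum()),
        }

    def summary(self) -> str:
        med = self.median_params() if self.fitted.any() else None
        lines = ["IVIM fit", "========",
                 f"voxels fitted : {int(self.fitted.sum())} / {self.fitted.size}",
                 f"D* convention : {self.model.dstar_convention}"]
        if med:
            lines += [
                f"median D      : {med['D']:.4g} mm^2/s",
                f"median f      : {med['f']:.4g}",
                f"median D*     : {med['D_star']:.4g} mm^2/s",
            ]
        return "\n".join(lines)


def geometric_mean_directions(dwi_directions, axis=0):
    """Combine diffusion directions/averages by the geometric mean.

    Under the isotropy assumption the trace-weighted signal is the geometric
    mean over the three orthogonal gradient directions.
    """
    x = np.clip(np.asarray(dwi_directions, dtype=float), 1e-12, None)
    return np.exp(np.mean(np.log(x), axis=axis))


def fit_ivim(dwi, b_values, tissue_t1_ms, tissue_t2_ms, **kw) -> IVIMResults:
    """Functional wrapper around :class:`IVIMModel`."""
    return IVIMModel(dwi, b_values, tissue_t1_ms, tissue_t2_ms, **kw).fit()


def summarize_ivim(results: IVIMResults, selection) -> dict:
    """Median D, f, D* over the DCE-matched voxel selection."""
    return results.median_params(selection)
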