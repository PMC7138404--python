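"""Gamma capillary transit time (GCTT) tissue model and multi-bolus fitting.

The GCTT model describes the tissue contrast-agent concentration after a
bolus as the sum of an intravascular and an interstitial term.  Capillary
transit times are gamma-distributed with mean ``t_c`` and heterogeneity
index ``alpha_inv`` (shape ``alpha = 1/alpha_inv``, scale
``theta = t_c * alpha_inv``), giving the vascular residue function

    R_v(t) = 1 - CDF_gamma(t; alpha, theta),        R_v(0) = 1,
    integral of R_v over [0, inf) = t_c.

With plasma input C_a delayed by the arrival time ``t_d``, blood flow
``F = v_b / t_c`` and per-agent extraction fraction ``E_n``, the tissue
curve is

    C_t(t) = F * (C_a (x) R_v)(t)
             + sum_n E_n * F * (C_a,n (x) h (x) exp(-k_ep,n t))(t),

where ``h`` is the gamma transit-time density, ``k_ep,n = E_n*F/v_e`` and
``(x)`` is convolution on the acquisition grid.  Across the three boluses the
hemodynamic parameters (v_b, t_c, alpha_inv, v_e, t_d) are shared while each
agent keeps its own extraction fraction, so one joint nonlinear
least-squares problem per voxel estimates (v_b, t_c, alpha_inv, v_e, t_d,
E_1..E_n).  Derived quantities: F = v_b/t_c and Ktrans_n = E_n*F.

Limiting cases (used as numerical oracles): for alpha_inv -> 0 the residue
tends to the plug-flow boxcar 1{t < t_c}; for t_c -> 0 with F fixed the model
collapses onto the (extended) Tofts form
v_b*C_a + Ktrans * integral C_a(tau) exp(-k_ep (t-tau)) dtau.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special
from scipy.optimize import least_squares
from scipy.signal import fftconvolve

#: Fitting box: (v_b, t_c [s], alpha_inv, v_e, t_d [s], E_n).
DEFAULT_LOWER = {"v_b": 1e-4, "t_c": 0.5, "alpha_inv": 1e-3, "v_e": 0.0,
                 "t_d": 0.0, "e": 0.0}
DEFAULT_UPPER = {"v_b": 0.5, "t_c": 60.0, "alpha_inv": 5.0, "v_e": 0.7,
                 "t_d": 10.0, "e": 0.9}

#: Deterministic multistart list for the joint fit, spanning low/typical/high
#: perfusion regimes.
DEFAULT_STARTS = (
    {"v_b": 0.03, "t_c": 5.0, "alpha_inv": 0.5, "v_e": 0.2, "t_d": 1.0,
     "e": (0.05, 0.1, 0.3)},
    {"v_b": 0.10, "t_c": 15.0, "alpha_inv": 1.5, "v_e": 0.4, "t_d": 3.0,
     "e": (0.2, 0.3, 0.5)},
    {"v_b": 0.01, "t_c": 2.0, "alpha_inv": 0.2, "v_e": 0.1, "t_d": 0.5,
     "e": (0.02, 0.05, 0.1)},
)

_VE_EPS = 1e-9


@dataclass
class GCTTParams:
    """Kinetic parameter set of one voxel.

    v_b : fractional blood volume (unitless, in (0, 1))
    t_c : mean capillary transit time, s
    alpha_inv : vascular heterogeneity index (gamma CV^2), unitless > 0
    v_e : interstitial volume fraction, unitless in [0, 1)
    t_d : bolus arrival delay, s
    e : per-agent extraction fractions, each in [0, 1)
    """

    v_b: float
    t_c: float
    alpha_inv: float
    v_e: float
    t_d: float
    e: tuple = field(default_factory=tuple)

    def __post_init__(self):
        self.e = tuple(float(x) for x in np.atleast_1d(self.e))

    def validate(self):
        if not 0.0 <= self.v_b < 1.0:
            raise ValueError("v_b must lie in [0, 1)")
        if self.t_c <= 0:
            raise ValueError("t_c must be positive")
        if self.alpha_inv <= 0:
            raise ValueError("alpha_inv must be positive")
        if not 0.0 <= self.v_e < 1.0:
            raise ValueError("v_e must lie in [0, 1)")
        if self.v_b + self.v_e >= 1.0:
            raise ValueError("v_b + v_e must be < 1")
        if self.t_d < 0:
            raise ValueError("t_d must be >= 0")
        if any(not 0.0 <= x < 1.0 for x in self.e):
            raise ValueError("extraction fractions must lie in [0, 1)")

    # -- derived hemodynamics --------------------------------------------
    @property
    def flow(self) -> float:
        """Blood flow F = v_b / t_c, s^-1."""
        return self.v_b / self.t_c

    @property
    def ktrans(self) -> tuple:
        """Per-agent volume transfer constant Ktrans_n = E_n * F, s^-1."""
        return tuple(en * self.flow for en in self.e)

    @property
    def kep(self) -> tuple:
        """Per-agent interstitial washout rate E_n*F/v_e, s^-1 (inf if v_e=0)."""
        if self.v_e > _VE_EPS:
            return tuple(en * self.flow / self.v_e for en in self.e)
        return tuple(np.inf if en > 0 else 0.0 for en in self.e)

    def as_array(self) -> np.ndarray:
        return np.array([self.v_b, self.t_c, self.alpha_inv, self.v_e,
                         self.t_d, *self.e])

    @classmethod
    def from_array(cls, x, n_agents) -> "GCTTParams":
        x = np.asarray(x, dtype=float)
        return cls(v_b=x[0], t_c=x[1], alpha_inv=x[2], v_e=x[3], t_d=x[4],
                   e=tuple(x[5:5 + n_agents]))


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def gctt_residue(t, t_c, alpha_inv):
    """Vascular residue R_v(t) = 1 - CDF_gamma(t; 1/alpha_inv, t_c*alpha_inv)."""
    if alpha_inv <= 0:
        raise ValueError("alpha_inv must be positive")
    if t_c <= 0:
        raise ValueError("t_c must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    alpha = 1.0 / alpha_inv
    theta = t_c * alpha_inv
    return special.gammaincc(alpha, t / theta)


def _transit_density_cells(t, dt, t_c, alpha_inv):
    """Cell-averaged gamma transit-time density on the grid.

    Averaging the density over each grid cell (via CDF differences) keeps the
    discrete kernel mass exact and tames the t=0 singularity when alpha < 1.
    """
    alpha = 1.0 / alpha_inv
    theta = t_c * alpha_inv
    lo = np.clip(t - 0.5 * dt, 0.0, None) / theta
    hi = (t + 0.5 * dt) / theta
    return (special.gammainc(alpha, hi) - special.gammainc(alpha, lo)) / dt


def _conv_trap(a, b, dt):
    """Causal trapezoid-rule convolution of two sampled functions."""
    n = a.shape[-1]
    full = fftconvolve(a, b)[..., :n]
    return dt * (full - 0.5 * (a[..., :1] * b + b[..., :1] * a))


def _conv_rect(a, b, dt):
    """Rectangle-rule convolution; used with cell-averaged kernels."""
    n = a.shape[-1]
    return dt * fftconvolve(a, b)[..., :n]


def _shift_curve(t, curve, t_d):
    """Delay a sampled curve by t_d seconds with linear interpolation."""
    if t_d == 0.0:
        return curve
    return np.interp(t - t_d, t, curve, left=0.0, right=curve[-1])


def forward_model(time_grid, aifs, params: GCTTParams,
                  active_agents=None) -> np.ndarray:
    """Tissue concentration curve for per-agent plasma inputs.

    Parameters
    ----------
    time_grid : ndarray (n_time,)
        Uniform time grid, s.
    aifs : ndarray (n_agents, n_time)
        Per-agent plasma concentration curves (undelayed).
    params : GCTTParams
        Kinetic parameters; ``params.e`` must have one entry per agent.
    active_agents : sequence of int, optional
        Restrict the model to these agent indices (used by per-bolus fits).
    """
    t = np.asarray(time_grid, dtype=float)
    aifs = np.atleast_2d(np.asarray(aifs, dtype=float))
    if len(params.e) != aifs.shape[0]:
        raise ValueError("params.e must have one entry per AIF")
    dt = float(t[1] - t[0])
    if active_agents is None:
        active_agents = range(aifs.shape[0])

    shifted = [_shift_curve(t, aifs[n], params.t_d) for n in active_agents]
    flow = params.flow
    rv = gctt_residue(t - t[0], params.t_c, params.alpha_inv)
    ca_total = np.sum(shifted, axis=0)
    c_t = flow * _conv_trap(ca_total, rv, dt)

    kep = params.kep
    h = None
    for j, n in enumerate(active_agents):
        en = params.e[n]
        if en <= 0 or params.v_e <= _VE_EPS:
            continue
        if h is None:
            h = _transit_density_cells(t - t[0], dt, params.t_c,
                                       params.alpha_inv)
        washout = np.exp(-kep[n] * (t - t[0]))
        kernel = _conv_rect(h, washout, dt)
        c_t = c_t + en * flow * _conv_trap(shifted[j], kernel, dt)
    return c_t


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _pack_bounds(lower, upper, n_agents):
    lo = [lower["v_b"], lower["t_c"], lower["alpha_inv"], lower["v_e"],
          lower["t_d"]] + [lower["e"]] * n_agents
    hi = [upper["v_b"], upper["t_c"], upper["alpha_inv"], upper["v_e"],
          upper["t_d"]] + [upper["e"]] * n_agents
    return np.array(lo), np.array(hi)


def _pack_start(start, n_agents):
    e = np.atleast_1d(start["e"])[:n_agents]
    if e.size < n_agents:
        e = np.resize(e, n_agents)
    return np.array([start["v_b"], start["t_c"], start["alpha_inv"],
                     start["v_e"], start["t_d"], *e])


class GCTTModel:
    """Joint multi-bolus GCTT fit for a set of tissue curves.

    Parameters
    ----------
    tissue_curves : ndarray (n_voxels, n_time) or (n_time,)
        Contrast-agent concentration per voxel.
    time_grid : ndarray (n_time,)
        Uniform acquisition times, s.
    aifs : ndarray (n_agents, n_time)
        Per-agent arterial input curves on the same grid.
    agents : sequence of str, optional
        Agent names for reporting.
    bounds : (dict, dict), optional
        Lower/upper fitting box per parameter name.
    starts : sequence of dict, optional
        Deterministic multistart list (default three starts).
    """

    def __init__(self, tissue_curves, time_grid, aifs, agents=None,
                 bounds=None, starts=DEFAULT_STARTS, max_nfev=600):
        self.time_grid = np.asarray(time_grid, dtype=float)
        self.curves = np.atleast_2d(np.asarray(tissue_curves, dtype=float))
        self.aifs = np.atleast_2d(np.asarray(aifs, dtype=float))
        if self.curves.shape[1] != self.time_grid.size:
            raise ValueError("tissue curves and time grid differ in length")
        if self.aifs.shape[1] != self.time_grid.size:
            raise ValueError("AIFs and time grid differ in length")
        self.n_agents = self.aifs.shape[0]
        self.agents = (list(agents) if agents is not None
                       else [f"agent{i+1}" for i in range(self.n_agents)])
        lower, upper = bounds if bounds else (DEFAULT_LOWER, DEFAULT_UPPER)
        self.lower, self.upper = _pack_bounds(lower, upper, self.n_agents)
        self.starts = [_pack_start(s, self.n_agents) for s in starts]
        self.max_nfev = int(max_nfev)

    # -- single-voxel machinery ------------------------------------------
    def _predict(self, x):
        return forward_model(self.time_grid, self.aifs,
                             GCTTParams.from_array(x, self.n_agents))

    def _fit_voxel(self, y, starts=None):
        starts = starts if starts is not None else self.starts

        def resid(x):
            return self._predict(x) - y

        best = None
        for x0 in starts:
            x0c = np.clip(x0, self.lower, self.upper)
            try:
                sol = least_squares(resid, x0c,
                                    bounds=(self.lower, self.upper),
                                    method="trf", x_scale="jac",
                                    ftol=1e-10, xtol=1e-10, gtol=1e-10,
                                    max_nfev=self.max_nfev)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            return None
        return best

    def fit(self, progress=False) -> "GCTTResults":
        """Joint bounded NLLS per voxel; returns :class:`GCTTResults`."""
        n_vox = self.curves.shape[0]
        n_par = 5 + self.n_agents
        params = np.full((n_vox, n_par), np.nan)
        r2 = np.full(n_vox, -np.inf)
        converged = np.zeros(n_vox, dtype=bool)
        for i in range(n_vox):
            y = self.curves[i]
            if not np.all(np.isfinite(y)):
                continue
            sol = self._fit_voxel(y)
            if sol is None:
                continue
            params[i] = sol.x
            ss_res = float(np.sum(sol.fun ** 2))
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            r2[i] = 1.0 - ss_res / ss_tot if ss_tot > 0 else -np.inf
            converged[i] = True
        return GCTTResults(self, params, r2, converged)

    # -- per-bolus comparison protocol -----------------------------------
    def fit_per_bolus(self, pre_window_s=20.0):
        """Independent single-bolus fits of the shared parameters.

        For each agent the model is fitted on that bolus' time window alone
        (from ``pre_window_s`` before the agent's bolus arrival to the next
        arrival), with a constant offset absorbing residual signal from
        earlier boluses.  Returns an array of shape
        (n_voxels, n_agents, 6): (v_b, t_c, alpha_inv, v_e, t_d, E_n).
        This is the baseline against which the joint fit's precision gain is
        measured.
        """
        t = self.time_grid
        onsets = []
        for n in range(self.n_agents):
            nz = np.nonzero(self.aifs[n] > 0)[0]
            onsets.append(t[nz[0]] if nz.size else t[0])
        out = np.full((self.curves.shape[0], self.n_agents, 6), np.nan)
        for n in range(self.n_agents):
            t_lo = max(t[0], onsets[n] - pre_window_s)
            t_hi = onsets[n + 1] if n + 1 < self.n_agents else t[-1] + 1.0
            win = (t >= t_lo) & (t < t_hi)
            idx = [0, 1, 2, 3, 4, 5 + n, 5 + self.n_agents]
            lo = np.concatenate([self.lower[idx[:-1]], [-np.inf]])
            hi = np.concatenate([self.upper[idx[:-1]], [np.inf]])

            def predict(xs):
                full = np.zeros(5 + self.n_agents)
                full[:5] = xs[:5]
                full[5 + n] = xs[5]
                p = GCTTParams.from_array(full, self.n_agents)
                return (forward_model(t, self.aifs, p, active_agents=[n])[win]
                        + xs[6])

            for i in range(self.curves.shape[0]):
                y = self.curves[i][win]
                if not np.all(np.isfinite(y)):
                    continue
                best = None
                for s in self.starts:
                    x0 = np.clip(np.concatenate([s[idx[:-1]], [y[0]]]),
                                 lo, hi)
                    try:
                        sol = least_squares(
                            lambda xs: predict(xs) - y, x0,
                            bounds=(lo, hi), method="trf", x_scale="jac",
                            ftol=1e-8, xtol=1e-8, gtol=1e-8, max_nfev=400)
                    except Exception:
                        continue
                    if best is None or sol.cost < best.cost:
                        best = sol
                if best is not None:
                    out[i, n] = best.x[:6]
        return out


class GCTTResults:
    """Fitted parameter maps, derived hemodynamics and voxel filtering."""

    _SHARED = ("v_b", "t_c", "alpha_inv", "v_e", "t_d")

    def __init__(self, model, params, r2, converged):
        self.model = model
        self.params = params          # (n_vox, 5 + n_agents)
        self.r2 = r2
        self.converged = converged

    # -- parameter access -------------------------------------------------
    def __getitem__(self, name):
        if name in self._SHARED:
            return self.params[:, self._SHARED.index(name)]
        if name == "F":
            return self.params[:, 0] / self.params[:, 1]
        if name.startswith("E_"):
            return self.params[:, 5 + self.model.agents.index(name[2:])]
        if name.startswith("Ktrans_"):
            agent = name[len("Ktrans_"):]
            return self["E_" + agent] * self["F"]
        if name.startswith("kep_"):
            agent = name[len("kep_"):]
            with np.errstate(divide="ignore", invalid="ignore"):
                return self["Ktrans_" + agent] / self.params[:, 3]
        raise KeyError(name)

    def voxel_params(self, i) -> GCTTParams:
        return GCTTParams.from_array(self.params[i], self.model.n_agents)

    @property
    def parameter_names(self):
        names = list(self._SHARED) + [f"E_{a}" for a in self.model.agents]
        names += ["F"] + [f"Ktrans_{a}" for a in self.model.agents]
        return names

    # -- filtering and summaries ------------------------------------------
    def retained_mask(self, r2_threshold=0.9):
        """Voxels kept by the goodness-of-fit rule (remove r2 < threshold)."""
        return self.converged & (self.r2 >= r2_threshold)

    def filter_and_summarize(self, r2_threshold=0.9) -> dict:
        """Median parameters over retained voxels plus the perfused fraction.

        Voxels with r2 below the threshold are removed before taking
        medians; the retained fraction of all voxels is reported as the
        'perfused percentage'.  Raises if nothing is retained.
        """
        keep = self.retained_mask(r2_threshold)
        if not keep.any():
            raise ValueError("no voxels retained at r2 >= "
                             f"{r2_threshold}")
        med = {name: float(np.median(self[name][keep]))
               for name in self.parameter_names}
        med["r2"] = float(np.median(self.r2[keep]))
        return {
            "medians": med,
            "retained": keep,
            "n_retained": int(keep.sum()),
            "n_total": int(keep.size),
            "perfused_percentage": 100.0 * keep.mean(),
            "r2_threshold": r2_threshold,
        }

    def summary(self, r2_threshold=0.9) -> str:
        lines = ["GCTT joint multi-bolus fit", "=========================="]
        lines.append(f"voxels          : {self.params.shape[0]}")
        lines.append(f"agents          : {', '.join(self.model.agents)}")
        lines.append(f"converged       : {int(self.converged.sum())}")
        try:
            s = self.filter_and_summarize(r2_threshold)
        except ValueError:
            lines.append("no voxels retained by the r2 filter")
            return "\n".join(lines)
        lines.append(f"retained (r2>={r2_threshold:g}): {s['n_retained']} "
                     f"({s['perfused_percentage']:.1f}% perfused)")
        for k, v in s["medians"].items():
            lines.append(f"  median {k:<12s}: {v:.5g}")
        return "\n".join(lines)


def fit_multi_agent(tissue_curve, time_grid, aifs, **kw) -> GCTTResults:
    """Fit one or more tissue curves jointly over all boluses."""
    return GCTTModel(tissue_curve, time_grid, aifs, **kw).fit()


# ---------------------------------------------------------------------------
# signal <-> concentration (spoiled gradient echo)
# ---------------------------------------------------------------------------

def spgr_signal(r1_per_s, tr_ms, flip_angle_deg, m0=1.0):
    """Steady-state spoiled gradient-echo signal for longitudinal rate R1."""
    e1 = np.exp(-(tr_ms / 1000.0) * np.asarray(r1_per_s, dtype=float))
    th = np.deg2rad(flip_angle_deg)
    return m0 * np.sin(th) * (1.0 - e1) / (1.0 - np.cos(th) * e1)


def signal_to_concentration(signal, time_grid, baseline_window, t10_ms,
                            relaxivity_per_s_mm, tr_ms, flip_angle_deg):
    """Invert SPGR signal to contrast-agent concentration.

    The pre-injection baseline fixes the scaling (M0 sin(theta)); the signal
    ratio to baseline is then inverted for R1(t) and converted to
    concentration through C = (R1 - R1_0) / r1.  Samples outside the
    invertible signal range are returned as NaN and flagged.

    Returns ``(concentration_mM, valid_mask)``.
    """
    s = np.asarray(signal, dtype=float)
    t = np.asarray(time_grid, dtype=float)
    base = (t >= baseline_window[0]) & (t <= baseline_window[1])
    if not base.any():
        raise ValueError("baseline window contains no samples")
    r10 = 1000.0 / t10_ms  # s^-1
    th = np.deg2rad(flip_angle_deg)
    e10 = np.exp(-(tr_ms / 1000.0) * r10)
    s_base = s[..., base].mean(axis=-1, keepdims=True)
    # M0 sin(theta) from the baseline signal
    m0s = s_base * (1.0 - np.cos(th) * e10) / (1.0 - e10)
    x = s / m0s
    e1 = (1.0 - x) / (1.0 - x * np.cos(th))
    valid = (e1 > 0.0) & (e1 < 1.0)
    r1 = np.full_like(s, np.nan)
    r1[valid] = -np.log(e1[valid]) / (tr_ms / 1000.0)
    conc = (r1 - r10) / relaxivity_per_s_mm
    return conc, valid
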