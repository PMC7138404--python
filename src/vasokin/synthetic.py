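"""Synthetic phantoms with known ground truth for every pipeline stage.

Animal data for this protocol are not publicly deposited, so validation runs
on digital phantoms that emulate the acquisition: a three-bolus arterial
input (G5 dendrimer, G2 dendrimer, Gd-DOTA in one session), tissue uptake
curves following the GCTT forward model, diffusion signals following the
relaxation-weighted IVIM equation at the protocol's 13 b-values,
mono-exponential T2 decay over the 8-400 ms echo train, and rasterised 3D
tube networks at 28 um isotropic voxels standing in for fluorescent vascular
casts.  Every generated dataset is paired with a :class:`PhantomTruth`
holding the exact generating parameters, and is bit-reproducible from
(truth, config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage

from .aif import BolusShape, generate_aif, gamma_variate  # noqa: F401
from .config import AcquisitionConfig
from . import gctt, ivim


@dataclass
class PhantomTruth:
    """Ground truth emitted alongside every synthetic dataset."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def to_json(self, path) -> None:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if hasattr(o, "__dict__"):
                return asdict(o)
            raise TypeError(type(o))
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=default)


# ---------------------------------------------------------------------------
# DCE
# ---------------------------------------------------------------------------

def generate_dce_phantom(truth_params: Sequence[gctt.GCTTParams],
                         aifs, config: AcquisitionConfig, *,
                         noise_sd: float | None = None,
                         noise_ref: str = "peak",
                         rng: np.random.Generator | None = None):
    """Tissue concentration curves obeying the GCTT forward model.

    Parameters
    ----------
    truth_params : sequence of GCTTParams
        One parameter set per voxel.
    aifs : ndarray (n_agents, n_time)
        Per-agent arterial input on ``config.time_grid``.
    noise_sd : float, optional
        Gaussian noise SD; by default ``config.noise_sd``.  Interpreted as a
        fraction of each voxel's peak concentration when ``noise_ref`` is
        ``"peak"`` (so SNR = 1/noise_sd at the curve maximum), or as an
        absolute concentration when ``"absolute"``.

    Returns ``(curves, truth)`` with ``curves`` of shape (n_voxels, n_time).
    """
    if noise_sd is None:
        noise_sd = config.noise_sd
    aifs = np.atleast_2d(np.asarray(aifs, dtype=float))
    curves = np.empty((len(truth_params), config.time_grid.size))
    for i, p in enumerate(truth_params):
        p.validate()
        if len(p.e) != aifs.shape[0]:
            raise ValueError("truth params and AIF agent count mismatch")
        curves[i] = gctt.forward_model(config.time_grid, aifs, p)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        if noise_ref == "peak":
            scale = noise_sd * np.abs(curves).max(axis=1, keepdims=True)
        elif noise_ref == "absolute":
            scale = noise_sd
        else:
            raise ValueError("noise_ref must be 'peak' or 'absolute'")
        curves = curves + rng.standard_normal(curves.shape) * scale
    truth = PhantomTruth(
        kind="dce_gctt",
        params={"voxels": [asdict(p) for p in truth_params],
                "noise_sd": noise_sd, "noise_ref": noise_ref},
        seed=config.seed)
    return curves, truth


# ---------------------------------------------------------------------------
# IVIM
# ---------------------------------------------------------------------------

def generate_ivim_phantom(d, f, d_star, tissue_t1_ms, tissue_t2_ms,
                          config: AcquisitionConfig, *, s0=1.0,
                          noise_sd: float | None = None,
                          noise_model: str = "gaussian",
                          dstar_convention: str = "total",
                          n_directions: int = 3, n_averages: int = 2,
                          rng: np.random.Generator | None = None):
    """Diffusion-weighted signals obeying the relaxation-weighted IVIM model.

    Parameter arrays are broadcast against each other to a common voxel
    shape; the output has one extra trailing axis over ``config.b_values``.
    Noise is scaled by the per-voxel b=0 signal, so SNR = 1/noise_sd per
    acquired image.  Emulating the protocol's 3 orthogonal gradient
    directions with 2 signal averages, ``n_directions * n_averages``
    independently noisy replicates are generated (the tissue is isotropic,
    so their noiseless signals coincide) and combined by the geometric mean,
    as the fitting stage prescribes for trace-weighted signals.  Set both to
    1 for single-shot data.
    """
    if noise_sd is None:
        noise_sd = config.noise_sd
    d, f, d_star, t1, t2, s0 = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in
          (d, f, d_star, tissue_t1_ms, tissue_t2_ms, s0)))
    b = np.asarray(config.b_values, dtype=float)
    shape = d.shape
    flat = [a.reshape(-1) for a in (d, f, d_star, t1, t2, s0)]
    sig = np.empty((flat[0].size, b.size))
    for i in range(flat[0].size):
        sig[i] = flat[5][i] * ivim.ivim_signal(
            b, flat[0][i], flat[1][i], flat[2][i],
            tissue_t1_ms=flat[3][i], tissue_t2_ms=flat[4][i],
            tr_ms=config.tr_ms, te_ms=config.te_ms,
            dstar_convention=dstar_convention)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        n_rep = int(n_directions) * int(n_averages)
        scale = noise_sd * sig[None, :, :1]
        reps = np.broadcast_to(sig, (n_rep,) + sig.shape)
        if noise_model == "gaussian":
            reps = reps + rng.standard_normal(reps.shape) * scale
        elif noise_model == "rician":
            reps = np.hypot(reps + rng.standard_normal(reps.shape) * scale,
                            rng.standard_normal(reps.shape) * scale)
        else:
            raise ValueError("noise_model must be 'gaussian' or 'rician'")
        sig = ivim.geometric_mean_directions(reps, axis=0)
    truth = PhantomTruth(
        kind="ivim",
        params={"D": d, "f": f, "D_star": d_star,
                "tissue_t1_ms": t1, "tissue_t2_ms": t2,
                "noise_sd": noise_sd, "noise_model": noise_model,
                "dstar_convention": dstar_convention},
        seed=config.seed)
    return sig.reshape(shape + (b.size,)), truth


# ---------------------------------------------------------------------------
# T2
# ---------------------------------------------------------------------------

def generate_t2_phantom(t2_ms, s0, config: AcquisitionConfig, *,
                        noise_sd: float | None = None,
                        noise_model: str = "gaussian",
                        rng: np.random.Generator | None = None):
    """Multi-echo magnitude volume with mono-exponential decay.

    ``noise_sd`` is a fraction of each voxel's S0; ``noise_model`` may be
    ``"gaussian"`` or ``"rician"`` (magnitude of complex Gaussian noise,
    which biases late low-signal echoes upward, as in magnitude MRI).
    """
    if noise_sd is None:
        noise_sd = config.noise_sd
    t2_ms, s0 = np.broadcast_arrays(np.asarray(t2_ms, dtype=float),
                                    np.asarray(s0, dtype=float))
    te = np.asarray(config.echo_times, dtype=float)
    sig = s0[..., None] * np.exp(-te / t2_ms[..., None])
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        scale = noise_sd * s0[..., None]
        if noise_model == "gaussian":
            sig = sig + rng.standard_normal(sig.shape) * scale
        elif noise_model == "rician":
            sig = np.hypot(sig + rng.standard_normal(sig.shape) * scale,
                           rng.standard_normal(sig.shape) * scale)
        else:
            raise ValueError("noise_model must be 'gaussian' or 'rician'")
    truth = PhantomTruth(kind="t2",
                         params={"T2_ms": t2_ms, "S0": s0,
                                 "noise_sd": noise_sd,
                                 "noise_model": noise_model},
                         seed=config.seed)
    return sig, truth


# ---------------------------------------------------------------------------
# vascular cast
# ---------------------------------------------------------------------------

@dataclass
class Tube:
    """Straight cylindrical vessel segment: endpoints and radius in um."""

    start: tuple
    end: tuple
    radius_um: float

    @property
    def length_um(self) -> float:
        return float(np.linalg.norm(np.subtract(self.end, self.start)))

    @property
    def volume_um3(self) -> float:
        return float(np.pi * self.radius_um ** 2 * self.length_um)


def generate_cast_phantom(tubes: Sequence[Tube], shape, *,
                          voxel_size_um: float = 28.0,
                          foreground: float = 200.0,
                          blur_sigma_vox: float = 0.0,
                          background_noise_sd: float = 0.0,
                          tumor_mask=None, seed: int = 0):
    """Rasterise a tube network into a 3D fluorescence stack.

    A voxel is foreground iff its centre lies within ``radius_um`` of a tube
    axis.  Coordinates are in micrometres with the centre of voxel
    (i, j, k) at ((i+0.5), (j+0.5), (k+0.5)) * voxel_size_um; voxels are
    isotropic (28 um by default, matching the resampled episcopic stacks).
    Optional Gaussian blur and background noise emulate imaging effects.

    The ground truth records the analytic tube volume (sum of pi*r^2*L,
    junction overlap ignored) and the segment count under the convention
    that each tube primitive is one vessel segment (arms of a junction count
    separately).

    Returns ``(stack, truth)``; ``truth.params['tumor_mask_volume_um3']``
    uses the supplied mask or the full field of view.
    """
    shape = tuple(int(s) for s in shape)
    v = float(voxel_size_um)
    sub_resolution = [t for t in tubes if t.radius_um < v]
    if sub_resolution:
        import warnings
        warnings.warn(f"{len(sub_resolution)} tube(s) thinner than one voxel "
                      "will rasterise poorly", stacklevel=2)
    vessel = np.zeros(shape, dtype=bool)
    centers = [(np.arange(s) + 0.5) * v for s in shape]
    for tube in tubes:
        p0 = np.asarray(tube.start, dtype=float)
        p1 = np.asarray(tube.end, dtype=float)
        r = tube.radius_um
        lo = np.minimum(p0, p1) - r - v
        hi = np.maximum(p0, p1) + r + v
        sl = []
        for ax in range(3):
            i0 = int(np.clip(np.floor(lo[ax] / v), 0, shape[ax]))
            i1 = int(np.clip(np.ceil(hi[ax] / v) + 1, 0, shape[ax]))
            sl.append(slice(i0, i1))
        if any(s.start >= s.stop for s in sl):
            continue
        xx, yy, zz = np.meshgrid(*(centers[ax][sl[ax]] for ax in range(3)),
                                 indexing="ij")
        pts = np.stack([xx, yy, zz], axis=-1)
        ab = p1 - p0
        denom = float(ab @ ab)
        if denom == 0.0:
            dist = np.linalg.norm(pts - p0, axis=-1)
        else:
            tpar = np.clip(((pts - p0) @ ab) / denom, 0.0, 1.0)
            proj = p0 + tpar[..., None] * ab
            dist = np.linalg.norm(pts - proj, axis=-1)
        vessel[sl[0], sl[1], sl[2]] |= dist <= r

    stack = np.where(vessel, foreground, 0.0)
    if blur_sigma_vox > 0:
        stack = ndimage.gaussian_filter(stack, blur_sigma_vox)
    if background_noise_sd > 0:
        rng = np.random.default_rng(seed)
        stack = np.clip(stack + rng.standard_normal(shape)
                        * background_noise_sd, 0.0, None)
    if tumor_mask is None:
        tumor_mask = np.ones(shape, dtype=bool)
    mask_vol = float(tumor_mask.sum()) * v ** 3
    vessel_vol = float(sum(t.volume_um3 for t in tubes))
    if vessel_vol > mask_vol:
        raise ValueError("true vessel volume exceeds tumor-mask volume")
    truth = PhantomTruth(
        kind="cast",
        params={
            "tubes": [asdict(t) for t in tubes],
            "n_segments": len(tubes),
            "vessel_volume_um3": vessel_vol,
            "tumor_mask_volume_um3": mask_vol,
            "rasterized_vessel_voxels": int(vessel.sum()),
            "voxel_size_um": v,
        },
        seed=seed)
    return stack, truth


# ---------------------------------------------------------------------------
# QC cohort
# ---------------------------------------------------------------------------

def generate_qc_cohort(n_specimens=10, n_incomplete=3, *,
                       filling_efficiency=0.2, seed=0):
    """Synthetic cohort for the cast/MRI concordance check.

    Each specimen gets an MRI perfused percentage and a cast-derived
    vascular volume fraction proportional to it; in ``n_incomplete``
    specimens the cast fraction is scaled down by ``filling_efficiency`` to
    emulate incomplete resin filling.  Returns a dict of arrays including
    the ground-truth incomplete flags.
    """
    rng = np.random.default_rng(seed)
    mri_pf = rng.uniform(50.0, 90.0, n_specimens)           # percent
    ratio = rng.uniform(0.025, 0.035, n_specimens)          # cast VVF per PF
    vvf = mri_pf * ratio                                    # percent scale
    incomplete = np.zeros(n_specimens, dtype=bool)
    incomplete[rng.choice(n_specimens, n_incomplete, replace=False)] = True
    vvf = np.where(incomplete, vvf * filling_efficiency, vvf)
    return {
        "specimen": np.array([f"S{i:02d}" for i in range(n_specimens)]),
        "mri_perfused_pct": mri_pf,
        "cast_vvf": vvf,
        "incomplete": incomplete,
    }
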