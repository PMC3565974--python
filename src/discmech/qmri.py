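"""Quantitative-MRI parameter estimation: T1, T2, MTR, ADC and FA.

The forward signal models defined here are the single source of truth for
both simulation (:mod:`discmech.synthetic`) and fitting, so noiseless
round trips are exact up to optimizer tolerance.

Signal models
-------------
Inversion-recovery TSE (T1)::

    SI(TI) = S0 * (1 - (1 - cos a) * E_TI * (1 - E_TW * f(N) * (1 - E_TE/2)^2))

with ``E_x = exp(-x/T1)``, ``f(N) = 1 - E_TE^N`` and the recovery delay
``TW = TR - TI - N*TE`` clamped at zero.  Multi-echo spin echo (T2)::

    SI(TE) = SI(0) * exp(-TE/T2)

Magnetization transfer ratio ``MTR = (M0 - MS)/M0``, and single-shell
diffusion ``SI(g) = SI(b=0) * exp(-b g^T D g)`` with mean diffusivity
``ADC = tr(D)/3`` and fractional anisotropy FA from the eigenvalues of D.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .acquisition import B0_INDEX, AcquisitionProtocol, SignalSeries

__all__ = [
    "ir_signal",
    "echo_signal",
    "dwi_signal",
    "fit_t1",
    "fit_t2",
    "compute_mtr",
    "fit_diffusion_tensor",
    "tensor_metrics",
    "fit_voxelwise",
    "roi_aggregate",
    "DiffusionFit",
    "QmriParams",
    "FitDiagnostics",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------

def ir_signal(ti, t1: float, s0: float, protocol: AcquisitionProtocol,
              magnitude: bool = False) -> np.ndarray:
    """Signed (or magnitude) IR-TSE signal at inversion times ``ti`` (ms)."""
    if t1 <= 0:
        raise ValueError("T1 must be positive")
    ti = np.asarray(ti, float)
    te, n, tr = protocol.te_readout, protocol.n_refocus, protocol.tr
    tw = np.maximum(tr - ti - n * te, 0.0)
    if np.all(tr - ti - n * te < 0):
        warnings.warn("recovery delay TW clamped at 0 for every TI; "
                      "protocol is infeasible for this TR", stacklevel=2)
    e_ti = np.exp(-ti / t1)
    e_tw = np.exp(-tw / t1)
    e_te = np.exp(-te / t1)
    f_n = 1.0 - e_te**n
    e_half = np.exp(-0.5 * te / t1)
    alpha = np.deg2rad(protocol.flip_alpha)
    si = s0 * (1.0 - (1.0 - np.cos(alpha)) * e_ti
               * (1.0 - e_tw * f_n * (1.0 - e_half) ** 2))
    return np.abs(si) if magnitude else si


def echo_signal(te, t2: float, si0: float) -> np.ndarray:
    """Mono-exponential T2 decay at echo times ``te`` (ms)."""
    if t2 <= 0:
        raise ValueError("T2 must be positive")
    return si0 * np.exp(-np.asarray(te, float) / t2)


def dwi_signal(dirs: np.ndarray, tensor: np.ndarray, si0: float,
               b_value: float) -> np.ndarray:
    """Diffusion-attenuated signal for unit directions ``dirs`` (rows)."""
    dirs = np.atleast_2d(np.asarray(dirs, float))
    quad = np.einsum("ij,jk,ik->i", dirs, tensor, dirs)
    return si0 * np.exp(-b_value * quad)


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class FitDiagnostics:
    converged: bool
    residual_norm: float
    message: str = ""


@dataclass
class DiffusionFit:
    """Fitted diffusion tensor with eigen-decomposition."""
    tensor: np.ndarray
    eigenvalues: np.ndarray  # sorted descending, mm^2/s
    s0_fit: float
    diagnostics: FitDiagnostics | None = None


@dataclass
class QmriParams:
    """The five imaging biomarkers for one sample/region (internal units:
    ms, fractions, mm^2/s)."""
    t1: float
    t2: float
    mtr: float
    adc: float
    fa: float
    fit_diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# fitters
# ---------------------------------------------------------------------------

def _profiled_s0(model_unit: np.ndarray, y: np.ndarray) -> float:
    """Least-squares amplitude for a model linear in S0."""
    denom = model_unit @ model_unit
    if denom == 0:
        return 0.0
    return float((model_unit @ y) / denom)


def fit_t1(series: SignalSeries, protocol: AcquisitionProtocol | None = None,
           magnitude: bool = False):
    """Nonlinear least-squares T1 from an inversion-recovery series.

    The amplitude S0 enters linearly and is profiled out, leaving a 1-D
    problem in T1 that is initialized by a coarse grid over [10, 5000] ms
    and polished by bounded minimization.

    Returns ``(t1, s0, diagnostics)``.
    """
    if series.kind != "IR":
        raise ValueError("fit_t1 expects an IR series")
    protocol = protocol or series.protocol
    if protocol is None:
        raise ValueError("an acquisition protocol is required")
    ti, y = series.x, series.y
    if ti.size < 3:
        raise ValueError("at least 3 inversion times are required")

    if np.ptp(y) <= 1e-12 * max(1.0, np.abs(y).max()):
        diag = FitDiagnostics(False, np.nan, "series has no TI dependence")
        return np.nan, np.nan, diag

    def sse(t1: float) -> float:
        m = ir_signal(ti, t1, 1.0, protocol, magnitude=magnitude)
        s0 = _profiled_s0(m, y)
        r = y - s0 * m
        return float(r @ r)

    grid = np.geomspace(10.0, 5000.0, 200)
    costs = np.array([sse(t1) for t1 in grid])
    k = int(np.argmin(costs))
    lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, grid.size - 1)]
    res = optimize.minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    t1 = float(res.x)
    m = ir_signal(ti, t1, 1.0, protocol, magnitude=magnitude)
    s0 = _profiled_s0(m, y)
    rn = float(np.linalg.norm(y - s0 * m))
    converged = bool(res.success) and not np.isclose(t1, grid[0]) \
        and not np.isclose(t1, grid[-1])
    diag = FitDiagnostics(converged, rn,
                          "" if converged else "T1 fit at grid boundary or failed")
    if not converged:
        log.warning("fit_t1 did not converge: %s", diag.message)
    return t1, s0, diag


def fit_t2(series: SignalSeries):
    """Log-linear T2 fit: regress ln(SI) on TE; T2 = -1/slope.

    Non-positive intensities are excluded with a warning.  Returns
    ``(t2, si0, diagnostics)``.
    """
    if series.kind != "ECHO":
        raise ValueError("fit_t2 expects an ECHO series")
    te, y = series.x, series.y
    keep = y > 0
    if keep.sum() < y.size:
        warnings.warn(f"excluding {int((~keep).sum())} non-positive intensities "
                      "from T2 fit", stacklevel=2)
    te, y = te[keep], y[keep]
    if te.size < 2:
        raise ValueError("need at least 2 positive-intensity echoes")
    slope, intercept = np.polyfit(te, np.log(y), 1)
    si0 = float(np.exp(intercept))
    rn = float(np.linalg.norm(np.log(y) - (slope * te + intercept)))
    if slope >= 0 or np.ptp(np.log(y)) < 1e-12:
        diag = FitDiagnostics(False, rn, "non-decaying series (slope >= 0)")
        log.warning("fit_t2: %s", diag.message)
        return np.nan, si0, diag
    return float(-1.0 / slope), si0, FitDiagnostics(True, rn)


def compute_mtr(m0: float, ms: float) -> float:
    """Magnetization transfer ratio (M0 - MS)/M0, as a fraction."""
    if m0 <= 0:
        raise ValueError("M0 must be positive")
    return (m0 - ms) / m0


def _dwi_design(dirs: np.ndarray, b_value: float) -> np.ndarray:
    g = np.atleast_2d(dirs)
    return b_value * np.column_stack([
        g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
        2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
    ])


def _tensor_from_packed(d: np.ndarray) -> np.ndarray:
    dxx, dyy, dzz, dxy, dxz, dyz = d
    return np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])


def fit_diffusion_tensor(series: SignalSeries,
                         protocol: AcquisitionProtocol | None = None) -> DiffusionFit:
    """Log-linear least-squares diffusion-tensor fit (single b-shell).

    For every diffusion-weighted sample, ``ln(SI/SI0) = -b g^T D g`` is a
    linear equation in the six unique tensor entries; they are solved by
    ordinary least squares with design rows
    ``b*(gx^2, gy^2, gz^2, 2gxgy, 2gxgz, 2gygz)``.
    """
    if series.kind != "DWI":
        raise ValueError("fit_diffusion_tensor expects a DWI series")
    protocol = protocol or series.protocol
    if protocol is None:
        raise ValueError("an acquisition protocol is required")
    idx = series.x.astype(int)
    y = series.y
    b0_mask = idx == B0_INDEX
    if not np.any(b0_mask):
        raise ValueError("a b=0 sample is required")
    si0 = float(np.mean(y[b0_mask]))
    dw_idx, dw_y = idx[~b0_mask], y[~b0_mask]
    keep = dw_y > 0
    if keep.sum() < dw_y.size:
        warnings.warn(f"excluding {int((~keep).sum())} non-positive DW signals",
                      stacklevel=2)
        dw_idx, dw_y = dw_idx[keep], dw_y[keep]
    if dw_idx.size < 6:
        raise ValueError("at least 6 diffusion-weighted samples are required")
    dirs = protocol.gradient_dirs[dw_idx]
    design = _dwi_design(dirs, protocol.b_value)
    if np.linalg.matrix_rank(design) < 6:
        raise ValueError("gradient design is rank-deficient; tensor unidentifiable")
    target = -np.log(dw_y / si0)
    packed, res, *_ = np.linalg.lstsq(design, target, rcond=None)
    tensor = _tensor_from_packed(packed)
    evals = np.linalg.eigvalsh(tensor)[::-1]
    rn = float(np.sqrt(res[0])) if res.size else 0.0
    return DiffusionFit(tensor=tensor, eigenvalues=evals, s0_fit=si0,
                        diagnostics=FitDiagnostics(True, rn))


def tensor_metrics(fit: DiffusionFit | np.ndarray):
    """ADC (mean diffusivity) and FA from tensor eigenvalues.

    FA is clipped to [0, 1]; clip events (possible with noisy, negative
    eigenvalues) are logged.  Returns ``(adc, fa)``.
    """
    ev = fit.eigenvalues if isinstance(fit, DiffusionFit) else np.asarray(fit, float)
    if not np.all(np.isfinite(ev)):
        raise ValueError("eigenvalues must be finite")
    if np.all(ev == 0):
        raise ValueError("FA undefined for an all-zero tensor")
    adc = float(np.mean(ev))
    num = np.sqrt(3.0 * np.sum((ev - adc) ** 2))
    den = np.sqrt(2.0 * np.sum(ev**2))
    fa = float(num / den)
    if fa > 1.0:
        log.info("FA=%.6f clipped to 1", fa)
        fa = 1.0
    return adc, fa


# ---------------------------------------------------------------------------
# voxelwise maps and ROI aggregation
# ---------------------------------------------------------------------------

def fit_voxelwise(phantom, magnitude_ir: bool = False) -> dict[str, np.ndarray]:
    """Apply the four fitters at every labelled voxel of a phantom.

    ``phantom`` is a :class:`discmech.synthetic.PhantomImage` (or anything
    with the same ``stacks``/``roi_labels``/``protocol`` attributes).
    Background voxels are skipped.  Returns a dict of parameter maps
    (``t1, t2, mtr, adc, fa``) plus a boolean ``converged`` map.
    """
    labels = phantom.roi_labels
    shape = labels.shape
    maps = {k: np.full(shape, np.nan) for k in ("t1", "t2", "mtr", "adc", "fa")}
    conv = np.zeros(shape, bool)
    proto = phantom.protocol
    for vox in np.ndindex(shape):
        if labels[vox] == "background":
            continue
        ok = True
        ir = SignalSeries("IR", np.array(proto.inversion_times),
                          phantom.stacks["ir"][vox], proto)
        t1, _, d1 = fit_t1(ir, proto, magnitude=magnitude_ir)
        ok &= d1.converged
        echo = SignalSeries("ECHO", np.array(proto.echo_times_t2),
                            phantom.stacks["echo"][vox], proto)
        t2, _, d2 = fit_t2(echo)
        ok &= d2.converged
        m0, ms = phantom.stacks["mt"][vox]
        mtr = compute_mtr(m0, ms)
        ndir = proto.gradient_dirs.shape[0]
        xdwi = np.concatenate([[B0_INDEX], np.arange(ndir)])
        dwi = SignalSeries("DWI", xdwi, phantom.stacks["dwi"][vox], proto)
        try:
            dfit = fit_diffusion_tensor(dwi, proto)
            adc, fa = tensor_metrics(dfit)
        except ValueError:
            adc, fa, ok = np.nan, np.nan, False
        maps["t1"][vox], maps["t2"][vox], maps["mtr"][vox] = t1, t2, mtr
        maps["adc"][vox], maps["fa"][vox] = adc, fa
        conv[vox] = ok
    maps["converged"] = conv
    return maps


def roi_aggregate(maps: dict[str, np.ndarray], roi_labels: np.ndarray,
                  rois: tuple[str, ...] = ("NP", "AF")) -> dict[str, dict]:
    """Per-ROI mean/SD of each parameter map over converged voxels.

    Returns ``{roi: {param: (mean, sd), ..., "excluded_fraction": f}}``.
    """
    conv = maps.get("converged")
    out: dict[str, dict] = {}
    for roi in rois:
        mask = roi_labels == roi
        if not np.any(mask):
            raise ValueError(f"ROI {roi!r} is empty")
        good = mask & conv if conv is not None else mask
        if not np.any(good):
            raise ValueError(f"ROI {roi!r} has no converged voxels")
        stats: dict = {}
        for k in ("t1", "t2", "mtr", "adc", "fa"):
            vals = maps[k][good]
            stats[k] = (float(np.mean(vals)),
                        float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0)
        stats["excluded_fraction"] = 1.0 - good.sum() / mask.sum()
        out[roi] = stats
    return out
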