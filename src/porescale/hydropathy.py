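"""Hydropathic moments and their decomposition around a pore point.

The hydropathic moment of order j collects noise-perturbed per-atom weights
w_{a,ι} = w_a + ι, ι ~ N(0, σ_ι), over the open ball B(p, l):

    even j = 2k:   h_j(l) = Σ_{r_a<l} r_a^j · w_{a,ι}            (scalar)
    odd  j = 2k+1: h⃗_j(l) = Σ_{r_a<l} r_a^{j−1} · r⃗_a · w_{a,ι}  (vector)

Odd orders are resolved into a membrane-perpendicular component (along e⊥,
the z axis) and an in-plane magnitude; j = 1 is the classic hydropathic
dipole.  Even orders probe rotational ("inertia") constraints, odd orders
translational ("conductivity") constraints.

The ± decomposition splits each moment into its hydrophilic-only and
hydrophobic-only contributions; their log-log slopes ψ_±, the imbalance
Δψ = ψ_+ − ψ_−, the interfacial coupling strength I = Δψ/l and the log
composite susceptibility ϕ = ln(−h_+/h_−) are the per-scale features used
for mutation-hotspot classification.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .packing_model import PackingFit, epsilon
from .pore_geometry import ScaleGrid
from .structure_io import MolecularStructure

__all__ = [
    "MomentProfile", "MomentSet", "ScalingExponents", "EnvelopeFit",
    "moments", "decompose", "log_slopes", "coupling_and_susceptibility",
    "scaling_exponents", "fit_wavepacket_envelope",
]

log = logging.getLogger(__name__)


def _l_values(grid) -> np.ndarray:
    return grid.l_values if isinstance(grid, ScaleGrid) else \
        np.asarray(grid, dtype=float)


@dataclass
class MomentProfile:
    """h_j traces on the scale grid for one pore point and order j.

    For odd j, ``trace`` is the membrane-perpendicular component h_j,⊥ and
    ``trace_para`` the in-plane magnitude h_j,∥.  ``philic_trace`` and
    ``phobic_trace`` are the single-sign-subset sums that feed the ±
    decomposition; ``plus_trace``/``minus_trace`` are set by
    :func:`decompose` and ψ/I/ϕ by the slope and coupling stages.
    """
    order: int
    parity: str                      # "even" | "odd"
    trace: np.ndarray
    philic_trace: np.ndarray
    phobic_trace: np.ndarray
    trace_para: np.ndarray | None = None
    noise_sigma: float = 0.0
    # decomposition results
    plus_trace: np.ndarray | None = None
    minus_trace: np.ndarray | None = None
    l_cutoff: float = np.nan
    case_label: str = ""             # "A" | "B" | ""
    decomposable: bool = False
    valid: np.ndarray | None = None  # grid mask l > l_cutoff
    # slope / coupling results
    psi_plus: np.ndarray | None = None
    psi_minus: np.ndarray | None = None
    delta_psi: np.ndarray | None = None
    coupling: np.ndarray | None = None        # I_j, Å⁻¹
    log_susceptibility: np.ndarray | None = None  # ϕ_j
    susceptibility: np.ndarray | None = None      # χ_j


@dataclass
class MomentSet:
    """All moment profiles of one pore point plus shared ball occupancies."""
    pore_point: np.ndarray
    l_values: np.ndarray
    counts: np.ndarray
    counts_philic: np.ndarray
    counts_phobic: np.ndarray
    profiles: dict                   # order j -> MomentProfile

    def __getitem__(self, j: int) -> MomentProfile:
        return self.profiles[j]


def _prefix_eval(sorted_radii, contrib, l_values):
    """Evaluate Σ_{r_a<l} contrib over a radius-sorted prefix at each l."""
    prefix = np.concatenate([[0.0], np.cumsum(contrib)])
    idx = np.searchsorted(sorted_radii, l_values, side="left")
    return prefix[idx]


def moments(structure: MolecularStructure, p, grid, orders_k=range(6),
            sigma_iota: float = 1e-3, seed: int = 0) -> MomentSet:
    """Compute h_j traces for j = 2k and 2k+1, k in ``orders_k``.

    Noise ι is drawn once per atom per run from N(0, σ_ι) with the given
    seed.  Empty balls yield zeros.  Weights must be assigned.
    """
    if np.isnan(structure.weight).any():
        raise ValueError("weights not assigned; run assign_hydropathy first")
    p = np.asarray(p, dtype=float)
    l_values = _l_values(grid)
    rel = structure.coords - p
    r = np.linalg.norm(rel, axis=1)
    order = np.argsort(r, kind="stable")
    r_s, rel_s = r[order], rel[order]
    w_base = structure.weight[order]
    rng = np.random.default_rng(seed)
    iota = rng.normal(0.0, sigma_iota, len(r)) if sigma_iota > 0 else 0.0
    w = w_base + iota
    philic = w_base > 0
    phobic = ~philic

    idx_all = np.searchsorted(r_s, l_values, side="left")
    counts = idx_all.astype(int)
    counts_phi = _prefix_eval(r_s, philic.astype(float), l_values).astype(int)
    counts_pho = counts - counts_phi

    profiles = {}
    z_s = rel_s[:, 2]
    xy_s = rel_s[:, :2]
    for k in orders_k:
        for j in (2 * k, 2 * k + 1):
            if j % 2 == 0:
                base = r_s ** j * w
                tr = _prefix_eval(r_s, base, l_values)
                phi_tr = _prefix_eval(r_s, base * philic, l_values)
                pho_tr = _prefix_eval(r_s, base * phobic, l_values)
                profiles[j] = MomentProfile(
                    order=j, parity="even", trace=tr,
                    philic_trace=phi_tr, phobic_trace=pho_tr,
                    noise_sigma=sigma_iota)
            else:
                scal = r_s ** (j - 1) * w
                perp = scal * z_s
                tr = _prefix_eval(r_s, perp, l_values)
                phi_tr = _prefix_eval(r_s, perp * philic, l_values)
                pho_tr = _prefix_eval(r_s, perp * phobic, l_values)
                px = _prefix_eval(r_s, scal * xy_s[:, 0], l_values)
                py = _prefix_eval(r_s, scal * xy_s[:, 1], l_values)
                profiles[j] = MomentProfile(
                    order=j, parity="odd", trace=tr,
                    philic_trace=phi_tr, phobic_trace=pho_tr,
                    trace_para=np.hypot(px, py), noise_sigma=sigma_iota)
    return MomentSet(pore_point=p, l_values=l_values, counts=counts,
                     counts_philic=counts_phi, counts_phobic=counts_pho,
                     profiles=profiles)


def _sign_stable_suffix(plus: np.ndarray, minus: np.ndarray) -> int:
    """Start index of the longest suffix with plus > 0 and minus < 0."""
    ok = (plus > 0) & (minus < 0)
    if not ok[-1]:
        return len(ok)
    bad = np.flatnonzero(~ok)
    return 0 if len(bad) == 0 else int(bad[-1]) + 1


def decompose(moment_set: MomentSet) -> MomentSet:
    """Assign ± components, the ansatz cutoff scale, and the case label.

    Case A identifies h_+ with the hydrophilic-only and h_− with the
    hydrophobic-only sum; case B swaps the roles.  The cutoff l_cutoff is
    the smallest scale beyond which both components hold constant opposite
    signs (h_+ > 0, h_− < 0); even orders with vanishing noise satisfy
    case A with the cutoff at the first hydrophilic-occupied scale.
    Profiles with no sign-stable region are flagged undecomposable, as are
    degenerate single-sign clouds.
    """
    l = moment_set.l_values
    for prof in moment_set.profiles.values():
        phi, pho = prof.philic_trace, prof.phobic_trace
        if not np.any(phi != 0) or not np.any(pho != 0):
            prof.decomposable = False
            prof.case_label = "degenerate"
            log.warning("order %d: single-sign cloud, decomposition "
                        "degenerate", prof.order)
            continue
        start_a = _sign_stable_suffix(phi, pho)
        start_b = _sign_stable_suffix(pho, phi)
        if start_a >= len(l) and start_b >= len(l):
            prof.decomposable = False
            warnings.warn(f"order {prof.order}: no sign-stable region; "
                          "profile excluded from ϕ/I features")
            continue
        if start_a <= start_b:          # tie broken toward case A
            prof.case_label = "A"
            prof.plus_trace, prof.minus_trace = phi, pho
            start = start_a
        else:
            prof.case_label = "B"
            prof.plus_trace, prof.minus_trace = pho, phi
            start = start_b
        prof.l_cutoff = float(l[start - 1]) if start > 0 else float(l[0])
        prof.valid = np.arange(len(l)) >= start
        prof.decomposable = True
    return moment_set


def log_slopes(profile: MomentProfile, grid, smooth_window: int = 5):
    """Continuously varying scaling exponents ψ_± = ∂ln(±h_±)/∂ln l.

    Centered finite differences on the decomposed range, after optional
    Savitzky–Golay smoothing (quadratic, ``smooth_window`` grid points) of
    the log traces.  Raises on a sign violation inside the declared range.
    """
    if not profile.decomposable:
        raise ValueError("profile is not decomposable")
    l = _l_values(grid)
    sel = profile.valid
    plus, minus = profile.plus_trace[sel], profile.minus_trace[sel]
    if np.any(plus <= 0) or np.any(minus >= 0):
        raise ValueError("sign violation inside the declared ± range")
    ln_l = np.log(l[sel])
    y_plus, y_minus = np.log(plus), np.log(-minus)
    if smooth_window and smooth_window >= 3 and len(ln_l) > smooth_window:
        win = smooth_window + (1 - smooth_window % 2)  # force odd
        y_plus = signal.savgol_filter(y_plus, win, 2)
        y_minus = signal.savgol_filter(y_minus, win, 2)
    psi_p = np.full(len(l), np.nan)
    psi_m = np.full(len(l), np.nan)
    if sel.sum() >= 2:
        psi_p[sel] = np.gradient(y_plus, ln_l)
        psi_m[sel] = np.gradient(y_minus, ln_l)
    profile.psi_plus, profile.psi_minus = psi_p, psi_m
    return psi_p, psi_m


def coupling_and_susceptibility(profile: MomentProfile, grid):
    """Δψ, interfacial coupling strength I = Δψ/l, and ϕ = ln(−h_+/h_−).

    ϕ is evaluated pointwise; by construction dϕ/dl = I, so the trapezoidal
    integral of I over [l_a, l_b] reproduces ϕ(l_b) − ϕ(l_a).  Points with
    h_− = 0 are masked.
    """
    if profile.psi_plus is None:
        raise ValueError("run log_slopes first")
    l = _l_values(grid)
    delta = profile.psi_plus - profile.psi_minus
    coupling = delta / l
    phi = np.full(len(l), np.nan)
    sel = profile.valid & (profile.minus_trace != 0) & \
        (profile.plus_trace > 0)
    n_masked = int(profile.valid.sum() - sel.sum())
    if n_masked:
        log.info("order %d: %d points masked in ϕ (h_− = 0)",
                 profile.order, n_masked)
    phi[sel] = np.log(-profile.plus_trace[sel] / profile.minus_trace[sel])
    profile.delta_psi = delta
    profile.coupling = coupling
    profile.log_susceptibility = phi
    profile.susceptibility = np.exp(phi)
    return coupling, profile.susceptibility, phi


@dataclass
class ScalingExponents:
    """Power-law exponents of |h_j| inside the PD and across the VSD range."""
    eta_lt: float
    eta_gt: float
    pearson_lt: float
    pearson_gt: float


def scaling_exponents(abs_trace: np.ndarray, fit: PackingFit,
                      grid) -> ScalingExponents:
    """OLS log-log slopes of |h_j| on (l0, l_i] (PD) and (l_i, l_>] (VSDs).

    Zeros and negative values are masked; a range with fewer than 5 usable
    grid points yields NaN with a warning.
    """
    l = _l_values(grid)
    y = np.abs(np.asarray(abs_trace, dtype=float))
    out = []
    for lo, hi, name in ((fit.params.l0, fit.l_i, "PD"),
                         (fit.l_i, fit.l_gt, "VSD")):
        sel = (l > lo) & (l <= hi) & (y > 0) & np.isfinite(y)
        if sel.sum() < 5:
            warnings.warn(f"{name} range has <5 usable points; "
                          "exponent undefined")
            out.append((np.nan, np.nan))
            continue
        res = stats.linregress(np.log(l[sel]), np.log(y[sel]))
        out.append((res.slope, res.rvalue))
    return ScalingExponents(eta_lt=out[0][0], pearson_lt=out[0][1],
                            eta_gt=out[1][0], pearson_gt=out[1][1])


@dataclass
class EnvelopeFit:
    """Wave-packet envelope A_j = (1 + κ_j ξ/s)·ε/l^j (diagnostic)."""
    kappa: float | None
    amplitude_trace: np.ndarray


def fit_wavepacket_envelope(trace: np.ndarray, counts: np.ndarray,
                            fit: PackingFit, grid, order: int,
                            s: float | None = None) -> EnvelopeFit:
    """Fit the adsorption correction κ_j of the |h_j|/n upper envelope.

    Least squares of the envelope peaks of |h_j|/n against
    (1 + κ ξ/s)·ε/l^j, linear in (1 + κ ξ/s).  Fewer than 3 peaks leave κ
    undefined (None).
    """
    l = _l_values(grid)
    if s is None:
        s = float(l[-1] - l[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.where(counts > 0, np.abs(trace) / np.maximum(counts, 1), 0.0)
    peaks, _ = signal.find_peaks(y)
    basis = epsilon(fit.params, l) / l ** order
    if len(peaks) < 3:
        return EnvelopeFit(kappa=None, amplitude_trace=basis)
    b = basis[peaks]
    a = float((y[peaks] @ b) / (b @ b))
    kappa = (a - 1.0) * s / fit.params.xi
    return EnvelopeFit(kappa=float(kappa), amplitude_trace=a * basis)
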