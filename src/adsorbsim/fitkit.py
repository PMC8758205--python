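"""Saturating-exponential regression for adsorption traces.

Fits y(t) = Amp * (1 - exp(-k*t)) by damped Gauss–Newton, optionally with
the amplitude held fixed (the usual case when the number of binding sites
is known).  The initial rate guess is ln(2) divided by the first time the
trace exceeds half its plateau; the plateau guess is the mean of the last
tenth of the trace.  Iterations that would increase the sum of squares are
step-halved, so the residual RMS is non-increasing across accepted
iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FitResult", "fit_saturating_exponential"]

_MAX_ITER = 500
_REL_TOL = 1e-10


@dataclass
class FitResult:
    """Result of a saturating-exponential fit."""

    amplitude: float
    k: float
    k_stderr: float
    converged: bool
    residual_rms: float
    n_iter: int = 0
    message: str = ""

    def predict(self, t):
        return self.amplitude * -np.expm1(-self.k * np.asarray(t, dtype=float))


def _model(t, amp, k):
    return amp * -np.expm1(-k * t)


def fit_saturating_exponential(
    t,
    y,
    fixed_amplitude: float | None = None,
) -> FitResult:
    """Least-squares fit of y = Amp*(1 - exp(-k*t)).

    Parameters
    ----------
    t, y:
        Nonnegative time grid (increasing) and trace; at least 5 points.
    fixed_amplitude:
        If given, Amp is pinned and only k is free.

    Returns
    -------
    FitResult
        ``converged`` is False (with a diagnostic message) when the trace
        has no usable plateau, e.g. all-zero data; no exception is raised
        for degenerate inputs.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 5:
        raise ValueError(f"need at least 5 points, got {t.size}")
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("t and y must be 1D arrays of equal length")
    if np.any(np.diff(t) < 0) or t[0] < 0:
        raise ValueError("t must be nonnegative and nondecreasing")
    if np.any(y < 0):
        raise ValueError("y must be nonnegative")

    plateau = fixed_amplitude if fixed_amplitude is not None else float(
        np.mean(y[max(1, int(0.9 * y.size)):])
    )
    if plateau <= 0 or not np.any(y > 0):
        return FitResult(
            amplitude=0.0, k=0.0, k_stderr=0.0, converged=False,
            residual_rms=float(np.sqrt(np.mean(y**2))),
            message="no plateau: trace has no positive signal",
        )
    above = np.nonzero(y >= 0.5 * plateau)[0]
    if above.size == 0 or t[above[0]] <= 0:
        # never reaches half plateau, or does so at t=0; fall back crudely
        t_half = t[-1] if t[-1] > 0 else 1.0
    else:
        t_half = t[above[0]]
    k = np.log(2.0) / t_half
    amp = float(plateau)
    fit_amp = fixed_amplitude is None

    resid = y - _model(t, amp, k)
    ssr = float(resid @ resid)
    converged = False
    n_iter = 0
    for n_iter in range(1, _MAX_ITER + 1):
        ek = np.exp(-k * t)
        J_k = amp * t * ek
        if fit_amp:
            J = np.column_stack([-np.expm1(-k * t), J_k])
        else:
            J = J_k[:, None]
        g = J.T @ resid
        H = J.T @ J
        try:
            delta = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return FitResult(
                amplitude=amp, k=k, k_stderr=np.inf, converged=False,
                residual_rms=float(np.sqrt(ssr / t.size)), n_iter=n_iter,
                message="singular normal equations",
            )
        # damped step: halve until SSR does not increase
        lam = 1.0
        for _ in range(60):
            if fit_amp:
                amp_new, k_new = amp + lam * delta[0], k + lam * delta[1]
            else:
                amp_new, k_new = amp, k + lam * delta[0]
            if k_new > 0 and (not fit_amp or amp_new > 0):
                resid_new = y - _model(t, amp_new, k_new)
                ssr_new = float(resid_new @ resid_new)
                if ssr_new <= ssr:
                    break
            lam *= 0.5
        else:
            converged = True  # cannot improve: at a minimum to rounding
            break
        rel = abs(k_new - k) / max(abs(k), 1e-300)
        if fit_amp:
            rel = max(rel, abs(amp_new - amp) / max(abs(amp), 1e-300))
        amp, k, resid, ssr = amp_new, k_new, resid_new, ssr_new
        if rel < _REL_TOL:
            converged = True
            break

    dof = max(t.size - (2 if fit_amp else 1), 1)
    sigma2 = ssr / dof
    ek = np.exp(-k * t)
    J_k = amp * t * ek
    if fit_amp:
        J = np.column_stack([-np.expm1(-k * t), J_k])
        try:
            cov = sigma2 * np.linalg.inv(J.T @ J)
            k_stderr = float(np.sqrt(cov[1, 1]))
        except np.linalg.LinAlgError:
            k_stderr = np.inf
    else:
        jj = float(J_k @ J_k)
        k_stderr = float(np.sqrt(sigma2 / jj)) if jj > 0 else np.inf

    return FitResult(
        amplitude=float(amp),
        k=float(k),
        k_stderr=k_stderr,
        converged=converged,
        residual_rms=float(np.sqrt(ssr / t.size)),
        n_iter=n_iter,
        message="" if converged else "maximum iterations reached",
    )
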