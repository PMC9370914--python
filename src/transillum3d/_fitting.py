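"""Vectorised Gaussian least-squares fitting.

Both the 1D profile features (inverted absorption dips) and the
per-pixel focus curves reduce to the same problem: fit

    y ~= c + A * exp(-(x - mu)^2 / (2 sigma^2))

to many curves that share one abscissa.  With up to ~10^5 curves per
call, a per-curve ``scipy.optimize.curve_fit`` loop is far too slow, so
a Levenberg-Marquardt iteration is run over all rows simultaneously with
analytic Jacobians and per-row damping.  Agreement with scipy on single
curves is covered by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GaussianFitResult", "batch_gaussian_fit"]


@dataclass
class GaussianFitResult:
    amplitude: np.ndarray   # A (signed: negative for dips)
    center: np.ndarray      # mu, same units as x
    sigma: np.ndarray       # |sigma|
    offset: np.ndarray      # c
    resid_rms: np.ndarray
    converged: np.ndarray   # per-row flag
    fitted: np.ndarray | None = None  # model evaluated at x (optional)


def _model(x, a, mu, sig, c):
    e = np.exp(-0.5 * ((x[None, :] - mu[:, None]) / sig[:, None]) ** 2)
    return c[:, None] + a[:, None] * e, e


def batch_gaussian_fit(x: np.ndarray, y: np.ndarray, *, peak_sign: int = 1,
                       baseline: str = "auto", max_iter: int = 60,
                       xtol: float = 1e-12, keep_model: bool = False
                       ) -> GaussianFitResult:
    """Fit ``c + A exp(-(x-mu)^2/(2 sigma^2))`` to each row of ``y``.

    Parameters
    ----------
    peak_sign : +1 for positive peaks, -1 for dips (constrains the
        initial guess only; the sign of A is free thereafter).
    baseline : "auto" (edge mean for dips, min for peaks), "edges",
        "min" or "max" -- how the initial offset is estimated.
    """
    x = np.asarray(x, dtype=float)
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n, m = y.shape
    dx = np.median(np.diff(x))

    if baseline == "auto":
        baseline = "edges" if peak_sign < 0 else "min"
    k = max(2, m // 10)
    if baseline == "edges":
        c0 = 0.5 * (y[:, :k].mean(axis=1) + y[:, -k:].mean(axis=1))
    elif baseline == "min":
        c0 = y.min(axis=1)
    elif baseline == "max":
        c0 = y.max(axis=1)
    else:
        raise ValueError(f"unknown baseline mode {baseline!r}")

    dev = peak_sign * (y - c0[:, None])
    amp0 = dev.max(axis=1)
    mu0 = x[np.argmax(dev, axis=1)]
    # width of the above-half-max region as the sigma seed
    above = dev > 0.5 * amp0[:, None]
    sig0 = np.maximum(above.sum(axis=1) * abs(dx) / 2.3548, abs(dx) * 0.5)

    a = peak_sign * amp0.copy()
    mu = mu0.copy()
    sig = sig0.copy()
    c = c0.copy()
    degenerate = ~(amp0 > 0) | ~np.isfinite(amp0)
    a[degenerate] = 0.0

    model, e = _model(x, a, mu, sig, c)
    resid = y - model
    cost = (resid**2).sum(axis=1)
    lam = np.full(n, 1e-3)
    active = ~degenerate

    for _ in range(max_iter):
        if not active.any():
            break
        xm = x[None, :] - mu[:, None]
        j_a = e
        j_mu = a[:, None] * e * xm / sig[:, None] ** 2
        j_sig = a[:, None] * e * xm**2 / sig[:, None] ** 3
        j_c = np.ones_like(e)
        jac = np.stack([j_a, j_mu, j_sig, j_c], axis=2)       # (n, m, 4)
        jtj = np.einsum("nmi,nmj->nij", jac, jac)
        jtr = np.einsum("nmi,nm->ni", jac, resid)
        diag = np.maximum(np.einsum("nii->ni", jtj), 1e-300)
        aug = jtj + lam[:, None, None] * diag[:, None, :] * np.eye(4)
        try:
            step = np.linalg.solve(aug, jtr[..., None])[..., 0]
        except np.linalg.LinAlgError:
            aug = aug + 1e-9 * np.eye(4)
            step = np.linalg.solve(aug, jtr[..., None])[..., 0]
        bad = ~np.isfinite(step).all(axis=1)
        step[bad] = 0.0

        a_n = a + step[:, 0]
        mu_n = mu + step[:, 1]
        sig_n = np.abs(sig + step[:, 2])
        sig_n = np.maximum(sig_n, 1e-6 * abs(dx))
        c_n = c + step[:, 3]
        model_n, e_n = _model(x, a_n, mu_n, sig_n, c_n)
        resid_n = y - model_n
        cost_n = (resid_n**2).sum(axis=1)

        better = (cost_n <= cost) & active & ~bad
        a = np.where(better, a_n, a)
        mu = np.where(better, mu_n, mu)
        sig = np.where(better, sig_n, sig)
        c = np.where(better, c_n, c)
        cost = np.where(better, cost_n, cost)
        e = np.where(better[:, None], e_n, e)
        resid = np.where(better[:, None], resid_n, resid)
        lam = np.where(better, lam / 3.0, lam * 10.0)
        lam = np.clip(lam, 1e-12, 1e12)
        # stop rows whose accepted step is negligible
        scale = np.maximum(np.abs(np.stack([a, mu, sig, c], axis=1)), 1.0)
        small = (np.abs(step) / scale < xtol).all(axis=1)
        active = active & ~(better & small) & (lam < 1e10)

    resid_rms = np.sqrt(cost / m)
    converged = ~degenerate & np.isfinite(cost)
    model_final = None
    if keep_model:
        model_final, _ = _model(x, a, mu, sig, c)
    return GaussianFitResult(amplitude=a, center=mu, sigma=np.abs(sig),
                             offset=c, resid_rms=resid_rms,
                             converged=converged, fitted=model_final)
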