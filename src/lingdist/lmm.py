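"""Linear mixed models by profiled REML, with Satterthwaite inference.

Fits ``y = X beta + Z_i u_i + eps`` with one grouping factor, ``u_i ~
N(0, G)`` (full covariance, log-Cholesky parameterized) and ``eps ~
N(0, sigma^2 I)``.  The restricted likelihood is profiled over ``beta``, so
optimization runs over the handful of variance parameters only; per-group
matrices are padded to a common size and all likelihood algebra is batched
over groups, which keeps repeated fitting (bootstrap resampling) cheap.

Inference on a fixed effect uses Satterthwaite's approximation: for a
contrast ``l``, the denominator degrees of freedom are

    df = 2 (l' C(theta) l)^2 / Var(l' C(theta) l),

where ``C(theta)`` is the fixed-effects covariance at the variance
parameters ``theta`` and the variance of the quadratic form follows from the
delta method with ``Cov(theta_hat)`` taken as twice the inverse Hessian of
the REML deviance.  Derivatives are finite differences; the parameter count
is tiny so this is both accurate and fast.  Results are checked in the test
suite against lme4/lmerTest and statsmodels on the same data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import t as t_dist

__all__ = ["LMM", "LMMResult", "fit_lmm"]

_BIG = 1e12


def _pack_theta(q: int) -> int:
    return q * (q + 1) // 2 + 1


def _chol_from_theta(theta: np.ndarray, q: int) -> np.ndarray:
    """Lower Cholesky factor of G from the packed parameter vector."""
    L = np.zeros((q, q))
    idx = 0
    for j in range(q):
        for i in range(j, q):
            if i == j:
                L[i, j] = np.exp(theta[idx])
            else:
                L[i, j] = theta[idx]
            idx += 1
    return L


class LMM:
    """One grouping factor, arbitrary fixed and random design columns."""

    def __init__(self, y, X, Z, groups):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        Z = np.asarray(Z, dtype=float)
        groups = np.asarray(groups)
        if X.ndim != 2 or Z.ndim != 2 or y.ndim != 1:
            raise ValueError("y must be 1-d; X and Z must be 2-d")
        n = len(y)
        if len(X) != n or len(Z) != n or len(groups) != n:
            raise ValueError("inconsistent row counts")
        codes, order = np.unique(groups, return_inverse=True)
        self.n, self.p, self.q = n, X.shape[1], Z.shape[1]
        self.n_groups = len(codes)
        counts = np.bincount(order)
        nmax = counts.max()
        G = self.n_groups
        self.Yp = np.zeros((G, nmax))
        self.Xp = np.zeros((G, nmax, self.p))
        self.Zp = np.zeros((G, nmax, self.q))
        self.mask = np.zeros((G, nmax), dtype=bool)
        pos = np.zeros(G, dtype=int)
        for r in range(n):
            g = order[r]
            k = pos[g]
            self.Yp[g, k] = y[r]
            self.Xp[g, k] = X[r]
            self.Zp[g, k] = Z[r]
            self.mask[g, k] = True
            pos[g] += 1
        self._pad_diag = (~self.mask).astype(float)
        self._rhs = np.concatenate([self.Xp, self.Yp[:, :, None]], axis=2)
        self._ZpT = np.ascontiguousarray(self.Zp.transpose(0, 2, 1))
        self._ar = np.arange(nmax)

    # -- likelihood ---------------------------------------------------------

    def _decompose(self, theta):
        L = _chol_from_theta(theta, self.q)
        sigma2 = np.exp(2.0 * theta[-1])
        V = (self.Zp @ (L @ L.T)) @ self._ZpT
        V[:, self._ar, self._ar] += sigma2 * self.mask + self._pad_diag
        Lc = np.linalg.cholesky(V)
        sol = np.linalg.solve(Lc, self._rhs)
        Xt = sol[:, :, :-1].reshape(-1, self.p)
        yt = sol[:, :, -1].reshape(-1)
        XtVX = Xt.T @ Xt
        XtVy = Xt.T @ yt
        ytVy = float(yt @ yt)
        logdetV = 2.0 * float(np.log(Lc[:, self._ar, self._ar]).sum())
        return XtVX, XtVy, ytVy, logdetV

    def _decompose_many(self, thetas):
        """Batched :meth:`_decompose` over S parameter points.

        Returns (XtVX (S,p,p), XtVy (S,p), ytVy (S,), logdetV (S,)); used by
        the finite-difference Hessian/gradient so that derivative evaluation
        is a handful of batched linear-algebra calls rather than a loop.
        """
        thetas = np.asarray(thetas, dtype=float)
        S = len(thetas)
        G, nmax, _ = self.Zp.shape
        Gcovs = np.stack([
            _chol_from_theta(t, self.q) @ _chol_from_theta(t, self.q).T
            for t in thetas
        ])
        sigma2 = np.exp(2.0 * thetas[:, -1])
        V = np.einsum("gik,skl,gjl->sgij", self.Zp, Gcovs, self.Zp,
                      optimize=True)
        diag = (sigma2[:, None, None] * self.mask[None]
                + self._pad_diag[None])
        V[:, :, self._ar, self._ar] += diag
        V = V.reshape(S * G, nmax, nmax)
        Lc = np.linalg.cholesky(V)
        rhs = np.broadcast_to(self._rhs, (S, G, nmax, self.p + 1)).reshape(
            S * G, nmax, self.p + 1)
        sol = np.linalg.solve(Lc, rhs).reshape(S, G * nmax, self.p + 1)
        Xt, yt = sol[:, :, :-1], sol[:, :, -1]
        XtVX = np.einsum("sip,siq->spq", Xt, Xt)
        XtVy = np.einsum("sip,si->sp", Xt, yt)
        ytVy = np.einsum("si,si->s", yt, yt)
        logdetV = 2.0 * np.log(
            Lc[:, self._ar, self._ar]).reshape(S, G, nmax).sum(axis=(1, 2))
        return XtVX, XtVy, ytVy, logdetV

    def deviance_many(self, thetas, reml: bool = True) -> np.ndarray:
        """Batched REML/ML deviance at several parameter points."""
        thetas = np.asarray(thetas, dtype=float)
        out = np.full(len(thetas), _BIG)
        try:
            XtVX, XtVy, ytVy, logdetV = self._decompose_many(thetas)
        except np.linalg.LinAlgError:
            return np.array([self.deviance(t, reml) for t in thetas])
        for s in range(len(thetas)):
            try:
                cf = np.linalg.cholesky(XtVX[s])
                beta = np.linalg.solve(XtVX[s], XtVy[s])
            except np.linalg.LinAlgError:
                continue
            quad = ytVy[s] - float(beta @ XtVy[s])
            if quad <= 0 or not np.isfinite(quad):
                continue
            dev = logdetV[s] + quad
            if reml:
                dev += 2.0 * float(np.sum(np.log(np.diag(cf))))
                dev += (self.n - self.p) * np.log(2.0 * np.pi)
            else:
                dev += self.n * np.log(2.0 * np.pi)
            out[s] = dev
        return out

    def cov_beta_many(self, thetas) -> np.ndarray:
        XtVX, _, _, _ = self._decompose_many(thetas)
        return np.linalg.inv(XtVX)

    def deviance(self, theta, reml: bool = True) -> float:
        """-2 log (restricted) likelihood with beta profiled out."""
        try:
            XtVX, XtVy, ytVy, logdetV = self._decompose(theta)
            cf = np.linalg.cholesky(XtVX)
            beta = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError:
            return _BIG
        quad = ytVy - float(beta @ XtVy)
        if quad <= 0 or not np.isfinite(quad):
            return _BIG
        dev = logdetV + quad
        if reml:
            dev += 2.0 * float(np.sum(np.log(np.diag(cf))))
            dev += (self.n - self.p) * np.log(2.0 * np.pi)
        else:
            dev += self.n * np.log(2.0 * np.pi)
        return float(dev)

    def cov_beta(self, theta) -> np.ndarray:
        XtVX, _, _, _ = self._decompose(theta)
        return np.linalg.inv(XtVX)

    def _col_scales(self) -> np.ndarray:
        """Per-column SD of the random-effects design (floor 1 for
        intercept-like or constant columns); conditions the start values."""
        z = self.Zp[self.mask]
        sd = z.std(axis=0)
        sd[sd < 1e-12] = 1.0
        return sd

    def _start(self) -> np.ndarray:
        y = self.Yp[self.mask]
        vy = max(float(np.var(y)), 1e-8)
        sd_z = self._col_scales()
        theta0 = np.zeros(_pack_theta(self.q))
        idx = 0
        for j in range(self.q):
            for i in range(j, self.q):
                if i == j:
                    theta0[idx] = 0.5 * np.log(vy / 2.0) - np.log(sd_z[j])
                idx += 1
        theta0[-1] = 0.5 * np.log(vy / 2.0)
        return theta0

    def fit(self, reml: bool = True, start=None) -> "LMMResult":
        k = _pack_theta(self.q)
        theta0 = np.asarray(start, dtype=float) if start is not None \
            else self._start()
        sd_z = self._col_scales()
        sd_y = max(float(self.Yp[self.mask].std()), 1e-8)
        bounds = []
        diag_centres = []
        for j in range(self.q):
            for i in range(j, self.q):
                if i == j:
                    centre = np.log(sd_y) - np.log(sd_z[j])
                    diag_centres.append(centre)
                    bounds.append((centre - 12.0, centre + 12.0))
                else:
                    bounds.append((None, None))
        bounds.append((np.log(sd_y) - 12.0, np.log(sd_y) + 12.0))
        def fun_and_grad(theta):
            h = 1e-5 * np.maximum(1.0, np.abs(theta))
            pts = [theta]
            for i in range(k):
                ei = np.zeros(k); ei[i] = h[i]
                pts.extend([theta + ei, theta - ei])
            f = self.deviance_many(np.asarray(pts), reml)
            grad = (f[1::2] - f[2::2]) / (2 * h)
            return f[0], grad

        res = optimize.minimize(
            fun_and_grad, theta0, jac=True, method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 200, "ftol": 1e-11, "gtol": 1e-7},
        )
        theta = res.x
        XtVX, XtVy, _, _ = self._decompose(theta)
        cov = np.linalg.inv(XtVX)
        beta = cov @ XtVy
        L = _chol_from_theta(theta, self.q)
        # singular when a variance component collapses relative to the
        # response/design scale (mirrors the boundary fits lme4 reports)
        rel = [theta[i] - c for i, c in zip(_diag_positions(self.q),
                                            diag_centres)]
        rel.append(theta[-1] - np.log(sd_y))
        singular = bool(min(rel) <= -7.0)
        return LMMResult(
            model=self, theta=theta, beta=beta, cov_beta=cov,
            sigma2=float(np.exp(2 * theta[-1])), cov_re=L @ L.T,
            deviance=float(res.fun), reml=reml,
            converged=bool(res.success) and res.fun < _BIG / 2,
            singular=singular,
        )


def _diag_positions(q: int) -> list[int]:
    pos, idx = [], 0
    for j in range(q):
        for i in range(j, q):
            if i == j:
                pos.append(idx)
            idx += 1
    return pos


@dataclass
class LMMResult:
    model: LMM
    theta: np.ndarray
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    cov_re: np.ndarray
    deviance: float
    reml: bool
    converged: bool
    singular: bool

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))

    def _theta_cov(self, step: float = 1e-4) -> np.ndarray:
        """Cov(theta_hat) = 2 H^-1 with H the FD Hessian of the deviance."""
        th = self.theta
        k = len(th)
        h = step * np.maximum(1.0, np.abs(th))
        points = [th]
        pairs = []
        for i in range(k):
            ei = np.zeros(k); ei[i] = h[i]
            points.extend([th + ei, th - ei])
        for i in range(k):
            for j in range(i + 1, k):
                ei = np.zeros(k); ei[i] = h[i]
                ej = np.zeros(k); ej[j] = h[j]
                pairs.append((i, j))
                points.extend([th + ei + ej, th + ei - ej,
                               th - ei + ej, th - ei - ej])
        f = self.model.deviance_many(np.asarray(points), self.reml)
        f0 = f[0]
        H = np.zeros((k, k))
        for i in range(k):
            H[i, i] = (f[1 + 2 * i] - 2 * f0 + f[2 + 2 * i]) / h[i] ** 2
        base = 1 + 2 * k
        for idx, (i, j) in enumerate(pairs):
            fpp, fpm, fmp, fmm = f[base + 4 * idx: base + 4 * idx + 4]
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        return 2.0 * np.linalg.pinv(H, rcond=1e-10)

    def satterthwaite_df(self, contrast, step: float = 1e-4) -> float:
        """Satterthwaite denominator df for the contrast ``l' beta``."""
        l = np.zeros(self.model.p)
        if np.isscalar(contrast):
            l[int(contrast)] = 1.0
        else:
            l = np.asarray(contrast, dtype=float)
        th = self.theta
        k = len(th)
        var0 = float(l @ self.cov_beta @ l)
        h = step * np.maximum(1.0, np.abs(th))
        points = []
        for i in range(k):
            ei = np.zeros(k); ei[i] = h[i]
            points.extend([th + ei, th - ei])
        try:
            covs = self.model.cov_beta_many(np.asarray(points))
        except np.linalg.LinAlgError:
            return float(self.model.n - self.model.p)
        v = covs @ l @ l
        grad = (v[0::2] - v[1::2]) / (2 * h)
        denom = float(grad @ self._theta_cov(step) @ grad)
        if denom <= 0 or not np.isfinite(denom):
            return float(self.model.n - self.model.p)
        df = 2.0 * var0 ** 2 / denom
        return float(np.clip(df, 1.0, 1e8))

    def t_test(self, j: int) -> dict:
        """Coefficient t-test with Satterthwaite df; also returns the Wald F
        (numerator df 1) used for semipartial variance explained."""
        beta_j = float(self.beta[j])
        se_j = float(self.se[j])
        df = self.satterthwaite_df(j)
        tval = beta_j / se_j if se_j > 0 else np.inf
        p = 2.0 * float(t_dist.sf(abs(tval), df))
        return {"beta": beta_j, "se": se_j, "t": tval, "df": df, "p": p,
                "F": tval ** 2}


def fit_lmm(y, X, Z, groups, reml: bool = True, start=None) -> LMMResult:
    """Convenience wrapper: build an :class:`LMM` and fit it."""
    return LMM(y, X, Z, groups).fit(reml=reml, start=start)
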