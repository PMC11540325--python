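"""Dense REML engine for Gaussian mixed models with coefficient random terms.

The model is

    y = X beta + sum_i Z_i u_i + e

where each random term i has q_i levels (genotypes, plots, ...) carrying m_i
coefficients per level, u_i ~ N(0, I_{q_i} (x) K_i) with K_i an unstructured
symmetric PSD m_i x m_i matrix shared across levels, and a diagonal residual
(homogeneous, or one variance per observation group).

Estimation is restricted maximum likelihood on Henderson's mixed-model
equations.  Each iteration computes the exact EM-REML update (monotone in the
restricted log-likelihood) and, after a few warm-up steps, an
average-information (AI) Newton proposal; whichever proposal achieves the
higher restricted log-likelihood is accepted, so the accepted path is never
below the EM path and monotonicity is preserved while convergence is fast.
PSD constraints are enforced by eigenvalue clipping ("bending") with the
number of clips recorded in the result.

The single-trait genotype model is the special case of one term with
m_i = 1; the random-regression growth model uses two terms (genetic and
permanent-environment Legendre coefficients).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = ["RandomTerm", "REMLResult", "MixedModelREML", "solve_blups"]

_LOG2PI = np.log(2.0 * np.pi)


def _sym(a: np.ndarray) -> np.ndarray:
    return 0.5 * (a + a.T)


def _clip_psd(a: np.ndarray, floor: float) -> tuple[np.ndarray, int]:
    """Project a symmetric matrix onto {eigenvalues >= floor}; count clips."""
    a = _sym(np.asarray(a, dtype=float))
    w, v = np.linalg.eigh(a)
    n_clip = int(np.sum(w < floor))
    if n_clip:
        a = _sym((v * np.maximum(w, floor)) @ v.T)
    return a, n_clip


def _inv_logdet_psd(a: np.ndarray) -> tuple[np.ndarray, float]:
    w, v = np.linalg.eigh(_sym(a))
    if np.any(w <= 0):
        raise np.linalg.LinAlgError("matrix not positive definite")
    inv = (v / w) @ v.T
    return _sym(inv), float(np.sum(np.log(w)))


@dataclass
class RandomTerm:
    """One random effect: ``n_levels`` levels of ``n_coef`` coefficients each.

    ``Z`` is n x (n_levels * n_coef), columns ordered level-major (all
    coefficients of level 0, then level 1, ...).  ``K0`` optionally seeds the
    coefficient covariance.
    """

    name: str
    Z: np.ndarray
    n_levels: int
    n_coef: int
    K0: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.shape[1] != self.n_levels * self.n_coef:
            raise ValueError(
                f"term {self.name!r}: Z has {self.Z.shape[1]} columns, "
                f"expected n_levels*n_coef = {self.n_levels * self.n_coef}"
            )


@dataclass
class REMLResult:
    """Converged (or last-iterate) REML estimates and BLUPs."""

    K: dict[str, np.ndarray]
    sigma2_e: np.ndarray  # one entry per residual group (length 1 if iid)
    beta: np.ndarray
    u: dict[str, np.ndarray]  # per term: (n_levels, n_coef)
    loglik: float
    loglik_path: np.ndarray
    n_iter: int
    converged: bool
    n_psd_clips: int
    message: str = ""

    @property
    def sigma2_e_scalar(self) -> float:
        return float(self.sigma2_e[0])


def _check_fixed_rank(X: np.ndarray, names) -> None:
    from scipy.linalg import qr

    if X.shape[1] == 0:
        raise ValueError("fixed-effect design has no columns")
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        _, _, piv = qr(X, mode="economic", pivoting=True)
        aliased = sorted(piv[r:])
        labels = [names[j] if names is not None else f"col{j}" for j in aliased]
        raise ValueError(f"fixed-effect design is rank deficient; aliased columns: {labels}")


class MixedModelREML:
    """Fit the mixed model by EM/AI REML.  See the module docstring."""

    def __init__(
        self,
        y,
        X,
        terms: list[RandomTerm],
        *,
        residual_groups=None,
        fixed_names=None,
    ) -> None:
        self.y = np.asarray(y, dtype=float).ravel()
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X must be 2-D with one row per observation")
        _check_fixed_rank(self.X, fixed_names)
        self.terms = list(terms)
        if not self.terms:
            raise ValueError("at least one random term is required")
        n = self.y.size
        for t in self.terms:
            if t.Z.shape[0] != n:
                raise ValueError(f"term {t.name!r}: Z row count != n observations")

        self.n = n
        self.p = self.X.shape[1]
        self.W = np.hstack([self.X] + [t.Z for t in self.terms])
        self.slices: list[slice] = []
        start = self.p
        for t in self.terms:
            self.slices.append(slice(start, start + t.n_levels * t.n_coef))
            start += t.n_levels * t.n_coef
        self.n_mme = start

        if residual_groups is None:
            self.groups = np.zeros(n, dtype=int)
            self.n_groups = 1
        else:
            g = np.asarray(residual_groups)
            _, self.groups = np.unique(g, return_inverse=True)
            self.n_groups = int(self.groups.max()) + 1
        self.group_counts = np.bincount(self.groups, minlength=self.n_groups)
        if np.any(self.group_counts == 0):
            raise ValueError("empty residual group")

        # Per-group Gram pieces let W'R^-1 W be assembled for any residual
        # variances without touching W again.
        self._grams = []
        self._wty = []
        self._yty = np.zeros(self.n_groups)
        for g in range(self.n_groups):
            mask = self.groups == g
            Wg = self.W[mask]
            yg = self.y[mask]
            self._grams.append(Wg.T @ Wg)
            self._wty.append(Wg.T @ yg)
            self._yty[g] = yg @ yg
        self._gram_total = np.sum(self._grams, axis=0)

    # -- likelihood / MME assembly ------------------------------------------

    def _assemble(self, Ks, sig2, *, need_cinv: bool):
        """Build and factor the MME at the given parameters.

        Returns a dict with the solution, restricted log-likelihood and
        (optionally) the dense inverse of the coefficient matrix.
        """
        w = 1.0 / sig2
        C = sum(Gg * wg for Gg, wg in zip(self._grams, w))
        C = np.array(C, dtype=float)
        rhs = sum(v * wg for v, wg in zip(self._wty, w))
        y_r_y = float(np.sum(self._yty * w))

        logdet_k_total = 0.0
        kinvs = []
        for t, s, K in zip(self.terms, self.slices, Ks):
            kinv, logdet = _inv_logdet_psd(K)
            kinvs.append(kinv)
            logdet_k_total += t.n_levels * logdet
            view = C[s, s].reshape(t.n_levels, t.n_coef, t.n_levels, t.n_coef)
            idx = np.arange(t.n_levels)
            view[idx, :, idx, :] += kinv
            C[s, s] = view.reshape(s.stop - s.start, s.stop - s.start)

        cho = cho_factor(C, lower=True, check_finite=False)
        theta = cho_solve(cho, rhs, check_finite=False)
        logdet_c = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        quad = y_r_y - float(theta @ rhs)
        logdet_r = float(np.sum(self.group_counts * np.log(sig2)))
        ll = -0.5 * (
            (self.n - self.p) * _LOG2PI + logdet_r + logdet_k_total + logdet_c + quad
        )
        out = {"theta": theta, "cho": cho, "loglik": ll, "kinvs": kinvs, "w": w}
        if need_cinv:
            out["cinv"] = cho_solve(cho, np.eye(self.n_mme), check_finite=False)
        return out

    def _level_blocks_of_cinv(self, cinv, i):
        t, s = self.terms[i], self.slices[i]
        block = cinv[s, s].reshape(t.n_levels, t.n_coef, t.n_levels, t.n_coef)
        idx = np.arange(t.n_levels)
        return block[idx, :, idx, :]  # (q, m, m)

    # -- EM proposal ---------------------------------------------------------

    def _em_step(self, state, Ks, sig2, floor):
        theta, cinv = state["theta"], state["cinv"]
        new_ks = []
        n_clips = 0
        for i, (t, s) in enumerate(zip(self.terms, self.slices)):
            U = theta[s].reshape(t.n_levels, t.n_coef)
            pev = self._level_blocks_of_cinv(cinv, i).sum(axis=0)
            K_new = (U.T @ U + pev) / t.n_levels
            K_new, c = _clip_psd(K_new, floor)
            n_clips += c
            new_ks.append(K_new)

        ehat = self.y - self.W @ theta
        if self.n_groups == 1:
            tr = float(np.sum(cinv * self._gram_total))
            s_new = np.array([max((ehat @ ehat + tr) / self.n, 1e-12)])
        else:
            diag_wcw = np.einsum("ij,ij->i", self.W @ cinv, self.W)
            s_new = np.zeros(self.n_groups)
            for g in range(self.n_groups):
                mask = self.groups == g
                s_new[g] = max(
                    (ehat[mask] @ ehat[mask] + diag_wcw[mask].sum()) / self.group_counts[g],
                    1e-12,
                )
        return new_ks, s_new, n_clips

    # -- AI proposal ---------------------------------------------------------

    def _param_vector(self, Ks, sig2):
        parts = []
        for t, K in zip(self.terms, Ks):
            i, j = np.tril_indices(t.n_coef)
            parts.append(K[i, j])
        parts.append(np.asarray(sig2, dtype=float))
        return np.concatenate(parts)

    def _unpack_params(self, vec, floor):
        Ks, pos, n_clips = [], 0, 0
        for t in self.terms:
            m = t.n_coef
            k = m * (m + 1) // 2
            K = np.zeros((m, m))
            i, j = np.tril_indices(m)
            K[i, j] = vec[pos : pos + k]
            K[j, i] = K[i, j]
            K, c = _clip_psd(K, floor)
            n_clips += c
            Ks.append(K)
            pos += k
        sig2 = np.maximum(vec[pos:], 1e-12)
        return Ks, sig2, n_clips

    def _ai_step(self, state, Ks, sig2, floor):
        """Average-information Newton proposal; None if numerically unusable."""
        theta, cinv, w = state["theta"], state["cinv"], state["w"]
        ehat = self.y - self.W @ theta
        py = w[self.groups] * ehat

        fs, grads = [], []
        for i, (t, s) in enumerate(zip(self.terms, self.slices)):
            m = t.n_coef
            V = (t.Z.T @ py).reshape(t.n_levels, m)
            vtv = V.T @ V
            kinv = state["kinvs"][i]
            blocks = self._level_blocks_of_cinv(cinv, i)  # (q, m, m)
            # tr(P dV) blocks: Z_i' P Z_i level-diagonal = Kinv - Kinv C^uu_ll Kinv
            t_blocks = kinv[None, :, :] - kinv @ blocks @ kinv
            t_sum = t_blocks.sum(axis=0)
            for a in range(m):
                for b in range(a + 1):
                    # dV/dK[a,b] = Z (I x E) Z' with E symmetric: E_aa on the
                    # diagonal, E_ab + E_ba off it.
                    E = np.zeros((m, m))
                    E[a, b] += 1.0
                    E[b, a] += 1.0
                    if a == b:
                        E[a, a] = 1.0
                    fs.append(t.Z @ (V @ E).ravel())
                    if a == b:
                        tr_term = t_sum[a, a]
                        quad_form = vtv[a, a]
                    else:
                        tr_term = 2.0 * t_sum[a, b]
                        quad_form = 2.0 * vtv[a, b]
                    grads.append(-0.5 * (tr_term - quad_form))

        if self.n_groups == 1:
            fs.append(py.copy())
            tr_p = self.n / sig2[0] - float(np.sum(cinv * self._gram_total)) / sig2[0] ** 2
            grads.append(-0.5 * (tr_p - float(py @ py)))
        else:
            diag_wcw = np.einsum("ij,ij->i", self.W @ cinv, self.W)
            for g in range(self.n_groups):
                mask = self.groups == g
                f = np.zeros(self.n)
                f[mask] = py[mask]
                fs.append(f)
                wg = 1.0 / sig2[g]
                tr_p = self.group_counts[g] * wg - wg**2 * diag_wcw[mask].sum()
                grads.append(-0.5 * (tr_p - float(py[mask] @ py[mask])))

        F = np.stack(fs, axis=1)  # n x P
        WF = self.W.T @ (w[self.groups, None] * F)
        B = cho_solve(state["cho"], WF, check_finite=False)
        PF = w[self.groups, None] * F - w[self.groups, None] * (self.W @ B)
        AI = 0.5 * (F.T @ PF)
        grad = np.asarray(grads)

        try:
            ridge = 1e-8 * max(1.0, float(np.trace(AI)) / AI.shape[0])
            step = np.linalg.solve(AI + ridge * np.eye(AI.shape[0]), grad)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(step)):
            return None
        cur = self._param_vector(Ks, sig2)
        return cur + step

    # -- main loop -----------------------------------------------------------

    def fit(
        self,
        *,
        tol: float = 1e-8,
        param_tol: float = 1e-6,
        max_iter: int = 500,
        use_ai: bool = True,
        n_em_warmup: int = 3,
        psd_floor: float = 1e-8,
        K_start=None,
        sigma2_start=None,
    ) -> REMLResult:
        var_y = float(np.var(self.y)) if self.n > 1 else 1.0
        var_y = max(var_y, 1e-10)
        n_terms = len(self.terms)
        Ks = []
        if K_start is not None:
            for t, K in zip(self.terms, K_start):
                K, _ = _clip_psd(np.asarray(K, dtype=float), psd_floor)
                Ks.append(K)
        else:
            for t in self.terms:
                mean_sq = float(np.mean(np.sum(t.Z**2, axis=1)))
                scale = var_y / (n_terms + 1) / max(mean_sq / max(t.n_coef, 1), 1e-12)
                Ks.append(scale * np.eye(t.n_coef))
        if sigma2_start is not None:
            sig2 = np.full(self.n_groups, float(np.mean(sigma2_start)))
        else:
            sig2 = np.full(self.n_groups, var_y / (n_terms + 1))
        sig2 = np.maximum(sig2, 1e-12)

        total_clips = 0
        path = []
        state = self._assemble(Ks, sig2, need_cinv=True)
        path.append(state["loglik"])
        converged = False
        message = "max_iter reached"
        it = 0
        for it in range(1, max_iter + 1):
            em_ks, em_sig2, clips_em = self._em_step(state, Ks, sig2, psd_floor)
            try:
                em_state = self._assemble(em_ks, em_sig2, need_cinv=False)
            except np.linalg.LinAlgError:
                message = "EM step produced singular system"
                break

            best = ("em", em_ks, em_sig2, em_state["loglik"], clips_em)
            if use_ai and it > n_em_warmup:
                vec = self._ai_step(state, Ks, sig2, psd_floor)
                if vec is not None:
                    for frac in (1.0, 0.5):
                        cur = self._param_vector(Ks, sig2)
                        ai_ks, ai_sig2, clips_ai = self._unpack_params(
                            cur + frac * (vec - cur), psd_floor
                        )
                        try:
                            ai_state = self._assemble(ai_ks, ai_sig2, need_cinv=False)
                        except np.linalg.LinAlgError:
                            continue
                        if np.isfinite(ai_state["loglik"]) and ai_state["loglik"] > best[3]:
                            best = ("ai", ai_ks, ai_sig2, ai_state["loglik"], clips_ai)
                            break

            _, new_ks, new_sig2, new_ll, clips = best
            total_clips += clips
            old_vec = self._param_vector(Ks, sig2)
            new_vec = self._param_vector(new_ks, new_sig2)
            d_param = float(np.max(np.abs(new_vec - old_vec) / (1.0 + np.abs(old_vec))))
            d_ll = new_ll - path[-1]

            Ks, sig2 = new_ks, new_sig2
            state = self._assemble(Ks, sig2, need_cinv=True)
            path.append(state["loglik"])

            if abs(d_ll) / (1.0 + abs(new_ll)) < tol or d_param < param_tol:
                converged = True
                message = "converged"
                break

        theta = state["theta"]
        u = {
            t.name: theta[s].reshape(t.n_levels, t.n_coef)
            for t, s in zip(self.terms, self.slices)
        }
        return REMLResult(
            K={t.name: K for t, K in zip(self.terms, Ks)},
            sigma2_e=np.asarray(sig2),
            beta=theta[: self.p].copy(),
            u=u,
            loglik=float(state["loglik"]),
            loglik_path=np.asarray(path),
            n_iter=it,
            converged=converged,
            n_psd_clips=total_clips,
            message=message,
        )


def solve_blups(y, X, terms: list[RandomTerm], Ks, sigma2_e, *, residual_groups=None):
    """Solve the mixed-model equations at fixed variance components.

    Returns ``(beta, {term_name: u_matrix})``.  Useful for shrinkage analyses
    and for predicting at externally supplied components.
    """
    model = MixedModelREML(y, X, terms, residual_groups=residual_groups)
    sig2 = np.atleast_1d(np.asarray(sigma2_e, dtype=float))
    if sig2.size == 1 and model.n_groups > 1:
        sig2 = np.full(model.n_groups, float(sig2[0]))
    Ks = [_clip_psd(np.asarray(K, dtype=float), 1e-12)[0] for K in Ks]
    state = model._assemble(Ks, sig2, need_cinv=False)
    theta = state["theta"]
    u = {
        t.name: theta[s].reshape(t.n_levels, t.n_coef)
        for t, s in zip(model.terms, model.slices)
    }
    return theta[: model.p].copy(), u
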