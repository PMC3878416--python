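"""REML log likelihood via the mixed-model equations.

With ``W = [X  Zg  Zu1 ... Zub]`` and diagonal per-trial residual weights,
the coefficient matrix

    C = W' R^-1 W + blockdiag(0, G^-1)

yields the REML log likelihood through the determinant identity

    log|V| + log|X' V^-1 X| = log|R| + log|G| + log|C|

and ``y' P y = y' R^-1 y - rhs' C^-1 rhs`` with ``rhs = W' R^-1 y``.
The constant ``-(n - p)/2 * log(2*pi)`` is included, so values are
comparable across nested models fitted to the same data (absolute values
still depend on this convention).

Two factorisation backends share the assembled system:

* ``schur`` — fine-grained random terms (few observations per level, e.g.
  one sample's plate plot or field cell) form tiny independent clusters
  in C.  They are eliminated block-wise and the dense Schur complement of
  the remainder is Cholesky-factorised.  This backend also provides the
  exact REML gradient from the selected inverse of C, which is what makes
  repeated fitting fast.
* ``splu`` — sparse LU of the full C, used when the remainder would be
  too large to densify.  No analytic gradient.

The dense path (:func:`reml_loglik_dense`) evaluates the direct formula
``-1/2 [log|V| + log|X'V^-1X| + y'Py] + const`` by materialising V and is
the independent oracle for both sparse backends on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.linalg.lapack import dpotri
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from .matrices import DesignMatrices
from .params import VarianceParams

_LOG2PI = float(np.log(2.0 * np.pi))


class NotPositiveDefiniteError(ArithmeticError):
    """The mixed-model system is not positive definite at these parameters."""


@dataclass
class _Factorisation:
    loglik: float
    solution: np.ndarray  # [tau_hat, g_hat, u_hat...] in global order
    pev_gg: np.ndarray | None = None  # (m_total, m_total) cultivar block of C^-1


def _csc_subset_map(sub: sp.csc_matrix, sup: sp.csc_matrix) -> np.ndarray:
    """Positions of ``sub``'s entries inside ``sup.data`` (patterns nested)."""
    out = np.empty(sub.nnz, dtype=np.int64)
    for j in range(sub.shape[1]):
        lo, hi = sub.indptr[j], sub.indptr[j + 1]
        if lo == hi:
            continue
        slo, shi = sup.indptr[j], sup.indptr[j + 1]
        pos = np.searchsorted(sup.indices[slo:shi], sub.indices[lo:hi])
        out[lo:hi] = slo + pos
    return out


class REMLWorkspace:
    """Cached structure for repeated REML evaluations on one dataset."""

    def __init__(
        self,
        mats: DesignMatrices,
        dense_limit: int = 2500,
        absorb_max_level: int = 8,
        max_cluster: int = 16,
    ):
        self.mats = mats
        spec = mats.spec
        self.trials = spec.trials
        self.p = len(self.trials)
        self.m_total = len(mats.g_labels)
        self.g_offset = self.p
        offset = self.p + self.m_total
        self.term_keys = list(spec.random_terms)
        self.term_offsets: dict[tuple[str, str], int] = {}
        self.term_sizes: dict[tuple[str, str], int] = {}
        blocks = [mats.X, mats.Zg]
        for key in self.term_keys:
            Z = mats.Z_terms[key]
            self.term_offsets[key] = offset
            self.term_sizes[key] = Z.shape[1]
            offset += Z.shape[1]
            blocks.append(Z)
        self.dim = offset
        self.W = sp.hstack(blocks, format="csr")
        y = mats.y
        self.trial_rows = [mats.trial_of_obs == ti for ti in range(self.p)]
        self.A: list[sp.csc_matrix] = []
        self.b: list[np.ndarray] = []
        self.yy: list[float] = []
        self.n_t: list[int] = []
        for ti in range(self.p):
            Wt = self.W[self.trial_rows[ti]]
            At = (Wt.T @ Wt).tocsc()
            At.sort_indices()
            self.A.append(At)
            self.b.append(Wt.T @ y[self.trial_rows[ti]])
            self.yy.append(float(y[self.trial_rows[ti]] @ y[self.trial_rows[ti]]))
            self.n_t.append(int(self.trial_rows[ti].sum()))
        self.n = int(sum(self.n_t))

        self._build_genetic_index()
        self._build_ginv_structure()
        self._build_union()
        self.backend = "splu"
        if self._try_schur_symbolic(dense_limit, absorb_max_level, max_cluster):
            self.backend = "schur"

    # ------------------------------------------------------------------
    # structure
    # ------------------------------------------------------------------

    def _build_genetic_index(self) -> None:
        mats = self.mats
        pairs = mats.shared_pairs()
        self.pair_i1 = np.array([i for i, _ in pairs], dtype=np.int64)
        self.pair_i2 = np.array([j for _, j in pairs], dtype=np.int64)
        self.use_cov = self.mats.spec.covariance and len(self.pair_i1) > 0
        in_pair = np.zeros(self.m_total, dtype=bool)
        if self.use_cov:
            in_pair[self.pair_i1] = True
            in_pair[self.pair_i2] = True
        trial_of_g = np.array([self.trials.index(t) for t, _ in mats.g_labels])
        self.single_g = {
            t: np.flatnonzero((trial_of_g == ti) & ~in_pair)
            for ti, t in enumerate(self.trials)
        }

    def _build_ginv_structure(self) -> None:
        """Fixed slot layout for G^-1 values and the matching CSC pattern."""
        off = self.g_offset
        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []
        if self.use_cov:
            i1, i2 = off + self.pair_i1, off + self.pair_i2
            rows += [i1, i2, i1, i2]
            cols += [i1, i2, i2, i1]
        for t in self.trials:
            idx = off + self.single_g[t]
            rows.append(idx)
            cols.append(idx)
        self._term_ranges: dict[tuple[str, str], np.ndarray] = {}
        for key in self.term_keys:
            o = self.term_offsets[key]
            idx = np.arange(o, o + self.term_sizes[key])
            self._term_ranges[key] = idx
            rows.append(idx)
            cols.append(idx)
        r = np.concatenate(rows) if rows else np.array([], dtype=np.int64)
        c = np.concatenate(cols) if cols else np.array([], dtype=np.int64)
        self._ginv_nslots = len(r)
        pat = sp.coo_matrix(
            (np.arange(1, len(r) + 1, dtype=np.float64), (r, c)),
            shape=(self.dim, self.dim),
        ).tocsc()
        pat.sort_indices()
        self._ginv_perm = pat.data.astype(np.int64) - 1  # slot -> csc position
        self._ginv_pat = pat

    def _ginv_values(self, params: VarianceParams) -> tuple[np.ndarray, float]:
        """Slot-ordered G^-1 values and log|G|."""
        vals = np.empty(self._ginv_nslots)
        logdet_g = 0.0
        pos = 0
        if self.use_cov:
            t1, t2 = self.trials[:2]
            v1, v2 = params.g_var[t1], params.g_var[t2]
            c = params.rho * np.sqrt(v1 * v2)
            det = v1 * v2 - c * c
            if det <= 0:
                raise NotPositiveDefiniteError("genetic matrix not positive definite")
            k = len(self.pair_i1)
            vals[pos : pos + k] = v2 / det
            vals[pos + k : pos + 2 * k] = v1 / det
            vals[pos + 2 * k : pos + 4 * k] = -c / det
            pos += 4 * k
            logdet_g += k * float(np.log(det))
        for t in self.trials:
            k = len(self.single_g[t])
            v = params.g_var[t]
            vals[pos : pos + k] = 1.0 / v
            pos += k
            logdet_g += k * float(np.log(v))
        for key in self.term_keys:
            k = self.term_sizes[key]
            v = params.term_var[key]
            vals[pos : pos + k] = 1.0 / v
            pos += k
            logdet_g += k * float(np.log(v))
        return vals, logdet_g

    def _build_union(self) -> None:
        pat = sp.csc_matrix(
            (np.ones(self._ginv_pat.nnz), self._ginv_pat.indices, self._ginv_pat.indptr),
            shape=(self.dim, self.dim),
        )
        U = pat + sp.identity(self.dim, format="csc")
        for At in self.A:
            U = U + At
        U = U.tocsc()
        U.sort_indices()
        U.data[:] = 1.0
        self.U = U
        self._mapA = [_csc_subset_map(At, U) for At in self.A]
        self._mapG = _csc_subset_map(self._ginv_pat, U)

    def _assemble(self, params: VarianceParams):
        """dataU for C plus the scalar pieces of the likelihood."""
        r = [params.resid[t] for t in self.trials]
        dataU = np.zeros(self.U.nnz)
        rhs = np.zeros(self.dim)
        yry = 0.0
        log_r = 0.0
        for ti in range(self.p):
            np.add.at(dataU, self._mapA[ti], self.A[ti].data / r[ti])
            rhs += self.b[ti] / r[ti]
            yry += self.yy[ti] / r[ti]
            log_r += self.n_t[ti] * np.log(r[ti])
        gvals, logdet_g = self._ginv_values(params)
        np.add.at(dataU, self._mapG, gvals[self._ginv_perm])
        return dataU, rhs, yry, log_r, logdet_g, r

    # ------------------------------------------------------------------
    # schur backend: symbolic analysis
    # ------------------------------------------------------------------

    def _upos(self, i: int, j: int) -> int:
        lo, hi = self.U.indptr[j], self.U.indptr[j + 1]
        k = np.searchsorted(self.U.indices[lo:hi], i)
        if k < hi - lo and self.U.indices[lo + k] == i:
            return int(lo + k)
        return -1

    def _try_schur_symbolic(
        self, dense_limit: int, absorb_max_level: int, max_cluster: int
    ) -> bool:
        level_counts = {}
        for key in self.term_keys:
            Z = self.mats.Z_terms[key]
            level_counts[key] = np.asarray(Z.sum(axis=0)).ravel()
        absorbable = sorted(
            (
                key
                for key in self.term_keys
                if level_counts[key].size and level_counts[key].max() <= absorb_max_level
            ),
            key=lambda k: float(level_counts[k].max()),
        )
        # percolating terms defeat the purpose: drop the coarsest ones until
        # the absorbed sub-graph splits into small clusters
        while True:
            in_a = np.zeros(self.dim, dtype=bool)
            for key in absorbable:
                in_a[self._term_ranges[key]] = True
            a_glob_all = np.flatnonzero(in_a)
            s_glob = np.flatnonzero(~in_a)
            if len(s_glob) > dense_limit:
                return False
            if len(a_glob_all) == 0:
                a_glob = a_glob_all
                sizes_sorted = np.array([], dtype=np.int64)
                break
            Uaa = self.U[np.ix_(a_glob_all, a_glob_all)].tocsr()
            ncomp, labels = connected_components(Uaa, directed=False)
            comp_sizes = np.bincount(labels)
            if comp_sizes.max() > max_cluster:
                absorbable.pop()
                continue
            # order clusters by size so blocks batch into (n, k, k) groups
            cluster_order = np.argsort(comp_sizes, kind="stable")
            rank = np.empty(ncomp, dtype=np.int64)
            rank[cluster_order] = np.arange(ncomp)
            order = np.lexsort((np.arange(len(a_glob_all)), rank[labels]))
            a_glob = a_glob_all[order]
            sizes_sorted = comp_sizes[cluster_order]
            break

        self._a_glob = a_glob
        self._s_glob = s_glob
        na, ns = len(a_glob), len(s_glob)
        pos = np.full(self.dim, -1, dtype=np.int64)
        pos[a_glob] = np.arange(na)
        s_pos = np.full(self.dim, -1, dtype=np.int64)
        s_pos[s_glob] = np.arange(ns)
        self._a_pos, self._s_pos = pos, s_pos

        # batched block gather indices per cluster size
        self._block_groups: list[tuple[int, np.ndarray]] = []  # (k, (n,k,k) dataU idx)
        self._block_diag_order: list[np.ndarray] = []
        lo = 0
        for k in np.unique(sizes_sorted):
            members = np.flatnonzero(sizes_sorted == k)
            nk = len(members)
            span = nk * k
            a_local = np.arange(lo, lo + span).reshape(nk, k)
            gidx = a_glob[a_local]
            bidx = np.full((nk, k, k), -1, dtype=np.int64)
            for bi in range(nk):
                for ii in range(int(k)):
                    for jj in range(int(k)):
                        bidx[bi, ii, jj] = self._upos(gidx[bi, ii], gidx[bi, jj])
            self._block_groups.append((int(k), bidx))
            lo += span
        # coo structure of the block-diagonal Caa^-1 (values supplied per eval)
        br, bc = [], []
        lo = 0
        for k, bidx in self._block_groups:
            nk = bidx.shape[0]
            base = lo + np.arange(nk)[:, None, None] * k
            ii = np.arange(k)
            br.append(np.broadcast_to(base + ii[None, :, None], (nk, k, k)).ravel())
            bc.append(np.broadcast_to(base + ii[None, None, :], (nk, k, k)).ravel())
            lo += nk * k
        self._blk_rows = np.concatenate(br) if br else np.array([], dtype=np.int64)
        self._blk_cols = np.concatenate(bc) if bc else np.array([], dtype=np.int64)

        # classify union entries into Cas and Css
        Ucoo = self.U.tocoo()  # keeps csc data order, so positions are 0..nnz-1
        ra, ca = pos[Ucoo.row], pos[Ucoo.col]
        rs, cs = s_pos[Ucoo.row], s_pos[Ucoo.col]
        upos_all = np.arange(self.U.nnz, dtype=np.int64)
        as_mask = (ra >= 0) & (cs >= 0)
        ss_mask = (rs >= 0) & (cs >= 0)
        self._css_r, self._css_c = rs[ss_mask], cs[ss_mask]
        self._css_upos = upos_all[ss_mask]
        cas = sp.coo_matrix(
            (upos_all[as_mask].astype(np.float64) + 1.0, (ra[as_mask], cs[as_mask])),
            shape=(na, ns),
        ).tocsr()
        cas.sort_indices()
        self._cas_upos = cas.data.astype(np.int64) - 1
        self._cas_indices = cas.indices
        self._cas_indptr = cas.indptr
        self._na, self._ns = na, ns

        # local views of genetic and term indices (all in s)
        self._g_local = s_pos[self.g_offset + np.arange(self.m_total)]
        if np.any(self._g_local < 0):
            return False
        self._term_local: dict[tuple[str, str], tuple[str, np.ndarray]] = {}
        for key in self.term_keys:
            idx = self._term_ranges[key]
            if in_a[idx[0]]:
                self._term_local[key] = ("a", pos[idx])
            else:
                self._term_local[key] = ("s", s_pos[idx])

        # per-trial split of A_t for the residual-gradient traces
        self._A_split = []
        for At in self.A:
            coo = At.tocoo()
            ra_t, ca_t = pos[coo.row], pos[coo.col]
            rs_t, cs_t = s_pos[coo.row], s_pos[coo.col]
            aa = (ra_t >= 0) & (ca_t >= 0)
            asx = (ra_t >= 0) & (cs_t >= 0)
            ssx = (rs_t >= 0) & (cs_t >= 0)
            A_aa = sp.csr_matrix(
                (coo.data[aa], (ra_t[aa], ca_t[aa])), shape=(na, na)
            )
            A_as = sp.coo_matrix(
                (coo.data[asx], (ra_t[asx], cs_t[asx])), shape=(na, ns)
            )
            self._A_split.append(
                {
                    "aa": A_aa,
                    "as_r": ra_t[asx],
                    "as_c": cs_t[asx],
                    "as_v": coo.data[asx],
                    "ss_r": rs_t[ssx],
                    "ss_c": cs_t[ssx],
                    "ss_v": coo.data[ssx],
                }
            )
        return True

    # ------------------------------------------------------------------
    # schur backend: numeric
    # ------------------------------------------------------------------

    def _eval_schur(self, params: VarianceParams, need_grad: bool, need_pev: bool):
        dataU, rhs, yry, log_r, logdet_g, r = self._assemble(params)
        na, ns = self._na, self._ns

        # Caa block inverses and log-determinant
        inv_groups = []
        logdet_caa = 0.0
        blk_data = []
        diag_a = []
        for k, bidx in self._block_groups:
            Bv = np.where(bidx >= 0, dataU[np.maximum(bidx, 0)], 0.0)
            try:
                L = np.linalg.cholesky(Bv)
            except np.linalg.LinAlgError as exc:
                raise NotPositiveDefiniteError("absorbed block not PD") from exc
            logdet_caa += 2.0 * float(np.sum(np.log(np.einsum("nii->ni", L))))
            Binv = np.linalg.inv(Bv)
            inv_groups.append(Binv)
            blk_data.append(Binv.reshape(-1))
            diag_a.append(np.einsum("nii->ni", Binv).ravel())
        if blk_data:
            Cinv_aa = sp.coo_matrix(
                (np.concatenate(blk_data), (self._blk_rows, self._blk_cols)),
                shape=(na, na),
            ).tocsr()
            diag_caainv = np.concatenate(diag_a)
        else:
            Cinv_aa = sp.csr_matrix((na, na))
            diag_caainv = np.array([])

        Cas = sp.csr_matrix(
            (dataU[self._cas_upos], self._cas_indices, self._cas_indptr), shape=(na, ns)
        )
        Wmat = Cinv_aa @ Cas  # Caa^-1 Cas
        S = np.zeros((ns, ns))
        S[self._css_r, self._css_c] = dataU[self._css_upos]
        if na:
            S -= (Cas.T @ Wmat).toarray()
        S = 0.5 * (S + S.T)
        try:
            cho = sla.cho_factor(S, lower=True, check_finite=False)
        except sla.LinAlgError as exc:
            raise NotPositiveDefiniteError("Schur complement not PD") from exc
        logdet_s = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))

        rhs_a, rhs_s = rhs[self._a_glob], rhs[self._s_glob]
        u = Cinv_aa @ rhs_a
        xs = sla.cho_solve(cho, rhs_s - Cas.T @ u, check_finite=False)
        xa = u - Wmat @ xs
        sol = np.empty(self.dim)
        sol[self._a_glob] = xa
        sol[self._s_glob] = xs

        ypy = yry - float(rhs_a @ xa) - float(rhs_s @ xs)
        ll = (
            -0.5 * (log_r + logdet_g + logdet_caa + logdet_s + ypy)
            - 0.5 * (self.n - self.p) * _LOG2PI
        )
        out = {"loglik": float(ll), "solution": sol}

        if not (need_grad or need_pev):
            return out

        # inverse of S from its Cholesky factor (dpotri fills one triangle)
        Sinv, info = dpotri(cho[0], lower=True)
        if info != 0:
            raise NotPositiveDefiniteError("dpotri failed")
        Sinv = np.tril(Sinv) + np.tril(Sinv, -1).T

        if need_pev:
            out["pev_gg"] = Sinv[np.ix_(self._g_local, self._g_local)]
        if not need_grad:
            return out

        T = np.asarray((Wmat @ Sinv)) if na else np.zeros((0, ns))
        diag_z = np.empty(self.dim)
        diag_z[self._s_glob] = np.diag(Sinv)
        if na:
            Wcoo = Wmat.tocoo()
            corr = np.bincount(Wcoo.row, weights=Wcoo.data * T[Wcoo.row, Wcoo.col], minlength=na)
            diag_z[self._a_glob] = diag_caainv + corr
        out["diag_z"] = diag_z
        out["grad"] = self._gradient(params, sol, diag_z, Sinv, T, Cinv_aa, Wmat, r)
        return out

    def _gradient(self, params, sol, diag_z, Sinv, T, Cinv_aa, Wmat, r):
        """Exact REML gradient w.r.t. the natural parameters, to_vector order."""
        grad: list[float] = []
        # genetic variances (and correlation) --------------------------------
        g_hat = sol[self.g_offset : self.g_offset + self.m_total]
        diag_zg = diag_z[self.g_offset : self.g_offset + self.m_total]
        d_gvar = {t: 0.0 for t in self.trials}
        d_rho = 0.0
        for t in self.trials:
            idx = self.single_g[t]
            if len(idx) == 0:
                continue
            v = params.g_var[t]
            tr_z = float(np.sum(diag_zg[idx]))
            uu = float(np.sum(g_hat[idx] ** 2))
            d_gvar[t] += -0.5 * ((len(idx) - tr_z / v) / v - uu / v**2)
        if self.use_cov:
            t1, t2 = self.trials[:2]
            v1, v2 = params.g_var[t1], params.g_var[t2]
            rho = params.rho
            c = rho * np.sqrt(v1 * v2)
            det = v1 * v2 - c * c
            Ginvb = np.array([[v2, -c], [-c, v1]]) / det
            l1, l2 = self._g_local[self.pair_i1], self._g_local[self.pair_i2]
            Zb = np.empty((len(l1), 2, 2))
            Zb[:, 0, 0] = Sinv[l1, l1]
            Zb[:, 1, 1] = Sinv[l2, l2]
            Zb[:, 0, 1] = Zb[:, 1, 0] = Sinv[l1, l2]
            H = Ginvb[None] - np.einsum("ij,njk,kl->nil", Ginvb, Zb, Ginvb)
            gp = np.stack([g_hat[self.pair_i1], g_hat[self.pair_i2]], axis=1)
            q = gp @ Ginvb  # Ginvb symmetric
            dc1, dc2 = c / (2 * v1), c / (2 * v2)
            s12 = np.sqrt(v1 * v2)
            for name, B in (
                (t1, np.array([[1.0, dc1], [dc1, 0.0]])),
                (t2, np.array([[0.0, dc2], [dc2, 1.0]])),
                ("rho", np.array([[0.0, s12], [s12, 0.0]])),
            ):
                tr_term = float(np.einsum("nij,ji->", H, B))
                quad = float(np.einsum("ni,ij,nj->", q, B, q))
                val = -0.5 * (tr_term - quad)
                if name == "rho":
                    d_rho = val
                else:
                    d_gvar[name] += val
        for t in self.trials:
            grad.append(d_gvar[t])
        if self.mats.spec.covariance:
            grad.append(d_rho)
        # independent random terms -------------------------------------------
        for key in self.term_keys:
            o = self.term_offsets[key]
            k = self.term_sizes[key]
            v = params.term_var[key]
            tr_z = float(np.sum(diag_z[o : o + k]))
            uu = float(np.sum(sol[o : o + k] ** 2))
            grad.append(-0.5 * ((k - tr_z / v) / v - uu / v**2))
        # residual variances --------------------------------------------------
        e = self.mats.y - self.W @ sol
        for ti, t in enumerate(self.trials):
            trZA = self._trace_za(self._A_split[ti], Sinv, T, Cinv_aa, Wmat)
            rt = r[ti]
            et = e[self.trial_rows[ti]]
            ee = float(et @ et)
            grad.append(-0.5 * ((self.n_t[ti] - trZA / rt) / rt - ee / rt**2))
        return np.array(grad)

    def _trace_za(self, split, Sinv, T, Cinv_aa, Wmat) -> float:
        """tr(C^-1 A_t) decomposed over the absorbed/dense partition.

        Uses C^-1 = [[Caa^-1 + W S^-1 W', -W S^-1], [-S^-1 W', S^-1]] with
        W = Caa^-1 Cas, so the trace needs only pattern gathers and one
        sparse product per trial.
        """
        total = 0.0
        if len(split["ss_v"]):
            total += float(np.sum(split["ss_v"] * Sinv[split["ss_r"], split["ss_c"]]))
        if self._na == 0:
            return total
        if split["aa"].nnz:
            total += float(Cinv_aa.multiply(split["aa"]).sum())
            AaW = (split["aa"] @ Wmat).tocoo()  # tr(W S^-1 W' A_aa) = sum (A_aa W) o T
            total += float(np.sum(AaW.data * T[AaW.row, AaW.col]))
        if len(split["as_v"]):
            total += -2.0 * float(np.sum(split["as_v"] * T[split["as_r"], split["as_c"]]))
        return total

    # ------------------------------------------------------------------
    # splu backend
    # ------------------------------------------------------------------

    def _eval_splu(self, params: VarianceParams, need_pev: bool):
        dataU, rhs, yry, log_r, logdet_g, r = self._assemble(params)
        C = sp.csc_matrix((dataU, self.U.indices, self.U.indptr), shape=(self.dim, self.dim))
        try:
            lu = splu(
                C,
                permc_spec="MMD_AT_PLUS_A",
                diag_pivot_thresh=0.001,
                options={"SymmetricMode": True},
            )
        except RuntimeError as exc:
            raise NotPositiveDefiniteError(str(exc)) from exc
        diag_u = lu.U.diagonal()
        if np.any(diag_u == 0) or not np.all(np.isfinite(diag_u)):
            raise NotPositiveDefiniteError("singular mixed-model equations")
        logdet_c = float(np.sum(np.log(np.abs(diag_u))))
        sol = lu.solve(rhs)
        ypy = yry - float(rhs @ sol)
        ll = -0.5 * (log_r + logdet_g + logdet_c + ypy) - 0.5 * (self.n - self.p) * _LOG2PI
        out = {"loglik": float(ll), "solution": sol}
        if need_pev:
            out["pev_gg"] = self._pev_splu(lu)
        return out

    def _pev_splu(self, lu, chunk: int = 256) -> np.ndarray:
        m = self.m_total
        pev = np.empty((m, m))
        for lo in range(0, m, chunk):
            hi = min(lo + chunk, m)
            E = np.zeros((self.dim, hi - lo))
            E[self.g_offset + lo : self.g_offset + hi, :] = np.eye(hi - lo)
            X = lu.solve(E)
            pev[:, lo:hi] = X[self.g_offset : self.g_offset + m, :]
        return 0.5 * (pev + pev.T)

    # ------------------------------------------------------------------
    # public interface
    # ------------------------------------------------------------------

    @property
    def has_gradient(self) -> bool:
        return self.backend == "schur"

    def loglik(self, params: VarianceParams) -> float:
        if self.backend == "schur":
            return self._eval_schur(params, need_grad=False, need_pev=False)["loglik"]
        return self._eval_splu(params, need_pev=False)["loglik"]

    def loglik_grad(self, params: VarianceParams) -> tuple[float, np.ndarray]:
        """Log likelihood and its exact gradient (natural scale, vector order)."""
        if self.backend != "schur":
            raise NotImplementedError("analytic gradient requires the schur backend")
        out = self._eval_schur(params, need_grad=True, need_pev=False)
        return out["loglik"], out["grad"]

    def factorize(self, params: VarianceParams, need_pev: bool = True) -> _Factorisation:
        if self.backend == "schur":
            out = self._eval_schur(params, need_grad=False, need_pev=need_pev)
        else:
            out = self._eval_splu(params, need_pev=need_pev)
        return _Factorisation(
            loglik=out["loglik"], solution=out["solution"], pev_gg=out.get("pev_gg")
        )


def reml_loglik(params: VarianceParams, mats: DesignMatrices, y=None) -> float:
    """REML log likelihood (sparse mixed-model-equations path).

    ``y`` is accepted for signature compatibility; the response is taken
    from ``mats`` and must match if supplied.
    """
    if y is not None and not np.array_equal(np.asarray(y, float), mats.y):
        raise ValueError("y does not match the response stored in the matrices")
    return REMLWorkspace(mats).loglik(params)


def genetic_cov_dense(params: VarianceParams, mats: DesignMatrices) -> np.ndarray:
    """Dense genetic covariance matrix over the cultivar-by-trial labels."""
    m = len(mats.g_labels)
    G = np.zeros((m, m))
    for i, (t, _) in enumerate(mats.g_labels):
        G[i, i] = params.g_var[t]
    if params.rho is not None:
        t1, t2 = mats.trials[:2]
        c = params.rho * np.sqrt(params.g_var[t1] * params.g_var[t2])
        for i, j in mats.shared_pairs():
            G[i, j] = G[j, i] = c
    return G


def reml_loglik_dense(params: VarianceParams, mats: DesignMatrices, y=None) -> float:
    """Direct dense REML formula; oracle for the sparse backends (small n)."""
    y = mats.y if y is None else np.asarray(y, float)
    n = len(y)
    if n > 4000:
        raise ValueError("dense path is for small instances only")
    X = mats.X.toarray()
    p = X.shape[1]
    r_obs = np.array([params.resid[mats.trials[t]] for t in mats.trial_of_obs])
    V = np.diag(r_obs)
    Zg = mats.Zg.toarray()
    V += Zg @ genetic_cov_dense(params, mats) @ Zg.T
    for key, Z in mats.Z_terms.items():
        Zd = Z.toarray()
        V += params.term_var[key] * (Zd @ Zd.T)
    sign, logdet_v = np.linalg.slogdet(V)
    if sign <= 0:
        raise NotPositiveDefiniteError("V not positive definite")
    Vinv = np.linalg.inv(V)
    XtVinvX = X.T @ Vinv @ X
    sign2, logdet_x = np.linalg.slogdet(XtVinvX)
    if sign2 <= 0:
        raise NotPositiveDefiniteError("X'V^-1X not positive definite")
    Viy = Vinv @ y
    beta = np.linalg.solve(XtVinvX, X.T @ Viy)
    Py = Viy - Vinv @ (X @ beta)
    ypy = float(y @ Py)
    return float(-0.5 * (logdet_v + logdet_x + ypy) - 0.5 * (n - p) * _LOG2PI)
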