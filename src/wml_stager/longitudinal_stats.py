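"""REML linear mixed models with an unstructured within-subject covariance.

The repeated-measures model for outcome ``y_ij`` of subject ``i`` at visit
``j`` (years 0..3, coded as a categorical factor with sum-to-zero contrasts):

    y_ij = b0 + b_v * log(V_i + eps) + sum_t b_t 1[j=t]
           + sum_t b_vt * log(V_i + eps) * 1[j=t]
           + b_age * age_i + b_sex * sex_i + b_edu * edu_i
           (+ b_f * log(V_FLAIR_i + eps))  + e_ij

with the per-subject residual vector ``e_i ~ N(0, Sigma)``, ``Sigma`` a free
symmetric positive-definite 4x4 matrix, subsetted to the observed visits of
incomplete subjects.  ``Sigma`` is estimated by restricted maximum
likelihood over its log-Cholesky factor (positive-definiteness by
construction) with analytic gradients; fixed effects are the GLS solution at
the optimum.  Denominator degrees of freedom use the Satterthwaite
approximation (switchable to residual df).

With sum-to-zero time contrasts the volume main effect is the
average-over-visits effect, the volume-by-time interaction is a 3-df test,
and per-year volume effects are linear contrasts whose mean over the four
years equals the main effect.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

DEFAULT_OUTCOMES = (
    "mmse_total", "vadas_total",
    "compound_speed", "compound_executive", "compound_memory",
)
DEFAULT_PREDICTORS = ("V_DC33", "V_DC66", "V_DC100")


@dataclass
class ModelSpec:
    """One mixed-model configuration (outcome, predictor, adjustments)."""

    outcome: str = "compound_executive"
    predictor: str = "V_DC33"
    covariates: tuple = ("age_baseline", "sex", "education")
    adjust_vflair: bool = False
    vflair_column: str = "V_FLAIR"
    epsilon_log: float = 0.024  # one 2x2x6 mm voxel in cm^3
    n_visits: int = 4
    ddf_method: str = "satterthwaite"  # or "residual"
    predictor_is_log: bool = False  # set True if the column is already a log volume


def log_transform_volume(v, epsilon_log: float = 0.024):
    """Natural log of (volume + epsilon); the floor is one voxel volume."""
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("volumes must be nonnegative")
    return np.log(v + epsilon_log)


def _sum_to_zero(t, k, ref):
    """Sum-to-zero contrast column k evaluated at time level t."""
    return (t == k).astype(float) - (t == ref).astype(float)


@dataclass
class MixedModelResult:
    fixed_effects: pd.DataFrame
    sigma_hat: np.ndarray
    reml_loglik: float
    converged: bool
    n_subjects: int
    n_observations: int
    spec: ModelSpec
    tests: dict = field(default_factory=dict)
    per_year: Optional[pd.DataFrame] = None
    message: str = ""
    # internals for contrast tests
    beta: np.ndarray = None
    cov_beta: np.ndarray = None
    theta: np.ndarray = None
    var_theta: np.ndarray = None
    column_names: list = None
    column_index: dict = None
    observed_years: tuple = ()
    _vsv: np.ndarray = None  # (q, p, p) dCov(beta)/dtheta_k at the optimum
    _kr: dict = None         # Kenward-Roger small-sample quantities


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def build_design(data: pd.DataFrame, spec: ModelSpec):
    """Assemble the fixed-effects design from a subject-visit table.

    The predictor enters as the subject's baseline value, log-transformed
    with the epsilon floor.  Rows with a missing outcome or covariate are
    dropped; subjects keep whatever visits remain (the unstructured
    covariance is subsetted per subject).
    """
    df = data.copy()
    required = [spec.outcome, spec.predictor, "subject_id", "visit_year",
                *spec.covariates]
    if spec.adjust_vflair:
        required.append(spec.vflair_column)
    for col in required:
        if col not in df.columns:
            raise ValueError(f"column {col!r} missing from data")

    # baseline (first-visit) volume per subject, constant across rows
    def _baseline_value(col):
        base = (
            df.sort_values("visit_year")
            .groupby("subject_id")[col]
            .first()
        )
        return df["subject_id"].map(base)

    vol = _baseline_value(spec.predictor)
    logv = vol if spec.predictor_is_log else log_transform_volume(vol, spec.epsilon_log)
    df["_logv"] = logv
    if spec.adjust_vflair:
        df["_logvf"] = log_transform_volume(
            _baseline_value(spec.vflair_column), spec.epsilon_log
        )

    if df["sex"].dtype == object:
        df["_sex"] = df["sex"].map({"M": 1.0, "F": 0.0})
    else:
        df["_sex"] = df["sex"].astype(float)

    cov_cols = ["_logv", "age_baseline", "_sex", "education"]
    if spec.adjust_vflair:
        cov_cols.append("_logvf")
    keep = df[spec.outcome].notna()
    for c in cov_cols:
        keep &= df[c].notna()
    df = df[keep]
    if df.empty:
        raise ValueError("no complete observations")

    t = df["visit_year"].to_numpy(dtype=int)
    if t.min() < 0 or t.max() >= spec.n_visits:
        raise ValueError("visit_year outside the modelled range")
    ref = spec.n_visits - 1
    ncon = spec.n_visits - 1
    names = ["intercept", "log_volume"]
    cols = [np.ones(len(df)), df["_logv"].to_numpy()]
    for k in range(ncon):
        cols.append(_sum_to_zero(t, k, ref))
        names.append(f"time_s{k}")
    for k in range(ncon):
        cols.append(df["_logv"].to_numpy() * _sum_to_zero(t, k, ref))
        names.append(f"log_volume:time_s{k}")
    cols += [
        df["age_baseline"].to_numpy(float),
        df["_sex"].to_numpy(float),
        df["education"].to_numpy(float),
    ]
    names += ["age", "sex_male", "education"]
    if spec.adjust_vflair:
        cols.append(df["_logvf"].to_numpy())
        names.append("log_vflair")

    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design (constant or collinear predictor)")
    y = df[spec.outcome].to_numpy(float)
    return X, y, df["subject_id"].to_numpy(), t, names


def _pack_patterns(X, y, subjects, tidx):
    """Group subjects by their observed-visit pattern for vectorized REML."""
    _, subj_codes = np.unique(subjects, return_inverse=True)
    by_subject = {}
    for row, (s, t) in enumerate(zip(subj_codes, tidx)):
        by_subject.setdefault(s, []).append((t, row))
    patterns = {}
    for s, pairs in by_subject.items():
        pairs.sort()
        obs = tuple(t for t, _ in pairs)
        if len(set(obs)) != len(obs):
            raise ValueError("duplicate visit rows for one subject")
        rows = [r for _, r in pairs]
        patterns.setdefault(obs, []).append(rows)
    packed = []
    for obs, row_lists in patterns.items():
        idx = np.array(row_lists)  # (S, m)
        packed.append((np.array(obs), X[idx], y[idx]))
    return packed, len(by_subject)


# ---------------------------------------------------------------------------
# REML criterion
# ---------------------------------------------------------------------------

def _theta_size(n_visits, structure):
    return n_visits * (n_visits + 1) // 2 if structure == "unstructured" else 1


def _build_L(theta, n_visits, structure):
    if structure == "scaled_identity":
        return np.exp(theta[0]) * np.eye(n_visits)
    L = np.zeros((n_visits, n_visits))
    L[np.diag_indices(n_visits)] = np.exp(theta[:n_visits])
    L[np.tril_indices(n_visits, -1)] = theta[n_visits:]
    return L


def _dL_stack(theta, L, n_visits, structure):
    if structure == "scaled_identity":
        return L[None, :, :].copy()
    q = _theta_size(n_visits, structure)
    dL = np.zeros((q, n_visits, n_visits))
    for k in range(n_visits):
        dL[k, k, k] = L[k, k]
    rows, cols = np.tril_indices(n_visits, -1)
    for j, (r, c) in enumerate(zip(rows, cols)):
        dL[n_visits + j, r, c] = 1.0
    return dL


def _neg2_reml(theta, packed, p, N, n_visits, structure, want_internals=False):
    L = _build_L(theta, n_visits, structure)
    Sigma = L @ L.T
    dL = _dL_stack(theta, L, n_visits, structure)
    dSigma = np.einsum("qij,kj->qik", dL, L)
    dSigma = dSigma + dSigma.transpose(0, 2, 1)
    q = dSigma.shape[0]

    M = np.zeros((p, p))
    cvec = np.zeros(p)
    ytWy = 0.0
    logdet = 0.0
    cache = []
    for obs, Xs, ys in packed:
        So = Sigma[np.ix_(obs, obs)]
        cf = cho_factor(So, lower=True)
        A = cho_solve(cf, np.eye(len(obs)))
        logdet += Xs.shape[0] * 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        AX = np.einsum("mn,snp->smp", A, Xs)
        M += np.einsum("smp,smq->pq", Xs, AX)
        cvec += np.einsum("smp,sm->p", AX, ys)
        Ay = ys @ A
        ytWy += float(np.einsum("sm,sm->", Ay, ys))
        cache.append((obs, Xs, ys, A, AX, Ay))

    Mcf = cho_factor(M)
    beta = cho_solve(Mcf, cvec)
    logdet_M = 2.0 * float(np.sum(np.log(np.diag(Mcf[0]))))
    Q = ytWy - float(beta @ cvec)
    f = logdet + logdet_M + Q + (N - p) * np.log(2.0 * np.pi)

    Minv = cho_solve(Mcf, np.eye(p))
    grad = np.zeros(q)
    Sk_total = np.zeros((q, p, p)) if want_internals else None
    for obs, Xs, ys, A, AX, Ay in cache:
        D = dSigma[:, obs][:, :, obs]
        n_s = Xs.shape[0]
        grad += n_s * np.einsum("mn,qnm->q", A, D)
        U = Ay - np.einsum("smp,p->sm", AX, beta)
        grad -= np.einsum("sm,qmn,sn->q", U, D, U)
        # tr(Minv sum_s B' D B) via the per-subject projector B Minv B'
        BM = np.einsum("smp,pq->smq", AX, Minv)
        G = np.einsum("smq,snq->smn", BM, AX)
        grad -= np.einsum("qmn,snm->q", D, G)
        if want_internals:
            Sk_total += np.einsum("smp,qmn,snr->qpr", AX, D, AX)

    if want_internals:
        return f, grad, {
            "beta": beta, "cov_beta": Minv, "Sk": Sk_total, "Sigma": Sigma,
        }
    return f, grad


def _kr_inflate(theta, packed, p, n_visits, structure, var_theta, internals):
    """Kenward-Roger small-sample inflation of the coefficient covariance.

    The naive GLS covariance ``V = M^-1`` ignores the sampling variability of
    the REML covariance estimate and is anticonservative at moderate n.  In
    the covariance-entry parameterization the residual covariance is linear,
    so the adjustment reduces to

        V_A = V + 2 V [ sum_kl W_kl (Q_kl - S_k V S_l) ] V

    with ``S_k = X' W E_k W X``, ``Q_kl = X' W E_k W E_l W X`` (``E_k`` the
    symmetric basis matrix of entry k) and ``W_kl`` the asymptotic covariance
    of the entry estimates, mapped from the log-Cholesky parameters by the
    delta method.  Stored as ``internals['cov_beta_adjusted']``.
    """
    L = _build_L(theta, n_visits, structure)
    Sigma = L @ L.T
    dL = _dL_stack(theta, L, n_visits, structure)
    dSigma = np.einsum("qij,kj->qik", dL, L)
    dSigma = dSigma + dSigma.transpose(0, 2, 1)

    rows, cols = np.tril_indices(n_visits)
    qe = rows.size
    E = np.zeros((qe, n_visits, n_visits))
    for e, (i, j) in enumerate(zip(rows, cols)):
        E[e, i, j] = 1.0
        E[e, j, i] = 1.0
    # delta method: W = J var_theta J', J[e, k] = dSigma_k[i_e, j_e]
    J = dSigma[:, rows, cols].T  # (qe, q)
    Wcov = J @ var_theta @ J.T

    V = internals["cov_beta"]
    Se = np.zeros((qe, p, p))
    Q = np.zeros((qe, qe, p, p))
    for obs, Xs, ys in packed:
        So = Sigma[np.ix_(obs, obs)]
        A = np.linalg.inv(So)
        B = np.einsum("mn,snp->smp", A, Xs)
        Eo = E[:, obs][:, :, obs]
        T = np.einsum("kmn,snp->ksmp", Eo, B)  # E_k W X
        Se += np.einsum("smp,ksmq->kpq", B, T)
        AT = np.einsum("mn,ksnp->ksmp", A, T)  # W E_k W X
        Q += np.einsum("ksmp,lsmq->klpq", AT, T)
    Lam = np.einsum("kl,klpq->pq", Wcov, Q) - np.einsum(
        "kl,kpi,ij,ljq->pq", Wcov, Se, V, Se
    )
    internals["cov_beta_adjusted"] = V + 2.0 * V @ Lam @ V
    internals["kr"] = {"W": Wcov, "Se": Se, "V": V}


def _start_theta(X, y, subjects, tidx, n_visits, structure):
    """OLS residual covariance (pairwise complete) as the starting point."""
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    _, codes = np.unique(subjects, return_inverse=True)
    R = np.full((codes.max() + 1, n_visits), np.nan)
    R[codes, tidx] = resid
    S = np.empty((n_visits, n_visits))
    for i in range(n_visits):
        for j in range(n_visits):
            both = ~np.isnan(R[:, i]) & ~np.isnan(R[:, j])
            if both.sum() > 2:
                S[i, j] = np.mean(R[both, i] * R[both, j])
            else:
                S[i, j] = 0.0 if i != j else np.nanvar(resid) + 1e-3
    S = (S + S.T) / 2.0
    w, V = np.linalg.eigh(S)
    floor = max(1e-4 * float(np.max(w)), 1e-8)
    S = (V * np.maximum(w, floor)) @ V.T
    if structure == "scaled_identity":
        return np.array([0.5 * np.log(np.trace(S) / n_visits)])
    L = np.linalg.cholesky(S)
    theta = np.concatenate([
        np.log(np.diag(L)), L[np.tril_indices(n_visits, -1)]
    ])
    return theta


def _fd_hessian(fun_grad, theta, h=1e-5):
    q = theta.size
    H = np.zeros((q, q))
    for k in range(q):
        step = h * max(1.0, abs(theta[k]))
        tp = theta.copy(); tp[k] += step
        tm = theta.copy(); tm[k] -= step
        _, gp = fun_grad(tp)
        _, gm = fun_grad(tm)
        H[:, k] = (gp - gm) / (2.0 * step)
    return (H + H.T) / 2.0


def reml_fit(
    data: pd.DataFrame,
    spec: ModelSpec,
    structure: str = "unstructured",
    max_iter: int = 500,
) -> MixedModelResult:
    """Fit the mixed model by REML and return estimates plus diagnostics.

    Raises on singular designs; non-convergence is reported through the
    ``converged`` flag with the gradient norm in ``message``, never silently.
    """
    X, y, subjects, tidx, names = build_design(data, spec)
    packed, n_subjects = _pack_patterns(X, y, subjects, tidx)
    if n_subjects < 10:
        warnings.warn(
            f"only {n_subjects} subjects; the unstructured covariance may be "
            "weakly identified", stacklevel=2,
        )
    N, p = X.shape
    n_visits = spec.n_visits

    def fun_grad(theta):
        try:
            return _neg2_reml(theta, packed, p, N, n_visits, structure)
        except np.linalg.LinAlgError:
            # infeasible trial point (numerically singular covariance):
            # return a large value so the line search backs off
            return 1e12 * (1.0 + float(theta @ theta)), 2e12 * theta

    theta0 = _start_theta(X, y, subjects, tidx, n_visits, structure)
    q = theta0.size
    bounds = [(-10.0, 10.0)] * (n_visits if structure == "unstructured" else 1)
    bounds += [(-1e3, 1e3)] * (q - len(bounds))
    res = minimize(
        fun_grad, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10},
    )
    theta = res.x
    f_val, grad = fun_grad(theta)

    # Newton polish (the Hessian also feeds the Satterthwaite/KR df)
    H = _fd_hessian(fun_grad, theta)
    moved = False
    for _ in range(5):
        if np.max(np.abs(grad)) < 1e-10:
            break
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(q), grad)
        except np.linalg.LinAlgError:
            break
        trial = theta - step
        try:
            f_try, g_try = fun_grad(trial)
        except np.linalg.LinAlgError:
            break
        if f_try <= f_val:
            theta, f_val, grad = trial, f_try, g_try
            moved = True
        else:
            break
    if moved:
        H = _fd_hessian(fun_grad, theta)

    f_val, grad, internals = _neg2_reml(
        theta, packed, p, N, n_visits, structure, want_internals=True
    )
    _kr_inflate(theta, packed, p, n_visits, structure,
                2.0 * np.linalg.pinv(H), internals)
    gnorm = float(np.max(np.abs(grad)))
    converged = bool(gnorm < 1e-3 * max(1.0, abs(f_val)))
    var_theta = 2.0 * np.linalg.pinv(H)

    beta = internals["beta"]
    cov_beta = internals.get("cov_beta_adjusted", internals["cov_beta"])
    Sk = internals["Sk"]
    vsv = np.einsum("pi,kij,jq->kpq", cov_beta, Sk, cov_beta)

    result = MixedModelResult(
        fixed_effects=None,
        sigma_hat=internals["Sigma"],
        reml_loglik=-0.5 * f_val,
        converged=converged,
        n_subjects=n_subjects,
        n_observations=N,
        spec=spec,
        beta=beta,
        cov_beta=cov_beta,
        theta=theta,
        var_theta=var_theta,
        column_names=names,
        column_index={n: i for i, n in enumerate(names)},
        observed_years=tuple(sorted(set(int(t) for t in tidx))),
        message="" if converged else f"max |gradient| = {gnorm:.3g}",
        _vsv=vsv,
        _kr=internals.get("kr"),
    )
    result.fixed_effects = _fixed_effects_table(result)
    if not converged:
        logger.warning("REML fit flagged non-converged: %s", result.message)
    return result


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def _contrast_df(result: MixedModelResult, c: np.ndarray) -> float:
    """Satterthwaite denominator df for a single contrast."""
    if result.spec.ddf_method == "residual":
        return float(result.n_observations - len(result.beta))
    denom_var = float(c @ result.cov_beta @ c)
    g = np.einsum("p,kpq,q->k", c, result._vsv, c)
    den = float(g @ result.var_theta @ g)
    if den <= 0:
        return float(result.n_observations - len(result.beta))
    return 2.0 * denom_var**2 / den


def _f_test(result: MixedModelResult, C: np.ndarray) -> dict:
    """Multi-df Wald F test.

    Uses the Kenward-Roger scaled F with approximate denominator df when the
    small-sample quantities are available, otherwise the Satterthwaite
    eigencontrast combination; ``ddf_method='residual'`` falls back to the
    residual degrees of freedom.
    """
    C = np.atleast_2d(C)
    qc = C.shape[0]
    Phi = C @ result.cov_beta @ C.T
    Cb = C @ result.beta
    F = float(Cb @ np.linalg.solve(Phi, Cb)) / qc
    if result.spec.ddf_method == "residual":
        ddf = float(result.n_observations - len(result.beta))
        return {"F": F, "num_df": qc, "den_df": ddf,
                "p": float(stats.f.sf(F, qc, ddf))}
    kr = getattr(result, "_kr", None)
    if kr is not None:
        scale, ddf = _kr_scale_ddf(kr, C, qc)
        F_scaled = scale * F
        return {"F": F_scaled, "num_df": qc, "den_df": ddf,
                "p": float(stats.f.sf(F_scaled, qc, ddf))}
    w, U = np.linalg.eigh(Phi)
    nus = []
    for m in range(qc):
        c_t = C.T @ U[:, m]
        nus.append(_contrast_df(result, c_t))
    E = sum(nu / (nu - 2.0) for nu in nus if nu > 2.0)
    ddf = 2.0 * E / (E - qc) if E > qc else 1e7
    return {"F": F, "num_df": qc, "den_df": ddf,
            "p": float(stats.f.sf(F, qc, ddf))}


def _kr_scale_ddf(kr: dict, C: np.ndarray, qc: int):
    """Kenward-Roger F scale factor and denominator df for contrast rows C."""
    W, Se, V = kr["W"], kr["Se"], kr["V"]
    Theta = C.T @ np.linalg.solve(C @ V @ C.T, C)
    VSV = np.einsum("pi,kij,jq->kpq", V, Se, V)
    TV = np.einsum("pq,kqr->kpr", Theta, VSV)  # Theta V P_k V (sign-free)
    tvec = np.einsum("kpp->k", TV)
    A1 = float(tvec @ W @ tvec)
    A2 = float(np.einsum("kl,kpq,lqp->", W, TV, TV))
    q = float(qc)
    B = (A1 + 6.0 * A2) / (2.0 * q)
    g = ((q + 1.0) * A1 - (q + 4.0) * A2) / ((q + 2.0) * A2) if A2 > 0 else 0.0
    den = 3.0 * q + 2.0 * (1.0 - g)
    c1 = g / den
    c2 = (q - g) / den
    c3 = (q + 2.0 - g) / den
    Estar = 1.0 / (1.0 - A2 / q) if A2 < q else 1.0
    Vstar = (2.0 / q) * (1.0 + c1 * B) / ((1.0 - c2 * B) ** 2 * (1.0 - c3 * B))
    rho = Vstar / (2.0 * Estar**2)
    ddf = 4.0 + (q + 2.0) / (q * rho - 1.0) if q * rho > 1.0 else 1e7
    scale = ddf / (Estar * (ddf - 2.0)) if ddf > 2.0 else 1.0
    return scale, ddf


def _fixed_effects_table(result: MixedModelResult) -> pd.DataFrame:
    rows = []
    for i, name in enumerate(result.column_names):
        c = np.zeros(len(result.beta)); c[i] = 1.0
        se = float(np.sqrt(result.cov_beta[i, i]))
        df = _contrast_df(result, c)
        tval = result.beta[i] / se
        rows.append({
            "term": name, "estimate": float(result.beta[i]), "se": se,
            "t": float(tval), "df": df,
            "p": float(2.0 * stats.t.sf(abs(tval), df)),
        })
    return pd.DataFrame(rows)


def per_year_contrast(result: MixedModelResult, year: int) -> np.ndarray:
    """Contrast for the volume effect at a given visit year (sum-to-zero coding)."""
    spec = result.spec
    ref = spec.n_visits - 1
    c = np.zeros(len(result.beta))
    c[result.column_index["log_volume"]] = 1.0
    for k in range(spec.n_visits - 1):
        s = (1.0 if year == k else 0.0) - (1.0 if year == ref else 0.0)
        c[result.column_index[f"log_volume:time_s{k}"]] += s
    return c


def test_effects(result: MixedModelResult, spec: ModelSpec = None) -> MixedModelResult:
    """Populate the main-effect, volume-by-time, and per-year tests.

    The main effect is the average-over-visits volume effect (the
    ``log_volume`` coefficient under sum-to-zero coding, with the
    interaction present); the interaction is a joint F test of the
    ``log_volume:time`` terms.
    """
    spec = spec or result.spec
    ci = result.column_index
    p_dim = len(result.beta)

    c_main = np.zeros(p_dim); c_main[ci["log_volume"]] = 1.0
    result.tests["main_effect"] = _f_test(result, c_main[None, :])

    C_int = np.zeros((spec.n_visits - 1, p_dim))
    for k in range(spec.n_visits - 1):
        C_int[k, ci[f"log_volume:time_s{k}"]] = 1.0
    result.tests["volume_by_time"] = _f_test(result, C_int)

    rows = []
    for year in range(spec.n_visits):
        if year not in result.observed_years:
            raise ValueError(f"no observations at visit year {year}")
        c = per_year_contrast(result, year)
        est = float(c @ result.beta)
        se = float(np.sqrt(c @ result.cov_beta @ c))
        df = _contrast_df(result, c)
        tval = est / se
        rows.append({
            "year": year, "estimate": est, "se": se, "df": df,
            "t": tval, "p": float(2.0 * stats.t.sf(abs(tval), df)),
        })
    result.per_year = pd.DataFrame(rows)
    return result


def fit_unstructured_covariance(Y: np.ndarray, max_iter: int = 500) -> np.ndarray:
    """REML estimate of the residual covariance under saturated time means.

    ``Y`` is an (n_subjects x n_visits) complete outcome matrix; the fixed
    effects are one mean per visit and the within-subject covariance is
    unstructured.  Runs the same REML optimizer as :func:`reml_fit`.  (On
    balanced complete data the estimate coincides with the n-1-denominator
    sample covariance — a classical identity that doubles as a correctness
    check of the optimizer.)
    """
    Y = np.asarray(Y, dtype=float)
    n, m = Y.shape
    X = np.tile(np.eye(m), (n, 1))
    y = Y.reshape(-1)
    subjects = np.repeat(np.arange(n), m)
    tidx = np.tile(np.arange(m), n)
    packed, _ = _pack_patterns(X, y, subjects, tidx)

    def fun_grad(theta):
        try:
            return _neg2_reml(theta, packed, m, n * m, m, "unstructured")
        except np.linalg.LinAlgError:
            return 1e12 * (1.0 + float(theta @ theta)), 2e12 * theta

    theta = _start_theta(X, y, subjects, tidx, m, "unstructured")
    res = minimize(
        fun_grad, theta, jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-15, "gtol": 1e-12},
    )
    theta, (f_val, grad) = res.x, fun_grad(res.x)
    H = _fd_hessian(fun_grad, theta)
    for _ in range(8):
        if np.max(np.abs(grad)) < 1e-12:
            break
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(theta.size), grad)
            f_try, g_try = fun_grad(theta - step)
        except np.linalg.LinAlgError:
            break
        if f_try <= f_val:
            theta, f_val, grad = theta - step, f_try, g_try
        else:
            break
    L = _build_L(theta, m, "unstructured")
    return L @ L.T


def fit_and_test(data: pd.DataFrame, spec: ModelSpec, **kw) -> MixedModelResult:
    """Convenience: :func:`reml_fit` followed by :func:`test_effects`."""
    return test_effects(reml_fit(data, spec, **kw))


def run_model_grid(
    data: pd.DataFrame,
    predictors: Sequence[str] = DEFAULT_PREDICTORS,
    outcomes: Sequence[str] = DEFAULT_OUTCOMES,
    adjust_vflair: Sequence[bool] = (False, True),
    alpha: float = 0.05,
    base_spec: ModelSpec = None,
) -> pd.DataFrame:
    """Fit every predictor x outcome x adjustment cell, one model per cell.

    Failed fits are recorded (``error`` column) and the grid continues.  The
    output mirrors the main-effect / volume-by-time / per-year reporting
    layout at significance level ``alpha``.
    """
    rows = []
    for pred in predictors:
        for out in outcomes:
            for adj in adjust_vflair:
                base = base_spec or ModelSpec()
                spec = ModelSpec(
                    outcome=out, predictor=pred, adjust_vflair=bool(adj),
                    covariates=base.covariates, vflair_column=base.vflair_column,
                    epsilon_log=base.epsilon_log, n_visits=base.n_visits,
                    ddf_method=base.ddf_method,
                )
                row = {"predictor": pred, "outcome": out, "adjust_vflair": bool(adj)}
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        res = fit_and_test(data, spec)
                    row.update({
                        "converged": res.converged,
                        "main_F": res.tests["main_effect"]["F"],
                        "main_p": res.tests["main_effect"]["p"],
                        "main_sig": res.tests["main_effect"]["p"] < alpha,
                        "interaction_F": res.tests["volume_by_time"]["F"],
                        "interaction_p": res.tests["volume_by_time"]["p"],
                        "interaction_sig": res.tests["volume_by_time"]["p"] < alpha,
                        "error": "",
                    })
                    for _, yr in res.per_year.iterrows():
                        y = int(yr["year"])
                        row[f"year{y}_estimate"] = yr["estimate"]
                        row[f"year{y}_p"] = yr["p"]
                        row[f"year{y}_sig"] = yr["p"] < alpha
                except Exception as exc:  # failed cell: record and continue
                    row.update({"converged": False, "error": str(exc)})
                    logger.warning("grid cell %s failed: %s", row, exc)
                rows.append(row)
    return pd.DataFrame(rows)
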