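"""Environment-genotype association via spatially lagged autoregressive models.

Genotype scores G (typically sPCA principal components) are regressed on
standardized environmental predictors while absorbing inherent spatial
autocorrelation with a lag term:

    G = rho * W G + X beta + eps,   eps ~ N(0, sigma^2 I),

with W a row-standardized inverse-distance weights matrix. Estimation is by
maximum likelihood with the likelihood profiled in rho (the Jacobian term
log|I - rho W| uses the eigenvalues of W). All 2^5 subsets of the five
standard predictors (light availability DSF, soil anion PC, two soil cation
PCs, field capacity) are fitted; models within 2 AIC units of the best are
retained, their Akaike weights renormalized, and coefficients model-averaged
in the Burnham-Anderson sense with relative importance w+ per predictor.
Residual Moran's I checks that the lag term removed the autocorrelation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .data_model import EnvironmentTable
from .spca import ConnectionNetwork, moran_i

__all__ = [
    "EnvPredictors",
    "SarFit",
    "ModelAverage",
    "build_env_predictors",
    "sar_fit",
    "model_select_average",
    "PREDICTOR_NAMES",
]

PREDICTOR_NAMES = ("dsf", "anions", "cations1", "cations2", "field_capacity")


# ---------------------------------------------------------------------------
# environmental predictor construction
# ---------------------------------------------------------------------------

@dataclass
class EnvPredictors:
    """Standardized predictors: DSF, soil-ion PCs and field capacity."""

    data: pd.DataFrame                      # columns PREDICTOR_NAMES, mean 0 sd 1
    variance_explained: dict[str, float]
    loadings: dict[str, pd.DataFrame]
    ids: list[str] = field(default_factory=list)

    def matrix(self) -> np.ndarray:
        return self.data[list(PREDICTOR_NAMES)].to_numpy(float)


def _standardize(v: np.ndarray, name: str) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"variable {name!r} is constant; cannot standardize")
    return (v - v.mean()) / sd


def _pca_scores(Z: np.ndarray, names: list[str], n_keep: int
                ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Correlation-matrix PCA with deterministic sign anchoring."""
    R = np.corrcoef(Z, rowvar=False)
    vals, vecs = np.linalg.eigh(R)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    # anchor each component: the largest-|loading| variable loads positively
    for k in range(vecs.shape[1]):
        j = int(np.argmax(np.abs(vecs[:, k])))
        if vecs[j, k] < 0:
            vecs[:, k] = -vecs[:, k]
    scores = Z @ vecs[:, :n_keep]
    expl = vals / vals.sum()
    load = pd.DataFrame(vecs[:, :n_keep], index=names,
                        columns=[f"PC{k + 1}" for k in range(n_keep)])
    return scores, expl[:n_keep], load


def build_env_predictors(env: EnvironmentTable) -> EnvPredictors:
    """Reduce the raw covariates to the five standard predictors.

    Soil cations (Na, K, Mg) are condensed by a correlation-matrix PCA into
    cations1/cations2, anions (total N, total P) into a single anions PC;
    DSF and field capacity are standardized directly. All outputs are
    standardized to mean 0, SD 1. Rows with missing covariates must be
    removed by the caller first.
    """
    df = env.data
    need = ["dsf", "na", "k", "mg", "n_total", "p_total", "field_capacity"]
    if df[need].isna().any().any():
        bad = [c for c in need if df[c].isna().any()]
        raise ValueError(f"missing values in covariates {bad}; filter rows first")
    if len(df) < 3:
        raise ValueError("need at least 3 individuals with complete soil data")

    cat_names = ["na", "k", "mg"]
    Zc = np.column_stack([_standardize(df[c].to_numpy(float), c)
                          for c in cat_names])
    cat_scores, cat_expl, cat_load = _pca_scores(Zc, cat_names, 2)

    an_names = ["n_total", "p_total"]
    Za = np.column_stack([_standardize(df[c].to_numpy(float), c)
                          for c in an_names])
    an_scores, an_expl, an_load = _pca_scores(Za, an_names, 1)

    out = pd.DataFrame({
        "dsf": _standardize(df["dsf"].to_numpy(float), "dsf"),
        "anions": _standardize(an_scores[:, 0], "anions"),
        "cations1": _standardize(cat_scores[:, 0], "cations1"),
        "cations2": _standardize(cat_scores[:, 1], "cations2"),
        "field_capacity": _standardize(df["field_capacity"].to_numpy(float),
                                       "field_capacity"),
    })
    return EnvPredictors(
        data=out,
        variance_explained={"cations1": float(cat_expl[0]),
                            "cations2": float(cat_expl[1]),
                            "anions": float(an_expl[0])},
        loadings={"cations": cat_load, "anions": an_load},
        ids=df["individual_id"].astype(str).tolist(),
    )


# ---------------------------------------------------------------------------
# lagged SAR maximum likelihood
# ---------------------------------------------------------------------------

@dataclass
class SarFit:
    rho: float
    beta: np.ndarray           # intercept first, then predictors
    beta_se: np.ndarray
    sigma2: float
    loglik: float
    aic: float
    predictor_names: list[str]
    rho_se: float | None = None
    residuals: np.ndarray | None = None
    residual_moran_I: float | None = None
    residual_moran_p: float | None = None


def _w_eigenvalues(W: np.ndarray) -> np.ndarray:
    """Eigenvalues of W; complex pairs are kept for the log-determinant
    (asymmetric W such as k-nearest-neighbour weights has conjugate pairs,
    whose contributions log|1 - rho lambda| are real)."""
    return np.linalg.eigvals(W)


def sar_fit(G: np.ndarray, X: np.ndarray | None, net: ConnectionNetwork,
            predictor_names: list[str] | None = None,
            moran_perm: int = 0, rng: np.random.Generator | None = None
            ) -> SarFit:
    """Maximum-likelihood fit of the spatial lag model G = rho W G + X b + e.

    ``X`` holds the predictor columns without intercept (``None`` fits the
    intercept-only model). The likelihood is profiled in rho: for a trial
    rho, beta is the least-squares fit of (I - rho W) G on [1 X] and
    sigma^2 = RSS/n; the concentrated log-likelihood adds
    sum_i log(1 - rho lambda_i) over eigenvalues of W and is maximized by
    bounded scalar optimization inside rho's admissible interval. A zero W
    (no connectivity) degenerates exactly to OLS with rho = 0.
    """
    G = np.asarray(G, float).ravel()
    n = len(G)
    W = net.weights
    if W.shape != (n, n):
        raise ValueError("network size does not match response length")
    zero_W = not np.any(W)
    if not zero_W and net.style != "row":
        raise ValueError("SAR requires a row-standardized network (style='row')")
    if X is None:
        X1 = np.ones((n, 1))
        names = []
    else:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[0] != n:
            X = X.T
        X1 = np.column_stack([np.ones(n), X])
        names = predictor_names or [f"x{i + 1}" for i in range(X1.shape[1] - 1)]
    k_beta = X1.shape[1]
    if n <= k_beta + 1:
        raise ValueError("too few observations for the requested model")
    if np.linalg.matrix_rank(X1) < k_beta:
        raise ValueError("singular predictor matrix")

    XtX_inv = np.linalg.inv(X1.T @ X1)
    H = XtX_inv @ X1.T
    WG = W @ G

    def profile(rho: float) -> tuple[float, np.ndarray, float, np.ndarray]:
        y = G - rho * WG
        beta = H @ y
        resid = y - X1 @ beta
        rss = float(resid @ resid)
        sigma2 = rss / n
        ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet(rho)
        return ll, beta, sigma2, resid

    if zero_W:
        def logdet(rho: float) -> float:
            return 0.0
        rho_hat, rho_se = 0.0, None
        lo = hi = 0.0
    else:
        lam = _w_eigenvalues(W)
        lam_real = np.sort(lam[np.abs(lam.imag) < 1e-10].real)
        lo = 1.0 / lam_real[0] if len(lam_real) and lam_real[0] < 0 else -np.inf
        hi = 1.0 / lam_real[-1] if len(lam_real) and lam_real[-1] > 0 else np.inf
        lo = max(lo, -5.0) + 1e-8
        hi = min(hi, 5.0) - 1e-8

        def logdet(rho: float) -> float:
            return float(np.sum(np.log(np.maximum(np.abs(1.0 - rho * lam),
                                                  1e-300))))

        res = optimize.minimize_scalar(lambda r: -profile(r)[0],
                                       bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-8})
        rho_hat = float(res.x)
        # numeric curvature of the profile log-likelihood for a Wald-style SE
        h = max(1e-5, 1e-5 * (hi - lo))
        if lo < rho_hat - h and rho_hat + h < hi:
            d2 = (profile(rho_hat + h)[0] - 2 * profile(rho_hat)[0]
                  + profile(rho_hat - h)[0]) / h ** 2
            rho_se = float(np.sqrt(-1.0 / d2)) if d2 < 0 else None
        else:
            rho_se = None

    ll, beta, sigma2, resid = profile(rho_hat)
    beta_se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 0.0))
    k = k_beta + 2  # + rho + sigma^2
    aic = -2.0 * ll + 2.0 * k

    mi = mp = None
    if moran_perm > 0:
        mi, mp = moran_i(resid, net, n_perm=moran_perm, rng=rng)
    return SarFit(rho=rho_hat, beta=beta, beta_se=beta_se, sigma2=sigma2,
                  loglik=ll, aic=aic, predictor_names=names, rho_se=rho_se,
                  residuals=resid, residual_moran_I=mi, residual_moran_p=mp)


# ---------------------------------------------------------------------------
# all-subsets selection and model averaging
# ---------------------------------------------------------------------------

@dataclass
class ModelAverage:
    table: pd.DataFrame            # per predictor: estimate, se, w_plus
    rho_estimate: float
    rho_se: float
    selected_models: list[dict]
    all_models: list[dict]
    variant: str


def model_select_average(G: np.ndarray, env: EnvPredictors,
                         net: ConnectionNetwork, variant: str = "full",
                         moran_perm: int = 199,
                         rng: np.random.Generator | None = None
                         ) -> ModelAverage:
    """All-subsets SAR fits with delta-AIC selection and model averaging.

    Fits the 2^5 predictor subsets (intercept and rho always included),
    computes Akaike weights over all fits, keeps models with delta AIC < 2,
    renormalizes their weights, and reports per predictor the averaged
    estimate, unconditional SE and relative importance w+ (sum of
    renormalized weights of selected models containing it; w+ of rho is 1
    by construction). ``variant="full"`` substitutes beta = 0 in models
    lacking a predictor; ``"conditional"`` averages only over models that
    contain it. Residual Moran's I is attached to every selected model.
    """
    if variant not in ("full", "conditional"):
        raise ValueError(f"unknown averaging variant {variant!r}")
    rng = rng or np.random.default_rng(0)
    Xall = env.matrix()
    fits: list[tuple[tuple[int, ...], SarFit]] = []
    for r in range(len(PREDICTOR_NAMES) + 1):
        for subset in itertools.combinations(range(len(PREDICTOR_NAMES)), r):
            try:
                f = sar_fit(G, Xall[:, subset] if subset else None, net,
                            predictor_names=[PREDICTOR_NAMES[i] for i in subset])
                fits.append((subset, f))
            except (ValueError, np.linalg.LinAlgError) as e:  # pragma: no cover
                warnings.warn(f"model {subset} dropped: {e}")
    if not fits:
        raise ValueError("no SAR model could be fitted")
    aics = np.array([f.aic for _, f in fits])
    delta = aics - aics.min()
    w_all = np.exp(-0.5 * delta)
    w_all /= w_all.sum()
    sel = np.where(delta < 2.0)[0]
    w_sel = w_all[sel] / w_all[sel].sum()

    def model_record(idx: int, weight: float, with_moran: bool) -> dict:
        subset, f = fits[idx]
        rec = {
            "predictors": [PREDICTOR_NAMES[i] for i in subset],
            "aic": float(f.aic), "delta_aic": float(delta[idx]),
            "weight": float(weight), "rho": float(f.rho),
            "loglik": float(f.loglik),
        }
        if with_moran:
            mi, mp = moran_i(f.residuals, net, n_perm=moran_perm, rng=rng)
            rec["residual_moran_I"], rec["residual_moran_p"] = mi, mp
        return rec

    rows = []
    for name in PREDICTOR_NAMES:
        est = se = wplus = 0.0
        cond_w = 0.0
        betas, ses, ws = [], [], []
        for widx, midx in zip(w_sel, sel):
            subset, f = fits[midx]
            if name in f.predictor_names:
                j = 1 + f.predictor_names.index(name)
                betas.append(f.beta[j]); ses.append(f.beta_se[j]); ws.append(widx)
                wplus += widx
            elif variant == "full":
                betas.append(0.0); ses.append(0.0); ws.append(widx)
        ws_arr = np.array(ws)
        if variant == "conditional" and ws_arr.sum() > 0:
            ws_arr = ws_arr / ws_arr.sum()
        if len(ws_arr):
            b = np.array(betas)
            s = np.array(ses)
            est = float(np.sum(ws_arr * b))
            se = float(np.sum(ws_arr * np.sqrt(s ** 2 + (b - est) ** 2)))
        rows.append({"predictor": name, "estimate": est, "se": se,
                     "w_plus": float(wplus)})

    rhos = np.array([fits[m][1].rho for m in sel])
    rho_ses = np.array([fits[m][1].rho_se or 0.0 for m in sel])
    rho_est = float(np.sum(w_sel * rhos))
    rho_se = float(np.sum(w_sel * np.sqrt(rho_ses ** 2 + (rhos - rho_est) ** 2)))

    return ModelAverage(
        table=pd.DataFrame(rows),
        rho_estimate=rho_est, rho_se=rho_se,
        selected_models=[model_record(m, w, True) for m, w in zip(sel, w_sel)],
        all_models=[model_record(m, w, False) for m, w in zip(range(len(fits)), w_all)],
        variant=variant,
    )
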