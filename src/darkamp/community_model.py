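"""Hierarchical hurdle models of microbial presence and abundance.

Two model components are fitted separately, in the spirit of joint
species distribution models with latent-factor random effects (HMSC):

* presence-absence of each taxon, Bernoulli with a probit link;
* abundance conditional on presence, Gaussian on log-transformed,
  per-taxon standardised values, with absences treated as missing.

Season and sex enter as fixed effects; site, host species, host
genotype, and the individual insect (sample unit) are community-level
random effects, each structured by latent factors eta with taxon
loadings Lambda.  A blocked Gibbs sampler with probit data augmentation
and a multiplicative-gamma shrinkage prior on loadings draws the
posterior; derived per-level association matrices are
Omega = Lambda' Lambda, correlation-scaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

__all__ = [
    "ModelInput",
    "Posterior",
    "hurdle_split",
    "fit",
    "fit_with_convergence",
    "psrf",
    "psrf_check",
    "variance_partition",
    "evaluate",
    "auc",
    "tjur_r2",
    "fixed_effect_support",
    "residual_associations",
    "simulate_from_model",
]

DEFAULT_LEVELS = ("site", "species", "genotype", "unit")


@dataclass
class ModelInput:
    """Design for one model component.

    ``Y`` is samples x taxa (binary for presence; real with NaN at
    non-presences for conditional abundance).  ``X`` is the fixed design
    including an intercept column.  ``levels`` maps a random-effect level
    name to an integer group index per sample.
    """

    Y: np.ndarray
    X: np.ndarray
    covariates: list[str]
    levels: dict[str, np.ndarray]
    taxa: list[str] = field(default_factory=list)
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        n = self.Y.shape[0]
        if self.X.shape[0] != n:
            raise ValueError("X and Y disagree on sample count")
        for name, g in self.levels.items():
            g = np.asarray(g)
            if g.shape[0] != n:
                raise ValueError(f"level {name!r} has wrong length")
            self.levels[name] = g.astype(int)
        if not self.taxa:
            self.taxa = [f"taxon{j + 1}" for j in range(self.Y.shape[1])]
        if not self.samples:
            self.samples = [f"s{i + 1}" for i in range(n)]

    @property
    def n_groups(self) -> dict[str, int]:
        return {name: int(g.max()) + 1 for name, g in self.levels.items()}


@dataclass
class Posterior:
    """Retained MCMC draws for one hurdle component.

    ``chains`` holds per-chain dicts with keys ``B`` (draws x p x T),
    ``Lambda`` (level -> draws x q x T) and, for the abundance component,
    ``sigma2`` (draws x T).  ``pred_mean`` is the posterior-mean
    prediction on the response scale (probability for presence).
    """

    component: str
    chains: list[dict]
    covariates: list[str]
    taxa: list[str]
    level_names: list[str]
    pred_mean: np.ndarray
    test_pred_mean: Optional[np.ndarray] = None
    converged: bool = True
    thin: int = 1

    def stacked(self, key: str) -> np.ndarray:
        """All retained draws pooled across chains (first axis)."""
        return np.concatenate([c[key] for c in self.chains], axis=0)

    def stacked_lambda(self, level: str) -> np.ndarray:
        return np.concatenate([c["Lambda"][level] for c in self.chains], axis=0)


# ----------------------------------------------------------------------
# hurdle split


def hurdle_split(abundance: pd.DataFrame, min_present: int = 2
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a taxa x samples abundance table into hurdle responses.

    Returns (P, A): P is the 0/1 presence table; A holds
    log-transformed, per-taxon standardised abundances with NaN where
    the taxon is absent.  Taxa present in fewer than ``min_present``
    samples are dropped from A (a standard deviation needs >= 2 cells).
    """
    if abundance.empty:
        raise ValueError("empty abundance table")
    P = (abundance > 0).astype(int)
    logged = np.log(abundance.where(abundance > 0))
    present_counts = P.sum(axis=1)
    keep = present_counts[present_counts >= min_present].index
    A = logged.loc[keep]
    mu = A.mean(axis=1)
    sd = A.std(axis=1, ddof=0).replace(0.0, 1.0)
    A = A.sub(mu, axis=0).div(sd, axis=0)
    return P, A


# ----------------------------------------------------------------------
# Gibbs sampler internals

_MGP_A1, _MGP_A2, _MGP_NU = 2.1, 3.1, 3.0
_SIGMA_A0, _SIGMA_B0 = 0.5, 0.5


def _truncated_probit_z(m: np.ndarray, y: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw latent z ~ N(m, 1) truncated by the observed binary y."""
    u = rng.uniform(size=m.shape)
    p0 = ndtr(-m)  # P(z < 0)
    lo = np.where(y > 0.5, p0, 0.0)
    hi = np.where(y > 0.5, 1.0, p0)
    p = np.clip(lo + u * (hi - lo), 1e-12, 1.0 - 1e-12)
    return m + ndtri(p)


class _State:
    """Mutable sampler state for one chain."""

    def __init__(self, inp: ModelInput, gaussian: bool, n_factors: dict[str, int],
                 rng: np.random.Generator):
        n, T = inp.Y.shape
        p = inp.X.shape[1]
        self.gaussian = gaussian
        self.mask = ~np.isnan(inp.Y)
        self.Yobs = np.nan_to_num(inp.Y, nan=0.0)
        self.B = np.zeros((p, T))
        self.sigma2 = np.ones(T)
        self.eta = {}
        self.lam = {}
        self.phi = {}
        self.delta = {}
        for name, q in n_factors.items():
            G = int(inp.levels[name].max()) + 1
            self.eta[name] = rng.standard_normal((G, q)) * 0.1
            self.lam[name] = rng.standard_normal((q, T)) * 0.1
            self.phi[name] = np.ones((q, T))
            self.delta[name] = np.ones(q)
        self.Z = np.where(self.mask, self.Yobs, 0.0)
        if not gaussian:
            self.Z = np.where(self.Yobs > 0.5, 0.5, -0.5)

    def random_part(self, inp: ModelInput,
                    exclude: str | None = None) -> np.ndarray:
        out = np.zeros_like(self.Z)
        for name, eta in self.eta.items():
            if name == exclude:
                continue
            out += eta[inp.levels[name]] @ self.lam[name]
        return out

    def tau(self, name: str) -> np.ndarray:
        return np.cumprod(self.delta[name])


def _update_B(state: _State, inp: ModelInput, rng: np.random.Generator) -> None:
    X = inp.X
    R = state.Z - state.random_part(inp)
    p, T = state.B.shape
    if not state.gaussian:
        prec = X.T @ X + np.eye(p)
        L = np.linalg.cholesky(np.linalg.inv(prec))
        mean = np.linalg.solve(prec, X.T @ R)
        state.B = mean + L @ rng.standard_normal((p, T))
        return
    for j in range(T):
        o = state.mask[:, j]
        Xo = X[o]
        s2 = state.sigma2[j]
        prec = Xo.T @ Xo / s2 + np.eye(p)
        cov = np.linalg.inv(prec)
        mean = cov @ (Xo.T @ R[o, j]) / s2
        state.B[:, j] = rng.multivariate_normal(mean, cov, method="cholesky")


def _update_eta(state: _State, inp: ModelInput, rng: np.random.Generator) -> None:
    for name, eta in state.eta.items():
        lam = state.lam[name]
        q = lam.shape[0]
        g = inp.levels[name]
        G = eta.shape[0]
        R = state.Z - inp.X @ state.B - state.random_part(inp, exclude=name)
        if not state.gaussian:
            # homoscedastic, fully observed: batch groups by size
            S = np.zeros((G, R.shape[1]))
            np.add.at(S, g, R)
            counts = np.bincount(g, minlength=G)
            M = S @ lam.T  # G x q
            A = lam @ lam.T
            new = np.empty_like(eta)
            for n_u in np.unique(counts):
                idx = counts == n_u
                prec = np.eye(q) + n_u * A
                cov = np.linalg.inv(prec)
                L = np.linalg.cholesky(cov)
                new[idx] = M[idx] @ cov.T + \
                    rng.standard_normal((int(idx.sum()), q)) @ L.T
            state.eta[name] = new
        else:
            w = 1.0 / state.sigma2  # per-taxon precision
            Rw = np.where(state.mask, R, 0.0) * w
            Sw = np.zeros((G, R.shape[1]))
            np.add.at(Sw, g, Rw)
            Dw = np.zeros((G, R.shape[1]))
            np.add.at(Dw, g, state.mask * w)
            new = np.empty_like(eta)
            for u in range(G):
                prec = np.eye(q) + (lam * Dw[u]) @ lam.T
                cov = np.linalg.inv(prec)
                mean = cov @ (lam @ Sw[u])
                new[u] = rng.multivariate_normal(mean, cov, method="cholesky")
            state.eta[name] = new


def _update_lambda(state: _State, inp: ModelInput, rng: np.random.Generator) -> None:
    names = list(state.eta)
    H = np.concatenate([state.eta[name][inp.levels[name]] for name in names], axis=1)
    offsets = np.cumsum([0] + [state.lam[n].shape[0] for n in names])
    R = state.Z - inp.X @ state.B
    qtot = H.shape[1]
    T = R.shape[1]
    prior_prec = np.concatenate(
        [state.phi[n] * state.tau(n)[:, None] for n in names], axis=0)  # qtot x T
    HtH = H.T @ H
    for j in range(T):
        if state.gaussian:
            o = state.mask[:, j]
            Ho = H[o]
            s2 = state.sigma2[j]
            prec = Ho.T @ Ho / s2 + np.diag(prior_prec[:, j])
            rhs = Ho.T @ R[o, j] / s2
        else:
            prec = HtH + np.diag(prior_prec[:, j])
            rhs = H.T @ R[:, j]
        cov = np.linalg.inv(prec)
        draw = rng.multivariate_normal(cov @ rhs, cov, method="cholesky")
        for k, name in enumerate(names):
            state.lam[name][:, j] = draw[offsets[k]:offsets[k + 1]]


def _update_shrinkage(state: _State, rng: np.random.Generator) -> None:
    """Multiplicative-gamma shrinkage prior updates per level."""
    for name, lam in state.lam.items():
        q, T = lam.shape
        tau = state.tau(name)
        lam2 = lam ** 2
        state.phi[name] = rng.gamma(
            (_MGP_NU + 1) / 2.0,
            1.0 / ((_MGP_NU + tau[:, None] * lam2) / 2.0))
        phi_lam2 = (state.phi[name] * lam2).sum(axis=1)  # per factor h
        delta = state.delta[name]
        for r in range(q):
            shape = (_MGP_A1 if r == 0 else _MGP_A2) + T * (q - r) / 2.0
            tau_wo = np.cumprod(delta)
            tau_wo_r = tau_wo[r:] / delta[r]
            rate = 1.0 + 0.5 * (tau_wo_r * phi_lam2[r:]).sum()
            delta[r] = rng.gamma(shape, 1.0 / rate)
        state.delta[name] = delta


def _update_sigma2(state: _State, inp: ModelInput, rng: np.random.Generator) -> None:
    R = state.Z - inp.X @ state.B - state.random_part(inp)
    for j in range(state.sigma2.shape[0]):
        o = state.mask[:, j]
        ssr = float((R[o, j] ** 2).sum())
        shape = _SIGMA_A0 + o.sum() / 2.0
        rate = _SIGMA_B0 + ssr / 2.0
        state.sigma2[j] = 1.0 / rng.gamma(shape, 1.0 / rate)


def _update_z(state: _State, inp: ModelInput, rng: np.random.Generator) -> None:
    if state.gaussian:
        state.Z = np.where(state.mask, state.Yobs, 0.0)
        return
    M = inp.X @ state.B + state.random_part(inp)
    state.Z = _truncated_probit_z(M, state.Yobs, rng)


def _predict_draw(state: _State, X: np.ndarray, level_maps: dict[str, np.ndarray],
                  gaussian: bool) -> np.ndarray:
    """Response-scale prediction for one draw.

    Groups coded -1 (unseen during fitting) contribute nothing to the
    mean; for the probit model their factor variance widens the link
    denominator instead.
    """
    M = X @ state.B
    v_unseen = np.zeros(state.B.shape[1])
    for name, eta in state.eta.items():
        g = level_maps[name]
        seen = g >= 0
        contrib = np.zeros((len(g), state.B.shape[1]))
        contrib[seen] = eta[g[seen]] @ state.lam[name]
        M += contrib
        if not seen.all():
            v_unseen = v_unseen + (state.lam[name] ** 2).sum(axis=0)
    if gaussian:
        return M
    denom = np.sqrt(1.0 + np.where(v_unseen > 0, v_unseen, 0.0))
    return ndtr(M / denom)


# ----------------------------------------------------------------------
# fitting


def fit(model_input: ModelInput, component: str = "presence",
        n_factors: dict[str, int] | int = 2,
        chains: int = 4, retained: int = 250, thin: int = 1,
        seed: int = 0, max_factors: int = 10,
        predict_for: tuple[np.ndarray, dict[str, np.ndarray]] | None = None
        ) -> Posterior:
    """Blocked Gibbs sampler for one hurdle component.

    Each chain runs ``375 * thin`` iterations; the first ``125 * thin``
    are burn-in and the rest are thinned by ``thin`` to retain
    ``retained`` draws per chain.  ``n_factors`` sets latent factors per
    random level (int applies to all levels, capped at ``max_factors``).
    ``predict_for`` optionally supplies (X_new, level maps with -1 for
    unseen groups) whose posterior-mean predictions are accumulated
    during sampling.
    """
    if component not in ("presence", "abundance"):
        raise ValueError(f"unknown component {component!r}")
    gaussian = component == "abundance"
    if gaussian and np.isnan(model_input.Y).all():
        raise ValueError("abundance component has no observed cells")
    if not gaussian and np.isnan(model_input.Y).any():
        raise ValueError("presence component must have a complete 0/1 matrix")
    if isinstance(n_factors, int):
        n_factors = {name: min(n_factors, max_factors)
                     for name in model_input.levels}
    else:
        n_factors = {k: min(v, max_factors) for k, v in n_factors.items()}
    burn = 125 * thin
    total = 375 * thin
    keep_every = max((total - burn) // retained, 1)
    chain_results = []
    pred_acc = np.zeros_like(model_input.Y, dtype=float)
    test_acc = None
    if predict_for is not None:
        test_acc = np.zeros((predict_for[0].shape[0], model_input.Y.shape[1]))
    n_pred = 0
    for c in range(chains):
        rng = np.random.default_rng(np.random.SeedSequence([seed, c]))
        state = _State(model_input, gaussian, n_factors, rng)
        draws_B, draws_lam, draws_s2 = [], {n: [] for n in n_factors}, []
        kept = 0
        for it in range(total):
            _update_z(state, model_input, rng)
            _update_B(state, model_input, rng)
            _update_eta(state, model_input, rng)
            _update_lambda(state, model_input, rng)
            _update_shrinkage(state, rng)
            if gaussian:
                _update_sigma2(state, model_input, rng)
            if it >= burn and (it - burn) % keep_every == 0 and kept < retained:
                kept += 1
                draws_B.append(state.B.copy())
                for name in n_factors:
                    draws_lam[name].append(state.lam[name].copy())
                if gaussian:
                    draws_s2.append(state.sigma2.copy())
                in_maps = {n: model_input.levels[n] for n in n_factors}
                pred_acc += _predict_draw(state, model_input.X, in_maps, gaussian)
                if predict_for is not None:
                    test_acc += _predict_draw(state, predict_for[0],
                                              predict_for[1], gaussian)
                n_pred += 1
        chain = {"B": np.array(draws_B),
                 "Lambda": {n: np.array(v) for n, v in draws_lam.items()}}
        if gaussian:
            chain["sigma2"] = np.array(draws_s2)
        chain_results.append(chain)
    return Posterior(
        component=component,
        chains=chain_results,
        covariates=model_input.covariates,
        taxa=model_input.taxa,
        level_names=list(n_factors),
        pred_mean=pred_acc / max(n_pred, 1),
        test_pred_mean=None if test_acc is None else test_acc / max(n_pred, 1),
        thin=thin,
    )


def fit_with_convergence(model_input: ModelInput, component: str = "presence",
                         thin_schedule: Sequence[int] = (1, 10, 100),
                         seed: int = 0, **kwargs) -> Posterior:
    """Fit at escalating thinning until the PSRF check passes.

    Follows the thin = 1, 10, 100, ... escalation; the posterior from
    the last attempted thinning is returned with ``converged`` set from
    the check.
    """
    post = None
    for thin in thin_schedule:
        post = fit(model_input, component, thin=thin, seed=seed, **kwargs)
        ok, _ = psrf_check(post)
        post.converged = bool(ok)
        if ok:
            return post
    return post


# ----------------------------------------------------------------------
# diagnostics


def psrf(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one parameter.

    ``draws`` is chains x iterations; each chain is split in half before
    applying the between/within variance formula.
    """
    m, n = draws.shape
    if m < 2:
        raise ValueError("PSRF needs at least 2 chains")
    half = n // 2
    splits = np.concatenate([draws[:, :half], draws[:, half:2 * half]], axis=0)
    n = half
    means = splits.mean(axis=1)
    W = splits.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def psrf_check(posterior: Posterior, params: Sequence[str] = ("season", "sex"),
               quantile: float = 0.75, threshold: float = 1.05
               ) -> tuple[bool, pd.Series]:
    """Convergence check on the taxa's season and sex responses.

    Passes iff the chosen quantile (third quartile by default) of the
    per-parameter split-chain PSRFs is at most ``threshold``.
    """
    if len(posterior.chains) < 2:
        raise ValueError("PSRF check needs >= 2 chains")
    idx = [posterior.covariates.index(p) for p in params
           if p in posterior.covariates]
    if not idx:
        raise ValueError(f"none of {params} in covariates {posterior.covariates}")
    values = {}
    for k in idx:
        for j, taxon in enumerate(posterior.taxa):
            draws = np.stack([c["B"][:, k, j] for c in posterior.chains])
            values[f"{posterior.covariates[k]}:{taxon}"] = psrf(draws)
    series = pd.Series(values)
    q3 = float(series.quantile(quantile))
    return q3 <= threshold, series


# ----------------------------------------------------------------------
# summaries


def variance_partition(posterior: Posterior, X: np.ndarray,
                       covariate_groups: dict[str, list[int]] | None = None
                       ) -> pd.DataFrame:
    """Attribute explained variance to fixed covariates and random levels.

    Fixed-effect variance is decomposed over covariates via the
    covariance of the design (the intercept carries no variance); each
    random level contributes the diagonal of Omega = Lambda' Lambda.
    Fractions are normalised to sum to 1 per taxon and averaged over
    draws.  Taxa with zero total variance in every draw are dropped.
    """
    B = posterior.stacked("B")  # S x p x T
    S, p, T = B.shape
    if covariate_groups is None:
        covariate_groups = {name: [k] for k, name in enumerate(posterior.covariates)
                            if name != "intercept"}
    covX = np.cov(X.T, ddof=0) if p > 1 else np.zeros((1, 1))
    covX = np.atleast_2d(covX)
    lam = {name: posterior.stacked_lambda(name) for name in posterior.level_names}
    parts = list(covariate_groups) + posterior.level_names
    frac_sum = np.zeros((T, len(parts)))
    n_used = np.zeros(T)
    for s in range(S):
        comps = np.zeros((T, len(parts)))
        for ci, name in enumerate(covariate_groups):
            ks = covariate_groups[name]
            # symmetric covariance attribution, clipped at zero
            v = np.zeros(T)
            for k in ks:
                v += B[s, k, :] * (covX[k] @ B[s])
            comps[:, ci] = np.clip(v, 0.0, None)
        for li, name in enumerate(posterior.level_names):
            comps[:, len(covariate_groups) + li] = (lam[name][s] ** 2).sum(axis=0)
        tot = comps.sum(axis=1)
        ok = tot > 0
        frac_sum[ok] += comps[ok] / tot[ok, None]
        n_used += ok
    keep = n_used > 0
    frac = frac_sum[keep] / n_used[keep, None]
    frac = frac / frac.sum(axis=1, keepdims=True)
    return pd.DataFrame(frac, index=[t for t, k in zip(posterior.taxa, keep) if k],
                        columns=parts)


def auc(y: np.ndarray, score: np.ndarray) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic."""
    y = np.asarray(y, dtype=bool)
    pos, neg = score[y], score[~y]
    if len(pos) == 0 or len(neg) == 0:
        return float("nan")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    return float((ranks[:len(pos)].sum() - len(pos) * (len(pos) + 1) / 2)
                 / (len(pos) * len(neg)))


def tjur_r2(y: np.ndarray, prob: np.ndarray) -> float:
    """Tjur's coefficient of discrimination for a binary response."""
    y = np.asarray(y, dtype=bool)
    if y.all() or (~y).all():
        return float("nan")
    return float(prob[y].mean() - prob[~y].mean())


def evaluate(posterior: Posterior, model_input: ModelInput,
             folds: int = 2, seed: int = 0,
             stratify_by: str | None = "species",
             refit_kwargs: dict | None = None) -> pd.DataFrame:
    """Explanatory and predictive fit per taxon.

    Explanatory metrics come from the fitted posterior's in-sample
    posterior-mean predictions; predictive metrics from k-fold
    cross-validation with refits, folds assigned at random over sample
    units (stratified by a random level so each fold sees every group).
    Presence models report AUC and Tjur R2; abundance models report R2
    (squared Pearson correlation) on observed cells.
    """
    gaussian = posterior.component == "abundance"
    Y = model_input.Y
    n, T = Y.shape
    rng = np.random.default_rng(seed)
    fold_of = np.zeros(n, dtype=int)
    if stratify_by and stratify_by in model_input.levels:
        g = model_input.levels[stratify_by]
        for grp in np.unique(g):
            idx = np.flatnonzero(g == grp)
            idx = rng.permutation(idx)
            fold_of[idx] = np.arange(len(idx)) % folds
    else:
        fold_of = rng.permutation(n) % folds
    cv_pred = np.full_like(Y, np.nan, dtype=float)
    refit_kwargs = dict(refit_kwargs or {})
    refit_kwargs.setdefault("thin", posterior.thin)
    for f in range(folds):
        test = fold_of == f
        train = ~test
        tr_levels = {}
        te_levels = {}
        for name, g in model_input.levels.items():
            seen = np.unique(g[train])
            remap = -np.ones(g.max() + 1, dtype=int)
            remap[seen] = np.arange(len(seen))
            tr_levels[name] = remap[g[train]]
            te_levels[name] = remap[g[test]]
        tr_input = ModelInput(Y[train], model_input.X[train],
                              model_input.covariates, tr_levels,
                              taxa=model_input.taxa)
        post_f = fit(tr_input, posterior.component, seed=seed + 1000 + f,
                     predict_for=(model_input.X[test], te_levels),
                     **refit_kwargs)
        cv_pred[test] = post_f.test_pred_mean
    rows = []
    for j, taxon in enumerate(posterior.taxa):
        row = {"taxon": taxon}
        if gaussian:
            o = ~np.isnan(Y[:, j])
            for label, pred in (("explanatory", posterior.pred_mean),
                                ("predictive", cv_pred)):
                yy, pp = Y[o, j], pred[o, j]
                if len(yy) >= 3 and np.std(yy) > 0 and np.std(pp) > 0:
                    row[f"{label}_R2"] = float(np.corrcoef(yy, pp)[0, 1] ** 2)
                else:
                    row[f"{label}_R2"] = float("nan")
        else:
            row["explanatory_AUC"] = auc(Y[:, j], posterior.pred_mean[:, j])
            row["explanatory_TjurR2"] = tjur_r2(Y[:, j], posterior.pred_mean[:, j])
            row["predictive_AUC"] = auc(Y[:, j], cv_pred[:, j])
            row["predictive_TjurR2"] = tjur_r2(Y[:, j], cv_pred[:, j])
        rows.append(row)
    return pd.DataFrame(rows).set_index("taxon")


def fixed_effect_support(posterior: Posterior, prob: float = 0.95
                         ) -> pd.DataFrame:
    """Per-taxon sign calls for each non-intercept covariate.

    A taxon is called positive (negative) for a covariate when at least
    ``prob`` of the pooled draws of its coefficient are > 0 (< 0).
    """
    B = posterior.stacked("B")
    rows = []
    for k, name in enumerate(posterior.covariates):
        if name == "intercept":
            continue
        p_pos = (B[:, k, :] > 0).mean(axis=0)
        p_neg = (B[:, k, :] < 0).mean(axis=0)
        for j, taxon in enumerate(posterior.taxa):
            call = "none"
            if p_pos[j] >= prob:
                call = "positive"
            elif p_neg[j] >= prob:
                call = "negative"
            rows.append({"covariate": name, "taxon": taxon,
                         "p_positive": float(p_pos[j]),
                         "p_negative": float(p_neg[j]), "call": call})
    df = pd.DataFrame(rows)
    return df


def residual_associations(posterior: Posterior, level: str, prob: float = 0.90
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Supported pairwise residual associations at one random level.

    Per draw, Omega = Lambda' Lambda is correlation-scaled; per pair the
    support is the larger of the fractions of draws with positive or
    negative correlation.  Returns (edge list with sign for pairs at
    support >= prob, full support matrix signed by direction).
    """
    if level not in posterior.level_names:
        raise ValueError(f"level {level!r} not in model ({posterior.level_names})")
    lam = posterior.stacked_lambda(level)  # S x q x T
    S, _, T = lam.shape
    pos = np.zeros((T, T))
    for s in range(S):
        omega = lam[s].T @ lam[s]
        d = np.sqrt(np.clip(np.diag(omega), 1e-12, None))
        corr = omega / np.outer(d, d)
        pos += corr > 0
    pos /= S
    neg = 1.0 - pos
    support = np.where(pos >= neg, pos, -neg)
    taxa = posterior.taxa
    edges = []
    for i in range(T):
        for j in range(i + 1, T):
            sup = max(pos[i, j], neg[i, j])
            if sup >= prob:
                edges.append({"taxon_a": taxa[i], "taxon_b": taxa[j],
                              "sign": "+" if pos[i, j] >= neg[i, j] else "-",
                              "support": float(sup)})
    support_df = pd.DataFrame(support, index=taxa, columns=taxa)
    return pd.DataFrame(edges, columns=["taxon_a", "taxon_b", "sign", "support"]), \
        support_df


# ----------------------------------------------------------------------
# generative simulation (for calibration checks)


def simulate_from_model(n_samples: int = 500, n_taxa: int = 30,
                        n_sites: int = 6, n_species: int = 25,
                        genotypes_per_species: int = 3,
                        n_factors: int = 2,
                        season_effect: float = 1.0, sex_effect: float = -1.0,
                        affected_frac: float = 0.5,
                        species_loading_sd: float = 1.5,
                        other_loading_sd: float = 0.3,
                        component: str = "presence",
                        seed: int = 0) -> tuple[ModelInput, dict]:
    """Draw a dataset from the model's own generative process.

    A random subset of taxa (``affected_frac``) receives the planted
    season and sex effects and strong species-level loadings; remaining
    loadings are weak.  Returns the model input and a truth dict with
    the fixed effects, loadings, and level maps.
    """
    rng = np.random.default_rng(seed)
    season = rng.integers(0, 2, n_samples)
    sex = rng.integers(0, 2, n_samples)
    X = np.column_stack([np.ones(n_samples), season, sex]).astype(float)
    site = rng.integers(0, n_sites, n_samples)
    species = rng.integers(0, n_species, n_samples)
    genotype = species * genotypes_per_species + \
        rng.integers(0, genotypes_per_species, n_samples)
    unit = np.arange(n_samples)
    levels = {"site": site, "species": species, "genotype": genotype,
              "unit": unit}
    affected = rng.permutation(n_taxa) < int(affected_frac * n_taxa)
    B = np.zeros((3, n_taxa))
    B[0] = rng.normal(0.0, 0.5, n_taxa)
    B[1] = np.where(affected, season_effect, 0.0) + rng.normal(0, 0.1, n_taxa)
    B[2] = np.where(affected, sex_effect, 0.0) + rng.normal(0, 0.1, n_taxa)
    lam = {}
    eta = {}
    G = {"site": n_sites, "species": n_species,
         "genotype": n_species * genotypes_per_species, "unit": n_samples}
    for name in levels:
        lam[name] = rng.normal(0.0, other_loading_sd, (n_factors, n_taxa))
        if name == "species":
            # planted species effect: guaranteed-strong loadings of random sign
            mag = species_loading_sd * rng.uniform(0.7, 1.3, (n_factors, n_taxa))
            sign = rng.choice([-1.0, 1.0], (n_factors, n_taxa))
            lam[name] = np.where(affected, mag * sign, lam[name])
        eta[name] = rng.standard_normal((G[name], n_factors))
    M = X @ B
    for name in levels:
        M += eta[name][levels[name]] @ lam[name]
    if component == "presence":
        Y = (M + rng.standard_normal(M.shape) > 0).astype(float)
    else:
        Y = M + rng.standard_normal(M.shape)
    inp = ModelInput(Y, X, ["intercept", "season", "sex"], levels)
    truth = {"B": B, "Lambda": lam, "eta": eta, "affected": affected}
    return inp, truth
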