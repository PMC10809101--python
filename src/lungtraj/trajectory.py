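"""Bayesian group-based trajectory model for joint FEV1/FVC Z-scores.

A finite mixture of linear regressions over the predictor set
[1, t, pack-years, smoker*t], with both spirometry targets modeled jointly
(conditionally independent given the trajectory). Inference is mean-field
coordinate-ascent variational Bayes with fully conjugate factors:

* mixture weights        pi ~ Dirichlet(alpha0) (sparse symmetric prior, so
  superfluous components of the K_max-component mixture empty out),
* per-component, per-target coefficients and residual precision
  (beta, lambda) ~ Normal-Gamma: lambda ~ Gamma(a0, b0) and
  beta | lambda ~ N(m0, diag(v0)/lambda),
* per-subject trajectory indicator z_i, with the subject as the unit of
  exchangeability (all of a subject's observations share one z_i).

With K_max = 1 the variational posterior for the coefficients coincides with
the exact conjugate posterior, which anchors the oracle tests. Restart fits
are ranked by WAIC2 (variance-based effective-parameter form, subject-level
pointwise terms, Monte-Carlo over the variational posterior).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln, logsumexp

from .prep import DesignMatrix, build_design

LN2PI = float(np.log(2.0 * np.pi))
N_PRED = 4
N_TARGET = 2


@dataclass
class Priors:
    """Conjugate prior hyperparameters.

    ``m0``/``v0`` are (target, predictor) arrays; the intercept prior mean is
    forced to zero (Z-scores are zero-centered by construction in a reference
    population, which substitutes for absent early-adulthood data). ``v0`` is
    a *relative* variance: the coefficient prior is N(m0, diag(v0)/lambda).
    """

    m0: np.ndarray = field(default_factory=lambda: np.zeros((N_TARGET, N_PRED)))
    v0: np.ndarray = field(
        default_factory=lambda: np.tile(
            np.array([25.0, 0.25, 0.25, 0.25]), (N_TARGET, 1)
        )
    )
    a0: np.ndarray = field(default_factory=lambda: np.full(N_TARGET, 2.0))
    b0: np.ndarray = field(default_factory=lambda: np.full(N_TARGET, 1.0))
    alpha0: float = 0.1

    def __post_init__(self):
        self.m0 = np.broadcast_to(np.asarray(self.m0, float), (N_TARGET, N_PRED)).copy()
        self.v0 = np.broadcast_to(np.asarray(self.v0, float), (N_TARGET, N_PRED)).copy()
        self.a0 = np.broadcast_to(np.asarray(self.a0, float), (N_TARGET,)).copy()
        self.b0 = np.broadcast_to(np.asarray(self.b0, float), (N_TARGET,)).copy()
        self.validate()

    def validate(self):
        if np.any(self.v0 <= 0) or np.any(self.a0 <= 0) or np.any(self.b0 <= 0):
            raise ValueError("v0, a0, b0 must be positive")
        if self.alpha0 <= 0:
            raise ValueError("alpha0 must be positive")
        if np.any(self.m0[:, 0] != 0.0):
            raise ValueError("intercept prior means must be zero-centered")


@dataclass
class TrajectoryModel:
    """Fitted variational posterior for the trajectory mixture.

    ``coef_mean`` is (K, target, predictor); ``coef_V`` the matching
    (K, target, predictor, predictor) scale matrices with
    Cov(beta | lambda) = V / lambda; ``gamma_a``/``gamma_b`` the residual
    precision posteriors; ``alpha`` the Dirichlet posterior over weights.
    """

    K_max: int
    alpha: np.ndarray
    coef_mean: np.ndarray
    coef_V: np.ndarray
    gamma_a: np.ndarray
    gamma_b: np.ndarray
    responsibilities: np.ndarray
    subject_ids: np.ndarray
    elbo_trace: np.ndarray
    seed: int
    converged: bool
    priors: Priors | None = None
    waic2: float = np.nan
    point_mass: bool = False

    @property
    def K(self) -> int:
        return len(self.alpha)

    @property
    def weights(self) -> np.ndarray:
        return self.alpha / self.alpha.sum()

    @property
    def membership_fractions(self) -> np.ndarray:
        return self.responsibilities.mean(axis=0)

    @property
    def hard_labels(self) -> np.ndarray:
        return self.responsibilities.argmax(axis=1)

    def residual_sd(self) -> np.ndarray:
        """Posterior-mean residual SD per (component, target)."""
        return np.sqrt(self.gamma_b / self.gamma_a)

    def severity_scores(self, packyears: float = 40.0, t: float = 40.0) -> np.ndarray:
        """Predicted FEV1 Z at `t` years past peak for a non-smoker; lower
        = more severe. Used to order trajectories clinically."""
        x = np.array([1.0, t, packyears, 0.0])
        return self.coef_mean[:, 0, :] @ x

    def to_json(self, path) -> None:
        payload = {
            "K_max": int(self.K_max),
            "alpha": self.alpha.tolist(),
            "coef_mean": self.coef_mean.tolist(),
            "coef_V": self.coef_V.tolist(),
            "gamma_a": self.gamma_a.tolist(),
            "gamma_b": self.gamma_b.tolist(),
            "responsibilities": self.responsibilities.tolist(),
            "subject_ids": [str(s) for s in self.subject_ids],
            "elbo_trace": self.elbo_trace.tolist(),
            "seed": int(self.seed),
            "converged": bool(self.converged),
            "waic2": float(self.waic2),
            "priors": None if self.priors is None else {
                "m0": self.priors.m0.tolist(), "v0": self.priors.v0.tolist(),
                "a0": self.priors.a0.tolist(), "b0": self.priors.b0.tolist(),
                "alpha0": self.priors.alpha0,
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TrajectoryModel":
        with open(path) as fh:
            p = json.load(fh)
        priors = Priors(**p["priors"]) if p.get("priors") else None
        return cls(
            K_max=p["K_max"], alpha=np.array(p["alpha"]),
            coef_mean=np.array(p["coef_mean"]), coef_V=np.array(p["coef_V"]),
            gamma_a=np.array(p["gamma_a"]), gamma_b=np.array(p["gamma_b"]),
            responsibilities=np.array(p["responsibilities"]),
            subject_ids=np.array(p["subject_ids"]),
            elbo_trace=np.array(p["elbo_trace"]), seed=p["seed"],
            converged=p["converged"], priors=priors, waic2=p["waic2"],
        )


@dataclass
class PosteriorAssignment:
    """Subject x trajectory posterior probabilities with hard labels."""

    subject_ids: np.ndarray
    R: np.ndarray
    min_posterior: float

    def __post_init__(self):
        ok = np.isfinite(self.R).all(axis=1)
        sums = np.where(ok, self.R.sum(axis=1), 1.0)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("assignment rows must sum to 1")

    @property
    def hard_labels(self) -> np.ndarray:
        ok = np.isfinite(self.R).all(axis=1)
        safe = np.where(np.isfinite(self.R), self.R, -np.inf)
        return np.where(ok, safe.argmax(axis=1), -1)

    @property
    def max_posterior(self) -> np.ndarray:
        safe = np.where(np.isfinite(self.R), self.R, -np.inf)
        out = safe.max(axis=1)
        return np.where(np.isfinite(out), out, np.nan)

    @property
    def assigned(self) -> np.ndarray:
        ok = np.isfinite(self.R).all(axis=1)
        safe = np.where(np.isfinite(self.R), self.R, -np.inf)
        return ok & (safe.max(axis=1) >= self.min_posterior)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            self.R, columns=[f"p_traj_{k}" for k in range(self.R.shape[1])]
        )
        df.insert(0, "subject_id", self.subject_ids)
        df["hard_label"] = self.hard_labels
        df["assigned"] = self.assigned
        return df


def _normal_gamma_kl(m, V, a, b, m0, v0, a0, b0):
    """KL(q || p) between Normal-Gamma factors (p has diagonal scale v0)."""
    p = len(m)
    kl_gamma = ((a - a0) * digamma(a) - gammaln(a) + gammaln(a0)
                + a0 * (np.log(b) - np.log(b0)) + a * (b0 - b) / b)
    d0 = 1.0 / v0
    sign, logdet_v = np.linalg.slogdet(V)
    if sign <= 0:
        raise np.linalg.LinAlgError("non-PD coefficient scale matrix")
    diff = m - m0
    kl_norm = 0.5 * (np.sum(np.log(v0)) - logdet_v - p
                     + (a / b) * np.sum(d0 * diff * diff)
                     + np.sum(d0 * np.diag(V)))
    return kl_gamma + kl_norm


def _dirichlet_kl(alpha, alpha0):
    K = len(alpha)
    a_sum = alpha.sum()
    return (gammaln(a_sum) - gammaln(alpha).sum()
            - gammaln(K * alpha0) + K * gammaln(alpha0)
            + np.sum((alpha - alpha0) * (digamma(alpha) - digamma(a_sum))))


def fit_single(
    design: DesignMatrix,
    priors: Priors | None = None,
    K_max: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    compute_waic: bool = True,
    waic_draws: int = 200,
) -> TrajectoryModel:
    """One CAVI run from a random responsibility initialization.

    Iterates (weights, coefficient/precision, responsibility) updates until
    the relative ELBO change drops below ``tol`` or ``max_iter`` sweeps.
    The ELBO trace is monotone nondecreasing up to numerical slack; a
    non-finite ELBO aborts with a diagnostic.
    """
    if design.n_obs == 0:
        raise ValueError("empty design matrix")
    priors = priors or Priors()
    X, Y, sidx = design.X, design.Y, design.subject_index
    n_sub = design.n_subjects
    rng = np.random.default_rng(seed)
    K = int(K_max)

    r = rng.dirichlet(np.ones(K), size=n_sub)
    D0 = 1.0 / priors.v0                      # (d, p)
    prior_quad = np.sum(D0 * priors.m0 ** 2, axis=1)  # m0' D0 m0 per target

    alpha = np.full(K, priors.alpha0)
    m = np.zeros((K, N_TARGET, N_PRED))
    V = np.zeros((K, N_TARGET, N_PRED, N_PRED))
    a_post = np.ones((K, N_TARGET))
    b_post = np.ones((K, N_TARGET))

    elbo_trace = []
    converged = False
    prev_elbo = -np.inf
    for it in range(max_iter):
        Nk = r.sum(axis=0)
        alpha = priors.alpha0 + Nk

        w_obs = r[sidx, :]                    # (n_obs, K)
        Wk = w_obs.sum(axis=0)                # weighted obs count per comp
        for k in range(K):
            w = w_obs[:, k]
            Xw = X * w[:, None]
            Sxx = X.T @ Xw
            for d in range(N_TARGET):
                P = np.diag(D0[d]) + Sxx
                Sxy = Xw.T @ Y[:, d] + D0[d] * priors.m0[d]
                Vkd = np.linalg.inv(P)
                mkd = Vkd @ Sxy
                m[k, d] = mkd
                V[k, d] = Vkd
                a_post[k, d] = priors.a0[d] + 0.5 * Wk[k]
                Syy = w @ (Y[:, d] ** 2)
                b_post[k, d] = priors.b0[d] + 0.5 * (
                    Syy + prior_quad[d] - mkd @ P @ mkd
                )
        b_post = np.maximum(b_post, 1e-300)

        # responsibilities
        eln_pi = digamma(alpha) - digamma(alpha.sum())
        ll_obs = np.zeros((X.shape[0], K))
        for k in range(K):
            for d in range(N_TARGET):
                eln_lam = digamma(a_post[k, d]) - np.log(b_post[k, d])
                elam = a_post[k, d] / b_post[k, d]
                resid = Y[:, d] - X @ m[k, d]
                quad = elam * resid ** 2 + np.einsum(
                    "ij,jk,ik->i", X, V[k, d], X
                )
                ll_obs[:, k] += 0.5 * (eln_lam - LN2PI) - 0.5 * quad
        subj_ll = np.zeros((n_sub, K))
        np.add.at(subj_ll, sidx, ll_obs)
        ln_rho = eln_pi[None, :] + subj_ll
        r = np.exp(ln_rho - logsumexp(ln_rho, axis=1, keepdims=True))

        elbo = float(np.sum(logsumexp(ln_rho, axis=1)))
        elbo -= _dirichlet_kl(alpha, priors.alpha0)
        for k in range(K):
            for d in range(N_TARGET):
                elbo -= _normal_gamma_kl(
                    m[k, d], V[k, d], a_post[k, d], b_post[k, d],
                    priors.m0[d], priors.v0[d], priors.a0[d], priors.b0[d],
                )
        if not np.isfinite(elbo):
            raise FloatingPointError(
                f"non-finite ELBO at iteration {it} (seed {seed}); "
                "check the design matrix scale or priors"
            )
        elbo_trace.append(elbo)
        if it > 0 and abs(elbo - prev_elbo) <= tol * (abs(prev_elbo) + 1e-12):
            converged = True
            break
        prev_elbo = elbo

    model = TrajectoryModel(
        K_max=K, alpha=alpha, coef_mean=m, coef_V=V, gamma_a=a_post,
        gamma_b=b_post, responsibilities=r, subject_ids=design.subject_ids,
        elbo_trace=np.asarray(elbo_trace), seed=int(seed), converged=converged,
        priors=priors,
    )
    if compute_waic:
        waic_seed = int(np.random.SeedSequence([int(seed), 17]).generate_state(1)[0]
                        % 2 ** 31)
        model.waic2 = waic2(model, design, S=waic_draws, seed=waic_seed)
    return model


def waic2(model: TrajectoryModel, design: DesignMatrix, S: int = 200,
          seed: int = 0) -> float:
    """Watanabe-Akaike criterion, variance form, subject-level pointwise terms.

    Draws S joint parameter samples from the variational posterior and
    returns ``-2 * sum_i (lppd_i - p_i)`` with
    ``lppd_i = log mean_s p(y_i | theta_s)`` and
    ``p_i = Var_s log p(y_i | theta_s)``. Lower is better.
    """
    if S < 2:
        raise ValueError("S must be >= 2")
    X, Y, sidx = design.X, design.Y, design.subject_index
    n_sub = design.n_subjects
    K = model.K
    rng = np.random.default_rng(seed)

    ll = np.empty((S, n_sub))
    for s in range(S):
        if model.point_mass:
            pi = model.weights
            lam = model.gamma_a / model.gamma_b
            beta = model.coef_mean
        else:
            pi = rng.dirichlet(model.alpha)
            lam = rng.gamma(model.gamma_a, 1.0 / model.gamma_b)
            beta = np.empty_like(model.coef_mean)
            for k in range(K):
                for d in range(N_TARGET):
                    cov = model.coef_V[k, d] / lam[k, d]
                    beta[k, d] = rng.multivariate_normal(
                        model.coef_mean[k, d], cov, method="cholesky"
                    )
        obs_ll = np.zeros((X.shape[0], K))
        for k in range(K):
            for d in range(N_TARGET):
                resid = Y[:, d] - X @ beta[k, d]
                obs_ll[:, k] += 0.5 * (np.log(lam[k, d]) - LN2PI) \
                    - 0.5 * lam[k, d] * resid ** 2
        subj = np.zeros((n_sub, K))
        np.add.at(subj, sidx, obs_ll)
        with np.errstate(divide="ignore"):
            ll[s] = logsumexp(subj + np.log(np.maximum(pi, 1e-300)), axis=1)

    lppd = logsumexp(ll, axis=0) - np.log(S)
    p_eff = ll.var(axis=0, ddof=1)
    if np.allclose(p_eff, 0.0):
        warnings.warn("degenerate posterior draws: effective parameters = 0")
    return float(-2.0 * np.sum(lppd - p_eff))


def fit_ensemble(
    design: DesignMatrix,
    priors: Priors | None = None,
    K_max: int = 20,
    n_init: int = 20,
    base_seed: int = 0,
    **fit_kwargs,
) -> list[TrajectoryModel]:
    """Multi-restart protocol: independent CAVI runs from derived seeds,
    sorted ascending by WAIC2 (ties broken by lower seed). Per-run failures
    are logged and skipped; only total failure raises."""
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    seeds = np.random.SeedSequence(base_seed).generate_state(n_init) % 2 ** 31
    models, failures = [], []
    for s in seeds:
        try:
            models.append(fit_single(design, priors, K_max, seed=int(s), **fit_kwargs))
        except Exception as exc:  # logged skip, not a crash
            failures.append((int(s), repr(exc)))
            warnings.warn(f"restart seed {s} failed: {exc!r}")
    if not models:
        raise RuntimeError(f"all {n_init} restarts failed: {failures}")
    models.sort(key=lambda mdl: (mdl.waic2, mdl.seed))
    return models


def prune(model: TrajectoryModel, threshold: float = 0.02) -> TrajectoryModel:
    """Drop components holding less than ``threshold`` of the sample; the
    remaining weights and responsibilities are renormalized."""
    frac = model.membership_fractions
    keep = frac >= threshold
    if not keep.any():
        raise ValueError("all components fall below the membership threshold")
    if keep.all():
        return model
    r = model.responsibilities[:, keep]
    row = r.sum(axis=1, keepdims=True)
    # a subject fully owned by a pruned component falls back to the weights
    w = model.alpha[keep] / model.alpha[keep].sum()
    r = np.where(row > 0, r / np.where(row > 0, row, 1.0), w[None, :])
    return TrajectoryModel(
        K_max=model.K_max, alpha=model.alpha[keep],
        coef_mean=model.coef_mean[keep], coef_V=model.coef_V[keep],
        gamma_a=model.gamma_a[keep], gamma_b=model.gamma_b[keep],
        responsibilities=r, subject_ids=model.subject_ids,
        elbo_trace=model.elbo_trace, seed=model.seed,
        converged=model.converged, priors=model.priors, waic2=model.waic2,
        point_mass=model.point_mass,
    )


def assign(
    model: TrajectoryModel,
    visits,
    min_posterior: float = 0.5,
    method: str = "plugin",
) -> PosteriorAssignment:
    """Posterior trajectory probabilities for (possibly single-visit) subjects.

    ``method='plugin'`` evaluates a normal predictive density at the
    posterior-mean coefficients and precision (fast, deterministic);
    ``method='predictive'`` uses the full Student-t posterior predictive.
    Subjects with no usable (finite-Z) visits get a NaN row and are flagged
    unassigned.
    """
    if not 0.0 <= min_posterior <= 1.0:
        raise ValueError("min_posterior must lie in [0, 1]")
    import pandas as pd

    visits = pd.DataFrame(visits)
    all_ids = visits["subject_id"].drop_duplicates().to_numpy()
    usable = visits[np.isfinite(visits["fev1_z"]) & np.isfinite(visits["fvc_z"])]
    if usable.empty:
        R = np.full((len(all_ids), model.K), np.nan)
        return PosteriorAssignment(all_ids, R, min_posterior)
    design = build_design(usable)
    X, Y, sidx = design.X, design.Y, design.subject_index
    K = model.K

    obs_ll = np.zeros((X.shape[0], K))
    for k in range(K):
        for d in range(N_TARGET):
            mu = X @ model.coef_mean[k, d]
            if method == "plugin":
                var = model.gamma_b[k, d] / model.gamma_a[k, d]
                obs_ll[:, k] += -0.5 * (LN2PI + np.log(var)) \
                    - 0.5 * (Y[:, d] - mu) ** 2 / var
            elif method == "predictive":
                from scipy.stats import t as student_t

                df = 2.0 * model.gamma_a[k, d]
                scale2 = (model.gamma_b[k, d] / model.gamma_a[k, d]) * (
                    1.0 + np.einsum("ij,jk,ik->i", X, model.coef_V[k, d], X)
                )
                obs_ll[:, k] += student_t.logpdf(
                    Y[:, d], df, loc=mu, scale=np.sqrt(scale2)
                )
            else:
                raise ValueError(f"unknown predictive method {method!r}")
    subj_ll = np.zeros((design.n_subjects, K))
    np.add.at(subj_ll, sidx, obs_ll)
    ln_rho = np.log(model.weights)[None, :] + subj_ll
    R_usable = np.exp(ln_rho - logsumexp(ln_rho, axis=1, keepdims=True))

    R = np.full((len(all_ids), K), np.nan)
    pos = {s: i for i, s in enumerate(all_ids)}
    for j, s in enumerate(design.subject_ids):
        R[pos[s]] = R_usable[j]
    return PosteriorAssignment(all_ids, R, min_posterior)


def select_clinical(
    models: list[TrajectoryModel],
    outcomes,
    top_m: int = 5,
    alpha: float = 0.05,
    prune_threshold: float = 0.02,
    rule: str = "either",
) -> tuple[TrajectoryModel, dict]:
    """Clinical-relevance selection among the best-WAIC2 restarts.

    For each candidate (in WAIC2 order): prune, order active trajectories by
    severity (predicted FEV1 Z at 40 years past peak), take the trajectory
    whose severity score is closest to zero as reference, and test every
    adjacent pair along increasing severity with the reduced Cox mortality
    and ZINB exacerbation models (the less severe member as reference).
    The first candidate whose adjacent contrasts all reach p < ``alpha`` in
    either outcome model (``rule='either'``) or both (``rule='both'``) wins.
    If none passes, the best-WAIC2 model is returned with an audit flag.
    """
    from . import risk

    if not models:
        raise ValueError("no candidate models")
    audit = {"candidates": [], "rule": rule, "alpha": alpha,
             "flag": None, "chosen_seed": None}
    candidates = models[:top_m]
    if len(candidates) == 1:
        audit["flag"] = "single_candidate_passthrough"
        audit["chosen_seed"] = candidates[0].seed
        return candidates[0], audit
    for mdl in candidates:
        entry = {"seed": mdl.seed, "waic2": mdl.waic2, "pairs": [], "pass": None}
        try:
            pruned = prune(mdl, prune_threshold)
        except ValueError as exc:
            entry["pass"] = False
            entry["error"] = str(exc)
            audit["candidates"].append(entry)
            continue
        labels = pruned.hard_labels
        import pandas as pd

        lab = pd.DataFrame({"subject_id": pruned.subject_ids, "trajectory": labels})
        merged = pd.DataFrame(outcomes).merge(lab, on="subject_id", how="inner")
        scores = pruned.severity_scores(
            packyears=float(merged["packyears"].median())
        )
        order = np.argsort(-scores)  # least severe first
        ref = int(np.argmin(np.abs(scores)))
        chain = [ref] + [int(k) for k in order if scores[k] < scores[ref]]
        entry["severity_scores"] = scores.tolist()
        entry["reference"] = ref
        entry["chain"] = chain

        if len(chain) < 2:
            entry["pass"] = len(pruned.alpha) == 1  # degenerate single-trajectory
            audit["candidates"].append(entry)
            if entry["pass"]:
                audit["chosen_seed"] = mdl.seed
                return mdl, audit
            continue

        ok = True
        for lo, hi in zip(chain[:-1], chain[1:]):
            pair_df = merged[merged["trajectory"].isin([lo, hi])]
            try:
                cox = risk.cox_mortality(
                    pair_df, pair_df["trajectory"], model_form="reduced",
                    reference=lo,
                )
                p_cox = float(cox.loc[cox["trajectory"] == hi, "p"].iloc[0])
            except Exception:
                p_cox = np.nan
            try:
                zinb = risk.zinb_exacerbations(
                    pair_df, pair_df["trajectory"], model_form="reduced",
                    reference=lo,
                )
                p_zinb = float(zinb.loc[zinb["trajectory"] == hi, "p"].iloc[0])
            except Exception:
                p_zinb = np.nan
            ps = [p for p in (p_cox, p_zinb) if np.isfinite(p)]
            if rule == "either":
                pair_ok = bool(ps) and min(ps) < alpha
            elif rule == "both":
                pair_ok = len(ps) == 2 and max(ps) < alpha
            else:
                raise ValueError(f"unknown rule {rule!r}")
            entry["pairs"].append(
                {"less_severe": lo, "more_severe": hi,
                 "p_cox": p_cox, "p_zinb": p_zinb, "pass": pair_ok}
            )
            ok = ok and pair_ok
        entry["pass"] = ok
        audit["candidates"].append(entry)
        if ok:
            audit["chosen_seed"] = mdl.seed
            return mdl, audit

    audit["flag"] = "no clinically discriminating model"
    audit["chosen_seed"] = candidates[0].seed
    return candidates[0], audit
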