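"""Familiar-baby recognition: cohort simulation, Bayesian logistic mixed model,
posterior contrasts, and a machine-listener protocol.

The experiment: listeners are familiarized with one baby's discomfort cries
(two sessions of five cries) and later hear 20 pain cries -- 4 from the
familiar baby and 16 from four unknown babies (2 boys, 2 girls) -- answering
yes/no ("is this your baby?").  Chance level for familiar trials is
4/20 = 20%.

The analysis model is a Bernoulli-logit mixed model::

    response ~ status * parentality * sex
               + (status + parentality | stimulus baby)
               + (status | subject)

with sum-to-zero (+-1/2) covariate coding, Normal(0, 1) priors on the effect
coefficients and a Normal(logit(0.2), 1) prior on the intercept.  It is fitted
by a Polya-Gamma-augmented Gibbs sampler: conditional on auxiliary PG(1, psi)
variables, all coefficient and random-effect updates are conjugate Gaussian
draws and the random-effect variances have inverse-gamma updates.  Posterior
quantities are reported on the probability scale as marginal rates over the
observed trials (posterior-predictive means), summarized as medians with 95%
credible intervals; split-Rhat convergence diagnostics are computed on the
fixed-effect chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "ListenerError",
    "ExperimentDesign",
    "CohortParams",
    "MCMCConfig",
    "PosteriorSummary",
    "simulate_cohort",
    "fit_listener_model",
    "contrast_summaries",
    "contrast_draws",
    "machine_listener",
]


class ListenerError(ValueError):
    """Invalid listener-experiment input."""


@dataclass(frozen=True)
class ExperimentDesign:
    """Structure of the recognition test."""

    n_training_sessions: int = 2
    cries_per_training: int = 5
    n_test_trials: int = 20
    n_familiar_test: int = 4
    n_unknown_babies: int = 4  # 2 boys, 2 girls
    cries_per_unknown: int = 4

    def validate(self) -> None:
        if self.n_familiar_test + self.n_unknown_babies * self.cries_per_unknown != self.n_test_trials:
            raise ListenerError("familiar + unknown trials must equal n_test_trials")

    @property
    def chance_level(self) -> float:
        return self.n_familiar_test / self.n_test_trials


@dataclass(frozen=True)
class CohortParams:
    """Generative parameters of a simulated listener cohort.

    Rates are marginal yes-probabilities; variability SDs act on the logit
    scale; group offsets are logit shifts for the +-1/2-coded covariates.
    """

    hit_rate: float = 0.485
    false_alarm_rate: float = 0.308
    subject_intercept_sd: float = 0.4
    subject_status_sd: float = 0.3
    baby_intercept_sd: float = 0.4
    baby_status_sd: float = 0.3
    baby_parent_sd: float = 0.15
    sex_offset: float = 0.0
    parent_offset: float = 0.0

    def validate(self) -> None:
        for name in ("hit_rate", "false_alarm_rate"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ListenerError(f"{name} must lie strictly in (0, 1) (degenerate logit)")


def simulate_cohort(
    design: ExperimentDesign,
    params: CohortParams,
    n_subjects: int = 100,
    n_training_babies: int = 9,
    n_pool_babies: int = 22,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate one cohort (default 100 subjects: 25 per sex x parentality cell).

    Each subject is assigned a familiar baby from the training pool and hears
    4 familiar + 16 unknown pain cries; yes/no responses are Bernoulli draws
    from the logit model with subject and stimulus-baby random effects.
    Deterministic given the seed.
    """
    design.validate()
    params.validate()
    if n_subjects % 4 != 0:
        raise ListenerError("n_subjects must fill the 4 sex x parentality cells evenly")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x115]))

    babies = [f"B{i:02d}" for i in range(n_pool_babies)]
    baby_sex = {b: ("M" if i % 2 == 0 else "F") for i, b in enumerate(babies)}
    train_pool = babies[:n_training_babies]

    b_int = rng.normal(0, params.baby_intercept_sd, n_pool_babies)
    b_sta = rng.normal(0, params.baby_status_sd, n_pool_babies)
    b_par = rng.normal(0, params.baby_parent_sd, n_pool_babies)
    baby_idx = {b: i for i, b in enumerate(babies)}

    cells = [(s, p) for s in ("F", "M") for p in ("parent", "non-parent")]
    rows = []
    per_cell = n_subjects // 4
    subj = 0
    for sex, parent in cells:
        for _ in range(per_cell):
            sid = f"S{subj:03d}"
            fam = train_pool[subj % n_training_babies]
            u_int = rng.normal(0, params.subject_intercept_sd)
            u_sta = rng.normal(0, params.subject_status_sd)
            boys = [b for b in babies if baby_sex[b] == "M" and b != fam]
            girls = [b for b in babies if baby_sex[b] == "F" and b != fam]
            unknown = list(rng.choice(boys, 2, replace=False)) + list(
                rng.choice(girls, 2, replace=False)
            )
            stimuli = [fam] * design.n_familiar_test + [
                b for b in unknown for _ in range(design.cries_per_unknown)
            ]
            statuses = ["familiar"] * design.n_familiar_test + ["unknown"] * (
                design.n_test_trials - design.n_familiar_test
            )
            order = rng.permutation(design.n_test_trials)
            x_par = 0.5 if parent == "parent" else -0.5
            x_sex = 0.5 if sex == "F" else -0.5
            for k in np.argsort(order):
                st = statuses[k]
                bid = stimuli[k]
                x_st = 0.5 if st == "familiar" else -0.5
                base = logit(params.hit_rate) if st == "familiar" else logit(
                    params.false_alarm_rate
                )
                psi = (
                    base
                    + params.sex_offset * x_sex
                    + params.parent_offset * x_par
                    + u_int
                    + u_sta * x_st
                    + b_int[baby_idx[bid]]
                    + b_sta[baby_idx[bid]] * x_st
                    + b_par[baby_idx[bid]] * x_par
                )
                rows.append(
                    {
                        "subject_id": sid,
                        "sex": sex,
                        "parental_status": parent,
                        "baby_id": bid,
                        "familiar_baby_id": fam,
                        "real_status": st,
                        "response": int(rng.random() < expit(psi)),
                        "trial_order": int(order[k]),
                    }
                )
            subj += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Polya-Gamma Gibbs sampler

def _sample_pg1(rng: np.random.Generator, c: np.ndarray, n_terms: int = 128) -> np.ndarray:
    """Draw PG(1, c) via the truncated infinite-sum-of-gammas representation,
    with an analytic mean correction for the discarded tail."""
    c = np.abs(np.asarray(c, dtype=float))
    h = (c / (2 * np.pi)) ** 2
    k = np.arange(1, n_terms + 1) - 0.5  # (K,)
    denom = k[None, :] ** 2 + h[:, None]
    g = rng.standard_exponential((len(c), n_terms))
    s = (g / denom).sum(axis=1)
    # tail mean: integral approximation of sum_{k>K} 1/((k-1/2)^2 + h)
    sq = np.sqrt(np.maximum(h, 1e-300))
    tail = np.where(
        h > 0, (np.pi / 2 - np.arctan(n_terms / sq)) / sq, 1.0 / n_terms
    )
    return (s + tail) / (2 * np.pi**2)


@dataclass(frozen=True)
class MCMCConfig:
    chains: int = 2
    iterations: int = 3000
    warmup: int = 1000
    seed: int = 0
    rhat_threshold: float = 1.05

    @classmethod
    def fast(cls, seed: int = 0) -> "MCMCConfig":
        """Reduced budget profile for quick runs."""
        return cls(chains=2, iterations=600, warmup=200, seed=seed)


_FIXED_TERMS = (
    "intercept",
    "status",
    "parentality",
    "sex",
    "status:parentality",
    "status:sex",
    "parentality:sex",
    "status:parentality:sex",
)


@dataclass
class PosteriorSummary:
    """Posterior medians and 95% credible intervals on the probability scale,
    plus the underlying draws and convergence diagnostics."""

    summaries: pd.DataFrame  # quantity, median, ci_low, ci_high
    draws: dict  # quantity -> 1D array of posterior draws
    fixed_effect_draws: dict  # term -> (chains, draws) array, logit scale
    max_rhat: float
    converged: bool
    n_draws: int

    def quantity(self, name: str) -> tuple[float, float, float]:
        row = self.summaries.set_index("quantity").loc[name]
        return float(row["median"]), float(row["ci_low"]), float(row["ci_high"])


def _design_matrices(trials: pd.DataFrame):
    required = {"subject_id", "sex", "parental_status", "baby_id", "real_status", "response"}
    missing = required - set(trials.columns)
    if missing:
        raise ListenerError(f"trials table lacks columns: {sorted(missing)}")
    y = trials["response"].to_numpy(dtype=float)
    x_st = np.where(trials["real_status"].to_numpy() == "familiar", 0.5, -0.5)
    x_par = np.where(trials["parental_status"].to_numpy() == "parent", 0.5, -0.5)
    x_sex = np.where(trials["sex"].to_numpy() == "F", 0.5, -0.5)
    X = np.column_stack(
        [
            np.ones(len(y)),
            x_st,
            x_par,
            x_sex,
            x_st * x_par,
            x_st * x_sex,
            x_par * x_sex,
            x_st * x_par * x_sex,
        ]
    )
    subj_codes, subj_idx = np.unique(trials["subject_id"], return_inverse=True)
    baby_codes, baby_idx = np.unique(trials["baby_id"], return_inverse=True)
    Zs = np.column_stack([np.ones(len(y)), x_st])  # subject: intercept + status
    Zb = np.column_stack([np.ones(len(y)), x_st, x_par])  # baby: + parentality
    return y, X, Zs, subj_idx, len(subj_codes), Zb, baby_idx, len(baby_codes)


def _grouped_normal_update(rng, Z, idx, n_groups, omega, resid, tau2):
    """Sample per-group Gaussian effects: posterior of u_g given the PG
    auxiliaries, residual kappa - omega*psi_other, and variances tau2."""
    q = Z.shape[1]
    A = np.zeros((n_groups, q, q))
    b = np.zeros((n_groups, q))
    for a_ in range(q):
        np.add.at(b[:, a_], idx, Z[:, a_] * resid)
        for c_ in range(a_, q):
            s = np.zeros(n_groups)
            np.add.at(s, idx, omega * Z[:, a_] * Z[:, c_])
            A[:, a_, c_] = s
            A[:, c_, a_] = s
    A += np.diag(1.0 / tau2)[None, :, :]
    u = np.empty((n_groups, q))
    for g in range(n_groups):
        L = np.linalg.cholesky(A[g])
        mean = np.linalg.solve(A[g], b[g])
        z = rng.standard_normal(q)
        u[g] = mean + np.linalg.solve(L.T, z)
    return u


def fit_listener_model(
    trials: pd.DataFrame, mcmc: MCMCConfig | None = None
) -> PosteriorSummary:
    """Fit the Bernoulli-logit mixed model to a trials table.

    Returns marginal posterior rates (probability scale): familiar recognition,
    false positives, the familiar-vs-unknown contrast, and sex/parentality
    contrasts on the recognition rate.  Non-convergence (split-Rhat above the
    configured threshold) is flagged on the result, never silent.
    """
    mcmc = mcmc or MCMCConfig()
    y, X, Zs, s_idx, n_subj, Zb, b_idx, n_baby = _design_matrices(trials)
    n, p = X.shape
    kappa = y - 0.5
    mu0 = np.zeros(p)
    mu0[0] = logit(0.2)  # intercept prior centered at the chance level
    prec0 = np.eye(p)  # Normal(., 1) priors
    a0, b0 = 2.0, 0.5  # inverse-gamma hyperpriors on RE variances

    fam_mask = X[:, 1] > 0
    unk_mask = ~fam_mask
    fam_F = fam_mask & (X[:, 3] > 0)
    fam_M = fam_mask & (X[:, 3] < 0)
    fam_par = fam_mask & (X[:, 2] > 0)
    fam_non = fam_mask & (X[:, 2] < 0)

    keep = mcmc.iterations - mcmc.warmup
    qty_names = [
        "familiar_recognition",
        "false_positive",
        "familiar_vs_unknown",
        "sex_contrast",
        "parentality_contrast",
    ]
    all_draws = {q: [] for q in qty_names}
    cell_names = ["rate_fam_F", "rate_fam_M", "rate_fam_parent", "rate_fam_nonparent"]
    for q in cell_names:
        all_draws[q] = []
    beta_chains = np.empty((mcmc.chains, keep, p))

    for chain in range(mcmc.chains):
        rng = np.random.default_rng(np.random.SeedSequence([mcmc.seed, 0x6153, chain]))
        beta = mu0.copy()
        u = np.zeros((n_subj, 2))
        v = np.zeros((n_baby, 3))
        tau_u = np.full(2, 0.5)
        tau_v = np.full(3, 0.5)
        for it in range(mcmc.iterations):
            psi_s = (Zs * u[s_idx]).sum(axis=1)
            psi_b = (Zb * v[b_idx]).sum(axis=1)
            psi = X @ beta + psi_s + psi_b
            omega = _sample_pg1(rng, psi)

            # fixed effects
            resid = kappa - omega * (psi_s + psi_b)
            A = X.T @ (omega[:, None] * X) + prec0
            b_vec = X.T @ resid + prec0 @ mu0
            L = np.linalg.cholesky(A)
            mean = np.linalg.solve(A, b_vec)
            beta = mean + np.linalg.solve(L.T, rng.standard_normal(p))

            # subject effects
            xb = X @ beta
            resid = kappa - omega * (xb + psi_b)
            u = _grouped_normal_update(rng, Zs, s_idx, n_subj, omega, resid, tau_u)
            psi_s = (Zs * u[s_idx]).sum(axis=1)

            # baby effects
            resid = kappa - omega * (xb + psi_s)
            v = _grouped_normal_update(rng, Zb, b_idx, n_baby, omega, resid, tau_v)
            psi_b = (Zb * v[b_idx]).sum(axis=1)

            # RE variances (inverse-gamma conjugate updates)
            for j in range(2):
                tau_u[j] = 1.0 / rng.gamma(a0 + n_subj / 2, 1.0 / (b0 + 0.5 * (u[:, j] ** 2).sum()))
            for j in range(3):
                tau_v[j] = 1.0 / rng.gamma(a0 + n_baby / 2, 1.0 / (b0 + 0.5 * (v[:, j] ** 2).sum()))

            if it >= mcmc.warmup:
                k_ = it - mcmc.warmup
                beta_chains[chain, k_] = beta
                prob = expit(X @ beta + psi_s + psi_b)
                fam = prob[fam_mask].mean()
                unk = prob[unk_mask].mean()
                all_draws["familiar_recognition"].append(fam)
                all_draws["false_positive"].append(unk)
                all_draws["familiar_vs_unknown"].append(fam - unk)
                all_draws["sex_contrast"].append(prob[fam_F].mean() - prob[fam_M].mean())
                all_draws["parentality_contrast"].append(
                    prob[fam_par].mean() - prob[fam_non].mean()
                )
                all_draws["rate_fam_F"].append(prob[fam_F].mean())
                all_draws["rate_fam_M"].append(prob[fam_M].mean())
                all_draws["rate_fam_parent"].append(prob[fam_par].mean())
                all_draws["rate_fam_nonparent"].append(prob[fam_non].mean())

    draws = {q: np.asarray(vals) for q, vals in all_draws.items()}
    rows = []
    for q in qty_names:
        d = draws[q]
        rows.append(
            {
                "quantity": q,
                "median": float(np.median(d)),
                "ci_low": float(np.percentile(d, 2.5)),
                "ci_high": float(np.percentile(d, 97.5)),
            }
        )
    summaries = pd.DataFrame(rows)

    import arviz as az

    fe = {term: beta_chains[:, :, j] for j, term in enumerate(_FIXED_TERMS)}
    if mcmc.chains > 1:
        rhats = az.rhat(az.convert_to_dataset(fe))
        max_rhat = float(max(rhats[t].values for t in _FIXED_TERMS))
    else:
        max_rhat = float("nan")
    converged = not (max_rhat > mcmc.rhat_threshold)
    return PosteriorSummary(
        summaries=summaries,
        draws=draws,
        fixed_effect_draws=fe,
        max_rhat=max_rhat,
        converged=converged,
        n_draws=mcmc.chains * keep,
    )


def contrast_draws(posterior: PosteriorSummary, group_a: str, group_b: str) -> np.ndarray:
    """Posterior draws of the marginal-rate difference between two groups
    (by stored cell-rate name); a group contrasted with itself is exactly 0."""
    for g in (group_a, group_b):
        if g not in posterior.draws:
            raise ListenerError(f"unknown group rate {g!r}")
    return posterior.draws[group_a] - posterior.draws[group_b]


def contrast_summaries(posterior: PosteriorSummary) -> pd.DataFrame:
    """Marginal contrasts (probability scale) with medians, 95% CIs and a
    'credible' flag set when the interval excludes zero."""
    rows = []
    for name in ("familiar_vs_unknown", "sex_contrast", "parentality_contrast"):
        d = posterior.draws[name]
        lo, hi = np.percentile(d, [2.5, 97.5])
        rows.append(
            {
                "contrast": name,
                "median": float(np.median(d)),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "credible": bool(lo > 0 or hi < 0),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# machine listener

def machine_listener(
    features,
    baby_sex: dict,
    design: ExperimentDesign | None = None,
    seed: int = 0,
    n_train: int = 10,
) -> dict:
    """Replay the human protocol with a two-class linear discriminant.

    For every baby with at least ``n_train`` discomfort cries and enough pain
    cries, an LDA (on 20 MPS principal components fitted to the training cries)
    is trained to separate that baby's discomfort cries from the other babies'
    discomfort cries, then applied to 20 pain cries: 4 familiar + 4 per
    unknown baby (2 boys, 2 girls).  Reports hit rate, false-alarm rate and
    percent correct on familiar trials, averaged over familiar babies.
    """
    from sklearn.decomposition import PCA
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.preprocessing import StandardScaler

    design = design or ExperimentDesign()
    design.validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x3AC]))
    X = np.asarray(features.X, dtype=float)
    babies = np.asarray(features.baby_ids)
    conds = np.asarray(features.conditions)

    def _count(b, c):
        return int(np.sum((babies == b) & (conds == c)))

    candidates = [
        b
        for b in sorted(set(babies))
        if _count(b, "discomfort") >= n_train and _count(b, "pain") >= design.n_familiar_test
    ]
    pain_ok = [
        b for b in sorted(set(babies)) if _count(b, "pain") >= design.cries_per_unknown
    ]
    shortfalls = []
    if not candidates:
        shortfalls.append(f"no baby has >= {n_train} discomfort and >= "
                          f"{design.n_familiar_test} pain cries")
    if len(pain_ok) < design.n_unknown_babies + 1:
        shortfalls.append(
            f"need {design.n_unknown_babies + 1} babies with >= "
            f"{design.cries_per_unknown} pain cries, have {len(pain_ok)}"
        )
    if shortfalls:
        raise ListenerError("machine listener cannot run: " + "; ".join(shortfalls))

    rows = []
    for fam in candidates:
        boys = [b for b in pain_ok if b != fam and baby_sex[b] == "M"]
        girls = [b for b in pain_ok if b != fam and baby_sex[b] == "F"]
        if len(boys) < 2 or len(girls) < 2:
            continue
        unknown = list(rng.choice(boys, 2, replace=False)) + list(
            rng.choice(girls, 2, replace=False)
        )
        fam_disc = np.flatnonzero((babies == fam) & (conds == "discomfort"))
        fam_disc = rng.choice(fam_disc, n_train, replace=False)
        other_disc = np.flatnonzero((babies != fam) & (conds == "discomfort"))
        train_idx = np.concatenate([fam_disc, other_disc])
        y_train = np.concatenate(
            [np.ones(len(fam_disc)), np.zeros(len(other_disc))]
        )
        fam_pain = np.flatnonzero((babies == fam) & (conds == "pain"))
        fam_pain = rng.choice(fam_pain, design.n_familiar_test, replace=False)
        unk_pain = []
        for b in unknown:
            idx = np.flatnonzero((babies == b) & (conds == "pain"))
            unk_pain.extend(rng.choice(idx, design.cries_per_unknown, replace=False))
        test_idx = np.concatenate([fam_pain, np.asarray(unk_pain, dtype=int)])
        is_fam = np.concatenate(
            [np.ones(len(fam_pain), bool), np.zeros(len(unk_pain), bool)]
        )

        scaler = StandardScaler().fit(X[train_idx])
        Xt = scaler.transform(X[train_idx])
        k = min(20, Xt.shape[0] - 1, Xt.shape[1])
        pca = PCA(n_components=k, random_state=seed).fit(Xt)
        # balanced priors: the listener has no base-rate information, so the
        # decision must not inherit the 1:many training imbalance
        lda = LinearDiscriminantAnalysis(
            solver="lsqr", shrinkage=0.1, priors=[0.5, 0.5]
        )
        lda.fit(pca.transform(Xt), y_train)
        pred = lda.predict(pca.transform(scaler.transform(X[test_idx])))
        rows.append(
            {
                "familiar_baby": fam,
                "hit_rate": float(pred[is_fam].mean()),
                "false_alarm_rate": float(pred[~is_fam].mean()),
            }
        )
    per_baby = pd.DataFrame(rows)
    n = len(per_baby)
    return {
        "per_baby": per_baby,
        "mean_hit_rate": float(per_baby["hit_rate"].mean()),
        "hit_rate_2se": float(2 * per_baby["hit_rate"].std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        "mean_false_alarm_rate": float(per_baby["false_alarm_rate"].mean()),
        "false_alarm_2se": float(2 * per_baby["false_alarm_rate"].std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        "percent_correct_familiar": float(100 * per_baby["hit_rate"].mean()),
    }
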