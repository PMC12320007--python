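"""Group-level random-effects Bayesian model selection and averaging.

Random-effects BMS treats the best model as varying across subjects: model
frequencies r follow a Dirichlet distribution whose concentration
parameters are estimated from the per-subject log evidences (free
energies) by the usual variational scheme.  Reported are the expected
posterior probability of each model and its exceedance probability — the
probability that it is the most frequent model in the population,
estimated by Monte-Carlo over the fitted Dirichlet.

Random-effects BMA averages parameters over models inside an Occam's
window and over subjects, by sampling: draw a model per subject from its
posterior assignment probabilities, draw parameters from that model's
Gaussian posterior (parameters absent from a model contribute zero), and
aggregate.  Sign probabilities P(parameter > 0) use the Gaussian CDF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import json
import numpy as np
import pandas as pd
from scipy.special import digamma
from scipy.stats import norm

from .inversion import Posterior
from .network_model import MODULATORY_INPUTS, N_REGIONS, REGIONS

__all__ = [
    "BMSResult",
    "BMAResult",
    "rfx_bms",
    "rfx_bma",
    "log_bayes_factor",
    "sign_probability",
]


@dataclass
class BMSResult:
    """Random-effects model-selection summary."""

    alpha: np.ndarray            # Dirichlet concentrations, one per model
    expected_prob: np.ndarray    # r_k = E[model frequency]
    exceedance_prob: np.ndarray  # xp_k
    assignment: np.ndarray       # (subjects, models) posterior assignments
    model_ids: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "models": list(self.model_ids),
            "alpha": self.alpha.tolist(),
            "expected_prob": self.expected_prob.tolist(),
            "exceedance_prob": self.exceedance_prob.tolist(),
        }


def rfx_bms(
    evidence: np.ndarray | pd.DataFrame,
    mc_samples: int = 1_000_000,
    seed: int = 0,
    model_ids: tuple[str, ...] | None = None,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> BMSResult:
    """Variational Dirichlet scheme over model frequencies.

    ``evidence`` is a (subjects x models) table of free energies in nats.
    A uniform Dirichlet(1) prior over frequencies is assumed; the fixed
    point iterates expected per-subject model assignments (softmax of
    evidence plus digamma terms) against the concentration parameters
    until the concentration change falls below ``tol``.
    """
    if isinstance(evidence, pd.DataFrame):
        if model_ids is None:
            model_ids = tuple(str(c) for c in evidence.columns)
        f = evidence.to_numpy(dtype=float)
    else:
        f = np.asarray(evidence, dtype=float)
    if f.ndim != 2 or f.shape[1] < 2 or f.shape[0] < 1:
        raise ValueError("evidence must be (subjects >= 1) x (models >= 2)")
    if not np.all(np.isfinite(f)):
        raise ValueError("evidence table contains non-finite values")
    n_sub, n_mod = f.shape
    if model_ids is None:
        model_ids = tuple(f"M{k + 1}" for k in range(n_mod))

    alpha0 = np.ones(n_mod)
    alpha = alpha0.copy()
    g = np.full((n_sub, n_mod), 1.0 / n_mod)
    for _ in range(max_iter):
        log_u = f + (digamma(alpha) - digamma(alpha.sum()))[None, :]
        log_u -= log_u.max(axis=1, keepdims=True)
        u = np.exp(log_u)
        g = u / u.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new

    r = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=int(mc_samples))
    winners = np.argmax(draws, axis=1)
    xp = np.bincount(winners, minlength=n_mod) / float(mc_samples)
    return BMSResult(
        alpha=alpha,
        expected_prob=r,
        exceedance_prob=xp,
        assignment=g,
        model_ids=tuple(model_ids),
    )


def log_bayes_factor(f_a: float, f_b: float) -> float:
    """Log Bayes factor of model a over model b from their free energies."""
    if not (np.isfinite(f_a) and np.isfinite(f_b)):
        raise ValueError("free energies must be finite")
    return float(f_a) - float(f_b)


def sign_probability(mean: float, variance: float) -> float:
    """Posterior probability that a Gaussian parameter exceeds zero."""
    if variance < 0:
        raise ValueError("variance must be non-negative")
    if variance == 0:
        return 1.0 if mean > 0 else (0.0 if mean < 0 else 0.5)
    return float(1.0 - norm.cdf(-mean / np.sqrt(variance)))


# ---------------------------------------------------------------------------
# BMA
# ---------------------------------------------------------------------------


def _named_entries() -> list[tuple]:
    """Canonical full parameter table: every A, B and C entry."""
    entries: list[tuple] = []
    for i in range(N_REGIONS):
        for j in range(N_REGIONS):
            entries.append(("A", i, j) if i != j else ("Aself", i))
    for m in range(len(MODULATORY_INPUTS)):
        for i in range(N_REGIONS):
            for j in range(N_REGIONS):
                if i != j:
                    entries.append(("B", m, i, j))
    for i in range(N_REGIONS):
        for k in range(3):
            entries.append(("C", i, k))
    return entries


def entry_label(entry: tuple) -> str:
    """Human-readable key, e.g. ``B[CF] lFFA->rFFA`` or ``A lV1->lOFA``."""
    kind = entry[0]
    if kind == "A":
        _, i, j = entry
        return f"A {REGIONS[j]}->{REGIONS[i]}"
    if kind == "Aself":
        return f"Aself {REGIONS[entry[1]]}"
    if kind == "B":
        _, m, i, j = entry
        return f"B[{MODULATORY_INPUTS[m]}] {REGIONS[j]}->{REGIONS[i]}"
    if kind == "C":
        _, i, k = entry
        return f"C[{('CS', 'LS', 'RS')[k]}] {REGIONS[i]}"
    raise ValueError(f"unknown entry {entry}")


@dataclass
class BMAResult:
    """Model-averaged parameters, per subject and group-aggregated.

    ``subject_mean``/``subject_var`` are (subjects x parameters) frames of
    the per-subject model-averaged posterior mean and variance; the group
    summary is the across-subject average of subject means, its
    Monte-Carlo variance, and the resulting sign probability.  All
    parameters are always tabulated; sign-probability thresholding is left
    to the caller's reporting.
    """

    entries: list[tuple]
    subject_mean: pd.DataFrame
    subject_var: pd.DataFrame
    group_mean: pd.Series
    group_var: pd.Series
    sign_prob: pd.Series
    models_in_window: tuple[str, ...]

    def parameter_table(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "mean": self.group_mean,
                "var": self.group_var,
                "sign_prob": self.sign_prob,
            }
        )
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.parameter_table().rename_axis("parameter").to_csv(path, sep="\t")


def rfx_bma(
    posteriors: list[list[Posterior]],
    evidence: np.ndarray | pd.DataFrame,
    window_odds: float = 0.05,
    window_mode: str = "odds",
    mc_samples: int = 5_000,
    seed: int = 0,
    bms: BMSResult | None = None,
) -> BMAResult:
    """Random-effects Bayesian model averaging.

    ``posteriors[s][k]`` is subject ``s``'s posterior under model ``k``
    (aligned with the evidence columns).  Models outside the Occam's
    window are excluded: with ``window_mode="odds"`` (default) a model is
    kept if its posterior frequency (mean per-subject assignment
    probability) is at least ``window_odds`` times the best model's; with
    ``"absolute"`` if that frequency exceeds ``window_odds`` outright.
    The best model is always retained.

    Averaging is by sampling: per draw and subject, a model is drawn from
    the subject's BMS assignment probabilities (restricted to the window,
    renormalised) and a parameter vector from that model's Gaussian
    posterior; parameters a model lacks contribute zero.  Deterministic
    for a fixed seed.
    """
    if bms is None:
        bms = rfx_bms(evidence, mc_samples=100_000, seed=seed)
    n_sub = bms.assignment.shape[0]
    n_mod = bms.assignment.shape[1]
    if len(posteriors) != n_sub or any(len(row) != n_mod for row in posteriors):
        raise ValueError("posterior grid does not match the evidence table")

    # Window on the posterior model frequency estimated from the data
    # (mean per-subject assignment probability).  The Dirichlet-smoothed
    # expected_prob is unsuitable here: its uniform prior floors every
    # model at 1/(K + S), so an odds window could never exclude anything
    # for small cohorts regardless of how decisive the evidence is.
    gbar = bms.assignment.mean(axis=0)
    if window_mode == "odds":
        keep = gbar >= window_odds * gbar.max()
    elif window_mode == "absolute":
        keep = gbar >= window_odds
    else:
        raise ValueError("window_mode must be 'odds' or 'absolute'")
    keep[np.argmax(gbar)] = True  # the best model can never drop out

    g = bms.assignment * keep[None, :]
    g = g / g.sum(axis=1, keepdims=True)

    entries = _named_entries()
    labels = [entry_label(e) for e in entries]
    n_par = len(entries)

    # per subject/model: projection of the free vector onto the full table
    rng = np.random.default_rng(seed)
    chol: dict[tuple[int, int], np.ndarray] = {}
    proj: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    for s in range(n_sub):
        for k in range(n_mod):
            if not keep[k]:
                continue
            post = posteriors[s][k]
            cov = post.cov
            w, v = np.linalg.eigh(0.5 * (cov + cov.T))
            w = np.clip(w, 0.0, None)
            chol[(s, k)] = v * np.sqrt(w)[None, :]
            rows, cols = [], []
            for p_idx, e in enumerate(entries):
                kpos = post.index._pos.get(e)
                if kpos is not None:
                    rows.append(p_idx)
                    cols.append(kpos)
            proj[(s, k)] = (np.array(rows, dtype=int), np.array(cols, dtype=int))

    sub_sum = np.zeros((n_sub, n_par))
    sub_sumsq = np.zeros((n_sub, n_par))
    group_draws = np.zeros((mc_samples, n_par))
    model_choices = np.array(
        [rng.choice(n_mod, size=mc_samples, p=g[s]) for s in range(n_sub)]
    )
    for d in range(mc_samples):
        acc = np.zeros(n_par)
        for s in range(n_sub):
            k = model_choices[s, d]
            post = posteriors[s][k]
            z = rng.standard_normal(len(post.mean))
            theta = post.mean + chol[(s, k)] @ z
            full = np.zeros(n_par)
            rows, cols = proj[(s, k)]
            full[rows] = theta[cols]
            sub_sum[s] += full
            sub_sumsq[s] += full**2
            acc += full
        group_draws[d] = acc / n_sub

    sub_mean = sub_sum / mc_samples
    sub_var = sub_sumsq / mc_samples - sub_mean**2
    grp_mean = group_draws.mean(axis=0)
    grp_var = group_draws.var(axis=0, ddof=0)
    sign = np.array(
        [sign_probability(m, v) for m, v in zip(grp_mean, grp_var)]
    )

    return BMAResult(
        entries=entries,
        subject_mean=pd.DataFrame(sub_mean, columns=labels),
        subject_var=pd.DataFrame(sub_var, columns=labels),
        group_mean=pd.Series(grp_mean, index=labels),
        group_var=pd.Series(grp_var, index=labels),
        sign_prob=pd.Series(sign, index=labels),
        models_in_window=tuple(
            m for m, k in zip(bms.model_ids, keep) if k
        ),
    )
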