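"""Random-effects Bayesian model selection (RFX BMS).

Treats the model generating each subject's data as a latent categorical
variable with unknown population frequencies r ~ Dirichlet(alpha). Given a
subjects x models matrix of log model evidences, variational updates yield
a Dirichlet posterior over frequencies, from which we report

- expected probabilities  E[r_k] = alpha_k / sum(alpha),
- exceedance probabilities P(r_k > r_j for all j != k), by Monte Carlo
  (exact via the regularised incomplete beta function when K = 2),
- the Bayesian omnibus risk (BOR): the posterior probability that all
  model frequencies are equal, i.e. that evidence differences are chance.

Family-level inference runs the same machinery with prior counts 1/m_j for
a model in a family of size m_j, so every family starts with equal prior
mass, and aggregates the Dirichlet posterior over family members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betainc, digamma, gammaln, logsumexp

from .model_space import FamilyPartition


@dataclass
class LogEvidenceMatrix:
    """Subjects x models free-energy approximations to log model evidence."""

    values: np.ndarray
    subject_ids: list[str]
    model_ids: list[int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.model_ids)):
            raise ValueError("evidence matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("evidence matrix contains non-finite entries")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_models(self) -> int:
        return self.values.shape[1]

    def select_models(self, model_ids: list[int]) -> "LogEvidenceMatrix":
        cols = [self.model_ids.index(m) for m in model_ids]
        return LogEvidenceMatrix(self.values[:, cols], list(self.subject_ids), list(model_ids))

    def to_csv(self, path: str) -> None:
        pd.DataFrame(self.values, index=self.subject_ids, columns=self.model_ids).to_csv(
            path, index_label="subject"
        )

    @classmethod
    def from_csv(cls, path: str) -> "LogEvidenceMatrix":
        df = pd.read_csv(path, index_col="subject")
        return cls(df.to_numpy(), [str(s) for s in df.index], [int(c) for c in df.columns])


@dataclass
class DirichletPosterior:
    alpha: np.ndarray
    alpha0: np.ndarray
    u: np.ndarray  # subjects x models assignment weights, rows sum to 1
    iterations: int
    converged: bool
    final_delta: float


@dataclass
class BMSResult:
    """Group-level comparison report (model- or family-level)."""

    level: str  # "model" | "family"
    names: list[str]
    expected_probs: np.ndarray
    exceedance_probs: np.ndarray
    protected_exceedance_probs: np.ndarray  # BOR-weighted extension
    bor: float
    posterior: DirichletPosterior = field(repr=False)
    mc_samples: int = 0
    seed: int | None = None
    n_models_used: int = 0  # columns entering the comparison

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names,
                "expected_prob": self.expected_probs,
                "exceedance_prob": self.exceedance_probs,
                "protected_exceedance_prob": self.protected_exceedance_probs,
            }
        )


def rfx_bms(
    L: LogEvidenceMatrix | np.ndarray,
    alpha0: float | np.ndarray = 1.0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> DirichletPosterior:
    """Variational Dirichlet posterior over model frequencies.

    Iterates assignment weights u_nk proportional to
    exp(L_nk + psi(alpha_k) - psi(sum alpha)) and counts
    alpha = alpha0 + sum_n u_n until max |delta alpha| < tol.
    """
    values = L.values if isinstance(L, LogEvidenceMatrix) else np.asarray(L, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("log evidences must be finite")
    n, k = values.shape
    a0 = np.broadcast_to(np.asarray(alpha0, dtype=float), (k,)).copy()
    if np.any(a0 <= 0):
        raise ValueError("alpha0 must be positive")

    alpha = a0.copy() + float(n) / k
    delta = np.inf
    u = np.full((n, k), 1.0 / k)
    for it in range(1, max_iter + 1):
        logu = values + digamma(alpha) - digamma(alpha.sum())
        logu -= logsumexp(logu, axis=1, keepdims=True)
        u = np.exp(logu)
        alpha_new = a0 + u.sum(axis=0)
        delta = float(np.abs(alpha_new - alpha).max())
        alpha = alpha_new
        if delta < tol:
            return DirichletPosterior(alpha, a0, u, it, True, delta)
    return DirichletPosterior(alpha, a0, u, max_iter, False, delta)


def expected_probs(post: DirichletPosterior) -> np.ndarray:
    return post.alpha / post.alpha.sum()


def exceedance_probs(
    post: DirichletPosterior,
    n_samples: int = 1_000_000,
    seed: int | None = None,
    groups: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Monte Carlo exceedance probabilities (argmax frequencies).

    ``groups`` aggregates sampled frequencies before the argmax (family
    level). Ties break to the first index -- a probability-zero event for
    continuous Dirichlet draws. Counts partition the samples, so the
    result sums to 1 exactly.
    """
    if n_samples < 10_000:
        raise ValueError("use at least 1e4 Monte Carlo samples")
    rng = np.random.default_rng(seed)
    k_out = len(groups) if groups is not None else len(post.alpha)
    counts = np.zeros(k_out, dtype=np.int64)
    chunk = 100_000
    done = 0
    while done < n_samples:
        m = min(chunk, n_samples - done)
        r = rng.dirichlet(post.alpha, size=m)
        if groups is not None:
            r = np.column_stack([r[:, g].sum(axis=1) for g in groups])
        counts += np.bincount(np.argmax(r, axis=1), minlength=k_out)
        done += m
    return counts / n_samples


def exceedance_exact_k2(post: DirichletPosterior) -> np.ndarray:
    """Exact two-model exceedance: P(r1 > 0.5) for r1 ~ Beta(a1, a2)."""
    if len(post.alpha) != 2:
        raise ValueError("exact form only available for K = 2")
    a1, a2 = post.alpha
    p1 = 1.0 - betainc(a1, a2, 0.5)  # survival of Beta(a1, a2) at 1/2
    return np.array([p1, 1.0 - p1])


def _dirichlet_kl(alpha: np.ndarray, alpha0: np.ndarray) -> float:
    """KL( Dir(alpha) || Dir(alpha0) )."""
    a_sum, a0_sum = alpha.sum(), alpha0.sum()
    return float(
        gammaln(a_sum)
        - gammaln(alpha).sum()
        - gammaln(a0_sum)
        + gammaln(alpha0).sum()
        + ((alpha - alpha0) * (digamma(alpha) - digamma(a_sum))).sum()
    )


def _free_energy_h1(values: np.ndarray, post: DirichletPosterior) -> float:
    """Variational lower bound of the random-effects model."""
    u = post.u
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = -np.where(u > 0, u * np.log(u), 0.0).sum()
    e_logr = digamma(post.alpha) - digamma(post.alpha.sum())
    return float((u * values).sum() + entropy + (u * e_logr).sum() - _dirichlet_kl(post.alpha, post.alpha0))


def _free_energy_h0(values: np.ndarray, alpha0: np.ndarray | None = None) -> float:
    """Evidence under the null of equal (fixed, known) frequencies.

    With uniform prior counts this is sum_n [logsumexp_k L_nk - log K];
    non-uniform prior counts (family-level) weight models by alpha0.
    """
    n, k = values.shape
    if alpha0 is None:
        logw = np.full(k, -np.log(k))
    else:
        logw = np.log(alpha0) - np.log(alpha0.sum())
    return float(logsumexp(values + logw, axis=1).sum())


def bayesian_omnibus_risk(
    L: LogEvidenceMatrix | np.ndarray, post: DirichletPosterior
) -> float:
    """BOR = 1 / (1 + exp(F1 - F0)): posterior probability of the null
    (all model frequencies equal) against the random-effects alternative."""
    values = L.values if isinstance(L, LogEvidenceMatrix) else np.asarray(L, dtype=float)
    f1 = _free_energy_h1(values, post)
    f0 = _free_energy_h0(values, post.alpha0)
    return float(1.0 / (1.0 + np.exp(np.clip(f1 - f0, -700, 700))))


def protected_exceedance(xp: np.ndarray, bor: float) -> np.ndarray:
    """BOR-weighted exceedance: chance-level under the null, xp otherwise."""
    k = len(xp)
    return (1.0 - bor) * xp + bor / k


def model_bms(
    L: LogEvidenceMatrix,
    alpha0: float = 1.0,
    n_samples: int = 1_000_000,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> BMSResult:
    """Model-level RFX comparison with uniform prior counts."""
    post = rfx_bms(L, alpha0=alpha0, tol=tol, max_iter=max_iter)
    xp = exceedance_probs(post, n_samples=n_samples, seed=seed)
    bor = bayesian_omnibus_risk(L, post)
    return BMSResult(
        level="model",
        names=[str(m) for m in L.model_ids],
        expected_probs=expected_probs(post),
        exceedance_probs=xp,
        protected_exceedance_probs=protected_exceedance(xp, bor),
        bor=bor,
        posterior=post,
        mc_samples=n_samples,
        seed=seed,
        n_models_used=L.n_models,
    )


def family_evidence(
    L: LogEvidenceMatrix, partition: FamilyPartition
) -> tuple[LogEvidenceMatrix, list[str]]:
    """Subjects x families log evidence: models are marginalised within
    their family under a uniform within-family prior,

        L_nj = logsumexp_{k in j} L_nk  -  log m_j,

    which gives every family equal prior mass regardless of size."""
    covered = partition.model_ids
    missing = [m for m in covered if m not in L.model_ids]
    if missing:
        raise ValueError(f"partition covers models absent from the evidence matrix: {missing}")
    Lsub = L.select_models(covered)
    col_of = {m: j for j, m in enumerate(Lsub.model_ids)}
    names = list(partition.groups)
    vals = np.empty((Lsub.n_subjects, len(names)))
    for j, name in enumerate(names):
        cols = [col_of[m] for m in partition.groups[name]]
        vals[:, j] = logsumexp(Lsub.values[:, cols], axis=1) - np.log(len(cols))
    fam_ids = list(range(1, len(names) + 1))
    return LogEvidenceMatrix(vals, list(Lsub.subject_ids), fam_ids), names


def family_bms(
    L: LogEvidenceMatrix,
    partition: FamilyPartition,
    n_samples: int = 1_000_000,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> BMSResult:
    """Family-level RFX comparison.

    Columns are restricted to the models the partition covers (merged
    schemes exclude the Null family). Models are first marginalised within
    each family under a uniform 1/m_j prior (equal prior mass per family);
    the random-effects machinery then runs over family frequencies with
    unit prior counts. With uninformative evidence this reproduces the
    exact prior (equal family probabilities) -- the naive alternative of
    feeding per-model counts alpha0 = 1/m_j straight into the mean-field
    update does not, because sub-unity asymmetric counts make the
    digamma-weighted assignment step prior-dominated.
    """
    Lfam, names = family_evidence(L, partition)
    post = rfx_bms(Lfam, alpha0=1.0, tol=tol, max_iter=max_iter)
    xp_fam = exceedance_probs(post, n_samples=n_samples, seed=seed)
    bor = bayesian_omnibus_risk(Lfam, post)
    return BMSResult(
        level="family",
        names=names,
        expected_probs=expected_probs(post),
        exceedance_probs=xp_fam,
        protected_exceedance_probs=protected_exceedance(xp_fam, bor),
        bor=bor,
        posterior=post,
        mc_samples=n_samples,
        seed=seed,
        n_models_used=len(partition.model_ids),
    )


def fixed_effects_log_group_bayes_factor(L: LogEvidenceMatrix) -> np.ndarray:
    """Summed log evidences (fixed-effects group comparison), relative to
    the best model. Debug output only; group inferences here use RFX."""
    tot = L.values.sum(axis=0)
    return tot - tot.max()
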