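"""Linear latent-variable (SEM) engine: implied moments, FIML, fit indices.

The engine uses the RAM (reticular action model) parameterization.  A model
over variables v_1..v_k (observed and latent) is described by

* a directed-path matrix ``A`` (regressions and factor loadings),
* a symmetric matrix ``S`` of variances / covariances of exogenous parts,
* a mean / intercept vector ``m``,
* a selector ``F`` picking out the observed variables.

The model-implied moments over the observed variables are

    Sigma = F (I - A)^{-1} S (I - A)^{-T} F^T
    mu    = F (I - A)^{-1} m

Estimation maximizes the full-information maximum-likelihood (FIML)
criterion: each person contributes the log multivariate-normal density of
their *observed* sub-vector under the matching sub-matrices of (mu, Sigma),
so missing entries are handled without imputation.  Equality constraints
are expressed by giving several parameters the same label; every distinct
free label is one estimated quantity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import linalg, optimize, stats
from statsmodels.tools import numdiff


class SemError(Exception):
    """Base error for model specification / estimation problems."""


class StructuralCycleError(SemError):
    """(I - A) is singular: the directed-path graph contains a cycle."""


class IdentificationError(SemError):
    """The model cannot be estimated from the data provided."""


class EstimationError(SemError):
    """The likelihood is undefined (e.g. non-PD implied covariance)."""


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Param:
    """A single model parameter.

    ``value`` is the fixed value (if not free) or the starting value (if
    free).  ``label`` names the parameter; free parameters must be labelled,
    and sharing a label imposes an equality constraint.  A *fixed* parameter
    may still carry a label so constraint-editing utilities can address it.
    """

    value: float
    label: str | None = None
    free: bool = False

    def __post_init__(self):
        if self.free and self.label is None:
            raise SemError("free parameters must carry a label")


def free(label: str, start: float = 0.0) -> Param:
    return Param(start, label, True)


def fixed(value: float, label: str | None = None) -> Param:
    return Param(value, label, False)


def _covkey(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class ModelSpec:
    """A linear latent-variable model as labelled parameter matrices.

    ``paths`` maps (source, target) to the regression/loading parameter,
    ``covariances`` maps unordered variable pairs (variances on the
    diagonal) to exogenous (co)variance parameters, and ``means`` maps a
    variable to its intercept/mean parameter.  Unlisted entries are fixed
    zeros.
    """

    name: str
    variables: tuple[str, ...]
    observed: tuple[str, ...]
    paths: Mapping[tuple[str, str], Param] = field(default_factory=dict)
    covariances: Mapping[tuple[str, str], Param] = field(default_factory=dict)
    means: Mapping[str, Param] = field(default_factory=dict)

    def __post_init__(self):
        known = set(self.variables)
        for (a, b) in self.paths:
            if a not in known or b not in known:
                raise SemError(f"path {a}->{b} references unknown variable")
        for (a, b) in self.covariances:
            if a not in known or b not in known:
                raise SemError(f"covariance {a}~~{b} references unknown variable")
            if (a, b) != _covkey(a, b):
                raise SemError(f"covariance key ({a},{b}) must be sorted; use cov()")
        for v in self.means:
            if v not in known:
                raise SemError(f"mean of unknown variable {v}")
        missing = set(self.observed) - known
        if missing:
            raise SemError(f"observed variables not declared: {sorted(missing)}")

    # -- bookkeeping ------------------------------------------------------

    def _all_params(self) -> Iterable[tuple[str, Param]]:
        for (a, b), p in self.paths.items():
            yield f"{a}->{b}", p
        for (a, b), p in self.covariances.items():
            yield f"{a}~~{b}", p
        for v, p in self.means.items():
            yield f"mean({v})", p

    @property
    def free_labels(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for _, p in self._all_params():
            if p.free and p.label not in seen:
                seen[p.label] = None
        return tuple(seen)

    @property
    def n_free(self) -> int:
        return len(self.free_labels)

    @property
    def n_moments(self) -> int:
        p = len(self.observed)
        return p * (p + 3) // 2  # p means + p(p+1)/2 (co)variances

    @property
    def df(self) -> int:
        return self.n_moments - self.n_free

    def start_values(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for _, p in self._all_params():
            if p.free and p.label not in out:
                out[p.label] = p.value
        return out

    # -- constraint editing ----------------------------------------------

    def _edit(self, fn) -> "ModelSpec":
        return replace(
            self,
            paths={k: fn(p) for k, p in self.paths.items()},
            covariances={k: fn(p) for k, p in self.covariances.items()},
            means={k: fn(p) for k, p in self.means.items()},
        )

    def _check_labels(self, labels: Sequence[str]):
        have = {p.label for _, p in self._all_params() if p.label is not None}
        unknown = [l for l in labels if l not in have]
        if unknown:
            raise SemError(
                f"unknown parameter label(s) {unknown}; available: {sorted(have)}"
            )

    def free_params(self, labels: Sequence[str]) -> "ModelSpec":
        """Return a copy with the given labelled parameters set free."""
        self._check_labels(labels)
        return self._edit(
            lambda p: replace(p, free=True) if p.label in labels else p
        )

    def fix_params(self, labels: Sequence[str], value: float | None = None) -> "ModelSpec":
        """Return a copy with the given parameters fixed (optionally to ``value``)."""
        self._check_labels(labels)

        def fn(p: Param) -> Param:
            if p.label in labels:
                return replace(p, free=False, value=p.value if value is None else value)
            return p

        return self._edit(fn)

    def equate_params(self, labels: Sequence[str], new_label: str) -> "ModelSpec":
        """Return a copy where all ``labels`` share ``new_label`` (one estimate)."""
        self._check_labels(labels)
        return self._edit(
            lambda p: replace(p, label=new_label) if p.label in labels else p
        )

    def relabel(self, mapping: Mapping[str, str]) -> "ModelSpec":
        """Rename labels (used e.g. to make group-specific copies)."""
        return self._edit(
            lambda p: replace(p, label=mapping[p.label])
            if p.label in mapping
            else p
        )

    def set_start(self, values: Mapping[str, float]) -> "ModelSpec":
        return self._edit(
            lambda p: replace(p, value=values[p.label])
            if (p.free and p.label in values)
            else p
        )

    # -- serialization ----------------------------------------------------

    def to_text(self) -> str:
        """Human-readable audit form of the specification."""
        lines = [f"model {self.name}"]
        lines.append("variables " + " ".join(self.variables))
        lines.append("observed " + " ".join(self.observed))

        def fmt(p: Param) -> str:
            tag = "free" if p.free else "fixed"
            lab = p.label if p.label is not None else "-"
            return f"{tag} {lab} {p.value!r}"

        for (a, b), p in self.paths.items():
            lines.append(f"path {a} {b} {fmt(p)}")
        for (a, b), p in self.covariances.items():
            lines.append(f"cov {a} {b} {fmt(p)}")
        for v, p in self.means.items():
            lines.append(f"mean {v} {fmt(p)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ModelSpec":
        name = "model"
        variables: tuple[str, ...] = ()
        observed: tuple[str, ...] = ()
        paths: dict = {}
        covs: dict = {}
        means: dict = {}

        def parse_param(tok: list[str]) -> Param:
            tag, lab, val = tok
            return Param(float(val), None if lab == "-" else lab, tag == "free")

        for raw in text.splitlines():
            tok = raw.split()
            if not tok:
                continue
            kind = tok[0]
            if kind == "model":
                name = tok[1]
            elif kind == "variables":
                variables = tuple(tok[1:])
            elif kind == "observed":
                observed = tuple(tok[1:])
            elif kind == "path":
                paths[(tok[1], tok[2])] = parse_param(tok[3:6])
            elif kind == "cov":
                covs[_covkey(tok[1], tok[2])] = parse_param(tok[3:6])
            elif kind == "mean":
                means[tok[1]] = parse_param(tok[2:5])
            else:
                raise SemError(f"unrecognized spec line: {raw!r}")
        return cls(name, variables, observed, paths, covs, means)


# ---------------------------------------------------------------------------
# Compiled model: fast evaluation of implied moments
# ---------------------------------------------------------------------------


class CompiledModel:
    """Index-based evaluator mapping a parameter vector to RAM matrices."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.labels = list(spec.free_labels)
        self.index = {l: i for i, l in enumerate(self.labels)}
        nv = len(spec.variables)
        vi = {v: i for i, v in enumerate(spec.variables)}
        self.nv = nv
        self.obs_idx = np.array([vi[v] for v in spec.observed], dtype=int)

        self.A0 = np.zeros((nv, nv))
        self.S0 = np.zeros((nv, nv))
        self.m0 = np.zeros(nv)
        self.A_fill: list[tuple[int, int, int]] = []  # (row=target, col=source, k)
        self.S_fill: list[tuple[int, int, int]] = []
        self.m_fill: list[tuple[int, int]] = []
        self.var_param_labels: set[str] = set()  # labels sitting on S diagonals

        for (src, dst), p in spec.paths.items():
            i, j = vi[dst], vi[src]
            if p.free:
                self.A_fill.append((i, j, self.index[p.label]))
            else:
                self.A0[i, j] = p.value
        for (a, b), p in spec.covariances.items():
            i, j = vi[a], vi[b]
            if p.free:
                self.S_fill.append((i, j, self.index[p.label]))
                if i == j:
                    self.var_param_labels.add(p.label)
            else:
                self.S0[i, j] = self.S0[j, i] = p.value
        for v, p in spec.means.items():
            i = vi[v]
            if p.free:
                self.m_fill.append((i, self.index[p.label]))
            else:
                self.m0[i] = p.value

    @property
    def n_free(self) -> int:
        return len(self.labels)

    def start_vector(self) -> np.ndarray:
        sv = self.spec.start_values()
        return np.array([sv[l] for l in self.labels])

    def values_to_vector(self, values: Mapping[str, float]) -> np.ndarray:
        missing = [l for l in self.labels if l not in values]
        if missing:
            raise SemError(f"no value supplied for free label(s) {missing}")
        return np.array([values[l] for l in self.labels], dtype=float)

    def vector_to_values(self, theta: np.ndarray) -> dict[str, float]:
        return {l: float(t) for l, t in zip(self.labels, theta)}

    def matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        A = self.A0.copy()
        S = self.S0.copy()
        m = self.m0.copy()
        for i, j, k in self.A_fill:
            A[i, j] = theta[k]
        for i, j, k in self.S_fill:
            S[i, j] = S[j, i] = theta[k]
        for i, k in self.m_fill:
            m[i] = theta[k]
        return A, S, m

    def implied_full(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Mean vector and covariance over *all* variables (latents included)."""
        A, S, m = self.matrices(theta)
        ImA = np.eye(self.nv) - A
        try:
            B = linalg.solve(ImA, np.eye(self.nv))
        except linalg.LinAlgError:
            raise StructuralCycleError(
                f"(I - A) is singular for model {self.spec.name!r}; "
                "check the directed paths for cycles"
            )
        cov = B @ S @ B.T
        mu = B @ m
        return mu, (cov + cov.T) / 2.0

    def implied(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mu, cov = self.implied_full(theta)
        o = self.obs_idx
        return mu[o], cov[np.ix_(o, o)]


def implied_moments(
    spec: ModelSpec, values: Mapping[str, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied (mean vector, covariance matrix) over observed variables."""
    comp = CompiledModel(spec)
    return comp.implied(comp.values_to_vector(values))


# ---------------------------------------------------------------------------
# FIML likelihood over missingness patterns
# ---------------------------------------------------------------------------

_LOG2PI = math.log(2.0 * math.pi)


class PatternData:
    """Per-missingness-pattern sufficient statistics of a data matrix.

    For a pattern with observed columns ``idx`` and persons x_1..x_nk the
    FIML contribution only needs n_k, the pattern mean and the centered
    scatter matrix, so likelihood evaluations cost O(patterns), not O(n).
    """

    def __init__(self, Y: np.ndarray):
        Y = np.asarray(Y, dtype=float)
        self.n_total, self.p = Y.shape
        obs = ~np.isnan(Y)
        keep = obs.any(axis=1)
        self.n_excluded = int((~keep).sum())
        if self.n_excluded:
            warnings.warn(
                f"{self.n_excluded} person(s) with no observed scores excluded "
                "from the likelihood (they carry no information under FIML)",
                stacklevel=2,
            )
        Y = Y[keep]
        obs = obs[keep]
        self.n = Y.shape[0]
        if self.n == 0:
            raise IdentificationError("no persons with observed data")
        pats, inverse = np.unique(obs, axis=0, return_inverse=True)
        self.patterns: list[tuple[np.ndarray, int, np.ndarray, np.ndarray]] = []
        for k in range(pats.shape[0]):
            idx = np.flatnonzero(pats[k])
            rows = Y[inverse == k][:, idx]
            nk = rows.shape[0]
            mean = rows.mean(axis=0)
            d = rows - mean
            scatter = d.T @ d
            self.patterns.append((idx, nk, mean, scatter))
        self.complete = len(self.patterns) == 1 and len(self.patterns[0][0]) == self.p

    def loglik(self, mu: np.ndarray, sigma: np.ndarray) -> float:
        """FIML log-likelihood of the data under MVN(mu, sigma)."""
        total = 0.0
        for idx, nk, mean, scatter in self.patterns:
            mu_k = mu[idx]
            sig_k = sigma[np.ix_(idx, idx)]
            try:
                c, low = linalg.cho_factor(sig_k, check_finite=False)
            except linalg.LinAlgError:
                raise EstimationError(
                    "implied covariance not positive definite on the observed "
                    f"pattern with columns {idx.tolist()}"
                )
            logdet = 2.0 * np.sum(np.log(np.diag(c)))
            inv_scatter = linalg.cho_solve((c, low), scatter, check_finite=False)
            d = mean - mu_k
            quad = d @ linalg.cho_solve((c, low), d, check_finite=False)
            pk = len(idx)
            total += -0.5 * (
                nk * (pk * _LOG2PI + logdet + quad) + np.trace(inv_scatter)
            )
        return float(total)

    def casewise_loglik(
        self, Y: np.ndarray, mu: np.ndarray, sigma: np.ndarray
    ) -> np.ndarray:
        """Per-person log densities (0 for persons with nothing observed)."""
        Y = np.asarray(Y, dtype=float)
        out = np.zeros(Y.shape[0])
        for i, row in enumerate(Y):
            idx = np.flatnonzero(~np.isnan(row))
            if idx.size == 0:
                continue
            out[i] = stats.multivariate_normal.logpdf(
                row[idx], mu[idx], sigma[np.ix_(idx, idx)], allow_singular=False
            )
        return out


def fiml_loglik(
    spec: ModelSpec, values: Mapping[str, float], data
) -> float:
    """FIML log-likelihood of ``data`` under ``spec`` at ``values``.

    ``data`` may be a LongitudinalDataset or a raw (n, p) array with NaN
    for missing entries, column order matching ``spec.observed``.
    """
    comp = CompiledModel(spec)
    mu, sigma = comp.implied(comp.values_to_vector(values))
    return PatternData(_as_matrix(data, spec)).loglik(mu, sigma)


def _as_matrix(data, spec: ModelSpec | None = None) -> np.ndarray:
    if hasattr(data, "to_matrix"):
        return data.to_matrix(list(spec.observed) if spec is not None else None)
    return np.asarray(data, dtype=float)


# ---------------------------------------------------------------------------
# Saturated (unrestricted) FIML moments via EM
# ---------------------------------------------------------------------------


def saturated_moments(
    pat: PatternData, tol: float = 1e-10, max_iter: int = 1000
) -> tuple[np.ndarray, np.ndarray, float]:
    """ML (mu, Sigma) of the unrestricted MVN under the FIML criterion.

    Complete data gives the closed form in one step; with missing entries a
    standard EM iteration on the pattern sufficient statistics is run until
    the log-likelihood is stationary.  Returns (mu, Sigma, loglik).
    """
    p = pat.p
    n = pat.n
    # initial values: available-case means, pooled diagonal, zero covariances
    mu = np.zeros(p)
    var = np.ones(p)
    cnt = np.zeros(p)
    ssq = np.zeros(p)
    s1 = np.zeros(p)
    for idx, nk, mean, scatter in pat.patterns:
        s1[idx] += nk * mean
        cnt[idx] += nk
        ssq[idx] += np.diag(scatter) + nk * mean**2
    ok = cnt > 0
    mu[ok] = s1[ok] / cnt[ok]
    with np.errstate(invalid="ignore"):
        v = ssq[ok] / cnt[ok] - mu[ok] ** 2
    var[ok] = np.maximum(v, 1e-8)
    sigma = np.diag(var)

    if pat.complete:
        idx, nk, mean, scatter = pat.patterns[0]
        mu = mean.copy()
        sigma = scatter / nk
        return mu, sigma, pat.loglik(mu, sigma)

    ll_old = -np.inf
    for _ in range(max_iter):
        T1 = np.zeros(p)
        T2 = np.zeros((p, p))
        for idx, nk, mean, scatter in pat.patterns:
            mis = np.setdiff1d(np.arange(p), idx)
            sxx = scatter + nk * np.outer(mean, mean)  # raw cross-products
            if mis.size == 0:
                T1[idx] += nk * mean
                T2[np.ix_(idx, idx)] += sxx
                continue
            soo = sigma[np.ix_(idx, idx)]
            smo = sigma[np.ix_(mis, idx)]
            W = linalg.solve(soo, smo.T, assume_a="pos").T  # Sigma_mo Sigma_oo^-1
            dbar = mean - mu[idx]
            mhat_sum = nk * mu[mis] + W @ (nk * dbar)
            V = sigma[np.ix_(mis, mis)] - W @ sigma[np.ix_(idx, mis)]
            # sums of E[x_m x_o'], E[x_m x_m']
            sum_d_xo = sxx - nk * np.outer(mu[idx], mean)  # sum (x_o - mu_o) x_o'
            Emo = nk * np.outer(mu[mis], mean) + W @ sum_d_xo
            Sdd = scatter + nk * np.outer(dbar, dbar)  # sum d d'
            Emm = (
                nk * V
                + nk * np.outer(mu[mis], mu[mis])
                + np.outer(mu[mis], (W @ (nk * dbar)))
                + np.outer(W @ (nk * dbar), mu[mis])
                + W @ Sdd @ W.T
            )
            T1[idx] += nk * mean
            T1[mis] += mhat_sum
            T2[np.ix_(idx, idx)] += sxx
            T2[np.ix_(mis, idx)] += Emo
            T2[np.ix_(idx, mis)] += Emo.T
            T2[np.ix_(mis, mis)] += Emm
        mu = T1 / n
        sigma = T2 / n - np.outer(mu, mu)
        sigma = (sigma + sigma.T) / 2.0
        ll = pat.loglik(mu, sigma)
        if abs(ll - ll_old) < tol * (1.0 + abs(ll)):
            break
        ll_old = ll
    return mu, sigma, pat.loglik(mu, sigma)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Outcome of a (FI)ML fit."""

    spec: ModelSpec
    estimates: dict[str, float]
    standard_errors: dict[str, float]
    loglik: float
    loglik_saturated: float
    n_free: int
    n: int
    converged: bool
    standardized: dict[str, float]
    warnings: list[str] = field(default_factory=list)
    theta: np.ndarray | None = None
    vcov: np.ndarray | None = None
    n_groups: int = 1
    _data_matrix: np.ndarray | None = None

    def casewise_loglik(self) -> np.ndarray:
        """Per-person log-likelihood contributions at the fitted values."""
        if self._data_matrix is None:
            raise SemError("fit carries no data; casewise log-likelihood unavailable")
        comp = CompiledModel(self.spec)
        mu, sigma = comp.implied(self.theta)
        return PatternData(self._data_matrix).casewise_loglik(
            self._data_matrix, mu, sigma
        )

    @property
    def chisq(self) -> float:
        return max(2.0 * (self.loglik_saturated - self.loglik), 0.0)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_free

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_free * math.log(self.n)

    def wald_z(self, label: str) -> float:
        se = self.standard_errors.get(label, float("nan"))
        return self.estimates[label] / se

    def summary_table(self):
        import pandas as pd

        rows = []
        for l in self.estimates:
            est = self.estimates[l]
            se = self.standard_errors.get(l, float("nan"))
            z = est / se if se and se > 0 else float("nan")
            rows.append(
                {
                    "label": l,
                    "estimate": est,
                    "se": se,
                    "z": z,
                    "p": 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else float("nan"),
                }
            )
        return pd.DataFrame(rows).set_index("label")


def _neg_loglik_factory(comp: CompiledModel, pat: PatternData, scale: float):
    def nll(theta: np.ndarray) -> float:
        try:
            mu, sigma = comp.implied(theta)
            return -pat.loglik(mu, sigma) * scale
        except (EstimationError, StructuralCycleError):
            return 1e12
        except linalg.LinAlgError:
            return 1e12

    return nll


def _loglik_and_grad(
    comp: CompiledModel, pat: PatternData, theta: np.ndarray
) -> tuple[float, np.ndarray]:
    """FIML log-likelihood and its analytic gradient in one pass.

    Uses d(I-A)^{-1} = B dA B and accumulates dl/dSigma, dl/dmu over
    missingness patterns before chaining through the RAM structure, so the
    cost per free parameter is a handful of length-p dot products.
    """
    A, S, m = comp.matrices(theta)
    nv = comp.nv
    ImA = np.eye(nv) - A
    B = linalg.solve(ImA, np.eye(nv))
    o = comp.obs_idx
    Bo = B[o, :]
    sigma = Bo @ S @ Bo.T
    sigma = (sigma + sigma.T) / 2.0
    mu = Bo @ m

    p = len(o)
    Gs = np.zeros((p, p))  # dl/dSigma (full-matrix convention)
    gm = np.zeros(p)  # dl/dmu
    ll = 0.0
    for idx, nk, mean, scatter in pat.patterns:
        sig_k = sigma[np.ix_(idx, idx)]
        c, low = linalg.cho_factor(sig_k, check_finite=False)
        W = linalg.cho_solve((c, low), np.eye(len(idx)), check_finite=False)
        d = mean - mu[idx]
        Wd = W @ d
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        pk = len(idx)
        ll += -0.5 * (
            nk * (pk * _LOG2PI + logdet + d @ Wd) + np.sum(W * scatter)
        )
        Ck = scatter + nk * np.outer(d, d)
        Gk = 0.5 * (W @ Ck @ W - nk * W)
        Gs[np.ix_(idx, idx)] += Gk
        gm[idx] += nk * Wd

    # chain rule through Sigma = Bo S Bo', mu = Bo m
    M = B @ (S @ Bo.T)  # nv x p
    Bm = B @ m
    GsBo = Gs @ Bo  # p x nv: (Gs @ Bo)[:, i] = Gs @ Bo[:, i]
    gmBo = gm @ Bo  # nv: gm . Bo[:, i]
    grad = np.zeros(comp.n_free)
    for i, j, k in comp.A_fill:
        grad[k] += 2.0 * (M[j, :] @ GsBo[:, i]) + Bm[j] * gmBo[i]
    for i, j, k in comp.S_fill:
        v = Bo[:, j] @ GsBo[:, i]
        grad[k] += v if i == j else 2.0 * v
    for i, k in comp.m_fill:
        grad[k] += gmBo[i]
    return float(ll), grad


def _neg_loglik_grad_factory(comp: CompiledModel, pat: PatternData, scale: float):
    zeros = np.zeros(comp.n_free)

    def nll(theta: np.ndarray):
        try:
            ll, g = _loglik_and_grad(comp, pat, theta)
            return -ll * scale, -g * scale
        except (EstimationError, StructuralCycleError, linalg.LinAlgError):
            return 1e12, zeros

    return nll


def _minimize_with_restarts(nll, x0, *, restarts: int, seed: int, maxiter: int, jac=None):
    """Quasi-Newton minimization with jittered multi-start on failure.

    A run counts as converged when the optimizer reports success or stops
    with only a precision-loss message at a near-zero gradient (a routine
    outcome for finite-difference BFGS at a well-resolved optimum).
    """
    best = None
    best_ok = False
    rng = np.random.default_rng(seed)
    for attempt in range(restarts + 1):
        xi = x0 if attempt == 0 else x0 + rng.normal(0.0, 0.1, x0.size) * (
            1.0 + np.abs(x0)
        )
        res = optimize.minimize(
            nll, xi, method="BFGS", jac=jac,
            options={"maxiter": maxiter, "gtol": 1e-6},
        )
        ok = bool(
            (res.success or np.max(np.abs(res.jac)) < 1e-4) and res.fun < 1e11
        )
        if best is None or res.fun < best.fun - 1e-10:
            best, best_ok = res, ok
        elif ok and not best_ok and res.fun < best.fun + 1e-8:
            best, best_ok = res, ok
        if best_ok:
            break
    return best, best_ok


def fit(
    spec: ModelSpec,
    data,
    *,
    compute_se: bool = True,
    standardized: bool = True,
    restarts: int = 5,
    restart_seed: int = 20190517,
    maxiter: int = 2000,
    start: Mapping[str, float] | None = None,
) -> FitResult:
    """Fit ``spec`` to ``data`` by FIML.

    On apparent non-convergence the optimizer is restarted from up to
    ``restarts`` jittered starting points (fixed jitter seed, so fits are
    reproducible); the best achieved optimum is kept and flagged.
    """
    Y = _as_matrix(data, spec)
    comp = CompiledModel(spec)
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        pat = PatternData(Y)
    notes = [str(w.message) for w in wrec]

    if pat.n < comp.n_free:
        raise IdentificationError(
            f"cannot fit {spec.name!r}: {pat.n} persons < {comp.n_free} free parameters"
        )

    scale = 1.0 / pat.n
    x0 = comp.start_vector()
    if start is not None:
        for l, v in start.items():
            if l in comp.index:
                x0[comp.index[l]] = v

    best, converged = _minimize_with_restarts(
        _neg_loglik_grad_factory(comp, pat, scale),
        x0,
        restarts=restarts,
        seed=restart_seed,
        maxiter=maxiter,
        jac=True,
    )
    if not converged:
        notes.append(f"optimizer did not converge: {best.message}")

    theta = best.x
    loglik = -best.fun / scale
    mu_sat, sig_sat, ll_sat = saturated_moments(pat)

    estimates = comp.vector_to_values(theta)
    for l in comp.var_param_labels:
        if estimates[l] < 0:
            notes.append(f"Heywood case: variance parameter {l!r} = {estimates[l]:.4g} < 0")

    ses: dict[str, float] = {}
    vcov = None
    if compute_se and converged:
        try:
            grad_only = lambda t: _loglik_and_grad(comp, pat, t)[1]
            H = -numdiff.approx_fprime(theta, grad_only, centered=True)
            H = (H + H.T) / 2.0
            vcov = linalg.inv(H)
            dg = np.diag(vcov)
            if np.any(dg <= 0):
                notes.append("observed information not positive definite; some SEs undefined")
            with np.errstate(invalid="ignore"):
                se_vec = np.sqrt(np.where(dg > 0, dg, np.nan))
            ses = {l: float(s) for l, s in zip(comp.labels, se_vec)}
        except linalg.LinAlgError:
            notes.append("observed information singular; standard errors unavailable")
            ses = {l: float("nan") for l in comp.labels}
    else:
        ses = {l: float("nan") for l in comp.labels}

    result = FitResult(
        spec=spec,
        estimates=estimates,
        standard_errors=ses,
        loglik=loglik,
        loglik_saturated=ll_sat,
        n_free=comp.n_free,
        n=pat.n,
        converged=converged,
        standardized={},
        warnings=notes,
        theta=theta,
        vcov=vcov,
        _data_matrix=Y,
    )
    if standardized and converged:
        result.standardized = standardize(result, spec)
    return result


# ---------------------------------------------------------------------------
# Standardized solution
# ---------------------------------------------------------------------------


def _standardized_vector(comp: CompiledModel, theta: np.ndarray):
    """Standardized values of all paths and covariances, with stable keys."""
    spec = comp.spec
    _, cov = comp.implied_full(theta)
    sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    vi = {v: i for i, v in enumerate(spec.variables)}
    values = comp.vector_to_values(theta)

    keys: list[str] = []
    out: list[float] = []
    flagged: list[str] = []

    def val_of(p: Param) -> float:
        return values[p.label] if p.free else p.value

    for (src, dst), p in spec.paths.items():
        s_from, s_to = sd[vi[src]], sd[vi[dst]]
        keys.append(f"{src}->{dst}")
        if s_to <= 0:
            out.append(float("nan"))
            flagged.append(keys[-1])
        else:
            out.append(val_of(p) * s_from / s_to)
    for (a, b), p in spec.covariances.items():
        keys.append(f"{a}~~{b}")
        if a == b:
            tot = cov[vi[a], vi[a]]
            out.append(val_of(p) / tot if tot > 0 else float("nan"))
            if tot <= 0:
                flagged.append(keys[-1])
        else:
            denom = sd[vi[a]] * sd[vi[b]]
            out.append(val_of(p) / denom if denom > 0 else float("nan"))
            if denom <= 0:
                flagged.append(keys[-1])
    return keys, np.array(out), flagged


def standardize(fit_result: FitResult, spec: ModelSpec | None = None) -> dict[str, float]:
    """Standardized solution: paths scaled by sd(from)/sd(to), covariances
    to correlations, variances to proportions of total variance."""
    spec = spec or fit_result.spec
    comp = CompiledModel(spec)
    keys, vals, flagged = _standardized_vector(comp, fit_result.theta)
    if flagged:
        fit_result.warnings.append(
            f"zero implied variance; standardized value undefined for {flagged}"
        )
    return dict(zip(keys, (float(v) for v in vals)))


def standardized_with_se(fit_result: FitResult) -> dict[str, tuple[float, float]]:
    """Standardized estimates with delta-method standard errors."""
    if fit_result.vcov is None:
        raise SemError("fit has no parameter covariance; refit with compute_se=True")
    comp = CompiledModel(fit_result.spec)

    def g(theta):
        return _standardized_vector(comp, theta)[1]

    keys, vals, _ = _standardized_vector(comp, fit_result.theta)
    J = numdiff.approx_fprime(fit_result.theta, g, centered=True)
    var = np.einsum("ij,jk,ik->i", J, fit_result.vcov, J)
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.where(var > 0, var, np.nan))
    return {k: (float(v), float(s)) for k, v, s in zip(keys, vals, se)}


# ---------------------------------------------------------------------------
# Fit indices and model comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitIndices:
    chisq: float
    df: int
    p: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    cfi: float
    srmr: float
    aic: float
    bic: float


def _rmsea(chisq: float, df: int, n: int) -> float:
    if df <= 0:
        return float("nan")
    return math.sqrt(max(chisq - df, 0.0) / (df * (n - 1)))


def _rmsea_ci(chisq: float, df: int, n: int, level: float = 0.90) -> tuple[float, float]:
    if df <= 0:
        return (float("nan"), float("nan"))
    lo_q = (1.0 + level) / 2.0  # 0.95
    hi_q = (1.0 - level) / 2.0  # 0.05

    def solve(q: float) -> float:
        # find lambda >= 0 with ncx2.cdf(chisq, df, lambda) = q
        f0 = stats.ncx2.cdf(chisq, df, 1e-12) if chisq > 0 else 0.0
        if chisq <= 0 or f0 < q:
            return 0.0
        hi = max(chisq, df) + 10.0
        while stats.ncx2.cdf(chisq, df, hi) > q:
            hi *= 2.0
            if hi > 1e8:
                return float("nan")
        return optimize.brentq(
            lambda lam: stats.ncx2.cdf(chisq, df, lam) - q, 1e-12, hi
        )

    lam_lo = solve(lo_q)
    lam_hi = solve(hi_q)
    return (
        math.sqrt(lam_lo / (df * (n - 1))),
        math.sqrt(lam_hi / (df * (n - 1))) if np.isfinite(lam_hi) else float("nan"),
    )


def rmsea(chisq: float, df: int, n: int) -> float:
    """Point RMSEA from a chi-square statistic: sqrt(max(chisq-df,0)/(df(n-1)))."""
    return _rmsea(chisq, df, n)


def rmsea_ci(chisq: float, df: int, n: int, level: float = 0.90) -> tuple[float, float]:
    """RMSEA confidence bounds by inverting the noncentral chi-square CDF."""
    return _rmsea_ci(chisq, df, n, level)


def fit_baseline(spec: ModelSpec, data) -> FitResult:
    """Independence baseline: free variances and means, zero covariances.

    Under independence the FIML likelihood separates by variable, so the ML
    solution is the per-variable available-case mean and ML variance.
    """
    Y = _as_matrix(data, spec)
    pat = PatternData(Y)
    p = Y.shape[1]
    mu = np.zeros(p)
    var = np.zeros(p)
    for j in range(p):
        col = Y[:, j]
        col = col[~np.isnan(col)]
        if col.size < 2:
            raise IdentificationError(f"variable {j} has fewer than 2 observations")
        mu[j] = col.mean()
        var[j] = col.var()  # ML divisor n
    sigma = np.diag(var)
    ll = pat.loglik(mu, sigma)
    _, _, ll_sat = saturated_moments(pat)
    ests = {f"mean_{i}": float(m) for i, m in enumerate(mu)}
    ests.update({f"var_{i}": float(v) for i, v in enumerate(var)})
    return FitResult(
        spec=spec,
        estimates=ests,
        standard_errors={},
        loglik=ll,
        loglik_saturated=ll_sat,
        n_free=2 * p,
        n=pat.n,
        converged=True,
        standardized={},
    )


def _srmr(sample_mu, sample_sigma, mu, sigma, include_means: bool = False) -> float:
    sdi = np.sqrt(np.diag(sample_sigma))
    denom = np.outer(sdi, sdi)
    resid = (sample_sigma - sigma) / denom
    iu = np.triu_indices_from(resid)
    vals = list(resid[iu] ** 2)
    if include_means:
        vals += list(((sample_mu - mu) / sdi) ** 2)
    return float(np.sqrt(np.mean(vals)))


def fit_indices(
    fit_result: FitResult,
    baseline: FitResult,
    n: int | None = None,
    data=None,
    srmr_include_means: bool = False,
) -> FitIndices:
    """Absolute and incremental fit statistics for a converged fit.

    ``baseline`` is the independence model (see :func:`fit_baseline`).  The
    RMSEA uses the n-1 divisor and its 90% CI inverts the noncentral
    chi-square distribution at the 5% / 95% points.
    """
    n = n or fit_result.n
    chisq = fit_result.chisq
    df = fit_result.spec.df * fit_result.n_groups if fit_result.n_groups > 1 else fit_result.spec.df
    pval = float(stats.chi2.sf(chisq, df)) if df > 0 else float("nan")
    chisq_b = baseline.chisq
    df_b = baseline.spec.n_moments - baseline.n_free
    num = max(chisq - df, 0.0)
    den = max(chisq_b - df_b, num)
    cfi = 1.0 - (num / den if den > 0 else 0.0)

    srmr = float("nan")
    if data is not None:
        comp = CompiledModel(fit_result.spec)
        mu, sigma = comp.implied(fit_result.theta)
        pat = PatternData(_as_matrix(data, fit_result.spec))
        smu, ssig, _ = saturated_moments(pat)
        srmr = _srmr(smu, ssig, mu, sigma, include_means=srmr_include_means)

    return FitIndices(
        chisq=chisq,
        df=df,
        p=pval,
        rmsea=_rmsea(chisq, df, n),
        rmsea_ci=_rmsea_ci(chisq, df, n),
        cfi=cfi,
        srmr=srmr,
        aic=fit_result.aic,
        bic=fit_result.bic,
    )


@dataclass(frozen=True)
class LRTResult:
    delta_chisq: float
    delta_df: int
    p: float
    warning: str | None = None


def likelihood_ratio_test(restricted: FitResult, full: FitResult) -> LRTResult:
    """Likelihood-ratio test of a restricted model nested in a full model.

    Nesting is asserted by the caller; a materially negative statistic is
    reported with a warning rather than silently truncated.
    """
    delta = 2.0 * (full.loglik - restricted.loglik)
    ddf = full.n_free - restricted.n_free
    warning = None
    if delta < -1e-6:
        warning = (
            f"negative LRT statistic ({delta:.4g}): models may not be nested "
            "or one fit did not reach its optimum"
        )
    delta = max(delta, 0.0)
    p = float(stats.chi2.sf(delta, ddf)) if ddf > 0 else (1.0 if delta == 0 else float("nan"))
    return LRTResult(delta_chisq=delta, delta_df=ddf, p=p, warning=warning)


def cross_sample_z(
    beta1: float, se1: float, beta2: float, se2: float, fisher: bool = False
) -> float:
    """z statistic for comparing an estimate across two independent samples.

    Default: z = (b1 - b2) / sqrt(se1^2 + se2^2).  With ``fisher=True`` the
    estimates are Fisher-z transformed first (appropriate for
    correlation-metric parameters) with delta-method SEs.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    if fisher:
        z1, z2 = np.arctanh(beta1), np.arctanh(beta2)
        s1 = se1 / (1.0 - beta1**2)
        s2 = se2 / (1.0 - beta2**2)
        return float((z1 - z2) / math.hypot(s1, s2))
    return float((beta1 - beta2) / math.hypot(se1, se2))


# ---------------------------------------------------------------------------
# Joint (multigroup) fitting
# ---------------------------------------------------------------------------


def fit_joint(
    pairs: Sequence[tuple[ModelSpec, object]],
    *,
    compute_se: bool = False,
    restarts: int = 5,
    restart_seed: int = 20190517,
    maxiter: int = 4000,
) -> FitResult:
    """Simultaneously fit one spec per group; equality across groups is
    encoded by sharing labels between the specs.

    Returns a FitResult whose loglik / n_free / chisq refer to the joint
    model (the saturated loglik is the sum of per-group saturated values).
    """
    comps = [CompiledModel(s) for s, _ in pairs]
    pats = [PatternData(_as_matrix(d, s)) for s, d in pairs]
    labels: dict[str, float] = {}
    for comp in comps:
        for l, v in comp.spec.start_values().items():
            labels.setdefault(l, v)
    order = list(labels)
    index = {l: i for i, l in enumerate(order)}
    maps = [np.array([index[l] for l in comp.labels], dtype=int) for comp in comps]
    n_total = sum(p.n for p in pats)
    scale = 1.0 / n_total

    def nll(theta: np.ndarray) -> float:
        total = 0.0
        try:
            for comp, pat, mp in zip(comps, pats, maps):
                mu, sigma = comp.implied(theta[mp])
                total += pat.loglik(mu, sigma)
        except (EstimationError, StructuralCycleError, linalg.LinAlgError):
            return 1e12
        return -total * scale

    zeros = np.zeros(len(order))

    def nll_grad(theta: np.ndarray):
        total = 0.0
        g = np.zeros(len(order))
        try:
            for comp, pat, mp in zip(comps, pats, maps):
                ll, gg = _loglik_and_grad(comp, pat, theta[mp])
                total += ll
                np.add.at(g, mp, gg)
        except (EstimationError, StructuralCycleError, linalg.LinAlgError):
            return 1e12, zeros
        return -total * scale, -g * scale

    x0 = np.array([labels[l] for l in order])
    best, converged = _minimize_with_restarts(
        nll_grad, x0, restarts=restarts, seed=restart_seed, maxiter=maxiter, jac=True
    )
    loglik = -best.fun / scale
    ll_sat = sum(saturated_moments(p)[2] for p in pats)

    ses: dict[str, float] = {l: float("nan") for l in order}
    vcov = None
    if compute_se and converged:
        H = numdiff.approx_hess(best.x, nll) / scale
        try:
            vcov = linalg.inv(H)
            dg = np.diag(vcov)
            with np.errstate(invalid="ignore"):
                ses = {
                    l: float(np.sqrt(d)) if d > 0 else float("nan")
                    for l, d in zip(order, dg)
                }
        except linalg.LinAlgError:
            pass

    return FitResult(
        spec=pairs[0][0],
        estimates={l: float(v) for l, v in zip(order, best.x)},
        standard_errors=ses,
        loglik=loglik,
        loglik_saturated=ll_sat,
        n_free=len(order),
        n=n_total,
        converged=converged,
        standardized={},
        warnings=[] if converged else [f"joint optimizer did not converge: {best.message}"],
        theta=best.x,
        vcov=vcov,
        n_groups=len(pairs),
    )
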